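"""Probe tables, intensity normalization, and 8-mer median summaries.

A protein-binding microarray (PBM) measures the fluorescence of a TF bound
to tens of thousands of double-stranded DNA probes.  This module reads and
writes the plain-text probe tables, applies the standard z-score-of-log
normalization, and condenses a probe table into per-8-mer median
intensities — the summary used to compare two arrays of different probe
design that share the same 8-mer universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _encode
from .errors import DegenerateInputError, DomainError, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass
class ProbeRecord:
    """One array spot: identifier, probe sequence, signal, optional background."""

    probe_id: str
    sequence: str
    signal: float
    background: Optional[float] = None


@dataclass
class ProbeTable:
    """Ordered collection of probes from a single array.

    Stored column-wise (lists/arrays) so numerical code can operate on the
    whole table; iteration yields :class:`ProbeRecord` views.
    """

    probe_ids: list[str]
    sequences: list[str]
    signal: np.ndarray
    background: Optional[np.ndarray] = None
    array_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
        if len(self.probe_ids) == 0:
            raise EmptyInputError("probe table is empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("probe_ids are not unique")
        if not (len(self.probe_ids) == len(self.sequences) == len(self.signal)):
            raise FormatError("probe table columns have unequal lengths")
        if np.any(self.signal <= 0):
            raise DomainError("signal intensities must be positive")
        if self.background is not None and np.any(self.background <= 0):
            raise DomainError("background intensities must be positive")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __iter__(self) -> Iterator[ProbeRecord]:
        for i in range(len(self)):
            yield ProbeRecord(
                self.probe_ids[i],
                self.sequences[i],
                float(self.signal[i]),
                None if self.background is None else float(self.background[i]),
            )

    @property
    def has_background(self) -> bool:
        return self.background is not None

    def normalized_signal(self) -> np.ndarray:
        """Z-score of log signal (see :func:`normalize_intensities`)."""
        return normalize_intensities(self.signal)

    def normalized_background(self) -> np.ndarray:
        if self.background is None:
            raise DomainError("probe table has no background column")
        return normalize_intensities(self.background)

    def encoded(self) -> np.ndarray:
        """Integer-encoded sequence matrix (requires equal probe lengths)."""
        return _encode.encode_sequences(self.sequences)


@dataclass
class KmerIntensityTable:
    """Canonical k-mer -> median normalized intensity for one array."""

    intensities: "pd.Series"  # index: k-mer strings, sorted
    array_id: str = ""
    k: int = 8

    def __post_init__(self):
        self.intensities = pd.Series(self.intensities, dtype=float).sort_index()
        if len(self.intensities) == 0:
            raise EmptyInputError("k-mer table is empty")
        bad = [s for s in self.intensities.index if len(s) != self.k]
        if bad:
            raise FormatError(f"k-mer of wrong length: {bad[0]!r}")

    def __len__(self) -> int:
        return len(self.intensities)


_DEFAULT_DIALECT = {"id": "probe_id", "sequence": "sequence",
                    "signal": "signal", "background": "background"}


def read_probe_table(path, dialect: Optional[Mapping[str, str]] = None,
                     array_id: str = "") -> ProbeTable:
    """Read a tab-separated probe table.

    Required columns: probe id, sequence, signal; optional background.
    ``dialect`` maps the logical names {id, sequence, signal, background}
    to the file's column headers.  Rows whose sequence contains characters
    outside ACGT are dropped (the energy model has no ambiguity states);
    the dropped count is logged.
    """
    names = dict(_DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical in ("id", "sequence", "signal"):
        if names[logical] not in df.columns:
            raise FormatError(f"missing required column {names[logical]!r} in {path}")
    seqs = df[names["sequence"]].str.upper()
    ok = seqs.map(lambda s: isinstance(s, str) and set(s) <= _VALID)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d probes with non-ACGT sequences from %s", n_dropped, path)
    df = df[ok]
    if len(df) == 0:
        raise EmptyInputError(f"no valid probes in {path}")
    background = None
    if names["background"] in df.columns:
        background = df[names["background"]].astype(float).to_numpy()
    return ProbeTable(
        probe_ids=df[names["id"]].tolist(),
        sequences=seqs[ok].tolist(),
        signal=df[names["signal"]].astype(float).to_numpy(),
        background=background,
        array_id=array_id or str(path),
    )


def write_probe_table(table: ProbeTable, path) -> None:
    data = {"probe_id": table.probe_ids, "sequence": table.sequences,
            "signal": table.signal}
    if table.background is not None:
        data["background"] = table.background
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def normalize_intensities(values) -> np.ndarray:
    """Z-score transformation of log intensities: (ln v − mean) / sd.

    Uses the natural log and the sample (n−1) standard deviation; the
    result has sample mean 0 and sample sd 1.  The log base is immaterial
    because the z-score divides it out.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise DomainError("need a 1-D vector of length >= 2")
    if np.any(v <= 0):
        raise DomainError("intensities must be positive for log transform")
    logv = np.log(v)
    sd = logv.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance after log transform")
    return (logv - logv.mean()) / sd


def kmer_median_intensities(probes: ProbeTable, k: int = 8,
                            collapse_rc: bool = True) -> KmerIntensityTable:
    """Median normalized signal over all probes containing each k-mer.

    A probe contributes at most one observation per k-mer even if the
    k-mer occurs several times (or on both strands) within it.  With
    ``collapse_rc`` a k-mer and its reverse complement are pooled under the
    lexicographically smaller of the two; otherwise only forward-strand
    occurrences are counted under their literal k-mer.
    """
    if any(len(s) < k for s in probes.sequences):
        raise DomainError(f"all probe sequences must be at least {k} long")
    norm = probes.normalized_signal()
    X = probes.encoded()
    W = _encode.window_view(X, k)          # (n, w, k)
    if collapse_rc:
        codes = _encode.canonical_kmer_codes(W)
    else:
        codes = _encode.kmer_codes(W)
    n, w = codes.shape
    probe_idx = np.repeat(np.arange(n, dtype=np.int64), w)
    flat = codes.reshape(-1)
    keep = flat >= 0
    # one observation per (probe, k-mer) pair
    pair = np.unique(probe_idx[keep] * (4 ** k) + flat[keep])
    p_of = pair // (4 ** k)
    c_of = pair % (4 ** k)
    med = pd.Series(norm[p_of]).groupby(c_of).median()
    med.index = [_encode.code_to_kmer(int(c), k) for c in med.index]
    return KmerIntensityTable(intensities=med, array_id=probes.array_id, k=k)


def match_paired_kmers(table_a: KmerIntensityTable,
                       table_b: KmerIntensityTable) -> tuple[np.ndarray, np.ndarray]:
    """Intensities over the shared k-mers of two arrays, re-z-scored.

    Returns ``(x1, x2)`` in sorted-key order.  Each vector is z-scored
    (mean 0, sample sd 1) after restriction to the intersection so the two
    arrays are on a common scale regardless of how many k-mers they share.
    """
    shared = table_a.intensities.index.intersection(table_b.intensities.index)
    if len(shared) == 0:
        raise EmptyInputError("k-mer tables share no keys")
    shared = shared.sort_values()
    x1 = table_a.intensities.loc[shared].to_numpy()
    x2 = table_b.intensities.loc[shared].to_numpy()

    def _z(x):
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("zero variance in paired k-mer intensities")
        return (x - x.mean()) / sd

    return _z(x1), _z(x2)


def read_kmer_table(path, array_id: str = "", k: int = 8) -> KmerIntensityTable:
    """Read a TSV with header ``kmer<TAB>intensity``."""
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str})
    if "kmer" not in df.columns or "intensity" not in df.columns:
        raise FormatError(f"expected columns kmer, intensity in {path}")
    ser = pd.Series(df["intensity"].astype(float).to_numpy(),
                    index=df["kmer"].str.upper())
    return KmerIntensityTable(intensities=ser, array_id=array_id or str(path), k=k)


def write_kmer_table(table: KmerIntensityTable, path) -> None:
    pd.DataFrame({"kmer": table.intensities.index,
                  "intensity": table.intensities.to_numpy()}
                 ).to_csv(path, sep="\t", index=False)
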