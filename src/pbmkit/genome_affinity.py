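"""Scanning genomic peaks with an energy model and affinity regression.

A fitted (or PWM-converted) energy model is slid over the central 200 bp
of each ChIP-seq peak, summing Fermi–Dirac occupancies over both strands
to give a predicted binding affinity.  An ordinary least-squares
regression of the observed tag counts on those affinities then tests
whether in-vitro-derived energetics explain in-vivo occupancy; the slope
t-statistic and √R² summarize the dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import _encode
from .energy_model import BindingModel, EnergyMatrix, probe_occupancy
from .errors import DegenerateInputError, DomainError, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """A called peak (0-based, half-open) with its sequencing tag count."""

    chrom: str
    start: int
    end: int
    tag_count: int

    def __post_init__(self):
        if self.end <= self.start:
            raise DomainError(f"peak end must exceed start: {self}")
        if self.tag_count < 0:
            raise DomainError("tag count must be nonnegative")


@dataclass(frozen=True)
class AffinityRegression:
    """OLS summary of tag counts on predicted affinities."""

    slope: float
    t_value: float
    r: float          # sqrt of R-square
    n: int


def read_bed4(path) -> list[Peak]:
    """Read peaks from BED4: chrom, start, end, tag_count."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "tag_count"],
                     dtype={"chrom": str})
    if df.isna().any().any():
        raise FormatError(f"malformed BED4 file: {path}")
    return [Peak(r.chrom, int(r.start), int(r.end), int(r.tag_count))
            for r in df.itertuples()]


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> uppercase sequence mapping."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def pwm_to_energy(pwm, pseudocount: float = 1e-6) -> EnergyMatrix:
    """Convert base probabilities to binding energies.

    E[i, a] = ln((f[i,a] + ε) / (max_b f[i,b] + ε)).  Every entry is ≤ 0
    with the consensus base at exactly 0, so the magnitude of the negative
    entries tracks the motif's information content and the
    :func:`~pbmkit.energy_model.energy_level` summary applies directly.
    The pseudocount ε keeps zero probabilities finite.
    """
    f = np.asarray(pwm, dtype=float)
    if f.ndim != 2 or f.shape[1] != 4:
        raise DomainError("PWM must be L x 4")
    if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-6):
        raise DomainError("PWM rows must be nonnegative and sum to 1")
    top = f.max(axis=1, keepdims=True)
    E = np.log((f + pseudocount) / (top + pseudocount))
    return EnergyMatrix(E)


def central_window(peak: Peak, window_bp: int = 200) -> tuple[int, int]:
    """Coordinates of the central window: midpoint ⌊(start+end)/2⌋ ± half,
    clipped to the peak."""
    if peak.end - peak.start <= window_bp:
        return peak.start, peak.end
    mid = (peak.start + peak.end) // 2
    lo = max(peak.start, mid - window_bp // 2)
    return lo, lo + window_bp


def peak_affinity(model: BindingModel, genome: Mapping[str, str], peak: Peak,
                  window_bp: int = 200) -> float:
    """Σ P(S) over all sliding windows (both strands) of the central
    ``window_bp`` of the peak; computed with w1 = 1, b1 = 0 so the value
    is a pure occupancy sum.  Windows containing ambiguous bases are
    skipped; a peak shorter than the motif scores 0 with a warning.
    """
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} not in sequence source")
    lo, hi = central_window(peak, window_bp)
    seq = genome[peak.chrom][lo:hi]
    if len(seq) < model.L:
        logger.warning("peak %s:%d-%d shorter than motif; affinity 0",
                       peak.chrom, peak.start, peak.end)
        return 0.0
    scan_model = replace(model, w1=1.0, b1=0.0)
    return probe_occupancy(scan_model, seq, both_strands=True)


def top_bottom_selection(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """Top-n plus bottom-n peaks by tag count (descending, stable ties)."""
    peaks = list(peaks)
    if n < 0 or 2 * n > len(peaks):
        raise DomainError(f"n = {n} too large for {len(peaks)} peaks")
    if n == 0:
        return []
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].tag_count, i))
    chosen = order[:n] + order[-n:]
    return [peaks[i] for i in chosen]


def affinity_regression(affinities, tag_counts) -> AffinityRegression:
    """OLS of tag counts on affinities (with intercept): slope, t, √R²."""
    x = np.asarray(affinities, dtype=float)
    y = np.asarray(tag_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("need equal-length vectors of length >= 3")
    if x.std() == 0:
        raise DegenerateInputError("zero variance in affinities")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return AffinityRegression(slope=float(res.params[1]),
                              t_value=float(res.tvalues[1]),
                              r=float(np.sqrt(max(res.rsquared, 0.0))),
                              n=len(x))


def scan_peaks(model: BindingModel, genome: Mapping[str, str],
               peaks: Sequence[Peak], window_bp: int = 200) -> pd.DataFrame:
    """Affinity of every peak, as a tidy frame ready for regression."""
    rows = [(p.chrom, p.start, p.end, p.tag_count,
             peak_affinity(model, genome, p, window_bp)) for p in peaks]
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "tags", "affinity"])
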