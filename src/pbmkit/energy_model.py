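"""Biophysical occupancy model of TF-DNA binding.

A TF bound to a length-L window S has free energy
``E(S) = Σ_i E[i, S_i] + Σ_j D[j, (S_j, S_{j+1})]`` — a position-specific
mononucleotide energy matrix plus an optional adjacent-dinucleotide
correction (16 parameters per adjacent pair, 16(L−1) in total).  The
two-state (Fermi–Dirac) occupancy of the window is
``P(S) = 1 / (1 + exp(E(S) − μ))`` with chemical potential μ set by the
TF concentration: lower energy means stronger binding, and P = 1/2 when
E(S) = μ.  A probe's predicted intensity sums window occupancies over
both strands through a linear output unit, ``Y = w1·Σ P(S) + b1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from . import _encode
from .errors import DomainError, FormatError, UndefinedMetricError
from .pbm_io import ProbeTable

BASES = _encode.BASES


@dataclass
class EnergyMatrix:
    """L×4 interaction energies, columns ordered A,C,G,T (k_BT units)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise DomainError("energy matrix must be L x 4")
        if self.matrix.shape[0] < 2:
            raise DomainError("motif length must be >= 2")
        if not np.isfinite(self.matrix).all():
            raise DomainError("energy matrix must be finite")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DinucCorrection:
    """(L−1)×16 adjacent-pair energy corrections.

    Row j covers positions (j, j+1) (0-based); the pair (a, b) is indexed
    as 4·code(a) + code(b) with A,C,G,T -> 0..3.
    """

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 16:
            raise DomainError("dinucleotide correction must be (L-1) x 16")
        if not np.isfinite(self.matrix).all():
            raise DomainError("dinucleotide correction must be finite")

    @property
    def L(self) -> int:
        return self.matrix.shape[0] + 1


@dataclass
class BindingModel:
    """Energy matrix, optional dinucleotide correction, μ, and output layer."""

    energy: EnergyMatrix
    dinuc: Optional[DinucCorrection] = None
    mu: float = 0.0
    w1: float = 1.0
    b1: float = 0.0

    def __post_init__(self):
        if self.dinuc is not None and self.dinuc.L != self.energy.L:
            raise DomainError("dinucleotide correction length does not match motif")

    @property
    def L(self) -> int:
        return self.energy.L

    @property
    def dependent(self) -> bool:
        return self.dinuc is not None


def _encode_window(model: BindingModel, window: str) -> np.ndarray:
    codes = _encode.encode_sequence(window)
    if len(codes) != model.L:
        raise DomainError(f"window length {len(codes)} != motif length {model.L}")
    if (codes < 0).any():
        raise DomainError("window contains non-ACGT characters")
    return codes


def window_energy(model: BindingModel, window: str) -> float:
    """E(S) of one window: mononucleotide sum plus adjacent-pair corrections."""
    codes = _encode_window(model, window)
    e = float(model.energy.matrix[np.arange(model.L), codes].sum())
    if model.dinuc is not None:
        pair = 4 * codes[:-1] + codes[1:]
        e += float(model.dinuc.matrix[np.arange(model.L - 1), pair].sum())
    return e


def binding_probability(model: BindingModel, window: str) -> float:
    """Fermi–Dirac occupancy P(S) = 1/(1 + exp(E(S) − μ)); overflow-safe."""
    return float(expit(model.mu - window_energy(model, window)))


def _flat_params(model: BindingModel) -> tuple[np.ndarray, Optional[np.ndarray]]:
    e = model.energy.matrix.reshape(-1)
    d = None if model.dinuc is None else model.dinuc.matrix.reshape(-1)
    return e, d


def occupancy_from_design(model: BindingModel, probe_idx: np.ndarray,
                          mono_idx: np.ndarray, pair_idx: np.ndarray,
                          n_probes: int) -> tuple[np.ndarray, np.ndarray]:
    """(window occupancies P, per-probe sums ΣP) for precomputed windows."""
    e_flat, d_flat = _flat_params(model)
    E_win = e_flat[mono_idx].sum(axis=1)
    if d_flat is not None:
        E_win += d_flat[pair_idx].sum(axis=1)
    P = expit(model.mu - E_win)
    sums = np.bincount(probe_idx, weights=P, minlength=n_probes)
    return P, sums


def probe_occupancy(model: BindingModel, sequence: str,
                    both_strands: bool = True) -> float:
    """Predicted intensity of one probe: Y = w1·Σ_windows P(S) + b1.

    Windows slide by one base over the sequence and, with ``both_strands``
    (the default — PBM probes are double-stranded), over its reverse
    complement as well.  Windows containing ambiguous bases are skipped.
    """
    codes = _encode.encode_sequence(sequence)
    if len(codes) < model.L:
        raise DomainError("sequence shorter than the motif")
    probe_idx, mono_idx, pair_idx = _encode.window_design(
        codes[None, :], model.L, both_strands=both_strands)
    _, sums = occupancy_from_design(model, probe_idx, mono_idx, pair_idx, 1)
    return float(model.w1 * sums[0] + model.b1)


def predict_intensities(model: BindingModel, probes: ProbeTable,
                        both_strands: bool = True) -> np.ndarray:
    """Predicted intensities for every probe, in probe order."""
    lengths = {len(s) for s in probes.sequences}
    if min(lengths) < model.L:
        raise DomainError("some probes are shorter than the motif")
    if len(lengths) == 1:
        X = probes.encoded()
        probe_idx, mono_idx, pair_idx = _encode.window_design(
            X, model.L, both_strands=both_strands)
        _, sums = occupancy_from_design(model, probe_idx, mono_idx, pair_idx,
                                        len(probes))
        return model.w1 * sums + model.b1
    return np.array([probe_occupancy(model, s, both_strands)
                     for s in probes.sequences])


def num_parameters(L: int, dependent: bool) -> int:
    """Free parameters: 4L energies + μ + w1 + b1, plus 16(L−1) pair terms."""
    if L < 2:
        raise DomainError("motif length must be >= 2")
    n = 4 * L + 3
    if dependent:
        n += 16 * (L - 1)
    return n


def energy_level(matrix: EnergyMatrix) -> float:
    """Motif energy-level summary: ln(−median of the negative energies).

    Strong (informative) motifs have deep negative energies at their
    preferred bases, so this statistic tracks motif information content.
    """
    neg = matrix.matrix[matrix.matrix < 0]
    if neg.size == 0:
        raise UndefinedMetricError("energy matrix has no negative entries")
    return float(np.log(-np.median(neg)))


# ---------------------------------------------------------------------------
# PBEM text format

def write_pbem(model: BindingModel, path) -> None:
    """Write the protein-binding energy matrix text format.

    Header ``#L=<int> mu=<float> w1=<float> b1=<float>``, then L rows of 4
    tab-separated energies (A C G T), then optionally ``#dinuc`` and L−1
    rows of 16 energies.
    """
    with open(path, "w") as fh:
        fh.write(f"#L={model.L} mu={model.mu!r} w1={model.w1!r} b1={model.b1!r}\n")
        for row in model.energy.matrix:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
        if model.dinuc is not None:
            fh.write("#dinuc\n")
            for row in model.dinuc.matrix:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_pbem(path) -> BindingModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#L="):
        raise FormatError("PBEM file must start with a '#L=' header")
    header = dict(item.split("=", 1) for item in lines[0][1:].split())
    try:
        L = int(header["L"])
        mu = float(header["mu"])
        w1 = float(header["w1"])
        b1 = float(header["b1"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed PBEM header: {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) < L:
        raise FormatError("PBEM file truncated")
    E = np.array([[float(x) for x in body[i].split("\t")] for i in range(L)])
    dinuc = None
    rest = body[L:]
    if rest:
        if rest[0] != "#dinuc":
            raise FormatError("unexpected content after energy matrix")
        if len(rest) != L:
            raise FormatError("dinucleotide block must have L-1 rows")
        D = np.array([[float(x) for x in rest[1 + j].split("\t")]
                      for j in range(L - 1)])
        dinuc = DinucCorrection(D)
    return BindingModel(energy=EnergyMatrix(E), dinuc=dinuc, mu=mu, w1=w1, b1=b1)


def reverse_complement_model(model: BindingModel) -> BindingModel:
    """The same model read on the opposite strand."""
    E = model.energy.matrix[::-1, ::-1].copy()
    dinuc = None
    if model.dinuc is not None:
        D = model.dinuc.matrix
        L1 = D.shape[0]
        Drc = np.empty_like(D)
        for j in range(L1):
            for a in range(4):
                for b in range(4):
                    # pair (a,b) at (j, j+1) reads as (comp b, comp a) at
                    # positions (L-2-j, L-1-j) on the other strand
                    Drc[L1 - 1 - j, 4 * (3 - b) + (3 - a)] = D[j, 4 * a + b]
        dinuc = DinucCorrection(Drc)
    return BindingModel(energy=EnergyMatrix(E), dinuc=dinuc,
                        mu=model.mu, w1=model.w1, b1=model.b1)
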