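"""Synthetic PBM experiments with a known ground-truth binding model.

The generators emulate the designs the analysis modules target: a single
array measured from a known energy model with Gaussian noise, a
training/testing array pair on disjoint probe designs with controllable
agreement, and clusterable QC feature sets with planted labels.  Probe
intensities are built on the normalized (log) scale — the latent value is
T_i = Y_i(truth) + ε_i — and stored as exp(latent) so the positive-signal
invariant holds and the z-of-log normalization recovers the latent scale
exactly.

Bad-quality paired arrays receive an 8-mer-level multiplicative bias:
every canonical 8-mer draws a log-scale bias, and a probe's latent value
shifts by the sum of its constituent 8-mers' biases scaled by
1/√(#8-mers), giving a per-probe disturbance of sd ``array_bias_sd`` that
is correlated across probes sharing 8-mers — the simplest mechanism that
selectively destroys paired 8-mer agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _encode
from .cluster import FeatureMatrix
from .energy_model import (BindingModel, DinucCorrection, EnergyMatrix,
                           predict_intensities)
from .errors import DomainError
from .pbm_io import ProbeTable


@dataclass
class SimConfig:
    """Conditions of one simulated PBM experiment."""

    truth: BindingModel
    n_probes: int = 10000
    probe_length: int = 35
    noise_sd: float = 0.2
    array_bias_sd: float = 0.0      # 0 = good quality
    seed: int = 0
    background_fraction: float = 0.1
    background_noise_sd: float = 0.5

    def __post_init__(self):
        if self.probe_length < self.truth.L:
            raise DomainError("probes must be at least as long as the motif")
        if self.noise_sd < 0 or self.array_bias_sd < 0:
            raise DomainError("noise levels must be nonnegative")


def sample_probe_sequences(n: int, length: int, seed: int = 0) -> list[str]:
    """n i.i.d. uniform-ACGT sequences; deterministic given seed."""
    if n <= 0 or length < 1:
        raise DomainError("n and length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(_encode.BASES[c] for c in row) for row in codes]


def make_binding_model(L: int = 8, seed: int = 0,
                       penalty_range: tuple[float, float] = (0.5, 1.5),
                       mu: Optional[float] = None,
                       dinuc_entries: Optional[dict] = None) -> BindingModel:
    """A random ground-truth model: consensus at energy 0, mismatch
    penalties drawn uniformly from ``penalty_range``.

    The default penalties (0.5–1.5 k_BT per mismatch) with μ = L/2 give a
    moderate-affinity motif whose occupancy varies smoothly over random
    probes.  ``dinuc_entries`` maps ``(position j, (base_a, base_b))`` to
    a pair energy, planting adjacent-base interdependence.
    """
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=L)
    E = rng.uniform(*penalty_range, size=(L, 4))
    E[np.arange(L), consensus] = 0.0
    dinuc = None
    if dinuc_entries:
        D = np.zeros((L - 1, 16))
        for (j, (a, b)), energy in dinuc_entries.items():
            ia = _encode.BASES.index(a) if isinstance(a, str) else int(a)
            ib = _encode.BASES.index(b) if isinstance(b, str) else int(b)
            D[j, 4 * ia + ib] = energy
        dinuc = DinucCorrection(D)
    return BindingModel(energy=EnergyMatrix(E), dinuc=dinuc,
                        mu=L / 2.0 if mu is None else mu)


def model_consensus(model: BindingModel) -> np.ndarray:
    """Lowest-energy base per position of the truth matrix."""
    return model.energy.matrix.argmin(axis=1)


def sharp_truth(L: int = 8, seed: int = 0) -> BindingModel:
    """A high-specificity truth motif (2.5–3.5 k_BT per mismatch, μ = L/2).

    Only near-consensus 8-mers bind, concentrating the signal in a small
    k-mer set — the regime where per-8-mer median intensities are well
    determined, used for paired-array agreement studies.
    """
    return make_binding_model(L=L, seed=seed, penalty_range=(2.5, 3.5),
                              mu=L / 2.0)


def interdependent_truth(L: int = 8, seed: int = 1, mu: float = 2.5,
                         pair_energy: float = -2.0,
                         position: Optional[int] = None) -> BindingModel:
    """A moderate motif with one strong adjacent-pair interaction.

    The pair energy is planted on a *non-consensus* dinucleotide at the
    motif core, creating an alternative recognition mode that no
    mononucleotide matrix can express (a separable compensation would
    wrongly boost every sequence carrying either base alone).  The
    chemical potential sits below the default so near-consensus windows
    are not saturated — saturation would hide the interaction entirely.
    """
    base = make_binding_model(L=L, seed=seed, mu=mu)
    cons = model_consensus(base)
    j = L // 2 if position is None else position
    pair = ((int(cons[j]) + 1) % 4, (int(cons[j + 1]) + 2) % 4)
    return make_binding_model(L=L, seed=seed, mu=mu,
                              dinuc_entries={(j, pair): pair_energy})


def paired_qc_config(seed: int, quality_bias_sd: float = 1.0) -> SimConfig:
    """Canonical conditions for paired-array agreement experiments.

    Array-scale designs (40,000 probes, the size of real universal PBM
    designs), a high-specificity truth, low measurement noise (the 8-mer
    medians of real arrays are averages of dozens of spots), and a
    log-scale 8-mer bias of sd 1 for the bad-quality arm.
    """
    return SimConfig(truth=sharp_truth(), n_probes=40000, noise_sd=0.02,
                     array_bias_sd=quality_bias_sd, seed=seed)


def _kmer_bias_shift(sequences: list[str], bias_sd: float, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-probe latent shift from canonical-k-mer biases, sd = bias_sd."""
    biases = rng.standard_normal(4 ** k)
    X = _encode.encode_sequences(sequences)
    codes = _encode.canonical_kmer_codes(_encode.window_view(X, k))
    total = biases[codes].sum(axis=1)
    return bias_sd * total / np.sqrt(codes.shape[1])


def simulate_pbm(config: SimConfig, array_id: str = "sim") -> ProbeTable:
    """One simulated array: latent T_i = Y_i(truth) + ε_i, ε ~ N(0, σ²).

    Background latents are independent noise plus a small fraction of the
    signal latent, mimicking optical bleed-through.  Signals are stored as
    exp(latent − mean latent); the shift is immaterial after z-of-log
    normalization and keeps the exponentials in range.
    """
    rng = np.random.default_rng(config.seed)
    seqs = sample_probe_sequences(config.n_probes, config.probe_length,
                                  seed=int(rng.integers(2 ** 31)))
    table = ProbeTable(probe_ids=[f"{array_id}_{i}" for i in range(len(seqs))],
                       sequences=seqs, signal=np.ones(len(seqs)),
                       array_id=array_id)
    Y = predict_intensities(config.truth, table)
    latent = Y + config.noise_sd * rng.standard_normal(len(seqs))
    if config.array_bias_sd > 0:
        latent = latent + _kmer_bias_shift(seqs, config.array_bias_sd, 8, rng)
    bg_latent = (config.background_noise_sd * rng.standard_normal(len(seqs))
                 + config.background_fraction * latent)
    return ProbeTable(
        probe_ids=table.probe_ids, sequences=seqs,
        signal=np.exp(latent - latent.mean()),
        background=np.exp(bg_latent - bg_latent.mean()),
        array_id=array_id)


def simulate_paired_pbm(config: SimConfig,
                        quality: str = "good") -> tuple[ProbeTable, ProbeTable]:
    """A training/testing pair on disjoint probe designs, same truth.

    ``quality="good"`` uses no array bias; ``"bad"`` applies the 8-mer
    bias (sd ``config.array_bias_sd``, default 1.0 if the config left it
    at 0) to the second array only, degrading 8-mer agreement while
    preserving each array's own dynamic range.
    """
    if quality not in ("good", "bad"):
        raise DomainError("quality must be 'good' or 'bad'")
    bias = 0.0
    if quality == "bad":
        bias = config.array_bias_sd if config.array_bias_sd > 0 else 1.0
    cfg_a = replace(config, array_bias_sd=0.0, seed=config.seed)
    cfg_b = replace(config, array_bias_sd=bias, seed=config.seed + 1)
    return (simulate_pbm(cfg_a, array_id=f"train_{quality}"),
            simulate_pbm(cfg_b, array_id=f"test_{quality}"))


def simulate_qc_features(n_items: int, separation: float,
                         seed: int = 0) -> FeatureMatrix:
    """Two planted clusters in (major, minor) QC-feature space.

    Cluster means are ``separation`` apart (in units of the within-
    cluster sd) along the direction (larger major axis, smaller minor
    axis), so the planted "good" group looks like long, narrow ellipses.
    Labels: 1 = good, 0 = bad, stored in ``planted_labels``.
    """
    if n_items < 4:
        raise DomainError("need at least 4 items")
    rng = np.random.default_rng(seed)
    n_good = (n_items + 1) // 2
    u = np.array([1.0, -1.0]) / np.sqrt(2.0)
    centers = np.where(np.arange(n_items)[:, None] < n_good,
                       separation / 2.0 * u, -separation / 2.0 * u)
    values = centers + rng.standard_normal((n_items, 2))
    labels = (np.arange(n_items) < n_good).astype(int)
    return FeatureMatrix.from_raw(values,
                                  item_ids=[f"item_{i}" for i in range(n_items)],
                                  columns=["major", "minor"],
                                  planted_labels=labels)
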