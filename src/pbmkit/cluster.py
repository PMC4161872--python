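"""Fuzzy neural-gas classification of arrays into quality groups.

TFs (or arrays) are described by their QC parameters — typically the
major and minor axis lengths of the paired-array control ellipse — and
partitioned into two clusters by a neural-gas procedure: prototypes adapt
under rank-based soft-max weights h(r) = exp(−r/λ) with λ annealed
geometrically, and final fuzzy memberships follow the inverse-squared-
distance rule of fuzzy c-means.  Because the optimum is seed-dependent,
the classification is repeated (ten runs by default) and consolidated by
majority vote after aligning labels across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError

_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Items × QC-parameter matrix, standardized per column."""

    values: np.ndarray
    item_ids: list[str]
    columns: list[str]
    planted_labels: Optional[np.ndarray] = None   # ground truth, synthetic data

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise DomainError("feature matrix contains non-finite values")

    @classmethod
    def from_raw(cls, values, item_ids, columns, planted_labels=None):
        """Standardize columns to zero mean, unit (sample) variance."""
        v = np.asarray(values, dtype=float)
        sd = v.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return cls((v - v.mean(axis=0)) / sd, list(item_ids), list(columns),
                   planted_labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterResult:
    prototypes: np.ndarray          # k x d
    memberships: np.ndarray         # n x k, rows sum to 1
    hard_labels: np.ndarray         # argmax membership
    run_labels: Optional[np.ndarray] = None   # n_runs x n, for consensus
    quality_map: Optional[dict] = None        # cluster index -> "good"/"bad"

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]


def _memberships(X: np.ndarray, prototypes: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, _EPS)
    u = d2 ** (-1.0 / (m - 1.0))
    return u / u.sum(axis=1, keepdims=True)


def fuzzy_neural_gas(features: FeatureMatrix, k: int = 2, seed: int = 0,
                     epochs: int = 100, lambda0: Optional[float] = None,
                     lambda_final: float = 0.01, m: float = 2.0) -> ClusterResult:
    """Cluster items into k groups with graded memberships.

    Each epoch ranks the prototypes by distance for every item and moves
    each prototype to the h-weighted mean of the data, h = exp(−rank/λ);
    λ anneals geometrically from ``lambda0`` (default k/2) to
    ``lambda_final``, ending close to winner-take-all.  Memberships use
    the fuzzy-c-means rule with fuzzifier ``m``.
    """
    X = features.values
    n = X.shape[0]
    if n < k:
        raise DomainError(f"need at least {k} items")
    if lambda0 is None:
        lambda0 = k / 2.0
    rng = np.random.default_rng(seed)
    prototypes = X[rng.choice(n, size=k, replace=False)].copy()
    denom = max(epochs - 1, 1)
    for t in range(epochs):
        lam = lambda0 * (lambda_final / lambda0) ** (t / denom)
        d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
        ranks = np.argsort(np.argsort(d2, axis=1), axis=1)
        h = np.exp(-ranks / lam)
        weights = h.sum(axis=0)
        weights[weights == 0] = _EPS
        prototypes = (h.T @ X) / weights[:, None]
    u = _memberships(X, prototypes, m)
    return ClusterResult(prototypes=prototypes, memberships=u,
                         hard_labels=u.argmax(axis=1))


def _align_to_reference(ref_protos: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Permutation mapping each prototype to its nearest reference prototype.

    For k = 2 this is exact; for larger k it is greedy by distance.
    """
    k = ref_protos.shape[0]
    d = ((protos[:, None, :] - ref_protos[None, :, :]) ** 2).sum(axis=2)
    perm = np.full(k, -1)
    used = set()
    for i in np.argsort(d.min(axis=1)):
        choices = np.argsort(d[i])
        for c in choices:
            if c not in used:
                perm[i] = c
                used.add(c)
                break
    return perm


def consensus_clustering(features: FeatureMatrix, k: int = 2,
                         n_runs: int = 10, base_seed: int = 0,
                         **kwargs) -> ClusterResult:
    """Average of repeated classifications.

    Runs :func:`fuzzy_neural_gas` with seeds ``base_seed .. base_seed +
    n_runs − 1``, aligns cluster labels across runs by prototype matching
    against the first run, and assigns each item its majority hard label
    and mean membership.
    """
    runs = [fuzzy_neural_gas(features, k=k, seed=base_seed + r, **kwargs)
            for r in range(n_runs)]
    ref = runs[0]
    n = features.n
    votes = np.zeros((n, k))
    mean_u = np.zeros((n, k))
    aligned_labels = np.zeros((n_runs, n), dtype=int)
    proto_sum = np.zeros_like(ref.prototypes)
    for ri, run in enumerate(runs):
        perm = _align_to_reference(ref.prototypes, run.prototypes)
        labels = perm[run.hard_labels]
        aligned_labels[ri] = labels
        for c in range(k):
            votes[labels == c, c] += 1
            mean_u[:, perm[c]] += run.memberships[:, c]
            proto_sum[perm[c]] += run.prototypes[c]
    mean_u /= n_runs
    mean_u /= mean_u.sum(axis=1, keepdims=True)
    return ClusterResult(prototypes=proto_sum / n_runs, memberships=mean_u,
                         hard_labels=votes.argmax(axis=1),
                         run_labels=aligned_labels)


def label_quality_groups(result: ClusterResult, features: FeatureMatrix,
                         major_axis_column: str = "major",
                         minor_axis_column: str = "minor") -> ClusterResult:
    """Name the clusters: long major axis (and short minor axis on ties)
    marks the good-quality group."""
    if major_axis_column not in features.columns:
        raise DomainError(f"no column named {major_axis_column!r}")
    jmaj = features.columns.index(major_axis_column)
    jmin = (features.columns.index(minor_axis_column)
            if minor_axis_column in features.columns else None)
    k = result.k
    if k == 1:
        result.quality_map = {0: "good"}
        return result
    means_maj = np.array([
        features.values[result.hard_labels == c, jmaj].mean()
        if np.any(result.hard_labels == c) else -np.inf
        for c in range(k)])
    if np.all(means_maj == means_maj[0]) and jmin is not None:
        means_key = -np.array([
            features.values[result.hard_labels == c, jmin].mean()
            if np.any(result.hard_labels == c) else -np.inf
            for c in range(k)])
    else:
        means_key = means_maj
    good = int(np.argmax(means_key))
    result.quality_map = {c: ("good" if c == good else "bad") for c in range(k)}
    return result
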