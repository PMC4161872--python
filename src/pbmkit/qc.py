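"""PCA quality-control ellipse and PBM quality parameters.

Two measurements of the same quantities (signal vs background within one
array, or 8-mer medians across a training/testing pair) are assessed with
a Hotelling-T² control ellipse on their scatter: the sample covariance is
eigendecomposed, observations are scored by their Mahalanobis distance T²
from the mean, and the ellipse drawn at the T² control limit (default
99.73%, the three-sigma convention) separates conforming points from
outliers.  The ellipse's major axis length tracks the dynamic range of
the measurements; the minor axis length tracks their disagreement — a
narrow ellipse means the two measurements agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import CapabilityError, DegenerateInputError, DomainError
from .pbm_io import KmerIntensityTable, ProbeTable, match_paired_kmers

#: Relative eigenvalue threshold below which the covariance is treated as singular.
_SINGULAR_RTOL = 1e-12

#: Sample size beyond which the χ²(2) quantile replaces the exact F-based
#: control limit (difference < 1e-3 there; the χ² form is numerically stable).
_LARGE_N = 5000


@dataclass
class EllipseModel:
    """Geometry of the two-component Hotelling control ellipse.

    ``eigvecs`` columns are the principal directions (descending
    eigenvalue order); slopes follow V = U·diag(√l): major V21/V11,
    minor −V11/V21.  Axis *lengths* are full axes, 2×semi-axis.
    """

    center: np.ndarray          # (x̄1, x̄2)
    eigvals: np.ndarray         # l1 >= l2 >= 0
    eigvecs: np.ndarray         # 2x2 orthonormal, columns
    p_tail: float
    t2_limit: float
    semi_major: float
    semi_minor: float
    slope_major: float
    slope_minor: float
    n: int
    degenerate: bool = False

    @property
    def major_axis_length(self) -> float:
        return 2.0 * self.semi_major

    @property
    def minor_axis_length(self) -> float:
        return 2.0 * self.semi_minor


@dataclass
class QCReport:
    """Quality parameters of one array (MA mode) or one array pair."""

    major_axis_length: float
    minor_axis_length: float
    corr_coef: float
    regression_coef: float
    n_points: int
    outlier_flags: np.ndarray
    mode: str                   # "single_ma" | "paired_kmer"
    ellipse: Optional[EllipseModel] = None

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.outlier_flags))


def ma_transform(signal, background) -> tuple[np.ndarray, np.ndarray]:
    """MA coordinates of two intensity channels.

    M = log2(signal) − log2(background) (the log-ratio) and
    A = (log2(signal) + log2(background)) / 2 (mean log intensity).
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(background, dtype=float)
    if s.shape != b.shape:
        raise DomainError("signal and background must have equal length")
    if np.any(s <= 0) or np.any(b <= 0):
        raise DomainError("MA transform requires positive intensities")
    ls, lb = np.log2(s), np.log2(b)
    return (ls + lb) / 2.0, ls - lb


def t2_control_limit(n: int, p_tail: float) -> float:
    """Hotelling-T² upper control limit for 2 components at tail p.

    UCL = [2(n−1)(n+1) / (n(n−2))] · F_{1−p}(2, n−2); for very large n the
    χ²_{1−p}(2) quantile is used instead.
    """
    if n < 3:
        raise DomainError("need at least 3 observations")
    if not (0.0 < p_tail < 1.0):
        raise DomainError("p_tail must be in (0,1)")
    if n > _LARGE_N:
        return float(stats.chi2.ppf(1.0 - p_tail, 2))
    c = 2.0 * (n - 1) * (n + 1) / (n * (n - 2))
    return float(c * stats.f.ppf(1.0 - p_tail, 2, n - 2))


def pca_ellipse(x1, x2, p_tail: float = 0.0027) -> EllipseModel:
    """Fit the PCA control ellipse to a bivariate scatter.

    The sample covariance (n−1 denominator) is eigendecomposed; semi-axis
    lengths are √(l_i · T²-limit) so the ellipse covers ≈(1−p_tail) of
    points under a bivariate normal.  A singular covariance (perfect
    agreement) is reported as a degenerate ellipse with minor axis 0
    rather than an error.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise DomainError("x1 and x2 must be equal-length vectors")
    n = len(x1)
    if n < 3:
        raise DomainError("need at least 3 observations for the ellipse")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise DomainError("non-finite values in input")
    X = np.column_stack([x1, x2])
    center = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(S)       # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    degenerate = evals[1] <= _SINGULAR_RTOL * max(evals[0], 1e-300)
    if degenerate:
        evals = np.array([evals[0], 0.0])
    limit = t2_control_limit(n, p_tail)
    semi = np.sqrt(evals * limit)
    V = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
    # slopes from V = U L^{1/2}; the sqrt(l) factor cancels within a column
    v11, v21 = V[0, 0], V[1, 0]
    if v11 != 0:
        slope_major = v21 / v11
    else:
        slope_major = np.inf
    slope_minor = -v11 / v21 if v21 != 0 else np.inf
    return EllipseModel(
        center=center, eigvals=evals, eigvecs=evecs, p_tail=p_tail,
        t2_limit=limit, semi_major=float(semi[0]), semi_minor=float(semi[1]),
        slope_major=float(slope_major), slope_minor=float(slope_minor),
        n=n, degenerate=bool(degenerate),
    )


def t2_scores(x1, x2, ellipse: EllipseModel) -> np.ndarray:
    """T² of each observation: Mahalanobis distance from the sample mean.

    Computed through the y-scores (principal components scaled to unit
    variance), which equals (x−x̄)' S⁻¹ (x−x̄).
    """
    if ellipse.degenerate or ellipse.eigvals[1] <= 0:
        raise DegenerateInputError(
            "covariance is singular; T² undefined (use the degenerate ellipse path)")
    X = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    Z = (X - ellipse.center) @ ellipse.eigvecs
    Y = Z / np.sqrt(ellipse.eigvals)
    return np.einsum("ij,ij->i", Y, Y)


def flag_outliers(x1, x2, ellipse: EllipseModel) -> np.ndarray:
    """Out-of-control points: T² above the limit AND at least one
    coordinate below its sample mean (high-side excursions reflect strong
    specific binding, not poor quality, and are not flagged)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if ellipse.degenerate:
        # variation only along the major axis: score with the pseudo-inverse
        X = np.column_stack([x1, x2]) - ellipse.center
        z1 = (X @ ellipse.eigvecs[:, 0]) / np.sqrt(ellipse.eigvals[0])
        t2 = z1 ** 2
    else:
        t2 = t2_scores(x1, x2, ellipse)
    below = (x1 < ellipse.center[0]) | (x2 < ellipse.center[1])
    return (t2 > ellipse.t2_limit) & below


def single_pbm_qc(probes: ProbeTable, p_tail: float = 0.0027) -> QCReport:
    """Quality parameters of a single array from its MA plot.

    The ellipse and the regression slope (M on A) are computed on the MA
    scatter of signal vs background; the correlation coefficient is
    between the normalized (z-of-log) signal and background intensities.
    A long major axis indicates a wide dynamic range; high signal-
    background correlation indicates the array may mostly reflect
    background.
    """
    if not probes.has_background:
        raise CapabilityError("single-array QC requires a background column")
    A, M = ma_transform(probes.signal, probes.background)
    ellipse = pca_ellipse(A, M, p_tail=p_tail)
    corr = float(np.corrcoef(probes.normalized_signal(),
                             probes.normalized_background())[0, 1])
    slope = _ols_slope(A, M)
    flags = flag_outliers(A, M, ellipse)
    return QCReport(
        major_axis_length=ellipse.major_axis_length,
        minor_axis_length=ellipse.minor_axis_length,
        corr_coef=corr, regression_coef=slope,
        n_points=len(A), outlier_flags=flags, mode="single_ma",
        ellipse=ellipse,
    )


def paired_pbm_qc(table_a: KmerIntensityTable, table_b: KmerIntensityTable,
                  p_tail: float = 0.0027) -> QCReport:
    """Agreement of a training/testing array pair from shared 8-mer medians.

    Both arrays' medians over the shared k-mers are z-scored, then the
    ellipse, the Pearson correlation, and the OLS slope (array 2 on
    array 1) are computed on that scatter.  Good agreement gives a long,
    narrow ellipse (large major, small minor axis).
    """
    x1, x2 = match_paired_kmers(table_a, table_b)
    ellipse = pca_ellipse(x1, x2, p_tail=p_tail)
    if ellipse.degenerate:
        corr = 1.0 if ellipse.slope_major > 0 else -1.0
    else:
        corr = float(np.corrcoef(x1, x2)[0, 1])
    slope = _ols_slope(x1, x2)
    flags = flag_outliers(x1, x2, ellipse)
    return QCReport(
        major_axis_length=ellipse.major_axis_length,
        minor_axis_length=ellipse.minor_axis_length,
        corr_coef=corr, regression_coef=slope,
        n_points=len(x1), outlier_flags=flags, mode="paired_kmer",
        ellipse=ellipse,
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of y on x by ordinary least squares with intercept."""
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0:
        raise DegenerateInputError("zero variance in regressor")
    return float(dx @ (y - y.mean()) / sxx)
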