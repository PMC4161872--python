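"""PCA control ellipse, T² statistics, and array quality parameters."""

import numpy as np
import pytest
from scipy import stats

from pbmkit import qc, synth
from pbmkit.errors import CapabilityError, DegenerateInputError, DomainError
from pbmkit.pbm_io import kmer_median_intensities
from pbmkit.qc import (flag_outliers, ma_transform, paired_pbm_qc,
                       pca_ellipse, single_pbm_qc, t2_scores)


class TestMATransform:
    def test_equal_channels_give_zero_m(self):
        s = np.array([1.0, 4.0, 16.0])
        A, M = ma_transform(s, s)
        np.testing.assert_allclose(M, 0.0, atol=1e-12)
        np.testing.assert_allclose(A, np.log2(s), atol=1e-12)

    def test_hand_computed_point(self):
        A, M = ma_transform([4.0], [1.0])
        assert A[0] == pytest.approx(1.0)
        assert M[0] == pytest.approx(2.0)

    def test_antisymmetry(self):
        A1, M1 = ma_transform([1.0], [4.0])
        assert M1[0] == pytest.approx(-2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            ma_transform([1.0, -1.0], [1.0, 1.0])


class TestPCAEllipse:
    def test_perfect_agreement_degenerates(self, rng):
        x = rng.normal(size=100)
        e = pca_ellipse(x, x)
        assert e.degenerate
        assert e.minor_axis_length == 0.0
        assert e.slope_major == pytest.approx(1.0)

    def test_known_covariance_eigenstructure(self):
        # exact covariance [[2,1],[1,2]] has eigenvalues 3 and 1
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal([0, 0], cov, size=200_000)
        e = pca_ellipse(X[:, 0], X[:, 1])
        np.testing.assert_allclose(e.eigvals, [3.0, 1.0], rtol=0.03)
        assert e.semi_major / e.semi_minor == pytest.approx(np.sqrt(3), rel=0.03)

    def test_axis_lengths_are_rotation_invariant(self, rng):
        X = rng.multivariate_normal([1, 2], [[2, 0.5], [0.5, 1]], size=500)
        e0 = pca_ellipse(X[:, 0], X[:, 1])
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Xr = X @ R.T
        e1 = pca_ellipse(Xr[:, 0], Xr[:, 1])
        assert e1.major_axis_length == pytest.approx(e0.major_axis_length, abs=1e-8)
        assert e1.minor_axis_length == pytest.approx(e0.minor_axis_length, abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            pca_ellipse([1.0, 2.0], [1.0, 2.0])

    def test_orthogonal_axis_slopes(self, rng):
        X = rng.multivariate_normal([0, 0], [[3, 1], [1, 2]], size=1000)
        e = pca_ellipse(X[:, 0], X[:, 1])
        assert e.slope_major * e.slope_minor == pytest.approx(-1.0, rel=1e-9)


class TestT2Scores:
    def test_zero_at_the_mean(self, rng):
        X = rng.normal(size=(50, 2))
        e = pca_ellipse(X[:, 0], X[:, 1])
        t2 = t2_scores(np.array([e.center[0]]), np.array([e.center[1]]), e)
        assert t2[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_mahalanobis(self, rng):
        # brute-force oracle: (x-m)' S^{-1} (x-m) with the explicit inverse
        for _ in range(20):
            A = rng.normal(size=(2, 2))
            cov = A @ A.T + 0.5 * np.eye(2)
            X = rng.multivariate_normal(rng.normal(size=2), cov, size=1000)
            e = pca_ellipse(X[:, 0], X[:, 1])
            t2 = t2_scores(X[:, 0], X[:, 1], e)
            S = np.cov(X, rowvar=False, ddof=1)
            d = X - X.mean(axis=0)
            oracle = np.einsum("ij,jk,ik->i", d, np.linalg.inv(S), d)
            assert np.max(np.abs(t2 - oracle)) < 1e-10

    def test_identity_covariance_euclidean_case(self):
        e = qc.EllipseModel(center=np.zeros(2), eigvals=np.array([1.0, 1.0]),
                            eigvecs=np.eye(2), p_tail=0.0027, t2_limit=11.8,
                            semi_major=1.0, semi_minor=1.0, slope_major=0.0,
                            slope_minor=np.inf, n=100)
        t2 = t2_scores(np.array([3.0]), np.array([0.0]), e)
        assert t2[0] == pytest.approx(9.0)

    def test_singular_covariance_raises(self, rng):
        x = rng.normal(size=100)
        e = pca_ellipse(x, 2 * x)
        with pytest.raises(DegenerateInputError):
            t2_scores(x, 2 * x, e)


class TestControlLimitCoverage:
    def test_bivariate_normal_coverage_matches_limit(self):
        # analytic twin of the 99.73% three-sigma convention
        rng = np.random.default_rng(2024)
        X = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 2]], size=200_000)
        e = pca_ellipse(X[:, 0], X[:, 1], p_tail=0.0027)
        t2 = t2_scores(X[:, 0], X[:, 1], e)
        frac = np.mean(t2 <= e.t2_limit)
        assert 0.9963 <= frac <= 0.9983

    def test_f_and_chi2_limits_agree_at_large_n(self):
        f_lim = qc.t2_control_limit(5000, 0.0027)
        chi2_lim = float(stats.chi2.ppf(1 - 0.0027, 2))
        assert f_lim == pytest.approx(chi2_lim, rel=0.005)


class TestOutlierFlags:
    def test_rule_combines_t2_and_below_mean(self):
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal([0, 0], np.eye(2), size=500)
        e = pca_ellipse(X[:, 0], X[:, 1])
        # far point above both means: not flagged; far point below: flagged
        x1 = np.concatenate([X[:, 0], [9.0, -9.0]])
        x2 = np.concatenate([X[:, 1], [9.0, -9.0]])
        flags = flag_outliers(x1, x2, e)
        assert not flags[-2]
        assert flags[-1]

    def test_point_at_mean_not_flagged(self, rng):
        X = rng.normal(size=(100, 2))
        e = pca_ellipse(X[:, 0], X[:, 1])
        flags = flag_outliers(np.array([e.center[0]]),
                              np.array([e.center[1]]), e)
        assert not flags[0]


class TestSinglePBMQC:
    def test_background_equal_to_signal(self, rng):
        s = np.exp(rng.normal(size=200))
        from pbmkit.pbm_io import ProbeTable
        table = ProbeTable([f"p{i}" for i in range(200)],
                           ["ACGTACGT"] * 200, s, background=s.copy())
        rep = single_pbm_qc(table)
        assert rep.corr_coef == pytest.approx(1.0)
        assert rep.minor_axis_length == pytest.approx(0.0, abs=1e-8)

    def test_independent_background_low_correlation(self, rng):
        from pbmkit.pbm_io import ProbeTable
        n = 5000
        table = ProbeTable([f"p{i}" for i in range(n)], ["ACGTACGT"] * n,
                           np.exp(rng.normal(size=n)),
                           background=np.exp(rng.normal(size=n)))
        rep = single_pbm_qc(table)
        assert abs(rep.corr_coef) < 0.05

    def test_missing_background_is_capability_error(self, sim_probes):
        from pbmkit.pbm_io import ProbeTable
        bare = ProbeTable(sim_probes.probe_ids, sim_probes.sequences,
                          sim_probes.signal, array_id="nobg")
        with pytest.raises(CapabilityError):
            single_pbm_qc(bare)


class TestPairedPBMQC:
    def test_identical_tables(self, sim_probes):
        kt = kmer_median_intensities(sim_probes, k=8)
        rep = paired_pbm_qc(kt, kt)
        assert rep.corr_coef == pytest.approx(1.0)
        assert rep.regression_coef == pytest.approx(1.0)
        assert rep.minor_axis_length == pytest.approx(0.0, abs=1e-8)

    def test_permuted_partner_destroys_agreement(self, sim_probes, rng):
        import pandas as pd
        kt = kmer_median_intensities(sim_probes, k=8)
        vals = kt.intensities.to_numpy().copy()
        rng.shuffle(vals)
        kt2 = type(kt)(pd.Series(vals, index=kt.intensities.index), k=8)
        rep = paired_pbm_qc(kt, kt2)
        assert abs(rep.corr_coef) < 0.2
        assert rep.minor_axis_length > 0.5 * rep.major_axis_length
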