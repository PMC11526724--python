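"""Fidelity metrics: printed-formula examples, bounds, symmetry, consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermaug.errors import ValidationError
from dermaug.quality import (
    PMFPair,
    discretize_pair,
    hellinger,
    maep,
    pcd,
    quality_report,
    rsvr,
)


def _pmf(values):
    v = np.asarray(values, dtype=float)
    return v / v.sum()


class TestDiscretize:
    def test_identical_columns_identical_pmfs(self):
        x = np.random.default_rng(0).standard_normal(100)
        pair = discretize_pair(x, x.copy())
        assert np.allclose(pair.P, pair.Q)

    def test_disjoint_supports_two_bins(self):
        pair = discretize_pair(np.linspace(0, 0.99, 50),
                               np.linspace(1.01, 2, 50), n_bins=2)
        assert np.allclose(pair.P, [1, 0])
        assert np.allclose(pair.Q, [0, 1])

    def test_pmfs_sum_to_one(self):
        rng = np.random.default_rng(1)
        pair = discretize_pair(rng.normal(0, 1, 77), rng.normal(2, 3, 31))
        assert pair.P.sum() == pytest.approx(1.0)
        assert pair.Q.sum() == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            discretize_pair([1.0, np.nan], [0.0, 1.0])


class TestHellinger:
    def test_identical_is_zero(self):
        pair = PMFPair(_pmf([1, 2, 3]), _pmf([1, 2, 3]))
        assert hellinger(pair) == 0.0

    def test_disjoint_is_one(self):
        assert hellinger(PMFPair([1.0, 0.0], [0.0, 1.0])) == pytest.approx(1.0)

    def test_printed_formula_value(self):
        """(1/sqrt2) sqrt((sqrt.5-1)^2 + (sqrt.5)^2) = 0.5412."""
        assert hellinger(PMFPair([0.5, 0.5], [1.0, 0.0])) == \
            pytest.approx(0.5412, abs=1e-4)


class TestMAEP:
    def test_identical_is_zero(self):
        assert maep(PMFPair([0.3, 0.7], [0.3, 0.7])) == 0.0

    def test_disjoint_is_two(self):
        assert maep(PMFPair([1.0, 0.0], [0.0, 1.0])) == pytest.approx(2.0)

    def test_printed_formula_value(self):
        assert maep(PMFPair([0.5, 0.5], [1.0, 0.0])) == pytest.approx(1.0)

    def test_mean_flag_divides_by_bins(self):
        pair = PMFPair([0.5, 0.5], [1.0, 0.0])
        assert maep(pair, mean=True) == pytest.approx(0.5)


class TestPCD:
    def test_identical_matrices_zero(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        assert pcd(X, X.copy()) == 0.0

    def test_perfect_vs_independent_closed_form(self):
        """Real: two perfectly correlated columns (off-diagonal 1); synthetic:
        an exactly orthogonal design (off-diagonal 0) -> Frobenius sqrt(2)."""
        x = np.arange(8.0)
        X_real = np.column_stack([x, 2 * x + 1])
        X_syn = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 2, dtype=float)
        assert np.corrcoef(X_syn.T)[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert pcd(X_real, X_syn) == pytest.approx(np.sqrt(2.0))

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(2)
        Xr = rng.standard_normal((30, 3))
        Xs = rng.standard_normal((40, 3))
        assert pcd(Xr, Xs) == pytest.approx(
            pcd(Xr[rng.permutation(30)], Xs[rng.permutation(40)]))

    def test_constant_column_convention(self):
        rng = np.random.default_rng(3)
        Xr = np.column_stack([rng.standard_normal(20), np.full(20, 5.0)])
        Xs = rng.standard_normal((20, 2))
        assert np.isfinite(pcd(Xr, Xs))

    def test_single_feature_rejected(self):
        with pytest.raises(ValidationError, match="features"):
            pcd(np.zeros((5, 1)), np.zeros((5, 1)))


class TestRSVR:
    def test_all_unique_is_zero(self):
        X = np.arange(12.0).reshape(4, 3)
        assert rsvr(X) == 0.0

    def test_n_identical_rows(self):
        X = np.tile([1.0, 2.0], (7, 1))
        assert rsvr(X) == pytest.approx(6 / 7)

    def test_empty_is_zero(self):
        assert rsvr(np.empty((0, 3))) == 0.0

    def test_exact_equality_no_rounding(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0 + 1e-12]])
        assert rsvr(X) == 0.0


class TestQualityReport:
    def test_identical_data_all_zero(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        rep = quality_report(X, X.copy())
        assert rep.mean_hd == 0.0
        assert rep.mean_maep == 0.0
        assert rep.pcd == 0.0
        assert rep.rsvr == 0.0

    def test_bootstrap_resample_is_high_fidelity(self):
        """Resampling the real rows themselves: HD and PCD sit inside the
        sampling-noise band (n=5000, D=5 -> mean HD < 0.1, PCD < 0.2)."""
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(5),
                                    0.5 * np.eye(5) + 0.5, size=5000)
        Xs = X[rng.integers(0, len(X), len(X))]
        rep = quality_report(X, Xs)
        assert rep.mean_hd < 0.1
        assert rep.pcd < 0.2

    def test_feature_order_invariant_up_to_relabelling(self):
        rng = np.random.default_rng(2)
        Xr = rng.standard_normal((60, 4))
        Xs = rng.standard_normal((60, 4))
        names = list("abcd")
        rep = quality_report(Xr, Xs, feature_names=names)
        perm = [2, 0, 3, 1]
        rep_p = quality_report(Xr[:, perm], Xs[:, perm],
                               feature_names=[names[p] for p in perm])
        for name in names:
            assert rep.hd[name] == pytest.approx(rep_p.hd[name])
        assert rep.pcd == pytest.approx(rep_p.pcd)

    def test_feature_mismatch_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError, match="features"):
            quality_report(pd.DataFrame({"a": [1.0, 2, 3]}),
                           pd.DataFrame({"b": [1.0, 2, 3]}))

    def test_consistency_hd_decreases_with_sample_size(self):
        """Synthetic drawn from the real empirical distribution: median HD
        and MAEP fall as n grows through 100, 1000, 10000."""
        hd_by_n = {}
        maep_by_n = {}
        for n in (100, 1000, 10_000):
            hds, maeps = [], []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                real = rng.standard_normal((2000, 2))
                syn = real[rng.integers(0, len(real), n)]
                rep = quality_report(real, syn)
                hds.append(rep.mean_hd)
                maeps.append(rep.mean_maep)
            hd_by_n[n] = np.median(hds)
            maep_by_n[n] = np.median(maeps)
        assert hd_by_n[100] > hd_by_n[1000] > hd_by_n[10_000]
        assert maep_by_n[100] > maep_by_n[1000] > maep_by_n[10_000]


class TestMetricProperties:
    @given(arrays(np.float64, st.integers(1, 12),
                  elements=st.floats(0.001, 1.0)),
           arrays(np.float64, st.integers(1, 12),
                  elements=st.floats(0.001, 1.0)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, p_raw, q_raw):
        k = min(len(p_raw), len(q_raw))
        pair = PMFPair(_pmf(p_raw[:k]), _pmf(q_raw[:k]))
        swapped = PMFPair(pair.Q, pair.P)
        h = hellinger(pair)
        m = maep(pair)
        assert 0.0 <= h <= 1.0
        assert 0.0 <= m <= 2.0
        assert h == pytest.approx(hellinger(swapped))
        assert m == pytest.approx(maep(swapped))

    @given(st.integers(0, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pcd_nonnegative_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        Xr = rng.standard_normal((rng.integers(3, 30), 3))
        Xs = rng.standard_normal((rng.integers(3, 30), 3))
        v = pcd(Xr, Xs)
        assert v >= 0.0
        assert v == pytest.approx(pcd(Xs, Xr))

    @given(st.integers(0, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rsvr_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(rng.integers(1, 40), 2)).astype(float)
        assert 0.0 <= rsvr(X) <= 1.0
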