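from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from epikinet import asym_index, compare_groups, control_mean_abs_asym, correlate_asym
from epikinet.asymmetry_stats import UndefinedIndexError, holm_correction

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


class TestAsymIndex:
    def test_symmetric_pair_is_zero(self):
        assert asym_index(3.7, 3.7) == 0.0

    def test_hand_computed_value(self):
        assert asym_index(1.25, 0.75) == pytest.approx(0.5)

    def test_undefined_for_zero_sum(self):
        with pytest.raises(UndefinedIndexError):
            asym_index(0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(c=positive, i=positive)
    def test_antisymmetry_under_side_swap(self, c, i):
        assert asym_index(c, i) == pytest.approx(-asym_index(i, c), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(c=positive, i=positive, a=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c, i, a):
        """Global calibration cancels: why an unscaled IDIF is admissible."""
        assert asym_index(a * c, a * i) == pytest.approx(asym_index(c, i), rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(c=positive, i=positive)
    def test_bounded_for_nonnegative_inputs(self, c, i):
        assert -2.0 <= asym_index(c, i) <= 2.0


class TestControlMeanAbsAsym:
    def _records(self, asyms):
        return pd.DataFrame([
            {"region_id": f"r{k}", "parameter": "K1", "asym": a}
            for k, a in enumerate(asyms)
        ])

    def test_perfectly_symmetric_controls(self):
        out = control_mean_abs_asym(self._records([0.0] * 6), [f"r{k}" for k in range(6)])
        assert out["K1"] == 0.0

    def test_arithmetic_mean_of_absolute_values(self):
        out = control_mean_abs_asym(self._records([0.01, 0.02, 0.03, 0.0, 0.02, 0.04]),
                                    [f"r{k}" for k in range(6)])
        assert out["K1"] == pytest.approx(0.02)

    def test_sign_flips_do_not_matter(self):
        a = control_mean_abs_asym(self._records([0.01, -0.02, 0.03, 0.0, -0.02, 0.04]),
                                  [f"r{k}" for k in range(6)])
        b = control_mean_abs_asym(self._records([0.01, 0.02, 0.03, 0.0, 0.02, 0.04]),
                                  [f"r{k}" for k in range(6)])
        assert a["K1"] == b["K1"]

    def test_missing_region_is_an_error(self):
        with pytest.raises(ValueError):
            control_mean_abs_asym(self._records([0.01] * 5), [f"r{k}" for k in range(6)])


def _brute_force_ranksum_p(a, b):
    """Enumerate subsets of the pooled values; U from pair counting."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def ustat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = ustat(a, b)
    center = n1 * len(b) / 2.0
    hits = total = 0
    idx = range(len(pooled))
    for subset in combinations(idx, n1):
        rest = [i for i in idx if i not in subset]
        u = ustat(pooled[list(subset)], pooled[rest])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return hits / total


class TestCompareGroups:
    def test_identical_paired_samples_degenerate(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_fully_separated_five_vs_five(self):
        res = compare_groups([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert res.exact
        assert res.pvalue == pytest.approx(2.0 / 252.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_value_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(0.8, size=4)
        res = compare_groups(a, b)
        assert res.exact
        assert res.pvalue == pytest.approx(_brute_force_ranksum_p(a, b))

    def test_exact_p_with_ties_matches_enumeration(self):
        a = np.array([1.0, 2.0, 2.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 6.0])
        res = compare_groups(a, b)
        assert res.exact
        assert res.pvalue == pytest.approx(_brute_force_ranksum_p(a, b))

    def test_exact_matches_scipy_for_tie_free_data(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=5), rng.normal(size=6)
        res = compare_groups(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=15), rng.normal(0.5, size=15)
        res = compare_groups(a, b)
        assert not res.exact
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_paired_exact_matches_scipy_signed_rank(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=8)
        b = a + rng.normal(0.3, 0.5, size=8)
        res = compare_groups(a, b, paired=True)
        assert res.exact
        ref = sstats.wilcoxon(a, b, method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelateAsym:
    def _table(self, cols):
        return pd.DataFrame(cols)

    def test_monotone_increasing_gives_rho_one(self):
        t = self._table({"K1": [1, 2, 3, 4, 5, 6], "k3": [2, 4, 5, 7, 8, 11]})
        out = correlate_asym(t, parameters=("K1", "k3"))
        assert out.rho.loc["K1", "k3"] == pytest.approx(1.0)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        t = self._table({"K1": [1, 2, 3, 4, 5], "k3": [9, 7, 5, 3, 1]})
        out = correlate_asym(t, parameters=("K1", "k3"))
        assert out.rho.loc["K1", "k3"] == pytest.approx(-1.0)

    def test_midrank_tie_handling_matches_hand_construction(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 6.0, 7.0, 8.0, 8.0])
        # hand-built midranks
        rx = np.array([1.0, 2.5, 2.5, 4.5, 4.5, 6.0])
        ry = np.array([1.5, 1.5, 3.0, 4.0, 5.5, 5.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        out = correlate_asym(self._table({"K1": x, "k3": y}), parameters=("K1", "k3"))
        assert out.rho.loc["K1", "k3"] == pytest.approx(expected)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = correlate_asym(self._table({"K1": x, "k3": y}), ("K1", "k3"))
        warped = correlate_asym(self._table({"K1": np.exp(x), "k3": y ** 3}), ("K1", "k3"))
        assert base.rho.loc["K1", "k3"] == pytest.approx(warped.rho.loc["K1", "k3"])

    def test_matrix_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        t = self._table({p: rng.normal(size=8) for p in ("K1", "k2", "k3")})
        out = correlate_asym(t, ("K1", "k2", "k3"))
        np.testing.assert_allclose(out.rho.values, out.rho.values.T)
        np.testing.assert_allclose(np.diag(out.rho.values), 1.0)

    def test_constant_column_reported_missing(self):
        t = self._table({"K1": [1.0] * 6, "k3": [1, 2, 3, 4, 5, 6]})
        out = correlate_asym(t, ("K1", "k3"))
        assert np.isnan(out.rho.loc["K1", "k3"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            correlate_asym(self._table({"K1": [1, 2, 3], "k3": [1, 2, 3]}), ("K1", "k3"))


def test_holm_correction_is_step_down_monotone():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_correction(p)
    assert adj[0] == pytest.approx(0.04)
    assert np.all(adj <= 1.0)
    assert np.all(adj >= p)
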