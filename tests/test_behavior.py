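import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fpetki.behavior import (
    StepwisePolynomialRegression,
    group_tests,
    holm_adjust,
    ki_behavior_correlation,
    normalize_rt,
    stepwise_polyfit,
)
from fpetki.synthetic import simulate_rt_amount_data


class TestNormalizeRt:
    def test_constant_rts_center_to_zero(self):
        df = pd.DataFrame({"block": [0, 0, 1, 1], "reaction_time": [500.0] * 4})
        np.testing.assert_array_equal(normalize_rt(df), 0.0)

    def test_two_value_block(self):
        df = pd.DataFrame({"block": [0, 0], "reaction_time": [400.0, 600.0]})
        np.testing.assert_array_equal(normalize_rt(df), [-100.0, 100.0])

    def test_per_block_sums_vanish(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"block": rng.integers(0, 4, 200), "reaction_time": rng.normal(500, 80, 200)})
        centered = normalize_rt(df)
        sums = centered.groupby(df["block"]).sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            normalize_rt(pd.DataFrame({"rt": [1.0]}))


class TestStepwisePolyfit:
    def test_pure_linear_data_selects_linear_only(self):
        a = np.tile([-3, -2, -1, 1, 2, 3], 20).astype(float)
        rt = -2.36 * a
        model = stepwise_polyfit(a, rt)
        assert model.terms_ == (1,)
        assert model.coef_[1] == pytest.approx(-2.36, rel=1e-9)

    def test_symmetric_inverted_u_selects_quadratic_only(self):
        """On a design symmetric in amount, a pure even signal is orthogonal
        to the odd linear term, so only the quadratic enters."""
        a = np.tile([-3, -2, -1, 1, 2, 3], 50).astype(float)
        rng = np.random.default_rng(1)
        rt = -1.16 * a**2 + rng.normal(0, 5, a.size)
        rt = rt - rt.mean()
        model = stepwise_polyfit(a, rt)
        assert 2 in model.terms_
        assert model.coef_[2] < 0
        if 1 in model.pvalues_:
            pass  # linear may enter only by noise; quadratic must dominate
        assert model.entry_pvalues_[2] < 1e-6

    def test_generating_coefficients_recovered_within_three_se(self):
        """Trial-level data from an inverted-U model with Gaussian noise:
        both coefficients land within 3 standard errors of the generating
        values (n = 1000)."""
        rng = np.random.default_rng(2)
        a = rng.choice([-3, -2, -1, 1, 2, 3], size=1000).astype(float)
        rt = 4.31 - 0.95 * a - 1.16 * a**2 + rng.normal(0, 10, a.size)
        model = stepwise_polyfit(a, rt)
        assert set(model.terms_) == {1, 2}
        assert abs(model.coef_[1] - (-0.95)) < 3 * model.bse_[1]
        assert abs(model.coef_[2] - (-1.16)) < 3 * model.bse_[2]

    def test_too_few_distinct_amounts_rejected(self):
        with pytest.raises(ValueError):
            stepwise_polyfit(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_sklearn_estimator_interface(self):
        est = StepwisePolynomialRegression(entry_alpha=0.01)
        assert est.get_params()["entry_alpha"] == 0.01
        a = np.tile([-2, -1, 0, 1, 2], 30).astype(float)
        est.fit(a, 3.0 - 2.0 * a)
        np.testing.assert_allclose(est.predict(np.array([2.0])), [-1.0], atol=1e-8)


class TestHolm:
    def test_textbook_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_matches_reference_implementation(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = holm_adjust(pvals)
        _, oracle, _, _ = multipletests(pvals, method="holm")
        np.testing.assert_allclose(ours, oracle, rtol=1e-12, atol=1e-12)
        # never below the raw p-value or above 1
        assert np.all(ours >= np.asarray(pvals) - 1e-15)
        assert np.all(ours <= 1.0)


class TestGroupTests:
    def test_identical_groups_give_zero_statistic(self):
        t = group_tests({"a": np.ones(5), "b": np.ones(5)}, popmean=1.0, pairs=[("a", "b")])
        two_sample = t[t["kind"] == "two-sample"].iloc[0]
        assert two_sample["t"] == 0.0 and two_sample["p_raw"] == 1.0
        assert np.all(t["p_holm"] >= t["p_raw"] - 1e-15)

    def test_matches_scipy_for_regular_data(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.5, 1, 10), rng.normal(0.0, 1, 12)
        t = group_tests({"a": a, "b": b}, pairs=[("a", "b")])
        t1 = stats.ttest_1samp(a, 0.0)
        row = t[t["test"] == "a vs 0"].iloc[0]
        assert row["t"] == pytest.approx(t1.statistic)
        assert row["p_raw"] == pytest.approx(t1.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests({"a": np.array([])})


class TestSpearman:
    def test_perfectly_monotone_pairs(self):
        x = np.arange(6.0)
        rho, p = ki_behavior_correlation(x, x**3)
        assert rho == pytest.approx(1.0)
        rho_r, _ = ki_behavior_correlation(x, -(x**3))
        assert rho_r == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration_oracle(self):
        """n = 7: the permutation p-value equals brute-force enumeration
        over all 5040 orderings computed with scipy per permutation."""
        from itertools import permutations

        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5, 6.0])
        rho, p = ki_behavior_correlation(x, y)
        obs = stats.spearmanr(x, y).statistic
        count = 0
        total = 0
        for perm in permutations(range(7)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            count += abs(r) >= abs(obs) - 1e-12
            total += 1
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(count / total)

    def test_ties_handled_by_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        rho, p = ki_behavior_correlation(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert 0.0 <= p <= 1.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ki_behavior_correlation(np.arange(3.0), np.arange(3.0))


def test_accumulated_balance_equals_sum_of_deltas():
    """Conservation between the simulator's trial log and the behavioral
    summary used for the group tests."""
    from fpetki.synthetic import accumulated_balance, simulate_mid_session

    trials = simulate_mid_session(seed=21)
    df = pd.DataFrame([t.__dict__ for t in trials])
    assert accumulated_balance(trials) == pytest.approx(df["balance_delta"].sum())
    gain = df[df["condition"] == "gain"]["balance_delta"].sum()
    assert accumulated_balance(trials, "gain") == pytest.approx(gain)
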