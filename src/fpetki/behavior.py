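"""Behavioral analysis of the monetary incentive delay task.

Reaction times are mean-centered within each block (the adaptive staircase
makes absolute RTs non-stationary), the RT-versus-amount relation is
modelled by stepwise polynomial regression up to second order, accumulated
gain/loss and group contrasts are tested with t-tests under Bonferroni-Holm
correction, and brain-behavior relations use Spearman correlation with an
exact permutation p-value at the small sample sizes typical of PET.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "normalize_rt",
    "StepwisePolynomialRegression",
    "stepwise_polyfit",
    "holm_adjust",
    "group_tests",
    "ki_behavior_correlation",
]


def normalize_rt(trials: pd.DataFrame, rt_col: str = "reaction_time", block_col: str = "block") -> pd.Series:
    """Mean-center reaction times within each block.

    Returns a series aligned with ``trials``; each block's centered values
    sum to zero.
    """
    if block_col not in trials or rt_col not in trials:
        raise ValueError(f"trials must have {block_col!r} and {rt_col!r} columns")
    grouped = trials.groupby(block_col)[rt_col]
    if (grouped.size() == 0).any():
        raise ValueError("empty block in trial table")
    return trials[rt_col] - grouped.transform("mean")


class StepwisePolynomialRegression(RegressorMixin, BaseEstimator):
    """Forward stepwise polynomial regression of RT on monetary amount.

    Starting from an intercept-only model, the candidate term (amount or
    amount squared) with the smallest OLS p-value is added while that
    p-value is below ``entry_alpha``; the final model is refitted with all
    selected terms. There is no removal step.

    Attributes
    ----------
    terms_ : tuple of selected polynomial degrees (subset of (1, 2))
    intercept_ : float
    coef_ : dict mapping degree -> coefficient (ms per unit^degree)
    pvalues_ : dict mapping degree -> p-value in the final model
    entry_pvalues_ : dict mapping degree -> p-value at its entry test
    """

    def __init__(self, entry_alpha: float = 0.05, max_degree: int = 2):
        self.entry_alpha = entry_alpha
        self.max_degree = max_degree

    def _design(self, a: np.ndarray, degrees: Sequence[int]) -> np.ndarray:
        return np.column_stack([np.ones_like(a)] + [a**d for d in degrees])

    def fit(self, X, y):
        a = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if a.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.unique(a).size < 3:
            raise ValueError("need at least 3 distinct amounts")
        import statsmodels.api as sm

        candidates = list(range(1, self.max_degree + 1))
        selected: list[int] = []
        entry_p: dict[int, float] = {}
        while candidates:
            trial_p = {}
            for d in candidates:
                res = sm.OLS(y, self._design(a, selected + [d])).fit()
                trial_p[d] = float(res.pvalues[-1])
            d_best = min(trial_p, key=trial_p.get)
            if trial_p[d_best] >= self.entry_alpha:
                break
            entry_p[d_best] = trial_p[d_best]
            selected.append(d_best)
            candidates.remove(d_best)
        selected_sorted = tuple(sorted(selected))
        final = sm.OLS(y, self._design(a, selected_sorted)).fit()
        self.terms_ = selected_sorted
        self.intercept_ = float(final.params[0])
        self.coef_ = {d: float(final.params[i + 1]) for i, d in enumerate(selected_sorted)}
        self.bse_ = {d: float(final.bse[i + 1]) for i, d in enumerate(selected_sorted)}
        self.pvalues_ = {d: float(final.pvalues[i + 1]) for i, d in enumerate(selected_sorted)}
        self.entry_pvalues_ = entry_p
        self.model_ = final
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "terms_")
        a = np.asarray(X, dtype=float).reshape(-1)
        out = np.full(a.shape, self.intercept_)
        for d, c in self.coef_.items():
            out += c * a**d
        return out


def stepwise_polyfit(amount, centered_rt, entry_alpha: float = 0.05) -> StepwisePolynomialRegression:
    """Fit the stepwise RT-versus-amount model; returns the fitted estimator."""
    return StepwisePolynomialRegression(entry_alpha=entry_alpha).fit(amount, centered_rt)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (two-sided family).

    adj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the ascending
    order statistics, mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _safe_ttest_1samp(values: np.ndarray, popmean: float) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size > 1 and np.ptp(values) == 0:
        # zero within-group variance: exact-equality fast path
        equal = np.isclose(values[0], popmean)
        return (0.0, 1.0) if equal else (np.inf, 0.0)
    t, p = stats.ttest_1samp(values, popmean)
    return float(t), float(p)


def _safe_ttest_ind(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        equal = np.isclose(a.mean(), b.mean())
        return (0.0, 1.0) if equal else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def group_tests(
    groups: Mapping[str, np.ndarray],
    popmean: float = 0.0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One-sample t-tests per group plus two-sample contrasts, Holm-adjusted.

    The test family for the Holm correction is every row of the returned
    table: one one-sample test (against ``popmean``) per group and one
    independent-samples test per requested pair. All tests are two-sided.
    """
    for name, values in groups.items():
        if len(np.asarray(values)) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for name, values in groups.items():
        t, p = _safe_ttest_1samp(np.asarray(values, dtype=float), popmean)
        rows.append({"test": f"{name} vs {popmean:g}", "kind": "one-sample", "t": t, "p_raw": p})
    for a, b in pairs or []:
        t, p = _safe_ttest_ind(groups[a], groups[b])
        rows.append({"test": f"{a} vs {b}", "kind": "two-sample", "t": t, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table


def ki_behavior_correlation(
    behavior: np.ndarray,
    ki: np.ndarray,
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p-value.

    For n <= ``exact_max_n`` the two-sided p-value is computed by complete
    enumeration of orderings (appropriate for the n < 10 per group typical
    of PET subsamples); larger samples fall back to the asymptotic p-value.
    Ties are handled by average ranks.
    """
    x = np.asarray(behavior, dtype=float)
    y = np.asarray(ki, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired observations with n >= 4")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n > exact_max_n:
        return rho, float(stats.spearmanr(x, y).pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    if denom == 0:
        return rho, 1.0
    perms = np.array(list(permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    observed = float(rx_c @ ry_c / denom)
    count = int(np.sum(np.abs(rhos) >= np.abs(observed) - 1e-12))
    return rho, count / len(perms)
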