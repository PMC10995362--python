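"""Cohort statistics: group comparisons, correlations, regression screening.

Implements the study-style statistics stage over the per-eye table:
one-way ANOVA with pairwise t-tests across the three refractive groups
(emmetropia EM, low/moderate myopia LM/MM, simple high myopia SHM), a
chi-square test of the sex distribution, Pearson correlations, and the
univariate -> multivariate linear-regression screen in which every predictor
univariately associated with the outcome at p < 0.05 enters a multivariable
OLS model that is then pruned by backward elimination until all retained
predictors satisfy p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GROUPS",
    "GroupComparison",
    "RegressionResult",
    "RegressionScreenResult",
    "compare_groups",
    "sex_distribution_test",
    "correlate",
    "regression_screen",
    "group_table",
]

GROUPS = ("EM", "LM/MM", "SHM")

# pairwise-contrast labels: P1 = EM vs LM/MM, P2 = EM vs SHM, P3 = LM/MM vs SHM
DEFAULT_PAIRS = {"P1": ("EM", "LM/MM"), "P2": ("EM", "SHM"), "P3": ("LM/MM", "SHM")}


@dataclass(frozen=True)
class GroupComparison:
    outcome: str
    group_means: dict
    group_sds: dict
    group_ns: dict
    f_stat: float
    p_overall: float
    pairwise_p: dict
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionResult:
    """One fitted OLS model: per-predictor betas (raw and standardized) and p."""

    outcome: str
    predictors: tuple[str, ...]
    beta: dict
    beta_standardized: dict
    p_values: dict
    r: float
    n: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionScreenResult:
    univariate: dict  # predictor -> RegressionResult (single-predictor model)
    selected: tuple[str, ...]  # predictors passing the univariate screen
    final: RegressionResult | None  # backward-eliminated multivariable model
    flags: tuple[str, ...] = ()


def compare_groups(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    groups: tuple[str, ...] = GROUPS,
    pairs: dict | None = None,
    welch: bool = False,
) -> GroupComparison:
    """One-way ANOVA over groups plus pairwise two-sample t-tests."""
    pairs = DEFAULT_PAIRS if pairs is None else pairs
    samples = {
        g: table.loc[table[group_col] == g, outcome].dropna().to_numpy(dtype=float)
        for g in groups
    }
    samples = {g: v for g, v in samples.items() if len(v) >= 2}
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    flags: list[str] = []
    if all(np.var(v) < 1e-30 for v in samples.values()):
        flags.append("zero_within_group_variance")
        f_stat, p_overall = float("nan"), float("nan")
    else:
        f_stat, p_overall = sps.f_oneway(*samples.values())
    pairwise = {}
    for label, (a, b) in pairs.items():
        if a in samples and b in samples:
            pairwise[label] = float(
                sps.ttest_ind(samples[a], samples[b], equal_var=not welch).pvalue
            )
    return GroupComparison(
        outcome=outcome,
        group_means={g: float(v.mean()) for g, v in samples.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in samples.items()},
        group_ns={g: int(len(v)) for g, v in samples.items()},
        f_stat=float(f_stat),
        p_overall=float(p_overall),
        pairwise_p=pairwise,
        flags=tuple(flags),
    )


def sex_distribution_test(
    table: pd.DataFrame, sex_col: str = "sex", group_col: str = "group"
) -> tuple[float, float]:
    """Pearson chi-square on the sex x group contingency table -> (chi2, p)."""
    ct = pd.crosstab(table[sex_col], table[group_col], dropna=False)
    if (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    chi2, p, _, _ = sps.chi2_contingency(ct.to_numpy(), correction=False)
    return float(chi2), float(p)


def correlate(table: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson product-moment correlation -> (r, two-sided p)."""
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.pearsonr(sub[x], sub[y])
    return float(res.statistic), float(res.pvalue)


def _fit_ols(df: pd.DataFrame, outcome: str, predictors: list[str]) -> RegressionResult:
    sub = df[[outcome, *predictors]].dropna()
    X = sm.add_constant(sub[list(predictors)].astype(float))
    fit = sm.OLS(sub[outcome].astype(float), X).fit()
    sd_y = sub[outcome].std(ddof=1)
    beta = {p: float(fit.params[p]) for p in predictors}
    beta_std = {p: float(fit.params[p] * sub[p].std(ddof=1) / sd_y) for p in predictors}
    pvals = {p: float(fit.pvalues[p]) for p in predictors}
    flags: list[str] = []
    if len(predictors) > 1:
        Z = (sub[predictors] - sub[predictors].mean()) / sub[predictors].std(ddof=1)
        if np.linalg.cond(Z.to_numpy()) > 1e3:
            flags.append("collinear_predictors")
    return RegressionResult(
        outcome=outcome,
        predictors=tuple(predictors),
        beta=beta,
        beta_standardized=beta_std,
        p_values=pvals,
        r=float(np.sqrt(max(fit.rsquared, 0.0))),
        n=int(fit.nobs),
        flags=tuple(flags),
    )


def regression_screen(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    alpha: float = 0.05,
) -> RegressionScreenResult:
    """Univariate screen at ``alpha``, then backward-eliminated multivariable OLS.

    Complete-case analysis per model.  If no predictor passes the screen the
    final model is None and the result is flagged.
    """
    n_complete = len(table[[outcome, *predictors]].dropna())
    if n_complete < len(predictors) + 2:
        raise ValueError("too few complete cases for the requested screen")
    uni = {p: _fit_ols(table, outcome, [p]) for p in predictors}
    selected = [p for p in predictors if uni[p].p_values[p] < alpha]
    flags: list[str] = []
    if not selected:
        return RegressionScreenResult(
            univariate=uni, selected=(), final=None, flags=("no_predictor_selected",)
        )
    current = list(selected)
    final = _fit_ols(table, outcome, current)
    while len(current) > 1:
        worst = max(current, key=lambda p: final.p_values[p])
        if final.p_values[worst] < alpha:
            break
        current.remove(worst)
        final = _fit_ols(table, outcome, current)
    if len(current) == 1 and final.p_values[current[0]] >= alpha:
        flags.append("final_predictor_not_significant")
    return RegressionScreenResult(
        univariate=uni, selected=tuple(selected), final=final, flags=tuple(flags)
    )


def group_table(
    table: pd.DataFrame, outcomes: list[str], group_col: str = "group"
) -> pd.DataFrame:
    """Study-style summary: per-group mean +- SD and P0-P3 for each outcome."""
    rows = []
    for outcome in outcomes:
        cmp_res = compare_groups(table, outcome, group_col=group_col)
        row: dict = {"outcome": outcome}
        for g in GROUPS:
            if g in cmp_res.group_means:
                row[f"{g}_mean"] = cmp_res.group_means[g]
                row[f"{g}_sd"] = cmp_res.group_sds[g]
        row["P0"] = cmp_res.p_overall
        row.update(cmp_res.pairwise_p)
        rows.append(row)
    return pd.DataFrame(rows)
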