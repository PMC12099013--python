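"""Two-group atrophy statistics: ANCOVA adjusted differences, correlations,
demographic comparisons, covariate residualisation.

The group comparison is a classic ANCOVA: ordinary least squares of the
outcome on a group indicator plus adjusting covariates, with the group
coefficient reported as the adjusted mean difference and a t-based 95% CI.
With no covariates this reduces exactly to the raw difference of group
means.  Group coding follows the patients-minus-controls convention: the
estimate is mean(group_order[0]) − mean(group_order[1]), adjusted.

No multiplicity correction is applied by default (each contrast is reported
at its nominal level); an optional Benjamini–Hochberg adjustment is
available for batch runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import StatsError

__all__ = [
    "AdjustedDifference",
    "CorrelationResult",
    "ancova_difference",
    "pearson_by_group",
    "compare_demographics",
    "residualize",
    "batch_ancova",
]


@dataclass
class AdjustedDifference:
    """ANCOVA group effect: adjusted mean difference with 95% CI."""

    outcome: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates_used: list[str]
    n_per_group: tuple[int, int]
    group_order: tuple[str, str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        assert self.ci_low <= self.estimate <= self.ci_high
        assert 0.0 <= self.p_value <= 1.0

    def __str__(self) -> str:
        g1, g2 = self.group_order
        adj = ", ".join(self.covariates_used) if self.covariates_used else "none"
        return (
            f"{self.outcome}: {g1} − {g2} = {self.estimate:.4g} "
            f"(95% CI {self.ci_low:.4g}; {self.ci_high:.4g}), "
            f"p = {self.p_value:.3g} [adjusted for: {adj}; "
            f"n = {self.n_per_group[0]}/{self.n_per_group[1]}]"
        )


@dataclass
class CorrelationResult:
    """Pearson correlation within one group."""

    x: str
    y: str
    group: str
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.r <= 1.0 + 1e-12
        assert self.n >= 3

    def __str__(self) -> str:
        return (
            f"{self.x} vs {self.y} in {self.group}: "
            f"r = {self.r:.3f}, p = {self.p_value:.3g}, n = {self.n}"
        )


def _two_levels(table: pd.DataFrame, group_col: str) -> list[str]:
    levels = list(pd.unique(table[group_col].dropna()))
    if len(levels) != 2:
        raise StatsError(
            f"group column {group_col!r} must have exactly 2 levels, got {levels}"
        )
    return levels


def _check_collinear(X: pd.DataFrame) -> None:
    """Raise naming the first column linearly dependent on the ones before it."""
    arr = np.asarray(X, dtype=float)
    for j in range(1, arr.shape[1]):
        r_prev = np.linalg.matrix_rank(arr[:, :j])
        if np.linalg.matrix_rank(arr[:, : j + 1]) == r_prev:
            raise StatsError(
                f"design column {X.columns[j]!r} is collinear with "
                f"{list(X.columns[:j])}"
            )


def ancova_difference(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    group_col: str = "group",
    group_order: tuple[str, str] | None = None,
) -> AdjustedDifference:
    """Adjusted mean difference between two groups by OLS ANCOVA.

    ``group_order`` fixes the sign convention (first minus second); by
    default the order of first appearance in the table is used.  Rows with
    missing outcome or covariates are dropped (complete-case), and the count
    is reported.
    """
    covariates = list(covariates or [])
    levels = _two_levels(table, group_col)
    if group_order is None:
        group_order = (levels[0], levels[1])
    if set(group_order) != set(levels):
        raise StatsError(f"group_order {group_order} does not match levels {levels}")

    cols = [outcome, group_col, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise StatsError(f"columns not in table: {missing}")
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    n1 = int((data[group_col] == group_order[0]).sum())
    n2 = int((data[group_col] == group_order[1]).sum())
    if min(n1, n2) < 3:
        raise StatsError(f"need ≥ 3 subjects per group, got {n1}/{n2}")

    y = data[outcome].astype(float)
    if np.ptp(y.to_numpy()) == 0:
        raise StatsError(f"outcome {outcome!r} is constant")
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["__group__"] = (data[group_col] == group_order[0]).astype(float)
    for cov in covariates:
        X[cov] = data[cov].astype(float)
    _check_collinear(X)

    fit = sm.OLS(y, X).fit()
    est = float(fit.params["__group__"])
    se = float(fit.bse["__group__"])
    degenerate = (
        se == 0.0
        or not np.isfinite(se)
        or fit.ssr <= 1e-10 * fit.centered_tss  # residuals at float-noise level
    )
    if degenerate:
        # outcome fully explained by the covariates: a zero-residual fit has
        # no sampling variability, so the (exactly zero) group effect gets a
        # degenerate CI and p = 1
        ci_lo, ci_hi, p = est, est, 1.0
    else:
        ci = fit.conf_int(alpha=0.05).loc["__group__"]
        ci_lo, ci_hi, p = float(ci[0]), float(ci[1]), float(fit.pvalues["__group__"])
    return AdjustedDifference(
        outcome=outcome,
        estimate=est,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_value=p,
        covariates_used=covariates,
        n_per_group=(n1, n2),
        group_order=group_order,
        n_dropped=n_dropped,
    )


def pearson_by_group(
    table: pd.DataFrame,
    x: str,
    y: str,
    group_level: str,
    group_col: str = "group",
) -> CorrelationResult:
    """Pearson correlation between two features within one group.

    Complete cases only; two-sided p from the exact t distribution.
    """
    sub = table.loc[table[group_col] == group_level, [x, y]].dropna()
    if len(sub) < 3:
        raise StatsError(f"need ≥ 3 complete pairs in {group_level}, got {len(sub)}")
    xa, ya = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise StatsError("zero variance in x or y")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(
        x=x, y=y, group=group_level,
        r=float(res.statistic), p_value=float(res.pvalue), n=len(sub),
    )


def compare_demographics(
    table: pd.DataFrame,
    variable: str,
    test: str,
    group_col: str = "group",
) -> tuple[float, float]:
    """Two-sample demographic comparison.

    ``test`` is one of ``"t"`` (Student, pooled variance), ``"mann_whitney"``
    (two-sided, exact where scipy chooses it), or ``"chi_square"`` (2×k
    contingency, no continuity correction).  Returns (statistic, p).
    """
    levels = _two_levels(table, group_col)
    if test == "chi_square":
        sub = table[[group_col, variable]].dropna()
        counts = pd.crosstab(sub[group_col], sub[variable])
        if counts.to_numpy().sum() == 0:
            raise StatsError("all cell counts are zero")
        stat, p, _, _ = sps.chi2_contingency(counts.to_numpy(), correction=False)
        return float(stat), float(p)
    a = table.loc[table[group_col] == levels[0], variable].dropna().to_numpy(float)
    b = table.loc[table[group_col] == levels[1], variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need ≥ 2 observations per group")
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=True)
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise StatsError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def residualize(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
) -> pd.Series:
    """Covariate-adjusted feature: OLS residual plus the grand mean.

    A plain linear stand-in for normative covariate adjustment: the returned
    column has the same mean as the original and zero partial correlation
    with each covariate.  Rows with missing values yield NaN.
    """
    cols = [outcome, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise StatsError(f"columns not in table: {missing}")
    data = table[cols].dropna()
    if len(data) <= len(covariates) + 1:
        raise StatsError("too few complete cases to residualize")
    y = data[outcome].astype(float)
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for cov in covariates:
        X[cov] = data[cov].astype(float)
    _check_collinear(X)
    fit = sm.OLS(y, X).fit()
    adjusted = fit.resid + y.mean()
    return adjusted.reindex(table.index)


def batch_ancova(
    table: pd.DataFrame,
    outcomes: list[str],
    covariates: list[str] | None = None,
    group_col: str = "group",
    group_order: tuple[str, str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """ANCOVA over several outcomes, one row each (Table-style output).

    Columns: outcome, estimate, ci_low, ci_high, p, n1, n2.  With
    ``fdr=True`` a Benjamini–Hochberg adjusted p column is appended
    (off by default: each contrast reported at its nominal level).
    """
    rows = []
    for out in outcomes:
        res = ancova_difference(table, out, covariates, group_col, group_order)
        rows.append(
            {
                "outcome": out,
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p_value,
                "n1": res.n_per_group[0],
                "n2": res.n_per_group[1],
            }
        )
    df = pd.DataFrame(rows)
    if fdr and len(df):
        df["p_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
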