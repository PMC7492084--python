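"""Exact and classical statistics used throughout the pipeline.

Fisher's exact test follows the probability-mass convention for the
two-sided p-value (the sum of the probabilities of all tables, with the
same margins, that are no more probable than the observed one), which is
the convention of R's ``fisher.test``.  Odds ratios are the sample odds
ratio ``(a*d)/(b*c)``, with the Haldane–Anscombe 0.5 correction applied
only when a cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "odds_ratio_2x2",
    "welch_t_test",
    "anova",
    "bh_adjust",
    "apply_deg_criteria",
]

# Relative tolerance used when comparing hypergeometric table probabilities,
# matching R's fisher.test (relErr = 1 + 1e-7).
_REL_ERR = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table laid out as [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with degrees of freedom and p-value."""

    test: str
    statistic: float
    df: float
    p_value: float


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with Haldane–Anscombe correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value)``.  The p-value sums hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1 = a + b  # first row margin
    c1 = a + c  # first column margin
    amin = max(0, r1 + c1 - n)
    amax = min(r1, c1)
    support = np.arange(amin, amax + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * _REL_ERR].sum())
    return odds_ratio_2x2(a, b, c, d), min(p, 1.0)


def welch_t_test(x, y, pooled: bool = False) -> TestResult:
    """Independent two-sample t-test, Welch (unequal variances) by default.

    With ``pooled=True`` the classical equal-variance test is used instead.
    Two constant samples with equal means give t=0, p=1; a single constant
    sample is rejected because the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return TestResult("welch_t" if not pooled else "pooled_t", 0.0, df, 1.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(
        "pooled_t" if pooled else "welch_t",
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
    )


def _oneway_anova(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    levels, idx = np.unique(labels, return_inverse=True)
    if levels.size < 2:
        raise ValueError("one-way ANOVA needs at least two factor levels")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = 0.0
    for k in range(levels.size):
        g = values[idx == k]
        ss_between += g.size * (g.mean() - grand) ** 2
    ss_within = ss_total - ss_between
    df_b = levels.size - 1
    df_w = values.size - levels.size
    if ss_total <= 1e-300 or ss_within <= 0.0 and ss_between <= 0.0:
        return pd.DataFrame(
            {"F": [0.0], "df": [df_b], "df_resid": [df_w], "p_value": [1.0]},
            index=["factor_a"],
        )
    if ss_within <= 0.0:
        # perfect separation: infinite F, p -> 0
        return pd.DataFrame(
            {"F": [np.inf], "df": [df_b], "df_resid": [df_w], "p_value": [0.0]},
            index=["factor_a"],
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return pd.DataFrame(
        {"F": [F], "df": [df_b], "df_resid": [df_w], "p_value": [p]},
        index=["factor_a"],
    )


def anova(
    observations,
    factor_a,
    factor_b=None,
    two_way: bool = False,
    interaction: bool = True,
) -> pd.DataFrame:
    """One- or two-way fixed-effects ANOVA.

    One-way uses the classical between/within decomposition.  Two-way uses
    Type II sums of squares (via an OLS fit), which coincides with the
    classical decomposition for balanced designs; the interaction term is
    included only when every occupied cell has at least two observations.
    Returns a DataFrame indexed by effect with columns F, df, df_resid,
    p_value.
    """
    values = np.asarray(observations, dtype=float)
    fa = np.asarray(factor_a)
    if values.size != fa.size:
        raise ValueError("observations and factor_a differ in length")
    if not two_way:
        return _oneway_anova(values, fa)

    if factor_b is None:
        raise ValueError("two-way ANOVA requires factor_b")
    fb = np.asarray(factor_b)
    if fb.size != values.size:
        raise ValueError("observations and factor_b differ in length")
    la, lb = np.unique(fa), np.unique(fb)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each factor needs at least two levels")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    empty = [(str(i), str(j)) for i in cells.index for j in cells.columns if cells.loc[i, j] == 0]
    if interaction and empty:
        raise ValueError(f"empty cells prevent the interaction test: {empty}")
    if interaction and (cells.values[cells.values > 0] < 2).any():
        interaction = False  # interaction not estimable with singleton cells

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "A": fa.astype(str), "B": fb.astype(str)})
    if float(np.var(values)) <= 1e-300:
        idx = ["factor_a", "factor_b"] + (["interaction"] if interaction else [])
        return pd.DataFrame(
            {
                "F": 0.0,
                "df": [la.size - 1, lb.size - 1] + ([(la.size - 1) * (lb.size - 1)] if interaction else []),
                "df_resid": float(values.size - la.size * lb.size),
                "p_value": 1.0,
            },
            index=idx,
        )
    formula = "y ~ C(A) * C(B)" if interaction else "y ~ C(A) + C(B)"
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    rename = {"C(A)": "factor_a", "C(B)": "factor_b", "C(A):C(B)": "interaction"}
    out = {}
    df_resid = float(tab.loc["Residual", "df"])
    for row, name in rename.items():
        if row in tab.index:
            F = float(tab.loc[row, "F"])
            p = float(tab.loc[row, "PR(>F)"])
            if not np.isfinite(F):
                F, p = 0.0, 1.0
            out[name] = {"F": F, "df": float(tab.loc[row, "df"]), "df_resid": df_resid, "p_value": p}
    return pd.DataFrame(out).T[["F", "df", "df_resid", "p_value"]]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_deg_criteria(lfc, padj, fc_cut: float = 2.0, padj_cut: float = 0.01) -> np.ndarray:
    """Differential-expression call from log2 fold change and adjusted p.

    A gene is differential iff |LFC| >= log2(fc_cut) and padj < padj_cut
    (strict).  Returns an array over {"up", "down", "none"}.
    """
    lfc = np.asarray(lfc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if lfc.shape != padj.shape:
        raise ValueError("lfc and padj must have the same shape")
    if np.nanmin(padj, initial=0.0) < 0 or np.nanmax(padj, initial=0.0) > 1:
        raise ValueError("padj must lie in [0, 1]")
    cut = math.log2(fc_cut)
    is_deg = (np.abs(lfc) >= cut) & (padj < padj_cut)
    out = np.full(lfc.shape, "none", dtype=object)
    out[is_deg & (lfc > 0)] = "up"
    out[is_deg & (lfc < 0)] = "down"
    return out
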