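"""Normality-gated group comparisons and factorial ANOVA with Sidak post hoc.

This layer applies textbook procedures only: a D'Agostino-Pearson normality
gate choosing between an unpaired two-tailed t-test and a Mann-Whitney
U-test, and one- or two-way ANOVA with Sidak-adjusted pairwise p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "sidak_adjust", "factorial_compare"]


@dataclass
class ComparisonResult:
    group_names: tuple[str, str]
    normality_p: tuple[float, float]
    test_name: str  # t-test | mann-whitney
    statistic: float
    p_value: float
    means: tuple[float, float]
    sems: tuple[float, float]


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    names: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-group comparison with a normality gate on both samples.

    Both samples pass the D'Agostino-Pearson test at ``alpha`` -> unpaired
    two-tailed t-test; otherwise Mann-Whitney U (two-sided).  The omnibus
    normality test needs n >= 8 per sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 8 or len(b) < 8:
        raise ValueError(
            "normality test requires n >= 8 per group; use the nonparametric "
            "test directly for smaller samples"
        )
    norm_a = sps.normaltest(a).pvalue
    norm_b = sps.normaltest(b).pvalue
    if norm_a > alpha and norm_b > alpha:
        res = sps.ttest_ind(a, b)
        test = "t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return ComparisonResult(
        group_names=names,
        normality_p=(float(norm_a), float(norm_b)),
        test_name=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        means=(float(a.mean()), float(b.mean())),
        sems=(float(sps.sem(a)), float(sps.sem(b))),
    )


def sidak_adjust(p: float, m: int) -> float:
    """Sidak correction ``1 - (1 - p)**m`` for a family of ``m`` comparisons."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def factorial_compare(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    pairwise_within: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA over one or two factors plus Sidak-adjusted pairwise tests.

    Parameters
    ----------
    data, response, factors
        Tidy table, response column name, and one or two categorical factor
        column names.  With two factors the model includes the interaction
        when every cell has replication, and drops it otherwise.
    pairwise_within
        Factor whose levels to compare pairwise (t-tests) inside each level
        of the other factor; defaults to the first factor.  The Sidak family
        is the set of reported comparisons.

    Returns
    -------
    ``(anova_table, pairwise)`` data frames.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(factors) not in (1, 2):
        raise ValueError("one or two factors supported")
    df = data[[response] + factors].dropna().copy()
    df.columns = ["y"] + [f"f{i}" for i in range(len(factors))]

    if len(factors) == 1:
        formula = "y ~ C(f0)"
    else:
        cell_sizes = df.groupby(["f0", "f1"], observed=True).size()
        if (cell_sizes < 2).any():
            if len(cell_sizes) == df.shape[0]:
                raise ValueError(
                    "single observation per cell: interaction model is not estimable"
                )
            formula = "y ~ C(f0) + C(f1)"
        else:
            formula = "y ~ C(f0) * C(f1)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    # zero-variance data: no effect sum of squares means no effect (F = 0,
    # p = 1), not an undefined ratio
    degenerate = anova["sum_sq"].abs() < 1e-12
    anova.loc[degenerate, "F"] = 0.0
    anova.loc[degenerate, "PR(>F)"] = 1.0
    anova = anova.rename(
        index={f"C(f{i})": factors[i] for i in range(len(factors))}
    )
    if len(factors) == 2:
        anova = anova.rename(index={"C(f0):C(f1)": f"{factors[0]}:{factors[1]}"})

    within = pairwise_within or factors[0]
    wi = factors.index(within)
    other = None if len(factors) == 1 else f"f{1 - wi}"
    comparisons = []
    strata = [None] if other is None else sorted(df[other].unique())
    for stratum in strata:
        sub = df if stratum is None else df[df[other] == stratum]
        levels = sorted(sub[f"f{wi}"].unique())
        for la, lb in combinations(levels, 2):
            ya = sub.loc[sub[f"f{wi}"] == la, "y"]
            yb = sub.loc[sub[f"f{wi}"] == lb, "y"]
            t = sps.ttest_ind(ya, yb)
            stat, pval = float(t.statistic), float(t.pvalue)
            if np.isnan(stat) and np.isclose(ya.mean(), yb.mean()):
                stat, pval = 0.0, 1.0  # identical constant groups
            comparisons.append(
                {
                    "stratum": "" if stratum is None else stratum,
                    "level_a": la,
                    "level_b": lb,
                    "mean_a": ya.mean(),
                    "mean_b": yb.mean(),
                    "t": stat,
                    "p_raw": pval,
                }
            )
    pairwise = pd.DataFrame(comparisons)
    m = len(pairwise)
    if m:
        pairwise["p_sidak"] = [sidak_adjust(p, m) for p in pairwise["p_raw"]]
    return anova, pairwise
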