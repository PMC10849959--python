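"""Group-level statistical wrappers used across the pipeline.

The comparison style follows common practice in systems-neuroscience
papers: a normality test gates the choice between parametric and
nonparametric two-sample tests; repeated-measures two-way ANOVA with
Bonferroni-corrected per-time contrasts handles treatment × time designs;
one-way designs use ANOVA with Holm–Šídák-corrected pairwise contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

#: sample-size cutoff between Shapiro–Wilk and D'Agostino–Pearson
NORMALITY_TEST_CUTOFF_N = 50


@dataclass
class TestResult:
    """Outcome of a single two-sample comparison."""

    test_name: str
    statistic: float
    p_value: float
    normality_p: float | None = None


@dataclass
class AnovaResult:
    """Two-way RM ANOVA main effects plus adjusted per-time contrasts."""

    anova_table: pd.DataFrame
    contrasts: pd.DataFrame  # time_bin, statistic, p_raw, p_adj


def normality_p(x: np.ndarray) -> float:
    """Shapiro–Wilk for n ≤ 50, D'Agostino–Pearson above."""
    x = np.asarray(x, dtype=float)
    if x.size <= NORMALITY_TEST_CUTOFF_N:
        return float(sps.shapiro(x).pvalue)
    return float(sps.normaltest(x).pvalue)


def paired_compare(
    x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05
) -> TestResult:
    """Paired t-test or Wilcoxon signed-rank, gated on difference normality.

    The normality test runs on the paired differences; the degenerate
    all-equal case reports p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    if np.all(d == d[0]) and d[0] == 0:
        return TestResult("paired t-test", 0.0, 1.0, None)
    p_norm = normality_p(d)
    if p_norm > normality_alpha:
        res = sps.ttest_rel(y, x)
        return TestResult("paired t-test", float(res.statistic), float(res.pvalue), p_norm)
    res = sps.wilcoxon(y, x)
    return TestResult(
        "Wilcoxon signed-rank", float(res.statistic), float(res.pvalue), p_norm
    )


def unpaired_compare(
    x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05
) -> TestResult:
    """Unpaired t-test or Mann–Whitney U, gated on per-group normality."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    p_norm = min(normality_p(x), normality_p(y))
    if p_norm > normality_alpha:
        res = sps.ttest_ind(y, x)
        return TestResult(
            "unpaired t-test", float(res.statistic), float(res.pvalue), p_norm
        )
    res = sps.mannwhitneyu(y, x, alternative="two-sided")
    return TestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue), p_norm
    )


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, m·p)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def _check_balanced(
    table: pd.DataFrame, unit: str, factors: tuple[str, str]
) -> None:
    counts = table.groupby([unit, *factors], observed=True).size()
    if (counts != 1).any():
        dupes = counts[counts != 1]
        raise ValueError(f"duplicate cells in design: {dupes.index.tolist()[:5]}")
    units = table[unit].unique()
    cells = list(itertools.product(*(table[f].unique() for f in factors)))
    seen = set(map(tuple, table[[unit, *factors]].itertuples(index=False)))
    missing = [
        (u, *c) for u in units for c in cells if (u, *c) not in seen
    ]
    if missing:
        raise ValueError(f"unbalanced design; missing cells: {missing[:5]}")


def two_way_rm_anova(
    table: pd.DataFrame,
    unit: str = "unit_id",
    factors: tuple[str, str] = ("treatment", "time_bin"),
    value: str = "value",
    correction: str = "bonferroni",
) -> AnovaResult:
    """Repeated-measures treatment × time ANOVA with per-time contrasts.

    Requires a balanced long-format table (every unit measured in every
    treatment × time cell, once).  Per-time contrasts are paired t-tests
    between the two treatment levels, adjusted by Bonferroni (default) or
    Holm–Šídák across time bins.
    """
    _check_balanced(table, unit, factors)
    fit = AnovaRM(
        data=table, depvar=value, subject=unit, within=list(factors)
    ).fit()
    treat_col, time_col = factors
    levels = sorted(table[treat_col].unique())
    if len(levels) != 2:
        raise ValueError("per-time contrasts require exactly two treatment levels")
    rows = []
    for t_bin, sub in table.groupby(time_col, observed=True):
        a = sub[sub[treat_col] == levels[0]].sort_values(unit)[value].to_numpy()
        b = sub[sub[treat_col] == levels[1]].sort_values(unit)[value].to_numpy()
        res = sps.ttest_rel(b, a)
        rows.append(
            {time_col: t_bin, "statistic": float(res.statistic), "p_raw": float(res.pvalue)}
        )
    contrasts = pd.DataFrame(rows)
    if correction == "bonferroni":
        contrasts["p_adj"] = bonferroni(contrasts["p_raw"].to_numpy(), len(contrasts))
    elif correction in ("holm-sidak", "holm_sidak"):
        contrasts["p_adj"] = multipletests(
            contrasts["p_raw"].to_numpy(), method="holm-sidak"
        )[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return AnovaResult(anova_table=fit.anova_table, contrasts=contrasts)


def one_way_anova(
    table: pd.DataFrame,
    group: str = "group",
    value: str = "value",
    correction: str = "holm-sidak",
) -> AnovaResult:
    """One-way ANOVA with corrected pairwise contrasts."""
    groups = {g: sub[value].to_numpy(float) for g, sub in table.groupby(group, observed=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f_stat, f_p = sps.f_oneway(*groups.values())
    anova_table = pd.DataFrame(
        {"F Value": [float(f_stat)], "Pr > F": [float(f_p)]}, index=[group]
    )
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        res = sps.ttest_ind(groups[b], groups[a])
        rows.append(
            {
                "contrast": f"{a} vs {b}",
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
            }
        )
    contrasts = pd.DataFrame(rows)
    if correction == "bonferroni":
        contrasts["p_adj"] = bonferroni(contrasts["p_raw"].to_numpy(), len(contrasts))
    else:
        contrasts["p_adj"] = multipletests(
            contrasts["p_raw"].to_numpy(), method="holm-sidak"
        )[1]
    return AnovaResult(anova_table=anova_table, contrasts=contrasts)
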