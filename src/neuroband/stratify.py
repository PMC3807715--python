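"""Cohort stratification by the alpha3/alpha2 ratio and group comparisons.

Fixed-cutoff mode uses the published boundaries (low < 1.0 <= middle < 1.17
<= high; boundary values belong to the upper group).  Tertile mode derives
empirical cutoffs from the sample so group sizes differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("low", "middle", "high")
FIXED_CUTOFFS = (1.0, 1.17)

#: Continuous CohortTable columns compared across groups by default.
CONTINUOUS_VARIABLES = (
    "age",
    "education",
    "mmse",
    "wmh_volume",
    "alpha3_alpha2",
    "babcock",
    "avlt_immediate",
    "avlt_delayed",
    "rey_recall",
)
DICHOTOMOUS_VARIABLES = ("sex",)


def assign_groups(
    ratios: Sequence[float] | np.ndarray,
    mode: str = "fixed",
    cutoffs: tuple[float, float] | None = None,
) -> np.ndarray:
    """Label each ratio low/middle/high.

    ``fixed`` mode uses ``cutoffs`` (default 1.0 and 1.17); ``tertile`` mode
    derives cutoffs from the empirical 1/3 and 2/3 ranks.  In both modes a
    ratio equal to a cutoff belongs to the upper group.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0) or np.any(~np.isfinite(ratios)):
        raise ValueError("all alpha3/alpha2 ratios must be positive and finite")
    if mode == "fixed":
        lo_cut, hi_cut = cutoffs if cutoffs is not None else FIXED_CUTOFFS
    elif mode == "tertile":
        if len(ratios) == 0:
            raise ValueError("tertile mode needs a non-empty sample")
        if cutoffs is not None:
            raise ValueError("tertile mode derives its own cutoffs")
        lo_cut, hi_cut = tertile_cutoffs(ratios)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'fixed' or 'tertile'")
    labels = np.full(len(ratios), "middle", dtype=object)
    labels[ratios < lo_cut] = "low"
    labels[ratios >= hi_cut] = "high"
    return labels


def tertile_cutoffs(ratios: np.ndarray) -> tuple[float, float]:
    """Empirical cutoffs splitting the sample into near-equal thirds.

    Cutoff values are sample values; boundary-to-upper-group assignment then
    yields group sizes differing by at most one when all values are distinct.
    """
    srt = np.sort(np.asarray(ratios, dtype=float))
    n = len(srt)
    i1 = int(round(n / 3))
    i2 = int(round(2 * n / 3))
    i1 = min(max(i1, 1), n - 1)
    i2 = min(max(i2, i1), n - 1)
    return float(srt[i1]), float(srt[i2])


@dataclass
class VariableComparison:
    """Omnibus and post-hoc results for one cohort variable."""

    variable: str
    test: str  # "anova" or "chi2"
    omnibus_p: float
    levene_p: float | None = None
    posthoc_method: str | None = None  # "games-howell" or "bonferroni"
    pairwise_p: dict[tuple[str, str], float] | None = None
    degenerate: bool = False


def games_howell(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Games-Howell pairwise comparisons (unequal variances).

    Welch-type statistic referred to the studentized-range distribution with
    Welch-Satterthwaite degrees of freedom.
    """
    k = len(groups)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(groups, 2):
        xa, xb = groups[a], groups[b]
        na, nb = len(xa), len(xb)
        va, vb = xa.var(ddof=1) / na, xb.var(ddof=1) / nb
        se2 = va + vb
        if se2 == 0:
            out[(a, b)] = 1.0
            continue
        t = abs(xa.mean() - xb.mean()) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        q = t * np.sqrt(2.0)
        out[(a, b)] = float(stats.studentized_range.sf(q, k, df))
    return out


def bonferroni_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pooled-variance pairwise t-tests with Bonferroni correction."""
    pairs = list(combinations(groups, 2))
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        if groups[a].var(ddof=1) == 0 and groups[b].var(ddof=1) == 0:
            p = 1.0
        else:
            p = stats.ttest_ind(groups[a], groups[b], equal_var=True).pvalue
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out


def _compare_continuous(
    values: pd.Series, labels: pd.Series, variable: str
) -> VariableComparison:
    groups = {
        g: values[labels == g].to_numpy(dtype=float)
        for g in GROUP_ORDER
        if (labels == g).any()
    }
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return VariableComparison(variable, "anova", 1.0, degenerate=True)
    if all(np.ptp(a) == 0 for a in arrays):
        # All within-group variances zero: the F statistic is undefined.
        return VariableComparison(variable, "anova", 1.0, degenerate=True)
    omnibus = float(stats.f_oneway(*arrays).pvalue)
    levene = float(stats.levene(*arrays, center="median").pvalue)
    if levene < 0.05:
        method, pairwise = "games-howell", games_howell(groups)
    else:
        method, pairwise = "bonferroni", bonferroni_pairwise(groups)
    return VariableComparison(variable, "anova", omnibus, levene, method, pairwise)


def _compare_dichotomous(
    values: pd.Series, labels: pd.Series, variable: str
) -> VariableComparison:
    table = pd.crosstab(labels, values)
    if table.shape[1] < 2:
        return VariableComparison(variable, "chi2", 1.0, degenerate=True)
    p = float(stats.chi2_contingency(table.to_numpy()).pvalue)
    return VariableComparison(variable, "chi2", p)


def demographics_compare(
    cohort: pd.DataFrame,
    continuous: Iterable[str] = CONTINUOUS_VARIABLES,
    dichotomous: Iterable[str] = DICHOTOMOUS_VARIABLES,
    group_column: str = "group",
) -> dict[str, VariableComparison]:
    """Compare cohort variables across the low/middle/high groups.

    One-way ANOVA for continuous variables with Levene's test selecting
    Games-Howell (heteroscedastic) versus Bonferroni post-hoc comparisons;
    chi-squared for dichotomous variables.  Constant variables are flagged
    degenerate with p = 1.
    """
    labels = cohort[group_column]
    sizes = labels.value_counts()
    present = [g for g in GROUP_ORDER if sizes.get(g, 0) >= 2]
    if len(present) < 2:
        raise ValueError("need at least two groups with at least two subjects each")
    keep = labels.isin(present)
    results: dict[str, VariableComparison] = {}
    for var in continuous:
        if var in cohort.columns:
            results[var] = _compare_continuous(
                cohort.loc[keep, var], labels[keep], var
            )
    for var in dichotomous:
        if var in cohort.columns:
            results[var] = _compare_dichotomous(
                cohort.loc[keep, var], labels[keep], var
            )
    return results


def stratify_cohort(
    cohort: pd.DataFrame,
    mode: str = "fixed",
    cutoffs: tuple[float, float] | None = None,
    ratio_column: str = "alpha3_alpha2",
) -> pd.DataFrame:
    """Return a copy of the cohort table with a ``group`` column added."""
    out = cohort.copy()
    out["group"] = assign_groups(out[ratio_column].to_numpy(), mode, cutoffs)
    return out
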