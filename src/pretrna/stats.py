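"""Statistical tests shared by the architecture and tail-classification stages.

One-way fixed-effects ANOVA is computed from sums of squares so the full
(F, df_between, df_within, p) tuple is reported; Tukey's HSD uses the
studentized-range distribution via scipy, and the two-way replicate design
for tail-presence counts is fitted by OLS with type-II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA: F = MS_between / MS_within.

    Raises ``ValueError`` with fewer than two groups, any group of size < 2,
    or zero pooled within-group variance (F undefined).
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(F=float(f), df_between=df_between, df_within=df_within, p=p)


def tukey_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons (studentized-range adjusted p).

    Returns a DataFrame with columns group_a, group_b, mean_diff, p_adj.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            rows.append({
                "group_a": keys[i], "group_b": keys[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def two_way_anova(table: pd.DataFrame, response: str,
                  factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction, type-II sums of squares.

    Type II keeps main-effect tests meaningful under mildly unbalanced
    replicate structures.  Returns the statsmodels ANOVA table.
    """
    formula = f"{response} ~ C({factor_a}) * C({factor_b})"
    model = smf.ols(formula, data=table).fit()
    return sm.stats.anova_lm(model, typ=2)


def bonferroni_by_level(table: pd.DataFrame, response: str, condition: str,
                        level: str) -> pd.DataFrame:
    """Per-level two-sample comparisons with Bonferroni adjustment.

    For each level of ``level`` (e.g. each uridylate tail length) the two
    conditions are compared by Welch's t-test and the p-value is multiplied
    by the number of levels, capped at 1.
    """
    levels = sorted(table[level].unique())
    conditions = sorted(table[condition].unique())
    if len(conditions) != 2:
        raise ValueError("per-level comparisons need exactly two conditions")
    rows = []
    for lv in levels:
        sub = table[table[level] == lv]
        a = sub.loc[sub[condition] == conditions[0], response].to_numpy(float)
        b = sub.loc[sub[condition] == conditions[1], response].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            p = 1.0  # identical constant responses: no evidence of a difference
        else:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({
            level: lv, "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "p_raw": p, "p_adj": min(1.0, p * len(levels)),
        })
    return pd.DataFrame(rows)


def pearson_log2(x: Sequence[float], y: Sequence[float],
                 log_x: bool = True, log_y: bool = False) -> tuple[float, float]:
    """Pearson r (and p) with optional log2 transform of either vector.

    Pairs where a to-be-logged value is <= 0 are dropped.  Requires >= 3
    informative pairs and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.ones(x.size, dtype=bool)
    if log_x:
        keep &= x > 0
    if log_y:
        keep &= y > 0
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three informative pairs")
    if log_x:
        x = np.log2(x)
    if log_y:
        y = np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
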