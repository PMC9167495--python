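"""Group statistics: one-way ANOVA and Tukey's HSD multiple comparison.

Used for comparisons such as protein length across the four CTLDcp families.
Implemented from the classical between/within mean-square formulas so that
the zero-within-variance edge case is defined (F reported as infinite with
p = 0 when means differ; F = 0, p = 1 when they agree); p values come from
scipy's F and studentized-range distributions.  Significance convention is
two-tailed p < 0.05; reported only, never used to filter data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    n_per_group: dict[str, int]
    df_between: int
    df_within: int
    ms_within: float


def _validate(groups: dict) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrays = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than two values")
        arrays[str(label)] = arr
    return arrays


def anova_oneway(groups: dict) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over labeled value lists."""
    arrays = _validate(groups)
    k = len(arrays)
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    n_total = all_values.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        if ms_b == 0:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=F,
        p=p,
        group_means={lab: float(a.mean()) for lab, a in arrays.items()},
        n_per_group={lab: int(a.size) for lab, a in arrays.items()},
        df_between=df_b,
        df_within=df_w,
        ms_within=float(ms_w),
    )


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """Tukey's HSD pairwise comparisons.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with adjusted p
    from the studentized range distribution (Tukey-Kramer for unequal n).
    """
    arrays = _validate(groups)
    anova = anova_oneway(groups)
    k = len(arrays)
    labels = list(arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[labels[i]], arrays[labels[j]]
            diff = float(a.mean() - b.mean())
            se = math.sqrt(anova.ms_within / 2 * (1 / a.size + 1 / b.size))
            if se == 0:
                q = 0.0 if diff == 0 else math.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, anova.df_within))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": p,
                }
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "q", "p_adj"])


__all__ = ["AnovaResult", "anova_oneway", "tukey_hsd"]
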