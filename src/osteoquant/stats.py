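"""Cohort statistics: pooled t-tests, one-way ANOVA and Tukey HSD.

Thin, typed wrappers over scipy.stats with the conventions used throughout
the package: two-sided tests, pooled-variance "Student" t by default (Welch
available), Tukey HSD flagged at alpha = 0.05 and 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupTable", "ComparisonResult", "student_t", "anova_tukey", "make_group_table"]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False  # zero pooled variance with equal means


def make_group_table(groups: dict[str, np.ndarray], metric: str, units: str = "") -> pd.DataFrame:
    """Long-format table: one row per sample with its group label."""
    rows = []
    for label, values in groups.items():
        for v in np.asarray(values, float):
            rows.append({"group": label, "value": v, "metric": metric, "units": units})
    df = pd.DataFrame(rows)
    if df["group"].nunique() < 2:
        raise ValueError("a group table needs at least two groups")
    return df


#: alias for documentation symmetry — a GroupTable is a plain DataFrame
GroupTable = pd.DataFrame


def student_t(
    group_a: np.ndarray, group_b: np.ndarray, kind: str = "pooled"
) -> ComparisonResult:
    """Two-sided t-test; ``kind`` is "pooled" (Student) or "welch"."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind not in ("pooled", "welch"):
        raise ValueError("kind must be 'pooled' or 'welch'")
    equal_var = kind == "pooled"
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return ComparisonResult("student_t", 0.0, df, 1.0, degenerate=True)
        sign = np.sign(a.mean() - b.mean())
        return ComparisonResult("student_t", float(sign * np.inf), df, 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(a.size + b.size - 2) if equal_var else float(res.df)
    name = "student_t" if equal_var else "welch_t"
    return ComparisonResult(name, float(res.statistic), df, float(res.pvalue))


def anova_tukey(
    groups: dict[str, np.ndarray], alphas: tuple[float, float] = (0.05, 0.01)
) -> ComparisonResult:
    """One-way ANOVA with post-hoc Tukey HSD on all group pairs.

    Pairwise results carry the mean difference, the studentized-range p-value,
    the confidence interval at the first alpha, and significance flags at each
    requested alpha.  Requires >= 3 groups (use :func:`student_t` for two).
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey requires at least 3 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], float) for k in labels]
    for k, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    if all(a.var(ddof=1) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        n_tot = sum(a.size for a in arrays)
        pw = pd.DataFrame(
            [
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": 0.0,
                    "p_value": 1.0,
                    "ci_low": 0.0,
                    "ci_high": 0.0,
                    f"significant_{alphas[0]}": False,
                    f"significant_{alphas[1]}": False,
                }
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
            ]
        )
        return ComparisonResult(
            "anova_tukey", 0.0, float(len(labels) - 1), 1.0, pw, degenerate=True
        )
    f_stat, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    ci = tk.confidence_interval(confidence_level=1.0 - alphas[0])
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pv = float(tk.pvalue[i, j])
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_value": pv,
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    f"significant_{alphas[0]}": pv < alphas[0],
                    f"significant_{alphas[1]}": pv < alphas[1],
                }
            )
    df_between = float(len(labels) - 1)
    return ComparisonResult("anova_tukey", float(f_stat), df_between, float(p), pd.DataFrame(rows))
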