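"""Cohort-level summaries and group comparisons.

Morphometry tables have a two-level structure — several villi measured per
mouse, several mice per group — so summaries are always emitted at both
levels: villus-level n counts villi, mouse-level n first averages within each
mouse. Reporting only the villus level risks pseudo-replication; the package
surfaces both rather than silently choosing.

Two-group comparisons default to Welch's two-tailed t-test (the pooled
classical test is available via ``equal_var=True``); multi-group designs use
one-way ANOVA with Tukey's HSD post hoc over all pairs. Reports include the
difference of means with a 95% confidence interval. No correction is applied
across metrics; Tukey already controls the family-wise error within one
ANOVA family.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("group", "mouse_id")


def _check_table(table: pd.DataFrame, metric: str | None = None) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table must have a {col!r} column")
    if metric is not None and metric not in table.columns:
        raise ValueError(f"metric {metric!r} not in table columns")


def summarize(table: pd.DataFrame, level: str = "villus",
              metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-group n, mean, s.e.m., median and IQR for each metric.

    ``level='villus'`` treats every row as one observation; ``level='mouse'``
    first collapses to per-mouse means. With n = 1 the s.e.m. is undefined
    and reported as NaN with a flag.
    """
    _check_table(table)
    if level not in ("villus", "mouse"):
        raise ValueError(f"level must be 'villus' or 'mouse', got {level!r}")
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in REQUIRED_COLUMNS + ("sample_id", "label_id", "flags",
                                                   "surface_method", "schema_version")
                   and pd.api.types.is_numeric_dtype(table[c])]
    data = table
    if level == "mouse":
        data = (table.groupby(["group", "mouse_id"], sort=True)[list(metrics)]
                .mean().reset_index())
    out = []
    for (group,), sub in data.groupby(["group"], sort=True):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            n = len(vals)
            row = {
                "group": group, "metric": m, "level": level, "n": n,
                "mean": float(np.mean(vals)) if n else float("nan"),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "median": float(np.median(vals)) if n else float("nan"),
                "q1": float(np.percentile(vals, 25)) if n else float("nan"),
                "q3": float(np.percentile(vals, 75)) if n else float("nan"),
                "flags": "" if n > 1 else "sem_undefined",
            }
            out.append(row)
    return pd.DataFrame(out)


def _mean_diff_ci(a: np.ndarray, b: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Welch 95% CI on mean(a) - mean(b)."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    if se == 0:
        return float(np.mean(a) - np.mean(b)), 0.0, 0.0
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    tcrit = stats.t.ppf(0.5 + conf / 2, df)
    d = float(np.mean(a) - np.mean(b))
    return d, d - tcrit * se, d + tcrit * se


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    design: str = "auto",
    level: str = "villus",
    equal_var: bool = False,
    post_hoc: bool = True,
) -> dict:
    """Two-group Welch t-test or one-way ANOVA + Tukey HSD on one metric.

    Returns a JSON-serialisable report with the test statistic, degrees of
    freedom, p-value(s) and effect sizes (differences of means with 95% CI).
    Results are invariant to group naming and row order (groups are processed
    in sorted order).
    """
    _check_table(table, metric)
    data = table
    if level == "mouse":
        data = (table.groupby(["group", "mouse_id"], sort=True)[[metric]]
                .mean().reset_index())
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    samples = []
    for g in groups:
        vals = data.loc[data["group"] == g, metric].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(vals)
    if design == "auto":
        design = "two_group" if len(groups) == 2 else "multi_group"
    if design == "two_group":
        if len(groups) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        a, b = samples
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        d, lo, hi = _mean_diff_ci(a, b)
        return {
            "design": "two_group",
            "test": "welch_t" if not equal_var else "student_t",
            "metric": metric,
            "level": level,
            "groups": list(groups),
            "n": [len(s) for s in samples],
            "means": [float(np.mean(s)) for s in samples],
            "t": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
            "mean_difference": d,
            "ci95": [lo, hi],
        }
    if design != "multi_group":
        raise ValueError(f"unknown design {design!r}")
    f, p = stats.f_oneway(*samples)
    pairs = []
    if post_hoc:
        tk = stats.tukey_hsd(*samples)
        ci = tk.confidence_interval(confidence_level=0.95)
        for i, j in itertools.combinations(range(len(groups)), 2):
            d = float(np.mean(samples[i]) - np.mean(samples[j]))
            pairs.append({
                "groups": [groups[i], groups[j]],
                "mean_difference": d,
                "p_adj": float(tk.pvalue[i, j]),
                "ci95": [float(ci.low[i, j]), float(ci.high[i, j])],
            })
    n_total = sum(len(s) for s in samples)
    return {
        "design": "multi_group",
        "test": "anova_tukey",
        "metric": metric,
        "level": level,
        "groups": list(groups),
        "n": [len(s) for s in samples],
        "means": [float(np.mean(s)) for s in samples],
        "F": float(f),
        "df": [len(groups) - 1, n_total - len(groups)],
        "p": float(p),
        "tukey": pairs,
    }
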