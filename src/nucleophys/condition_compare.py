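"""Condition-level aggregation and comparison statistics.

Per-cell measurements (mean RI, volume, diffusion coefficient) are held
in a long-format table with columns ``cell_id``, ``condition``,
``compartment``, ``metric``, ``value``.  Group summaries report mean,
SD, SEM (= SD / sqrt(n)) and n; conditions are compared to a baseline
with a two-sided Student's (pooled-variance) t-test at alpha = 0.05, a
Welch variant being available behind a flag.  No multiple-testing
correction is applied; raw p-values are reported.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "hypertonic", "hypotonic", "atp_depletion", "act_d")
COMPARTMENTS = ("nucleolus", "nucleoplasm", "cytoplasm")
METRICS = ("mean_ri", "volume_um3", "D_um2s")

_REQUIRED_COLUMNS = ("cell_id", "condition", "compartment", "metric", "value")


def validate_condition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table: required columns present
    and one value per (cell, condition, compartment, metric)."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"condition table missing columns: {missing}")
    keys = ["cell_id", "condition", "compartment", "metric"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (cell, condition, compartment, metric) rows")
    return table


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, SEM and n per (condition, compartment, metric) group.

    Raises if any group has fewer than two cells (SEM undefined).
    """
    validate_condition_table(table)
    g = table.groupby(["condition", "compartment", "metric"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, ["condition", "compartment", "metric"]]
        raise ValueError(f"groups with n < 2:\n{bad}")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


class TTestResult(NamedTuple):
    t: float
    p: float
    significant: bool


def ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sample two-sided t-test (Student's pooled-variance by default,
    Welch if ``welch=True``).  Degenerate zero-variance groups with equal
    means give t = 0, p = 1."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, significant=False)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t_stat, p_val = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t_stat):
        return TTestResult(t=0.0, p=1.0, significant=False)
    return TTestResult(t=t_stat, p=p_val, significant=p_val < alpha)


def condition_report(
    table: pd.DataFrame,
    baseline: str = "normal",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Compare every non-baseline condition with the baseline, per
    compartment and metric: percent change of the group mean, t-test
    and a significance star at p < alpha.

    A (compartment, metric) present in the baseline but missing for a
    condition is skipped with a logged warning.
    """
    validate_condition_table(table)
    if baseline not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline!r} absent from table")
    rows = []
    base = table[table["condition"] == baseline]
    for cond in sorted(set(table["condition"]) - {baseline}):
        cur = table[table["condition"] == cond]
        for (comp, metric), base_grp in base.groupby(["compartment", "metric"]):
            sel = cur[(cur["compartment"] == comp) & (cur["metric"] == metric)]
            if len(sel) < 2:
                logger.warning(
                    "condition %r has no usable group for (%s, %s); skipped",
                    cond, comp, metric,
                )
                continue
            a = base_grp["value"].to_numpy()
            b = sel["value"].to_numpy()
            res = ttest(a, b, alpha=alpha, welch=welch)
            rows.append(
                {
                    "condition": cond,
                    "compartment": comp,
                    "metric": metric,
                    "baseline_mean": a.mean(),
                    "condition_mean": b.mean(),
                    "percent_change": 100.0 * (b.mean() - a.mean()) / a.mean(),
                    "t": res.t,
                    "p": res.p,
                    "significant": res.significant,
                    "n_baseline": a.size,
                    "n_condition": b.size,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "compartment", "metric", "baseline_mean", "condition_mean",
            "percent_change", "t", "p", "significant", "n_baseline", "n_condition",
        ],
    )
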