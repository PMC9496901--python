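"""Longitudinal descriptive statistics: percent changes and t-tests.

The feature table is a wide DataFrame indexed by ``(patient_id,
scan_point)`` with one column per ``ROI_Sequence_Feature`` name.  The
longitudinal report gives, per feature: mean +/- SD and n at each scan
point, two-tailed t-tests against baseline and against the previous
scan, and percent changes of the scan means.  Tests default to the
unpaired two-sample form (per-scan sample sizes differ under
attrition); paired and Welch variants are available, and an optional
Benjamini-Hochberg correction is off by default (raw p-values are
reported).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["percent_change", "compare_groups", "longitudinal_report", "GroupComparison"]

SCAN_ORDER = ("S1", "S2", "S3", "S4")


def percent_change(v_ref: float, v_new: float) -> float:
    """Signed percent change of ``v_new`` relative to ``v_ref``.

    Returns NaN when the reference is zero (undefined change).
    """
    if v_ref == 0 or not np.isfinite(v_ref) or not np.isfinite(v_new):
        return float("nan")
    return 100.0 * (v_new - v_ref) / v_ref


def describe_change(pct: float) -> tuple[float, str]:
    """Magnitude plus direction flag, for 'decreased by x%' style reporting."""
    if not np.isfinite(pct):
        return float("nan"), "undefined"
    return abs(pct), ("increase" if pct > 0 else "decrease" if pct < 0 else "no change")


@dataclass
class GroupComparison:
    """Two-tailed t-test result with means and a CI on the mean difference."""

    t: float
    p: float
    mean_a: float
    mean_b: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    df: float
    missing: bool = False
    reason: str = ""


def _missing(reason: str) -> GroupComparison:
    nan = float("nan")
    return GroupComparison(nan, nan, nan, nan, nan, nan, 0, 0, nan, missing=True, reason=reason)


def compare_groups(
    a,
    b,
    *,
    paired: bool = False,
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-tailed Student (or Welch) t-test between two samples.

    For ``paired=True`` the inputs must be pandas Series aligned by
    patient id; incomplete pairs are dropped listwise.  Fewer than two
    observations per group (after deletion) yields a missing result with
    a reason rather than an exception.
    """
    if paired:
        if not isinstance(a, pd.Series) or not isinstance(b, pd.Series):
            a, b = pd.Series(np.asarray(a, float)), pd.Series(np.asarray(b, float))
        df_pairs = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
        if len(df_pairs) < 2:
            return _missing(f"only {len(df_pairs)} complete pairs")
        x, y = df_pairs["a"].to_numpy(), df_pairs["b"].to_numpy()
        res = sps.ttest_rel(x, y)
        d = x - y
        dof = len(d) - 1
        se = d.std(ddof=1) / np.sqrt(len(d))
        tcrit = sps.t.ppf(1 - alpha / 2, dof)
        lo, hi = d.mean() - tcrit * se, d.mean() + tcrit * se
        return GroupComparison(
            float(res.statistic), float(res.pvalue), float(x.mean()), float(y.mean()),
            float(lo), float(hi), len(d), len(d), float(dof),
        )
    x = np.asarray(pd.Series(a).dropna(), dtype=float)
    y = np.asarray(pd.Series(b).dropna(), dtype=float)
    if len(x) < 2 or len(y) < 2:
        return _missing(f"group sizes {len(x)}/{len(y)} below 2")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    dof = float(res.df)
    diff = x.mean() - y.mean()
    if welch:
        se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
    else:
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        se = np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    return GroupComparison(
        float(res.statistic), float(res.pvalue), float(x.mean()), float(y.mean()),
        float(diff - tcrit * se), float(diff + tcrit * se), len(x), len(y), dof,
    )


def longitudinal_report(
    table: pd.DataFrame,
    *,
    paired: bool = False,
    welch: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-feature, per-scan summary with change tests and percent changes.

    ``table`` must be indexed by ``(patient_id, scan_point)``.  Output has
    one row per (feature, scan_point) with n, mean, SD, percent change of
    the scan mean vs baseline and vs the previous scan, and the
    corresponding two-tailed t-test p-values.
    """
    scans = [s for s in SCAN_ORDER if s in table.index.get_level_values("scan_point")]
    if len(scans) < 2:
        raise ValueError("need at least two scan points for a longitudinal report")
    rows = []
    for feat in table.columns:
        per_scan = {s: table.xs(s, level="scan_point")[feat].dropna() for s in scans}
        base = scans[0]
        for k, s in enumerate(scans):
            vals = per_scan[s]
            row = {
                "feature": feat,
                "scan_point": s,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
            if s != base:
                row["pct_change_vs_baseline"] = percent_change(
                    per_scan[base].mean(), vals.mean()
                )
                cmp_b = compare_groups(vals, per_scan[base], paired=paired, welch=welch)
                row["p_vs_baseline"] = cmp_b.p
                prev = scans[k - 1]
                row["pct_change_vs_prev"] = percent_change(per_scan[prev].mean(), vals.mean())
                cmp_p = compare_groups(vals, per_scan[prev], paired=paired, welch=welch)
                row["p_vs_prev"] = cmp_p.p
            else:
                row.update(
                    pct_change_vs_baseline=float("nan"), p_vs_baseline=float("nan"),
                    pct_change_vs_prev=float("nan"), p_vs_prev=float("nan"),
                )
            rows.append(row)
    report = pd.DataFrame(rows)
    if bh_correct:
        for col in ("p_vs_baseline", "p_vs_prev"):
            mask = report[col].notna()
            if mask.any():
                report.loc[mask, col + "_bh"] = multipletests(
                    report.loc[mask, col], method="fdr_bh"
                )[1]
    return report
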