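"""Two-group and subgroup comparisons across adequate samples.

Per-sample metrics are compared with the two-sided Mann-Whitney U test —
exact enumeration for small tie-free groups, normal approximation with tie
correction otherwise.  No multiple-testing correction is applied by default
(each row is reported as-is); Benjamini-Hochberg is available behind a flag.
Group summaries report both mean and median, since means are the common
printed summary while plots usually mark medians.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import SampleResult

__all__ = [
    "compare_metric",
    "run_comparison_panel",
    "mann_whitney_row",
    "PANEL_METRICS",
]

COLUMNS = [
    "metric", "group_a", "group_b", "n_a", "n_b", "n_dropped",
    "mean_a", "mean_b", "median_a", "median_b",
    "statistic", "p_value", "direction", "flagged", "flag_reason",
]

#: cancer-vs-high-risk panel metrics (leukocyte compartment, TCPP strata and
#: the TCPP-bright epithelial compartment)
PANEL_METRICS = [
    "pct_cd45_of_live_singles",
    "pct_gate1_of_cd45",
    "pct_gate3_of_cd45",
    "pct_tcpp_low_of_live_singles",
    "pct_tcpp_im_of_live_singles",
    "pct_tcpp_high_of_live_singles",
    "tcpp_high_ssc_median",
    "tcpp_high_pct_pp_of_cd45neg",
    "tcpp_high_epcam_mfi_pp",
    "tcpp_high_panck_mfi_pp",
]
#: high-risk current-vs-former-smoker contrasts
SMOKING_METRICS = [
    "tcpp_high_pct_pp_of_cd45neg",
    "pct_gate2_of_cd45",
    "pct_gate3_of_cd45",
]


def _flagged_row(metric: str, a_label: str, b_label: str, reason: str) -> dict:
    return {
        "metric": metric, "group_a": a_label, "group_b": b_label,
        "n_a": 0, "n_b": 0, "n_dropped": 0,
        "mean_a": math.nan, "mean_b": math.nan,
        "median_a": math.nan, "median_b": math.nan,
        "statistic": math.nan, "p_value": math.nan,
        "direction": "n/a", "flagged": True, "flag_reason": reason,
    }


def mann_whitney_row(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    a_label: str = "A",
    b_label: str = "B",
    use_t_test: bool = False,
) -> dict:
    """One comparison-table row for two per-sample value lists.

    NaN values (undefined metrics) are dropped with their count noted.  A
    group left with fewer than two values flags the row as not computable.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n_dropped = int(np.isnan(a).sum() + np.isnan(b).sum())
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        row = _flagged_row(metric, a_label, b_label, "fewer than 2 samples in a group")
        row["n_a"], row["n_b"], row["n_dropped"] = len(a), len(b), n_dropped
        return row

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        stat, p = len(a) * len(b) / 2.0, 1.0
    elif use_t_test:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        small = max(len(a), len(b)) <= 20
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)

    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a != med_b:
        direction = f"{a_label}>{b_label}" if med_a > med_b else f"{a_label}<{b_label}"
    else:
        mean_a_, mean_b_ = float(np.mean(a)), float(np.mean(b))
        if mean_a_ > mean_b_:
            direction = f"{a_label}>{b_label}"
        elif mean_a_ < mean_b_:
            direction = f"{a_label}<{b_label}"
        else:
            direction = f"{a_label}={b_label}"
    return {
        "metric": metric, "group_a": a_label, "group_b": b_label,
        "n_a": len(a), "n_b": len(b), "n_dropped": n_dropped,
        "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        "median_a": med_a, "median_b": med_b,
        "statistic": float(stat), "p_value": min(max(float(p), 0.0), 1.0),
        "direction": direction, "flagged": False, "flag_reason": "",
    }


def _metric_values(
    results: Sequence[SampleResult], metric: str
) -> np.ndarray:
    return np.array([r.metrics.get(metric, math.nan) for r in results], dtype=float)


def compare_metric(
    results: Sequence[SampleResult],
    labels: Sequence[str],
    metric: str,
    group_a: str,
    group_b: str,
    use_t_test: bool = False,
) -> pd.DataFrame:
    """Compare one per-sample metric between two labeled groups."""
    labels = np.asarray(labels)
    res = np.asarray(results, dtype=object)
    a = _metric_values(res[labels == group_a], metric)
    b = _metric_values(res[labels == group_b], metric)
    row = mann_whitney_row(a, b, metric, group_a, group_b, use_t_test)
    return pd.DataFrame([row], columns=COLUMNS)


def run_comparison_panel(
    results: Sequence[SampleResult],
    meta: Sequence[Mapping[str, str]],
    use_t_test: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """The fixed comparison panel across an analyzed cohort.

    ``meta`` supplies per-sample ``group`` (cancer / high_risk), ``smoking``
    (current / former) and, for cancer samples, ``stage`` (I/II, III/IV,
    unknown).  Rows: the cancer-vs-high-risk metric panel, the within-cancer
    Stage I/II vs III/IV EpCAM intensity contrast, and the within-high-risk
    current-vs-former smoker contrasts.  ``bh_correct`` adds a
    Benjamini-Hochberg adjusted column (off by default: every row is
    reported unadjusted, as is conventional for exploratory panels).
    """
    results = list(results)
    meta = list(meta)
    if len(results) != len(meta):
        raise ValueError("results and meta must align")
    groups = np.array([m.get("group", "") for m in meta])
    if len(set(groups) & {"cancer", "high_risk"}) < 2:
        raise ValueError("panel needs both cancer and high_risk groups")
    rows = []
    labels = groups
    for metric in PANEL_METRICS:
        rows.append(
            compare_metric(results, labels, metric, "cancer", "high_risk", use_t_test)
            .iloc[0].to_dict()
        )

    # within cancer: Stage I/II vs III/IV EpCAM intensity of TCPP-high
    # EpCAM+panCK+ cells
    ca = [i for i, m in enumerate(meta) if m.get("group") == "cancer"]
    stages = np.array([meta[i].get("stage", "") for i in ca])
    ca_results = [results[i] for i in ca]
    if {"I/II", "III/IV"} <= set(stages):
        row = mann_whitney_row(
            _metric_values(np.asarray(ca_results, dtype=object)[stages == "I/II"],
                           "tcpp_high_epcam_mfi_pp"),
            _metric_values(np.asarray(ca_results, dtype=object)[stages == "III/IV"],
                           "tcpp_high_epcam_mfi_pp"),
            "tcpp_high_epcam_mfi_pp", "stage_I/II", "stage_III/IV", use_t_test,
        )
    else:
        row = _flagged_row(
            "tcpp_high_epcam_mfi_pp", "stage_I/II", "stage_III/IV",
            "stage covariate missing",
        )
    rows.append(row)

    # within high-risk: current vs former smokers
    hr = [i for i, m in enumerate(meta) if m.get("group") == "high_risk"]
    smoking = np.array([meta[i].get("smoking", "") for i in hr])
    hr_results = np.asarray([results[i] for i in hr], dtype=object)
    for metric in SMOKING_METRICS:
        if {"current", "former"} <= set(smoking):
            row = mann_whitney_row(
                _metric_values(hr_results[smoking == "current"], metric),
                _metric_values(hr_results[smoking == "former"], metric),
                metric, "hr_current", "hr_former", use_t_test,
            )
        else:
            row = _flagged_row(metric, "hr_current", "hr_former",
                               "smoking covariate missing")
        rows.append(row)

    table = pd.DataFrame(rows, columns=COLUMNS)
    if bh_correct:
        ok = ~table["p_value"].isna()
        adjusted = np.full(len(table), math.nan)
        if ok.any():
            p = table.loc[ok, "p_value"].to_numpy()
            order = np.argsort(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty_like(ranked)
            out[order] = np.clip(ranked, 0, 1)
            adjusted[ok.to_numpy()] = out
        table["p_adjusted_bh"] = adjusted
    return table
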