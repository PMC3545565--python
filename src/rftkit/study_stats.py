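"""Group-level statistics: fold changes, paired t-tests, one-way ANOVA
with Bonferroni-corrected pairwise comparisons, and a grouped summary
report in the style of a three-condition (baseline / pre-training /
post-training) physiology study.

Also bundles the published reference group means for the wearable
RFT-biofeedback validation study's HRV table, used to verify the
reporting arithmetic (normalized-unit ratios and fold changes) rather
than to reproduce human-subject data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change",
    "paired_ttest",
    "oneway_anova_bonferroni",
    "build_group_report",
    "REFERENCE_GROUP_MEANS",
    "GROUP_LABELS",
    "BONFERRONI_ALPHA",
]

GROUP_LABELS = ("BL", "PRE_RFT", "POST_RFT")
PAIRWISE_ALPHA = 0.05
#: three pairwise comparisons -> 0.05 / 3
BONFERRONI_ALPHA = 0.05 / 3

#: Published reference group means (BL, pre-RFT, post-RFT) of the HRV
#: variables in the validation study; units: CR ratio, SDNN/rMSSD ms,
#: LF/HF normalized units (%), LF/HF ratio, TP ms^2.  Used for
#: arithmetic-consistency checks only.
REFERENCE_GROUP_MEANS = pd.DataFrame(
    {
        "BL": [1.98, 56.4, 30.3, 68.7, 31.3, 2.19, 2154.0],
        "PRE_RFT": [0.87, 27.8, 19.4, 86.5, 13.5, 6.41, 998.0],
        "POST_RFT": [1.74, 55.3, 28.9, 65.7, 34.3, 1.92, 1966.0],
    },
    index=["cr", "sdnn", "rmssd", "lf_nu", "hf_nu", "lf_hf", "tp"],
)


def fold_change(a: float, b: float) -> tuple[float, float]:
    """Fold (b/a, 2 decimals) and percent change (100*(b-a)/a, 1 decimal).

    The two are consistent before rounding: fold = 1 + pct/100.
    """
    if a <= 0:
        raise ValueError(f"reference value must be positive, got {a}")
    fold = b / a
    pct = 100.0 * (b - a) / a
    return round(fold, 2), round(pct, 1)


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired Student's t-test with n-1 degrees of freedom.

    Identical samples return (0.0, 1.0); nonzero constant differences
    have zero variance and no finite t statistic, and raise instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def oneway_anova_bonferroni(*groups, alpha: float = BONFERRONI_ALPHA):
    """One-way ANOVA across k groups plus Bonferroni-flagged pairwise t-tests.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps index pairs
    ``(i, j)`` to ``(t, p, significant)`` with equal-variance two-sample
    t-tests flagged at ``alpha`` (0.05/3 by default).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    f_stat, p_val = stats.f_oneway(*arrays)
    pairwise = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
            pairwise[(i, j)] = (float(t), float(p), bool(p < alpha))
    return float(f_stat), float(p_val), pairwise


def build_group_report(cohort_metrics: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Grouped mean +/- SD summary with ANOVA and pre/post fold changes.

    ``cohort_metrics`` maps each of the three group labels to a
    DataFrame of per-subject metrics (one row per subject, one column
    per metric).  Output: one row per metric with columns
    ``{label}_mean, {label}_sd`` for each group, ``F``, ``p``,
    Bonferroni pairwise flags, and the pre->post fold/percent change.
    """
    missing = [g for g in GROUP_LABELS if g not in cohort_metrics]
    if missing:
        raise ValueError(f"missing group(s): {missing}")
    frames = {g: pd.DataFrame(cohort_metrics[g]) for g in GROUP_LABELS}
    metrics = frames[GROUP_LABELS[0]].columns
    rows = []
    for metric in metrics:
        values = [frames[g][metric].to_numpy(dtype=float) for g in GROUP_LABELS]
        f_stat, p_val, pairwise = oneway_anova_bonferroni(*values)
        row = {"metric": metric}
        for g, v in zip(GROUP_LABELS, values):
            row[f"{g}_mean"] = float(np.mean(v))
            row[f"{g}_sd"] = float(np.std(v, ddof=1))
        row["F"] = f_stat
        row["p"] = p_val
        for (i, j), (_, _, sig) in pairwise.items():
            row[f"sig_{GROUP_LABELS[i]}_vs_{GROUP_LABELS[j]}"] = sig
        fold, pct = fold_change(row["PRE_RFT_mean"], row["POST_RFT_mean"])
        row["fold_pre_post"] = fold
        row["pct_pre_post"] = pct
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
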