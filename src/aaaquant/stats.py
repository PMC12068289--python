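"""Statistical comparisons on pipeline outputs.

Group contrasts use Welch's unequal-variance t-test for two groups (the
reported group SDs in this setting are visibly unequal) and one-way ANOVA for
three or more; the SUV-RPI association pools quadrant-level pairs across
subjects in a Pearson correlation (Spearman by configuration).  Results are
reported in the clinical "mean +/- SD, P = ..." format.  No multiple-testing
correction is applied by default (per-contrast p values); Bonferroni is
available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = ["GroupComparison", "compare_groups", "quadrant_correlation",
           "subgroup_summary", "format_contrast"]


@dataclass
class GroupComparison:
    group_names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]
    statistic: float
    p_value: float
    test_name: str
    degenerate: bool = False

    def __str__(self) -> str:
        desc = " vs. ".join(f"{m:.2g} ± {s:.2g}" for m, s in zip(self.means, self.sds))
        return f"{desc}, P = {self.p_value:.3g} ({self.test_name})"


def compare_groups(values_by_group: dict[str, np.ndarray],
                   bonferroni_m: int = 1) -> GroupComparison:
    """Welch t-test (2 groups) or one-way ANOVA (>= 3 groups)."""
    names = tuple(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise DataError("need at least two groups to compare")
    for g, a in zip(names, arrays):
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise DataError(f"group '{g}' has n < 2 after dropping missing values")
    arrays = [a[~np.isnan(a)] for a in arrays]
    means = tuple(float(a.mean()) for a in arrays)
    sds = tuple(float(a.std(ddof=1)) for a in arrays)
    ns = tuple(len(a) for a in arrays)
    concat = np.concatenate(arrays)
    if np.all(concat == concat[0]):
        # identical constant data in every group: no evidence of a difference
        return GroupComparison(names, means, sds, ns, 0.0, 1.0,
                               "degenerate (zero variance)", degenerate=True)
    if len(arrays) == 2:
        stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
        test = "Welch two-sample t-test"
    else:
        stat, p = sps.f_oneway(*arrays)
        test = "one-way ANOVA"
    p = min(1.0, float(p) * bonferroni_m)
    return GroupComparison(names, means, sds, ns, float(stat), p, test)


def quadrant_correlation(suv_by_quadrant: np.ndarray, rpi_by_quadrant: np.ndarray,
                         method: str = "pearson") -> tuple[float, float]:
    """Correlation over paired (quadrant, subject) values; NaN pairs dropped."""
    x = np.asarray(suv_by_quadrant, dtype=float).ravel()
    y = np.asarray(rpi_by_quadrant, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("paired quadrant vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DataError(f"need >= 3 complete pairs for a correlation, have {len(x)}")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise DataError(f"unknown correlation method '{method}'")
    return float(r), float(p)


def format_contrast(label: str, cmp: GroupComparison) -> str:
    return f"{label}: {cmp}"


def subgroup_summary(table: pd.DataFrame, classification: dict[str, str],
                     diameters: dict[str, float] | None = None) -> dict:
    """High/low subgroup summaries of per-segment mean SUV_diff.

    ``table`` is a stacked per-subject uptake table (columns as produced by
    :func:`aaaquant.uptake.suv_diff_stats`).  Emits per-subgroup segment
    means +/- SD, Welch contrasts where both subgroups have n >= 2, and a
    diameter contrast documenting (in)dependence of the classification from
    aneurysm size.  Subgroups smaller than 2 suppress contrasts but still
    appear in the summary.
    """
    seg_rows = table[(table["region_type"] == "segment") & (~table["missing"])]
    out: dict = {"groups": {}, "contrasts": {}, "report_lines": []}
    labels = ("high", "low")
    for lab in labels:
        subj = [s for s, c in classification.items() if c == lab]
        out["groups"][lab] = {"subjects": subj, "n": len(subj)}
    for segname, chunk in seg_rows.groupby("region", sort=False):
        by = {}
        for lab in labels:
            subj = out["groups"][lab]["subjects"]
            vals = chunk[chunk["subject"].isin(subj)]["mean_suv_diff"].to_numpy()
            by[lab] = vals
            out["groups"][lab][segname] = {
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals))}
        if all(len(v) >= 2 for v in by.values()):
            cmp = compare_groups(by)
            out["contrasts"][segname] = cmp
            out["report_lines"].append(format_contrast(f"{segname} high vs. low", cmp))
        else:
            out["report_lines"].append(
                f"{segname}: contrast suppressed (a subgroup has n < 2)")
    if diameters is not None:
        by = {lab: np.array([diameters[s] for s in out["groups"][lab]["subjects"]
                             if s in diameters]) for lab in labels}
        if all(len(v) >= 2 for v in by.values()):
            cmp = compare_groups(by)
            out["contrasts"]["diameter"] = cmp
            out["report_lines"].append(format_contrast("aneurysm diameter high vs. low", cmp))
    return out
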