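"""Volcano-plot differential selection.

Per-probe log2 fold change and unpaired two-tailed t-test between a case
and a control group, classified against volcano cutoffs: a probe is called
up-regulated when ``p < p_thr`` and ``log2fc > lfc_thr``, down-regulated
when ``p < p_thr`` and ``log2fc < -lfc_thr``, and not significant otherwise
(strict inequalities; boundary values are not significant).  The published
settings pair p < 0.001 with a raw fold-change threshold of 2 or 3, i.e.
|log2FC| > 1 or > 1.58.

No multiple-testing correction is applied as a filter — selection uses raw
p values; a Benjamini-Hochberg column can be added to reports separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["VolcanoThresholds", "fc_to_log2", "log2_fold_change",
           "unpaired_t_test", "volcano_classify", "differential_expression",
           "select_candidates"]


@dataclass(frozen=True)
class VolcanoThresholds:
    """Volcano cutoffs: significance level and |log2FC| threshold."""

    p_thr: float = 0.001
    lfc_thr: float = 1.58

    def __post_init__(self) -> None:
        if not 0 < self.p_thr < 1:
            raise ValueError(f"p_thr must be in (0, 1), got {self.p_thr}")
        if self.lfc_thr < 0:
            raise ValueError(f"lfc_thr must be >= 0, got {self.lfc_thr}")


def fc_to_log2(fold_change: float) -> float:
    """Convert a raw-scale fold-change threshold to log2 (FC 3 -> 1.58...)."""
    if fold_change <= 0:
        raise ValueError("fold change must be > 0")
    return float(np.log2(fold_change))


def _check_group(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2 or not np.isfinite(values).all():
        raise ValueError(f"{name} group needs >= 2 finite values, "
                         f"got {values.tolist()}")
    return values


def log2_fold_change(case_values: Sequence[float],
                     control_values: Sequence[float]) -> float:
    """mean(case) - mean(control) on the log2 scale (= log2 of the FC ratio)."""
    case = _check_group(case_values, "case")
    control = _check_group(control_values, "control")
    return float(case.mean() - control.mean())


def unpaired_t_test(case_values: Sequence[float],
                    control_values: Sequence[float],
                    welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test; Student (pooled variance) by default.

    Degenerate convention: two groups of identical constants compare as
    (t=0, p=1); zero pooled variance with unequal means is an error.
    """
    case = _check_group(case_values, "case")
    control = _check_group(control_values, "control")
    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        if case.mean() == control.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means: "
                         "t statistic undefined")
    res = stats.ttest_ind(case, control, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def volcano_classify(log2fc: float, p_value: float,
                     thresholds: VolcanoThresholds) -> str:
    """Classify one probe as 'up', 'down' or 'ns' (strict inequalities)."""
    if not 0 <= p_value <= 1:
        raise ValueError(f"p value out of [0, 1]: {p_value}")
    if p_value < thresholds.p_thr:
        if log2fc > thresholds.lfc_thr:
            return "up"
        if log2fc < -thresholds.lfc_thr:
            return "down"
    return "ns"


def differential_expression(matrix: pd.DataFrame, annotation: pd.DataFrame,
                            case_group: str, control_group: str,
                            thresholds: VolcanoThresholds | None = None,
                            welch: bool = False) -> pd.DataFrame:
    """Per-probe volcano table for one case-vs-control comparison.

    ``case_group`` / ``control_group`` name annotation groups ("NBE", "LG",
    "HG") or the pooled cancer label "BlCa" (= LG + HG).  Returns a
    DataFrame indexed by probe id with columns ``log2fc``, ``t_stat``,
    ``p_value``, ``neg_log10_p`` and ``status``.
    """
    thresholds = thresholds or VolcanoThresholds()
    case_ids = _group_samples(annotation, case_group)
    control_ids = _group_samples(annotation, control_group)
    for name, ids in (("case", case_ids), ("control", control_ids)):
        if len(ids) < 2:
            raise ValueError(f"{name} group has {len(ids)} sample(s); "
                             "need >= 2")
    missing = [s for s in case_ids + control_ids if s not in matrix.columns]
    if missing:
        raise ValueError(f"annotated sample(s) absent from matrix: {missing}")

    case = matrix[case_ids].to_numpy(dtype=float)
    control = matrix[control_ids].to_numpy(dtype=float)
    lfc = case.mean(axis=1) - control.mean(axis=1)
    res = stats.ttest_ind(case, control, axis=1, equal_var=not welch)
    t_stat = np.asarray(res.statistic, dtype=float)
    p_value = np.asarray(res.pvalue, dtype=float)
    # degenerate rows (zero variance in both groups) -> scipy yields NaN
    degenerate = ~np.isfinite(t_stat)
    if degenerate.any():
        equal_means = np.isclose(case.mean(axis=1), control.mean(axis=1))
        bad = degenerate & ~equal_means
        if bad.any():
            raise ValueError(
                "zero pooled variance with unequal means for probe(s): "
                f"{matrix.index[bad].tolist()}")
        t_stat[degenerate] = 0.0
        p_value[degenerate] = 1.0

    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p_value)
    status = [volcano_classify(l, p, thresholds)
              for l, p in zip(lfc, p_value)]
    return pd.DataFrame(
        {"log2fc": lfc, "t_stat": t_stat, "p_value": p_value,
         "neg_log10_p": neg_log10_p, "status": status},
        index=matrix.index.copy())


def _group_samples(annotation: pd.DataFrame, group: str) -> list[str]:
    if group == "BlCa":
        mask = annotation["group"].isin(["LG", "HG"])
    else:
        if group not in {"NBE", "LG", "HG"}:
            raise ValueError(f"unknown group name: {group!r}")
        mask = annotation["group"] == group
    return annotation.index[mask].astype(str).tolist()


#: the two published comparisons: each cancer grade against normal epithelium
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (("LG", "NBE"),
                                                    ("HG", "NBE"))


def select_candidates(matrix: pd.DataFrame, annotation: pd.DataFrame,
                      thresholds: VolcanoThresholds | None = None,
                      comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
                      welch: bool = False,
                      ) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Volcano candidate features: union of hits over the comparisons.

    Returns the candidate probe ids sorted by probe id (deterministic) and
    the per-comparison volcano tables keyed by "CASE_vs_CONTROL".
    """
    thresholds = thresholds or VolcanoThresholds()
    tables: dict[str, pd.DataFrame] = {}
    hits: set[str] = set()
    for case_group, control_group in comparisons:
        table = differential_expression(matrix, annotation, case_group,
                                        control_group, thresholds, welch)
        tables[f"{case_group}_vs_{control_group}"] = table
        hits.update(table.index[table["status"] != "ns"].astype(str))
    return sorted(hits), tables
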