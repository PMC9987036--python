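"""Patient stratification on the signature panel and survival comparison.

The cancer samples are clustered hierarchically on the z-scored panel
expression (Euclidean distance, Ward linkage by default — heatmap
semantics), the dendrogram is cut into k patient groups, and the groups'
overall survival is compared with Kaplan-Meier curves and a k-sample
log-rank test (chi-square, k-1 degrees of freedom).

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
censored subjects reduce the risk set without producing steps, and tied
event times share a single risk-set computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["zscore_rows", "hierarchical_cluster", "assign_groups",
           "km_estimate", "logrank_test", "LogRankResult",
           "stratify_patients"]


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Z-score each feature row (population sd) across samples.

    Constant rows become all zeros and are flagged in the returned boolean
    Series.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples per row to z-score")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    constant = sd == 0
    sd = sd.mask(constant, 1.0)
    z = matrix.sub(mean, axis=0).div(sd, axis=0)
    return z, constant


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples",
                         metric: str = "euclidean",
                         linkage: str = "ward") -> np.ndarray:
    """Agglomerative linkage over samples (columns) or features (rows).

    Returns the scipy linkage matrix (merge history for dendrogram export).
    Deterministic given the input order.
    """
    if axis == "samples":
        data = matrix.to_numpy(dtype=float).T
    elif axis == "features":
        data = matrix.to_numpy(dtype=float)
    else:
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError(f"need >= 2 items on the {axis} axis to cluster")
    distances = pdist(data, metric=metric)
    return hierarchy.linkage(distances, method=linkage)


def assign_groups(linkage_record: np.ndarray, k: int,
                  item_ids: list[str]) -> pd.Series:
    """Cut the dendrogram into k groups with canonical labels 1..k.

    Labels are renumbered by order of first appearance over the input item
    order, so the assignment is stable under relabeling of the raw cut.
    """
    n = len(item_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.fcluster(linkage_record, t=k, criterion="maxclust")
    if len(raw) != n:
        raise ValueError("linkage record does not match the item list")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=pd.Index(item_ids, name="sample_id"),
                     name="patient_group")


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame over the sorted distinct observed times with columns
    ``survival_prob`` (S(t), starting from 1 and non-increasing),
    ``at_risk`` (count at risk just before t) and ``n_events``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.ndim != 1 or times.shape != events.shape or times.size == 0:
        raise ValueError("times and events must be equal-length, non-empty")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_table = kmf.event_table
    # lifelines pads a synthetic time-0 row when no subject was observed at 0
    if 0.0 in event_table.index and event_table.loc[0.0, "removed"] == 0:
        event_table = event_table.drop(index=0.0)
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "survival_prob": surv.reindex(event_table.index).to_numpy(),
        "at_risk": event_table["at_risk"].astype(int).to_numpy(),
        "n_events": event_table["observed"].astype(int).to_numpy(),
    }, index=pd.Index(event_table.index, name="time_months"))
    return out


@dataclass(frozen=True)
class LogRankResult:
    """k-sample log-rank test: chi-square statistic, k-1 df, upper-tail p."""

    statistic: float
    df: int
    p_value: float


def logrank_test(group_data: dict[int | str, tuple[np.ndarray, np.ndarray]],
                 ) -> LogRankResult:
    """Multi-group log-rank test over {group: (times, events)}."""
    if len(group_data) < 2:
        raise ValueError("need >= 2 groups for a log-rank test")
    times, events, labels = [], [], []
    for label, (t, e) in group_data.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=float)
        if t.size == 0:
            raise ValueError(f"group {label!r} has no subjects")
        if (t < 0).any():
            raise ValueError("times must be >= 0")
        times.append(t)
        events.append(e)
        labels.extend([label] * t.size)
    times = np.concatenate(times)
    events = np.concatenate(events)
    if events.sum() == 0:
        raise ValueError("no events in any group: log-rank undefined")
    res = multivariate_logrank_test(times, labels, events)
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(group_data) - 1,
                         p_value=float(res.p_value))


def stratify_patients(matrix: pd.DataFrame, annotation: pd.DataFrame,
                      panel: list[str], k: int,
                      metric: str = "euclidean", linkage: str = "ward",
                      ) -> dict:
    """Cluster cancer samples on the panel and compare group survival.

    Only cancer (LG+HG) samples are clustered; the panel rows are z-scored
    across those samples first.  Returns a dict with the group assignment,
    the z-scored heatmap slice (rows and columns in dendrogram leaf order),
    per-group Kaplan-Meier curves and the log-rank result (None if any
    group lacks survival data or no events occurred).
    """
    if not panel:
        raise ValueError("empty panel: nothing to stratify on")
    missing = [p for p in panel if p not in matrix.index]
    if missing:
        raise ValueError(f"panel feature(s) absent from matrix: {missing}")
    blca = annotation.index[annotation["group"].isin(["LG", "HG"])].tolist()
    blca = [s for s in blca if s in matrix.columns]
    if len(blca) < 2:
        raise ValueError("need >= 2 cancer samples to stratify")

    panel_slice = matrix.loc[panel, blca]
    z, _ = zscore_rows(panel_slice)
    sample_linkage = hierarchical_cluster(z, "samples", metric, linkage)
    groups = assign_groups(sample_linkage, k, blca)

    # leaf order for heatmap export
    sample_order = hierarchy.leaves_list(sample_linkage)
    if len(panel) >= 2:
        feature_linkage = hierarchical_cluster(z, "features", metric, linkage)
        feature_order = hierarchy.leaves_list(feature_linkage)
    else:
        feature_linkage = None
        feature_order = np.arange(len(panel))
    heatmap = z.iloc[feature_order, sample_order]

    km_curves: dict[int, pd.DataFrame] = {}
    group_surv: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    surv = pd.to_numeric(annotation["survival_months"], errors="coerce")
    ev = pd.to_numeric(annotation["event"], errors="coerce")
    for g in sorted(groups.unique()):
        ids = groups.index[groups == g]
        t = surv.reindex(ids).to_numpy(dtype=float)
        e = ev.reindex(ids).to_numpy(dtype=float)
        ok = np.isfinite(t) & np.isfinite(e)
        if ok.sum() > 0:
            group_surv[int(g)] = (t[ok], e[ok])
            km_curves[int(g)] = km_estimate(t[ok], e[ok])

    logrank: LogRankResult | None = None
    if len(group_surv) >= 2 and sum(e.sum() for _, e in group_surv.values()) > 0:
        logrank = logrank_test(group_surv)

    return {"groups": groups, "heatmap": heatmap,
            "sample_linkage": sample_linkage,
            "feature_linkage": feature_linkage,
            "km_curves": km_curves, "logrank": logrank}
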