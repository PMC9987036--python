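"""Rank-sum aggregation of the ensemble rankings and panel cutoff.

Each of the four rankers yields a rank 1..N over the same N candidate
features.  A rank maps to a score ``N - rank`` (best rank 1 scores N-1,
worst rank N scores 0); the per-method scores are summed with equal weight
and no normalization, and the features are re-sorted by the summed score.
The signature panel is the set of features whose sum score reaches a
fraction ``f`` of the maximum achievable sum ``n_methods * (N - 1)``
(inclusive threshold; published settings use f = 0.5 and f = 0.6).

Any affine rank-to-score mapping orders features identically; expressing the
cutoff as a fraction of the maximum makes the panel invariant to that choice.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["rank_to_score", "aggregate", "select_panel"]


def rank_to_score(rank: int, n_features: int) -> int:
    """Score for a rank among N features: N - rank."""
    if not 1 <= rank <= n_features:
        raise ValueError(f"rank {rank} out of range 1..{n_features}")
    return n_features - int(rank)


def aggregate(tables: Sequence[pd.DataFrame],
              cutoff_fraction: float = 0.5) -> pd.DataFrame:
    """Merge per-method importance tables into one aggregate score table.

    Parameters
    ----------
    tables:
        One table per method (as produced by
        :func:`ucrpanel.relevance.cross_validated_importance`), all covering
        the same feature set, each with columns ``method`` and ``rank``.
    cutoff_fraction:
        Fraction f of the maximum achievable sum score required for
        selection.

    Returns
    -------
    DataFrame indexed by feature id with per-method ``rank_<m>`` and
    ``score_<m>`` columns, ``sum_score``, and ``selected``; sorted by
    descending sum score, ties by ascending feature id.  Attributes
    ``max_sum``, ``cutoff_fraction`` and ``threshold`` are stored in
    ``DataFrame.attrs``.
    """
    if not 0 <= cutoff_fraction <= 1:
        raise ValueError(f"cutoff_fraction must be in [0, 1], "
                         f"got {cutoff_fraction}")
    if len(tables) == 0:
        raise ValueError("no importance tables given")
    feature_sets = [frozenset(t.index.astype(str)) for t in tables]
    reference = feature_sets[0]
    for fs, t in zip(feature_sets[1:], tables[1:]):
        if fs != reference:
            method = t["method"].iloc[0] if "method" in t else "?"
            raise ValueError(
                f"feature-set mismatch for method {method}: "
                f"missing {sorted(reference - fs)}, extra {sorted(fs - reference)}")

    n = len(reference)
    features = sorted(reference)
    out = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    for t in tables:
        method = str(t["method"].iloc[0])
        ranks = t["rank"].astype(int).reindex(features)
        out[f"rank_{method}"] = ranks
        out[f"score_{method}"] = [rank_to_score(r, n) for r in ranks]

    score_cols = [c for c in out.columns if c.startswith("score_")]
    out["sum_score"] = out[score_cols].sum(axis=1)
    max_sum = len(tables) * (n - 1)
    threshold = cutoff_fraction * max_sum
    out["selected"] = out["sum_score"] >= threshold

    # index is already in ascending feature-id order; a stable sort by
    # descending sum score therefore breaks ties by ascending feature id
    out = out.sort_values("sum_score", ascending=False, kind="stable")
    out.attrs.update(max_sum=max_sum, cutoff_fraction=cutoff_fraction,
                     threshold=threshold, n_features=n)
    return out


def select_panel(table: pd.DataFrame) -> tuple[list[str], dict]:
    """The selected features in table order, with selection metadata.

    Returns ``(panel, meta)`` where ``meta`` records the panel size M, the
    candidate count N, the cutoff fraction and the maximum sum score.  An
    empty selection is returned as an empty panel (callers should halt
    downstream stages).
    """
    panel = table.index[table["selected"]].astype(str).tolist()
    meta = {
        "panel_size": len(panel),
        "n_candidates": int(table.attrs.get("n_features", len(table))),
        "cutoff_fraction": table.attrs.get("cutoff_fraction"),
        "max_sum": table.attrs.get("max_sum"),
        "threshold": table.attrs.get("threshold"),
    }
    return panel, meta
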