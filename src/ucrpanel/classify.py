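"""Held-out evaluation of the signature panel as a diagnostic classifier.

The panel is judged by how well a logistic regression restricted to its
features separates cancer from normal samples on an independently selected
test split (30% of the data by default, stratified on the binary label).
Features are standardized with training statistics only; the decision
threshold is a predicted probability of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .relevance import standardize_features

__all__ = ["ConfusionMatrix", "stratified_split", "train_eval"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Held-out 2x2 confusion counts (positive class = cancer)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "n_test": self.n, "accuracy": self.accuracy}


def stratified_split(sample_ids, labels, test_fraction: float = 0.3,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test split stratified on the label.

    Deterministic per seed; errors if either class is too small to appear
    on both sides of the split.
    """
    sample_ids = list(map(str, sample_ids))
    labels = np.asarray(labels, dtype=int)
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples to appear in both "
                         "train and test")
    train_ids, test_ids = train_test_split(
        sample_ids, test_size=test_fraction, stratify=labels,
        random_state=seed)
    return list(train_ids), list(test_ids)


def train_eval(panel_matrix: pd.DataFrame, labels: pd.Series,
               split: tuple[list[str], list[str]],
               seed: int = 0) -> ConfusionMatrix:
    """Fit logistic regression on the train split, score the test split.

    Parameters
    ----------
    panel_matrix:
        Samples x panel-features slice (one row per sample).
    labels:
        Binary labels indexed by sample id (1 = cancer, 0 = normal).
    split:
        (train ids, test ids) as from :func:`stratified_split`.
    """
    train_ids, test_ids = split
    if panel_matrix.shape[1] == 0:
        raise ValueError("empty panel")
    y_train = labels.reindex(train_ids).to_numpy(dtype=int)
    y_test = labels.reindex(test_ids).to_numpy(dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")

    X_train = panel_matrix.loc[train_ids]
    X_test = panel_matrix.loc[test_ids]
    X_train_std, stats = standardize_features(X_train)
    X_test_std = (X_test - stats["mean"]) / stats["sd"]

    model = LogisticRegression(max_iter=5000, random_state=seed)
    model.fit(X_train_std.to_numpy(), y_train)
    prob = model.predict_proba(X_test_std.to_numpy())[:, 1]
    pred = (prob >= 0.5).astype(int)

    tp = int(((pred == 1) & (y_test == 1)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
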