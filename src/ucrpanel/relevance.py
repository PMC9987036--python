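"""Ensemble feature-importance ranking.

Four rankers score each candidate feature for separating cancer (LG+HG
pooled, labeled 1) from normal epithelium (labeled 0):

* ``LR`` — weakly L2-regularized logistic regression; importance is the
  absolute coefficient on standardized inputs.
* ``LASSO`` — L1-penalized logistic regression with the penalty chosen by
  cross-validated deviance inside each training fold; importance is the
  absolute coefficient (zeros mean the feature was dropped).
* ``RF`` — random forest; importance is the normalized mean decrease in
  node impurity (Gini), which sums to one over features.
* ``XGB`` — gradient-boosted trees; importance is the total gain
  accumulated over every split using the feature (0 if never used).

Importance is computed per stratified cross-validation fold on the training
portion only (features standardized with training statistics — no leakage),
averaged over folds, and ranked once; ties in averaged importance are broken
by ascending feature id so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = ["CVConfig", "METHODS", "standardize_features", "compute_importance",
           "cross_validated_importance", "rank_importances"]

METHODS = ("LR", "LASSO", "RF", "XGB")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (fivefold, stratified, by default)."""

    k: int = 5
    seed: int = 0
    stratified: bool = True

    def validate(self, y: np.ndarray) -> None:
        smaller = int(min(np.bincount(np.asarray(y, dtype=int))))
        if not 2 <= self.k <= smaller:
            raise ValueError(
                f"k={self.k} folds invalid for smaller class size {smaller}")


def standardize_features(X: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each feature column (population sd) over the samples.

    Returns the standardized slice and a per-feature table with columns
    ``mean``, ``sd`` and ``constant``; constant features get sd set to 1
    (values become 0) and are flagged.
    """
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    sd = sd.mask(constant, 1.0)
    stats = pd.DataFrame({"mean": mean, "sd": sd, "constant": constant})
    return (X - mean) / sd, stats


def _lr_model(seed: int) -> LogisticRegression:
    # weak L2 penalty: coefficients are examined, not shrunk
    return LogisticRegression(C=1e3, max_iter=5000, random_state=seed)


def _lasso_model(y: np.ndarray, seed: int, C: float | None) -> LogisticRegression:
    if C is not None:
        return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                  max_iter=5000, random_state=seed)
    inner = min(3, int(min(np.bincount(np.asarray(y, dtype=int)))))
    return LogisticRegressionCV(l1_ratios=(1.0,), solver="liblinear",
                                Cs=np.logspace(-2, 2, 10), cv=inner,
                                scoring="neg_log_loss", max_iter=5000,
                                use_legacy_attributes=False,
                                random_state=seed)


def compute_importance(X: np.ndarray, y: np.ndarray, method: str,
                       seed: int = 0, lasso_C: float | None = None,
                       ) -> np.ndarray:
    """Non-negative importance vector, one entry per feature column of X.

    ``X`` should already be standardized for the coefficient-based methods.
    Stochastic methods (RF, XGB) are fully determined by ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")

    if method == "LR":
        model = _lr_model(seed).fit(X, y)
        return np.abs(model.coef_.ravel())
    if method == "LASSO":
        model = _lasso_model(y, seed, lasso_C).fit(X, y)
        return np.abs(model.coef_.ravel())
    if method == "RF":
        # max_features=None: every feature considered at every split, so
        # importances are invariant to column order at a fixed seed
        model = RandomForestClassifier(n_estimators=500, max_features=None,
                                       random_state=seed, n_jobs=1).fit(X, y)
        return model.feature_importances_
    if method == "XGB":
        model = XGBClassifier(objective="binary:logistic", max_depth=3,
                              n_estimators=100, learning_rate=0.3,
                              random_state=seed, n_jobs=1,
                              tree_method="exact").fit(X, y)
        scores = model.get_booster().get_score(importance_type="total_gain")
        return np.array([scores.get(f"f{j}", 0.0) for j in range(X.shape[1])])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def rank_importances(importance: pd.Series) -> pd.Series:
    """Ranks 1..N by descending importance, ties by ascending feature id."""
    order = sorted(importance.index, key=lambda f: (-importance[f], str(f)))
    return pd.Series({f: r for r, f in enumerate(order, start=1)},
                     name="rank").reindex(importance.index)


def cross_validated_importance(X: pd.DataFrame, y: pd.Series | np.ndarray,
                               method: str, cv: CVConfig | None = None,
                               lasso_C: float | None = None,
                               average_ranks: bool = False) -> pd.DataFrame:
    """Fold-averaged importance table for one method.

    Returns a DataFrame indexed by feature id with columns ``method``,
    ``importance`` and ``rank``, sorted by rank.  By default the fold-wise
    importance vectors are averaged and ranked once; ``average_ranks``
    instead ranks within each fold and averages the ranks.
    """
    cv = cv or CVConfig()
    y_arr = np.asarray(y, dtype=int)
    cv.validate(y_arr)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True,
                                   random_state=cv.seed)
    else:
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)

    fold_importances = []
    fold_ranks = []
    for train_idx, _ in splitter.split(X, y_arr):
        X_train = X.iloc[train_idx]
        X_std, _ = standardize_features(X_train)
        imp = compute_importance(X_std.to_numpy(), y_arr[train_idx], method,
                                 seed=cv.seed, lasso_C=lasso_C)
        imp_series = pd.Series(imp, index=X.columns)
        fold_importances.append(imp_series)
        fold_ranks.append(rank_importances(imp_series))

    mean_importance = pd.concat(fold_importances, axis=1).mean(axis=1)
    if average_ranks:
        mean_rank = pd.concat(fold_ranks, axis=1).mean(axis=1)
        # lower mean rank = more important; re-rank with the standard tie rule
        order = sorted(mean_rank.index,
                       key=lambda f: (mean_rank[f], str(f)))
        rank = pd.Series({f: r for r, f in enumerate(order, start=1)},
                         name="rank").reindex(mean_rank.index)
    else:
        rank = rank_importances(mean_importance)

    table = pd.DataFrame({"method": method,
                          "importance": mean_importance,
                          "rank": rank})
    table.index.name = "feature_id"
    return table.sort_values("rank")
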