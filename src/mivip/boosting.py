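"""Stochastic gradient boosting with CV-chosen size and relative influence.

The boosting fit itself is scikit-learn's ``GradientBoostingRegressor``
(squared-error loss, depth-limited trees, row subsampling).  The tree count
is chosen by k-fold cross-validation: the fold-averaged validation MSE
curve over stages is minimized, and the final full-data model is truncated
at that stage for everything downstream.

Relative influence follows the classic squared-error-reduction recipe:
for one tree, a variable's squared importance is the sum of the weighted
squared-error decreases over the internal nodes that split on it; squared
importances are averaged over the retained trees, square-rooted, and
rescaled so the variable scores sum to 100 (the "scaled relative
importance" convention; the square root is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .cohort import CohortTable


@dataclass
class GBMConfig:
    max_trees: int = 5000
    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    interaction_depth: int = 3
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")


@dataclass
class TreeImportanceLedger:
    """Per-tree split records: (feature index, squared-error decrease) pairs.

    ``trees[t]`` is a pair of aligned arrays over tree t's nonterminal
    nodes.  Decreases are weighted SSE reductions and therefore
    nonnegative (up to float noise, clipped at zero on read-out).
    """

    trees: list
    n_features: int

    def truncated(self, n_trees: int) -> "TreeImportanceLedger":
        return TreeImportanceLedger(self.trees[:n_trees], self.n_features)


@dataclass
class GBMFit:
    model: GradientBoostingRegressor
    best_n_trees: int
    cv_curve: np.ndarray
    ledger: TreeImportanceLedger
    feature_names: list


def fit_gbm_cv(table: CohortTable, config: GBMConfig = None) -> GBMFit:
    if table.missing_mask.to_numpy().any():
        raise ValueError("table must be complete; impute first")
    X = table.encode_numeric().to_numpy(dtype=np.float64)
    return fit_gbm_arrays(X, table.outcome, table.predictor_names, config)


def fit_gbm_arrays(X, y, feature_names, config: GBMConfig = None) -> GBMFit:
    """CV-sized boosting fit on arrays; ledger recorded from the final model."""
    config = config or GBMConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if n < config.cv_folds:
        raise ValueError("fewer rows than CV folds")

    def make_model(seed, n_estimators):
        return GradientBoostingRegressor(
            n_estimators=n_estimators,
            learning_rate=config.learning_rate,
            subsample=config.bag_fraction,
            max_depth=config.interaction_depth,
            random_state=seed,
        )

    rng = np.random.default_rng(config.seed)
    kf = KFold(n_splits=config.cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    curve = np.zeros(config.max_trees)
    for train, val in kf.split(X):
        model = make_model(int(rng.integers(2**31)), config.max_trees)
        model.fit(X[train], y[train])
        yv = y[val]
        for stage, pred in enumerate(model.staged_predict(X[val])):
            curve[stage] += float(((yv - pred) ** 2).mean())
    curve /= config.cv_folds
    best_n_trees = int(np.argmin(curve)) + 1

    final = make_model(int(rng.integers(2**31)), config.max_trees)
    final.fit(X, y)
    ledger = extract_ledger(final, X.shape[1])
    return GBMFit(
        model=final,
        best_n_trees=best_n_trees,
        cv_curve=curve,
        ledger=ledger,
        feature_names=list(feature_names),
    )


def extract_ledger(model: GradientBoostingRegressor, n_features: int) -> TreeImportanceLedger:
    """Walk each boosted tree and record per-split weighted SSE decreases."""
    trees = []
    for est in model.estimators_[:, 0]:
        t = est.tree_
        internal = np.flatnonzero(t.children_left != -1)
        feats = t.feature[internal]
        w = t.weighted_n_node_samples
        imp = t.impurity
        dec = (
            w[internal] * imp[internal]
            - w[t.children_left[internal]] * imp[t.children_left[internal]]
            - w[t.children_right[internal]] * imp[t.children_right[internal]]
        )
        trees.append((feats.astype(np.intp), dec.astype(np.float64)))
    return TreeImportanceLedger(trees=trees, n_features=n_features)


def relative_importance(
    ledger: TreeImportanceLedger,
    best_n_trees: int,
    feature_names: list = None,
    scale: str = "sqrt",
) -> pd.DataFrame:
    """Per-variable relative influence over the first ``best_n_trees`` trees.

    Squared importances are summed per tree, averaged over trees, then
    (with ``scale="sqrt"``, the default) square-rooted before rescaling to
    sum 100.  ``scale="squared"`` skips the square root.
    """
    used = ledger.trees[:best_n_trees]
    if not used:
        raise ValueError("empty ledger")
    totals = np.zeros(ledger.n_features)
    for feats, dec in used:
        np.add.at(totals, feats, np.clip(dec, 0.0, None))
    mean_sq = totals / len(used)
    if not mean_sq.any():
        raise ValueError("all-zero ledger (constant outcome?)")
    raw = np.sqrt(mean_sq) if scale == "sqrt" else mean_sq
    scores = 100.0 * raw / raw.sum()
    names = feature_names or [f"x{j}" for j in range(ledger.n_features)]
    return pd.DataFrame({"variable": names, "relative_importance": scores})
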