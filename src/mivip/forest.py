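"""Regression random forest with explicit out-of-bag (OOB) machinery.

The forest is a plain bagged ensemble of CART regression trees with
random feature subsetting at each split, but unlike off-the-shelf forest
estimators it records every tree's bootstrap bag.  That record is what the
importance statistic needs: for each variable j, tree b and permutation
replicate k, variable j is permuted *within tree b's OOB rows only*, the
tree's OOB mean squared error is recomputed, and the increase over the
unpermuted per-tree OOB MSE is the elementary importance increment.  The
per-imputation importance theta_hat_j is the mean of the K*B increments;
its standard error is the standard deviation over trees of the K-averaged
per-tree increases divided by sqrt(B).

Also here: the OOB pseudo-R^2 (1 - OOB MSE / outcome variance) and the
calibration best-fit line of averaged OOB predictions against the
observed outcome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .cohort import CohortTable


@dataclass
class RFConfig:
    """Forest settings: 500 trees and K=5 OOB permutations per variable.

    ``mtry`` defaults to max(p // 3, 1), the standard regression-forest
    choice; ``min_samples_leaf=5`` matches the usual regression node size.
    """

    n_trees: int = 500
    n_permutations: int = 5
    mtry: int | None = None
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.n_permutations < 1:
            raise ValueError("n_trees and n_permutations must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        return self.mtry if self.mtry is not None else max(p // 3, 1)


@dataclass
class RFFit:
    """Fitted ensemble with per-tree bag records and cached OOB predictions."""

    trees: list
    bag_indices: list
    oob_indices: list
    X: np.ndarray  # float32, C-contiguous
    y: np.ndarray
    feature_names: list
    config: RFConfig
    oob_predictions: np.ndarray = field(default=None)
    n_never_oob: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def fit_rf_oob(table: CohortTable, config: RFConfig = None) -> RFFit:
    """Fit the forest on a complete cohort table (ordinal-encoded)."""
    if table.missing_mask.to_numpy().any():
        raise ValueError("table must be complete; impute first")
    X = table.encode_numeric().to_numpy(dtype=np.float32)
    y = table.outcome
    return fit_rf_arrays(X, y, table.predictor_names, config)


def fit_rf_arrays(X, y, feature_names, config: RFConfig = None) -> RFFit:
    """Array-level fit: bootstrap bags, random split features, OOB record."""
    config = config or RFConfig()
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if p == 0:
        raise ValueError("no predictors")
    if not np.issubdtype(y.dtype, np.number) or not np.isfinite(y).all():
        raise ValueError("outcome must be finite numeric")
    mtry = config.resolved_mtry(p)

    rng = np.random.default_rng(config.seed)
    trees, bags, oobs = [], [], []
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=np.int64)
    for _ in range(config.n_trees):
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), bag, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31)),
        ).fit(X[bag], y[bag])
        if oob.size:
            pred = tree.tree_.predict(np.ascontiguousarray(X[oob]))[:, 0]
            pred_sum[oob] += pred
            pred_cnt[oob] += 1
        trees.append(tree)
        bags.append(bag)
        oobs.append(oob)
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    return RFFit(
        trees=trees, bag_indices=bags, oob_indices=oobs,
        X=X, y=y, feature_names=list(feature_names), config=config,
        oob_predictions=oob_pred, n_never_oob=int((pred_cnt == 0).sum()),
    )


def oob_pseudo_r2(fit: RFFit, outcome: np.ndarray = None) -> float:
    """1 - OOB MSE / Var(outcome); the forest's internal explained variance."""
    y = fit.y if outcome is None else np.asarray(outcome, dtype=float)
    ok = ~np.isnan(fit.oob_predictions)
    if not ok.any():
        raise ValueError("no OOB predictions available")
    var = y.var()
    if var == 0:
        raise ValueError("outcome has zero variance")
    mse = float(((y[ok] - fit.oob_predictions[ok]) ** 2).mean())
    return 1.0 - mse / var


def calibration_line(
    predicted, observed, direction: str = "predicted_on_observed"
) -> tuple:
    """OLS best-fit (intercept, slope) for the calibration scatter.

    Default regresses predicted on observed (the y-on-x of a predicted vs
    observed plot); ``direction="observed_on_predicted"`` flips the roles.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if direction == "predicted_on_observed":
        x, y = observed, predicted
    elif direction == "observed_on_predicted":
        x, y = predicted, observed
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if x.var() == 0:
        raise ValueError("regressor has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def permutation_importance_oob(
    fit: RFFit,
    K: int = None,
    seed: int = None,
    variables: list = None,
) -> pd.DataFrame:
    """Per-variable OOB permutation importance (theta_hat) with SEs.

    Permutation streams are keyed by variable *name* (not position), so the
    result for a given fit does not depend on the order in which variables
    are evaluated.  A variable that is constant within every OOB sample
    yields exactly zero increases, hence theta_hat = 0 with se = 0.

    Returns a DataFrame with columns ``variable``, ``theta_hat``, ``se``.
    """
    K = K if K is not None else fit.config.n_permutations
    seed = seed if seed is not None else fit.config.seed
    if K < 1:
        raise ValueError("K must be >= 1")
    names = fit.feature_names if variables is None else list(variables)
    col_of = {nm: j for j, nm in enumerate(fit.feature_names)}

    B = fit.n_trees
    # cache per-tree OOB data and baseline MSEs
    oob_X, oob_y, base_mse = [], [], []
    for b in range(B):
        oob = fit.oob_indices[b]
        Xb = np.ascontiguousarray(fit.X[oob])
        yb = fit.y[oob]
        pred = fit.trees[b].tree_.predict(Xb)[:, 0] if oob.size else np.empty(0)
        oob_X.append(Xb)
        oob_y.append(yb)
        base_mse.append(float(((yb - pred) ** 2).mean()) if oob.size else np.nan)

    rows = []
    for nm in names:
        j = col_of[nm]
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(nm.encode())])
        )
        per_tree = np.full(B, np.nan)
        for b in range(B):
            Xb, yb = oob_X[b], oob_y[b]
            nb = Xb.shape[0]
            if nb == 0:
                continue
            rep = np.tile(Xb, (K, 1))
            for k in range(K):
                perm = rng.permutation(nb)
                rep[k * nb : (k + 1) * nb, j] = Xb[perm, j]
            preds = fit.trees[b].tree_.predict(np.ascontiguousarray(rep))[:, 0]
            sq = (preds - np.tile(yb, K)) ** 2
            mses = sq.reshape(K, nb).mean(axis=1)
            per_tree[b] = float((mses - base_mse[b]).mean())
        valid = per_tree[~np.isnan(per_tree)]
        theta = float(valid.mean())
        se = float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else 0.0
        rows.append({"variable": nm, "theta_hat": theta, "se": se})
    return pd.DataFrame(rows)
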