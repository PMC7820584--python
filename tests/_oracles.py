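"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and restate the formulas from
scratch; they must never import the code paths they check.
"""

import math

import numpy as np


def pool_brute_force(theta, se):
    """Pooled statistics via explicit loops: theta_bar, W_bar, B_bar, V, T."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    M, p = theta.shape
    out = {k: [] for k in ("theta_bar", "W_bar", "B_bar", "V", "T")}
    for j in range(p):
        tb = sum(theta[m, j] for m in range(M)) / M
        wb = sum(se[m, j] ** 2 for m in range(M)) / M
        bb = sum((theta[m, j] - tb) ** 2 for m in range(M)) / (M - 1)
        v = wb + (M + 1) / M * bb
        t = tb / math.sqrt(v) if v > 0 else 0.0
        out["theta_bar"].append(tb)
        out["W_bar"].append(wb)
        out["B_bar"].append(bb)
        out["V"].append(v)
        out["T"].append(t)
    return {k: np.array(v) for k, v in out.items()}


def relative_importance_brute_force(ledger_trees, n_features, n_trees):
    """Scaled relative influence by direct restatement of the recipe."""
    sq = [0.0] * n_features
    used = ledger_trees[:n_trees]
    for feats, decs in used:
        for f, d in zip(feats, decs):
            sq[f] += max(d, 0.0)
    mean_sq = [s / len(used) for s in sq]
    raw = [math.sqrt(s) for s in mean_sq]
    total = sum(raw)
    return np.array([100.0 * r / total for r in raw])


def permutation_importance_brute_force(fit, K, seed):
    """Naive re-walk of the OOB permutation scheme over a tiny forest.

    Shares the per-variable permutation stream construction with the
    implementation (seed contract), but recomputes every MSE with explicit
    loops through the public predict API.
    """
    import zlib

    results = {}
    B = len(fit.trees)
    for j, name in enumerate(fit.feature_names):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        )
        per_tree = []
        for b in range(B):
            oob = fit.oob_indices[b]
            if len(oob) == 0:
                continue
            Xb = fit.X[oob].astype(np.float64)
            yb = fit.y[oob]
            base_pred = fit.trees[b].predict(Xb.astype(np.float32))
            base_mse = sum((yb[i] - base_pred[i]) ** 2 for i in range(len(oob))) / len(oob)
            incs = []
            for _ in range(K):
                perm = rng.permutation(len(oob))
                Xp = Xb.copy()
                Xp[:, j] = Xb[perm, j]
                pred = fit.trees[b].predict(Xp.astype(np.float32))
                mse = sum((yb[i] - pred[i]) ** 2 for i in range(len(oob))) / len(oob)
                incs.append(mse - base_mse)
            per_tree.append(sum(incs) / len(incs))
        theta = sum(per_tree) / len(per_tree)
        var = sum((d - theta) ** 2 for d in per_tree) / (len(per_tree) - 1)
        se = math.sqrt(var) / math.sqrt(len(per_tree))
        results[name] = (theta, se)
    return results
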