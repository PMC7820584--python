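"""Multiple imputation by chained random forests (missForest-style).

Each of the M runs initializes missing cells (column mean for continuous,
mode for categorical/genotype), then cycles variables in order of
increasing missingness, refitting a small bootstrap forest of the other
predictors on the observed rows of each target column and predicting its
missing entries.  Cycling stops when the normalized change in the imputed
values increases (the previous iteration's values are kept), or at a hard
iteration cap.  Runs differ only through child seeds spawned from the
master seed, so a fixed ``(seed, M)`` is bit-reproducible and the first
``M'`` tables do not change when M grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort import CONTINUOUS, CohortTable


@dataclass
class ImputationSet:
    """M completed copies of one cohort table plus their provenance."""

    tables: list
    seeds: list
    n_iterations: list

    @property
    def M(self) -> int:
        return len(self.tables)

    def manifest(self) -> dict:
        return {
            "M": self.M,
            "seeds": [int(s) for s in self.seeds],
            "n_iterations": [int(k) for k in self.n_iterations],
        }

    def to_csvs(self, directory) -> None:
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m, table in enumerate(self.tables):
            table.to_csv(directory / f"imputation_{m:03d}.csv")
        (directory / "manifest.json").write_text(json.dumps(self.manifest(), indent=1))


def multiply_impute(
    table: CohortTable,
    M: int,
    seed: int = 0,
    n_trees: int = 100,
    max_iter: int = 10,
    use_outcome: bool = False,
) -> ImputationSet:
    """Produce M complete copies of ``table`` by iterative forest imputation.

    Parameters
    ----------
    n_trees : int
        Trees per per-column forest (missForest default 100).
    max_iter : int
        Hard cap on imputation cycles; the change-based stopping rule
        usually triggers after 2-4 cycles.
    use_outcome : bool
        Whether the outcome may serve as a predictor of missing covariates
        (off by default: importance scores should not be able to leak the
        outcome back through the imputed values).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    mask = table.missing_mask
    for v in table.variables:
        if mask[v.name].all():
            raise ValueError(f"column {v.name!r} is entirely missing")
    if mask[table.outcome_name].any():
        raise ValueError("outcome column must be complete")

    enc = table.encode_numeric(include_outcome=use_outcome)
    X = enc.to_numpy(dtype=np.float64)
    names = list(enc.columns)
    is_cat = np.array(
        [v.var_type != CONTINUOUS for v in table.variables]
        + [False] * (len(names) - table.p)
    )
    # columns eligible as targets: predictors only
    target_cols = list(range(table.p))

    child_seeds = np.random.SeedSequence(seed).spawn(M)
    tables, seeds, iters = [], [], []
    for m in range(M):
        rng = np.random.default_rng(child_seeds[m])
        run_seed = int(rng.integers(2**31))
        Xm, n_iter = _impute_once(
            X.copy(), is_cat, target_cols, np.random.default_rng(run_seed),
            n_trees=n_trees, max_iter=max_iter,
        )
        out = table.copy()
        for j in target_cols:
            v = table.variables[j]
            miss = mask[v.name].to_numpy()
            if miss.any():
                out.data.loc[miss, v.name] = table.decode_column(v.name, Xm[miss, j])
        out.validate()
        tables.append(out)
        seeds.append(run_seed)
        iters.append(n_iter)
    return ImputationSet(tables=tables, seeds=seeds, n_iterations=iters)


def _impute_once(X, is_cat, target_cols, rng, n_trees, max_iter):
    """One chained-forest imputation pass over the encoded matrix."""
    miss = np.isnan(X)
    todo = [j for j in target_cols if miss[:, j].any()]
    if not todo:
        return X, 0
    # initialize: mean / mode
    for j in range(X.shape[1]):
        mj = miss[:, j]
        if not mj.any():
            continue
        obs = X[~mj, j]
        if is_cat[j]:
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]
        else:
            fill = obs.mean()
        X[mj, j] = fill
    # increasing missingness order
    todo.sort(key=lambda j: (miss[:, j].sum(), j))

    has_cont = any(not is_cat[j] for j in todo)
    has_cat = any(is_cat[j] for j in todo)
    prev = X.copy()
    prev_dc = np.inf
    prev_df = np.inf
    n_iter = 0
    for it in range(max_iter):
        for j in todo:
            mj = miss[:, j]
            others = [k for k in range(X.shape[1]) if k != j]
            Xo = np.ascontiguousarray(X[np.ix_(~mj, others)], dtype=np.float32)
            Xp = np.ascontiguousarray(X[np.ix_(mj, others)], dtype=np.float32)
            yo = X[~mj, j]
            X[mj, j] = _forest_predict(Xo, yo, Xp, rng, bool(is_cat[j]), n_trees)
        n_iter = it + 1
        # normalized change in the imputed cells, by variable type
        dc = df = 0.0
        if has_cont:
            num = den = 0.0
            for j in todo:
                if is_cat[j]:
                    continue
                mj = miss[:, j]
                num += float(((X[mj, j] - prev[mj, j]) ** 2).sum())
                den += float((X[mj, j] ** 2).sum())
            dc = num / den if den > 0 else 0.0
        if has_cat:
            changed = total = 0
            for j in todo:
                if not is_cat[j]:
                    continue
                mj = miss[:, j]
                changed += int((X[mj, j] != prev[mj, j]).sum())
                total += int(mj.sum())
            df = changed / total if total else 0.0
        if it >= 1:
            worse_cont = (not has_cont) or (dc >= prev_dc)
            worse_cat = (not has_cat) or (df >= prev_df)
            if worse_cont and worse_cat:
                return prev, n_iter  # keep the previous, better iteration
        prev = X.copy()
        prev_dc, prev_df = dc, df
    return X, n_iter


def _forest_predict(Xo, yo, Xp, rng, classify, n_trees):
    """Bootstrap forest prediction of Xp from (Xo, yo)."""
    n, p = Xo.shape
    mtry = max(1, int(np.sqrt(p)))
    if classify:
        yo_codes = yo.astype(int)
        classes = np.unique(yo_codes)
        remap = {c: i for i, c in enumerate(classes)}
        votes = np.zeros((Xp.shape[0], len(classes)), dtype=np.int32)
    else:
        acc = np.zeros(Xp.shape[0])
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        ts = int(rng.integers(2**31))
        if classify:
            tree = DecisionTreeClassifier(
                max_features=mtry, random_state=ts
            ).fit(Xo[idx], yo_codes[idx])
            pred = tree.predict(Xp).astype(int)
            for i, c in enumerate(pred):
                votes[i, remap[c]] += 1
        else:
            tree = DecisionTreeRegressor(
                max_features=mtry, min_samples_leaf=5, random_state=ts
            ).fit(Xo[idx], yo[idx])
            acc += tree.tree_.predict(Xp)[:, 0]
    if classify:
        return classes[np.argmax(votes, axis=1)].astype(float)
    return acc / n_trees
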