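"""Min-max normalization of importance matrices and their consensus merge.

To make forest permutation importances and boosting relative influences
comparable, each method's M x p matrix is mapped through
``(x - min_avg) / (max_avg - min_avg)`` where the anchors are the minimum
and maximum *across-variable average* importance of that method.  Only the
column averages are anchored to [0, 1]; individual cells may fall outside
and are deliberately not clamped.  The two normalized matrices are then
stacked (2M rows) and averaged per variable into a single consensus score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pooling import ImportanceMatrix


@dataclass
class NormalizedImportanceMatrix:
    values: np.ndarray
    anchors: tuple
    variable_names: list
    method: str

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def minmax_normalize(matrix: ImportanceMatrix) -> NormalizedImportanceMatrix:
    """Normalize so the extreme column-average importances map to 0 and 1."""
    if matrix.p < 2:
        raise ValueError("need at least two variables")
    avg = matrix.theta.mean(axis=0)
    min_avg, max_avg = float(avg.min()), float(avg.max())
    if max_avg == min_avg:
        raise ValueError("all column averages equal; anchors degenerate")
    values = (matrix.theta - min_avg) / (max_avg - min_avg)
    return NormalizedImportanceMatrix(
        values=values,
        anchors=(min_avg, max_avg),
        variable_names=list(matrix.variable_names),
        method=matrix.method,
    )


def consensus_scores(
    rf_norm: NormalizedImportanceMatrix, gbm_norm: NormalizedImportanceMatrix
) -> pd.DataFrame:
    """Stack the two normalized matrices and average per variable.

    Returns per-variable ``rf_mean_norm``, ``gbm_mean_norm``,
    ``consensus_score`` and ``consensus_rank`` (rank 1 = highest score,
    average ranks on exact ties).
    """
    if rf_norm.variable_names != gbm_norm.variable_names:
        raise ValueError("variable sets differ between methods")
    if rf_norm.M != gbm_norm.M:
        raise ValueError("imputation counts differ between methods")
    stacked = np.vstack([rf_norm.values, gbm_norm.values])
    score = stacked.mean(axis=0)
    return pd.DataFrame(
        {
            "variable": rf_norm.variable_names,
            "rf_mean_norm": rf_norm.column_means(),
            "gbm_mean_norm": gbm_norm.column_means(),
            "consensus_score": score,
            "consensus_rank": rankdata(-score, method="average"),
        }
    )


def top_k(scores: pd.DataFrame, k: int, by: str = "consensus_score") -> pd.DataFrame:
    """The k highest-scoring variables, in descending score order."""
    p = len(scores)
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}]")
    return (
        scores.sort_values([by, "variable"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
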