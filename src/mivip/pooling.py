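"""Rubin-style pooling of per-imputation importance scores and rank CIs.

Given an M x p matrix of importance estimates theta_hat[m, j] (and, for the
forest method, their within-imputation standard errors s[m, j]), each
variable's pooled summary is

    theta_bar = mean_m theta_hat          (pooled importance)
    W_bar     = mean_m s^2                (within-imputation variance)
    B_bar     = var_m theta_hat (ddof=1)  (between-imputation variance)
    V         = W_bar + (M + 1) / M * B_bar
    T         = theta_bar / sqrt(V)       (standardized importance score)

Ranks are computed inside each imputation (rank 1 = most important,
average ranks on exact ties), and summarized across imputations by their
mean and empirical 2.5/97.5 percentiles, rounded half-up to integers for
reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ImportanceMatrix:
    """M imputations x p variables of raw importance scores for one method."""

    theta: np.ndarray
    variable_names: list
    method: str
    se: np.ndarray = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be M x p")
        if self.theta.shape[1] != len(self.variable_names):
            raise ValueError("variable_names length mismatch")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.theta.shape:
                raise ValueError("se shape mismatch")
            if (self.se < 0).any():
                raise ValueError("negative standard errors")

    @property
    def M(self) -> int:
        return self.theta.shape[0]

    @property
    def p(self) -> int:
        return self.theta.shape[1]


def round_half_up(x) -> np.ndarray:
    """Round .5 upward (the convention used for reported integer ranks)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def pool_importance(matrix: ImportanceMatrix) -> pd.DataFrame:
    """Pooled per-variable statistics; requires M >= 2 and SEs.

    Variables with V = 0 (identically zero importance and SE across all
    imputations) get T defined as 0.
    """
    if matrix.M < 2:
        raise ValueError("pooling needs M >= 2")
    if matrix.se is None:
        raise ValueError("pooling needs within-imputation standard errors")
    M = matrix.M
    theta_bar = matrix.theta.mean(axis=0)
    W_bar = (matrix.se**2).mean(axis=0)
    B_bar = ((matrix.theta - theta_bar) ** 2).sum(axis=0) / (M - 1)
    V = W_bar + (M + 1) / M * B_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(V > 0, theta_bar / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
    return pd.DataFrame(
        {
            "variable": matrix.variable_names,
            "theta_bar": theta_bar,
            "W_bar": W_bar,
            "B_bar": B_bar,
            "V": V,
            "T": T,
        }
    )


def rank_matrix(matrix: ImportanceMatrix) -> np.ndarray:
    """Within-imputation ranks (M x p), rank 1 = largest importance."""
    return rankdata(-matrix.theta, axis=1, method="average")


def rank_summary(matrix: ImportanceMatrix) -> pd.DataFrame:
    """Across-imputation mean rank and empirical 95% rank CI per variable.

    Percentiles use linear interpolation over the M per-imputation ranks;
    integers are produced by half-up rounding at reporting time, so a
    variable that is e.g. ranked first in every imputation gets the
    degenerate interval (1, 1).
    """
    ranks = rank_matrix(matrix)
    mean_raw = ranks.mean(axis=0)
    lo_raw = np.percentile(ranks, 2.5, axis=0)
    hi_raw = np.percentile(ranks, 97.5, axis=0)
    return pd.DataFrame(
        {
            "variable": matrix.variable_names,
            "mean_rank_raw": mean_raw,
            "mean_rank": round_half_up(mean_raw),
            "ci_low": round_half_up(lo_raw),
            "ci_high": round_half_up(hi_raw),
        }
    )
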