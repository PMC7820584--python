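"""The four report surfaces: importance bars, rank-CI dots, consensus bars,
and the calibration scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _save(fig, basepath) -> list:
    paths = []
    for ext in ("svg", "png"):
        path = Path(f"{basepath}.{ext}")
        fig.savefig(path, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def importance_bars(df: pd.DataFrame, value_col: str, basepath, k: int = 30,
                    title: str = "", xlabel: str = "") -> list:
    """Horizontal bar plot of the top-k variables, largest on top."""
    top = df.sort_values([value_col, "variable"], ascending=[False, True]).head(k)
    fig, ax = plt.subplots(figsize=(7, 0.28 * len(top) + 1.2))
    ax.barh(np.arange(len(top)), top[value_col].to_numpy(), color="#4878b0")
    ax.set_yticks(np.arange(len(top)))
    ax.set_yticklabels(top["variable"])
    ax.invert_yaxis()
    ax.set_xlabel(xlabel or value_col)
    ax.set_title(title)
    return _save(fig, basepath)


def rank_ci_plot(df: pd.DataFrame, basepath, k: int = 30, title: str = "") -> list:
    """Mean rank with 95% CI segment per variable, rank 1 at the top."""
    top = df.sort_values(["mean_rank_raw", "variable"]).head(k)
    ypos = np.arange(len(top))
    fig, ax = plt.subplots(figsize=(7, 0.28 * len(top) + 1.2))
    ax.hlines(ypos, top["ci_low"], top["ci_high"], color="#777777", lw=2)
    ax.plot(top["mean_rank"], ypos, "o", color="#c44e52")
    ax.set_yticks(ypos)
    ax.set_yticklabels(top["variable"])
    ax.invert_yaxis()
    ax.set_xlabel("rank (1 = most important)")
    ax.set_title(title)
    return _save(fig, basepath)


def calibration_plot(predicted, observed, line: tuple, basepath,
                     title: str = "") -> list:
    """Predicted-vs-observed scatter with identity and best-fit lines."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    intercept, slope = line
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.scatter(observed, predicted, s=14, alpha=0.6, color="#4878b0")
    lims = [min(observed.min(), predicted.min()), max(observed.max(), predicted.max())]
    ax.plot(lims, lims, "-", color="black", lw=1, label="x = y")
    xs = np.linspace(lims[0], lims[1], 2)
    ax.plot(xs, intercept + slope * xs, "--", color="#c44e52",
            label=f"fit: {intercept:.2f} + {slope:.2f} x")
    ax.set_xlabel("observed outcome")
    ax.set_ylabel("average OOB prediction")
    ax.legend()
    ax.set_title(title)
    return _save(fig, basepath)
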