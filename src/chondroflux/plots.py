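"""Minimal figure exports: correlation histogram and clustered heatmap.

Plain single-panel PNG/SVG renderings of the pipeline's CSV outputs, for
quick inspection; anything publication-grade should restyle from the CSVs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_correlation_histogram", "plot_heatmap"]


def plot_correlation_histogram(correlations: np.ndarray, path: str | Path,
                               title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(np.asarray(correlations, float), bins=40, range=(-1, 1),
            color="#41658a", edgecolor="white", linewidth=0.3)
    ax.axvline(0.5, color="#b2533e", linestyle="--", linewidth=1)
    ax.set_xlabel("Pearson correlation with original flux")
    ax.set_ylabel("randomized data sets")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "",
                 symmetric_scale: bool = True) -> None:
    values = matrix.to_numpy(dtype=float)
    lim = np.nanmax(np.abs(values)) if symmetric_scale else None
    fig, ax = plt.subplots(figsize=(max(4, 0.16 * matrix.shape[1]),
                                    max(3, 0.14 * matrix.shape[0])))
    im = ax.imshow(values, aspect="auto", cmap="RdBu_r",
                   vmin=-lim if lim else None, vmax=lim)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
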