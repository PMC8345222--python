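"""Plot helpers: Kaplan-Meier curves, correlation heatmaps, scaled 2D KDEs.

All functions take an optional matplotlib Axes and return it, so they can
be composed into panels; files are written only when a path is given.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .compare import CorrelationMatrix
from .spatial import KDEGrid


def plot_km(km: dict, ax: Optional[plt.Axes] = None,
            title: str = "", path: Optional[str | Path] = None) -> plt.Axes:
    """Step plot of the product-limit curves returned by ``km_estimate``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, curve in km.items():
        t = np.concatenate([[0.0], curve["times"]])
        s = np.concatenate([[1.0], curve["survival"]])
        ax.step(t, s, where="post", label=f"{name} (n={curve['n']})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_correlation_heatmap(corr: CorrelationMatrix,
                             ax: Optional[plt.Axes] = None,
                             path: Optional[str | Path] = None) -> plt.Axes:
    """Heatmap of the Spearman matrix, blue (-0.4) to red (1.0)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r.to_numpy(), vmin=-0.4, vmax=1.0, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.metrics)), corr.metrics, rotation=90)
    ax.set_yticks(range(len(corr.metrics)), corr.metrics)
    ax.figure.colorbar(im, ax=ax, label="Spearman r")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_kde2d(grid: KDEGrid, ax: Optional[plt.Axes] = None,
               title: str = "", path: Optional[str | Path] = None) -> plt.Axes:
    """Scaled joint NN-distance density with dotted median guides."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.x_grid, grid.y_grid, grid.density,
                         cmap="viridis", vmin=0.0, vmax=1.0, shading="auto")
    ax.axvline(grid.x_median, color="red", linestyle=":", linewidth=1)
    ax.axhline(grid.y_median, color="red", linestyle=":", linewidth=1)
    ax.set_xlabel("NN distance to Ki67+ (µm)")
    ax.set_ylabel("NN distance to Casp3+ (µm)")
    ax.figure.colorbar(mesh, ax=ax, label="scaled density")
    if title:
        ax.set_title(title)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
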