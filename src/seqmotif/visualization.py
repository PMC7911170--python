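"""Plots: 3-D bar charts, heatmaps, clustered heatmaps, PCA scatters.

All functions write an image file (png/svg/pdf) and return the matplotlib
Figure so callers can inspect labels or embed it elsewhere; inputs are never
mutated. Colormap defaults: a perceptually uniform map for frequencies and a
diverging map centered at D = 1 for D-ratio matrices, so over- and
under-representation are visually symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import TwoSlopeNorm
from scipy.cluster.hierarchy import dendrogram

from .clustering import ClusteringResult, ClusterMapResult
from .errors import ParameterError
from .feature_matrix import FeatureMatrix

_FORMATS = {".png", ".svg", ".pdf"}

# Legibility guards for grouped 3-D bars; overridable per call.
BAR3D_MAX_ROWS = 50
BAR3D_MAX_COLS = 64


@dataclass
class PlotSpec:
    """Where and how to render one plot."""

    output_path: str | Path
    title: str = ""
    dpi: int = 150
    colormap: str | None = None

    def __post_init__(self) -> None:
        if Path(self.output_path).suffix.lower() not in _FORMATS:
            raise ParameterError(
                f"output extension must be one of {sorted(_FORMATS)}: "
                f"{self.output_path}")
        if self.dpi <= 0:
            raise ParameterError("dpi must be positive")


def _default_cmap(matrix: FeatureMatrix, spec: PlotSpec) -> str:
    if spec.colormap:
        return spec.colormap
    return "RdBu_r" if matrix.basis == "dratio" else "viridis"


def _save(fig, spec: PlotSpec):
    fig.savefig(spec.output_path, dpi=spec.dpi)
    return fig


def plot_bar3d(matrix: FeatureMatrix, spec: PlotSpec,
               allow_large: bool = False):
    """Grouped 3-D bars over sequence × motif axes, bar height = value."""
    n, p = matrix.shape
    if not allow_large and (n > BAR3D_MAX_ROWS or p > BAR3D_MAX_COLS):
        raise ParameterError(
            f"{n}×{p} is too large for a legible 3-D bar chart "
            f"(limits {BAR3D_MAX_ROWS}×{BAR3D_MAX_COLS}); subset the motifs "
            "or pass allow_large=True")
    fig = plt.figure(figsize=(max(6, p * 0.35), max(5, n * 0.35)))
    ax = fig.add_subplot(projection="3d")
    xs, ys = np.meshgrid(np.arange(p), np.arange(n))
    xs, ys = xs.ravel(), ys.ravel()
    heights = matrix.values.ravel()
    cmap = plt.get_cmap(_default_cmap(matrix, spec))
    span = np.ptp(heights)
    colors = cmap((heights - heights.min()) / span if span else np.full_like(heights, 0.5))
    ax.bar3d(xs, ys, np.zeros_like(heights), 0.8, 0.8, heights, color=colors,
             shade=True)
    ax.set_xticks(np.arange(p) + 0.4)
    ax.set_xticklabels(matrix.col_names, rotation=60, fontsize=8)
    ax.set_yticks(np.arange(n) + 0.4)
    ax.set_yticklabels(matrix.row_ids, fontsize=8)
    ax.set_zlabel(matrix.basis)
    if spec.title:
        ax.set_title(spec.title)
    return _save(fig, spec)


def _heatmap_axes(ax, matrix: FeatureMatrix, spec: PlotSpec,
                  values: np.ndarray, row_ids, col_names):
    vmin, vmax = float(values.min()), float(values.max())
    cmap = _default_cmap(matrix, spec)
    norm = None
    if matrix.basis == "dratio" and vmin < 1.0 < vmax:
        norm = TwoSlopeNorm(vcenter=1.0, vmin=vmin, vmax=vmax)
    if vmin == vmax:  # constant matrix: widen the degenerate color range
        vmin, vmax = vmin - 0.5, vmax + 0.5
    if norm is not None:
        im = ax.imshow(values, aspect="auto", cmap=cmap, norm=norm)
    else:
        im = ax.imshow(values, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(np.arange(len(col_names)))
    ax.set_xticklabels(col_names, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(row_ids)))
    ax.set_yticklabels(row_ids, fontsize=7)
    return im


def plot_heatmap(matrix: FeatureMatrix, spec: PlotSpec):
    """Color-mapped rectangle per matrix cell, with a colorbar."""
    if matrix.df.size == 0:
        raise ParameterError("matrix is empty")
    values = matrix.values
    if not np.isfinite(values).all():
        raise ParameterError("matrix contains non-finite entries")
    n, p = matrix.shape
    fig, ax = plt.subplots(figsize=(max(6, p * 0.2), max(4, n * 0.2)))
    im = _heatmap_axes(ax, matrix, spec, values, matrix.row_ids, matrix.col_names)
    fig.colorbar(im, ax=ax, label=matrix.basis)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)


def plot_clustermap(result: ClusterMapResult, matrix: FeatureMatrix,
                    spec: PlotSpec):
    """Heatmap permuted by the clustermap orders, with dendrograms."""
    n, p = matrix.shape
    if len(result.row_order) != n or len(result.col_order) != p:
        raise ParameterError(
            f"clustermap result ({len(result.row_order)}×{len(result.col_order)}) "
            f"does not match the matrix ({n}×{p})")
    values = matrix.values[np.ix_(result.row_order, result.col_order)]
    row_ids = [matrix.row_ids[i] for i in result.row_order]
    col_names = [matrix.col_names[j] for j in result.col_order]

    fig = plt.figure(figsize=(max(7, p * 0.2), max(6, n * 0.2)))
    gs = fig.add_gridspec(2, 2, width_ratios=(1, 4), height_ratios=(1, 4),
                          wspace=0.02, hspace=0.02)
    ax_col = fig.add_subplot(gs[0, 1])
    ax_row = fig.add_subplot(gs[1, 0])
    ax_hm = fig.add_subplot(gs[1, 1])
    dendrogram(result.col_merges, ax=ax_col, no_labels=True,
               color_threshold=0, link_color_func=lambda _: "0.3")
    dendrogram(result.row_merges, ax=ax_row, no_labels=True,
               orientation="left", color_threshold=0,
               link_color_func=lambda _: "0.3")
    for ax in (ax_col, ax_row):
        ax.set_axis_off()
    ax_row.invert_yaxis()  # align dendrogram leaves with imshow row order
    im = _heatmap_axes(ax_hm, matrix, spec, values, row_ids, col_names)
    ax_hm.yaxis.tick_right()
    fig.colorbar(im, ax=ax_hm, pad=0.12, label=matrix.basis)
    if spec.title:
        fig.suptitle(spec.title)
    return _save(fig, spec)


def plot_pca_scatter(result: ClusteringResult, spec: PlotSpec):
    """2-D scatter of the PCA embedding colored by cluster label."""
    if result.embedding is None:
        raise ParameterError(
            "result has no PCA embedding; produce it with pca_kmeans")
    emb = result.embedding
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap(spec.colormap or "tab10")
    for c in range(result.n_clusters):
        mask = result.labels == c
        ax.scatter(emb[mask, 0], emb[mask, 1], s=18,
                   color=cmap(c % cmap.N), label=f"cluster {c}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)
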