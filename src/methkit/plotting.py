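"""Displays for methylation profiles: lollipop, co-occurrence matrix,
correspondence-analysis biplot and clustered heatmap.

Plot functions are pure consumers of computed objects: statistics are never
recomputed here.  Each display first builds a backend-independent layout
object (glyph states, coordinates, labels) which is what tests assert;
rendering to PNG/SVG is a thin final step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from matplotlib import colors
from matplotlib.figure import Figure

from .calls import MethylationDataset
from .stats import BiclusterResult, CAResult, CoOccurrenceMatrix

FILLED, EMPTY, ABSENT = "filled", "empty", "absent"


@dataclass
class LollipopLayout:
    """Geometry and glyph states of a lollipop display.

    One glyph row per clone plus a summary row whose per-site fill fraction
    equals the methylation percentage / 100; line weights between adjacent
    sites are monotone in |neighbour correlation|.
    """

    x_positions: np.ndarray
    clone_ids: list[str]
    glyphs: list[list[str]]          # clone rows of {filled, empty, absent}
    summary_fill: np.ndarray         # per-site fraction in [0,1] (NaN: no calls)
    line_weights: np.ndarray         # per adjacent pair, in [0.5, 4]
    mode: str
    positions: list[int]


def _line_weight(corr: float) -> float:
    """Monotone map |phi| -> line width (0.5 to 4 points)."""
    if np.isnan(corr):
        return 0.5
    return 0.5 + 3.5 * abs(float(corr))


def compute_lollipop_layout(ds: MethylationDataset, summary: pd.DataFrame,
                            neighbour_corr: CoOccurrenceMatrix | None = None,
                            mode: str = "genomic") -> LollipopLayout:
    """Build the layout: x coordinates, glyph states, summary fills."""
    if ds.n_sites == 0:
        raise ValueError("no CpG sites to display")
    if mode == "genomic":
        x = np.asarray(ds.cpg_positions, dtype=float)
    elif mode == "equidistant":
        x = np.arange(ds.n_sites, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    glyphs = []
    for row in ds.calls:
        glyphs.append([
            FILLED if v == 1.0 else EMPTY if v == 0.0 else ABSENT
            for v in row
        ])
    fills = summary["percent_methylated"].to_numpy() / 100.0
    if neighbour_corr is not None:
        pairs = neighbour_corr.neighbour_pairs()
        weights = np.array([_line_weight(v) for _, _, v in pairs])
    else:
        weights = np.full(max(ds.n_sites - 1, 0), 0.5)
    return LollipopLayout(
        x_positions=x,
        clone_ids=list(ds.clone_ids),
        glyphs=glyphs,
        summary_fill=fills,
        line_weights=weights,
        mode=mode,
        positions=list(ds.cpg_positions),
    )


def _save(fig: Figure, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    return path


def plot_lollipop(ds: MethylationDataset, summary: pd.DataFrame,
                  neighbour_corr: CoOccurrenceMatrix | None,
                  path: str | Path,
                  mode: str = "genomic") -> LollipopLayout:
    """Render the lollipop display; returns the layout actually drawn."""
    layout = compute_lollipop_layout(ds, summary, neighbour_corr, mode)
    n_rows = len(layout.clone_ids)
    fig = Figure(figsize=(max(6, ds.n_sites * 0.9), 1.2 + 0.5 * (n_rows + 1)))
    ax = fig.add_subplot(111)
    x = layout.x_positions
    y_summary = n_rows + 1.0

    for k in range(len(x) - 1):
        ax.plot(x[k:k + 2], [y_summary, y_summary], color="black",
                lw=layout.line_weights[k], zorder=1)
    for k, (xi, frac) in enumerate(zip(x, layout.summary_fill)):
        if np.isnan(frac):
            continue
        ax.scatter([xi], [y_summary], s=220, facecolors="white",
                   edgecolors="black", zorder=2)
        ax.scatter([xi], [y_summary], s=220 * frac, facecolors="black",
                   zorder=3)
        ax.annotate(f"{100 * frac:.0f}%", (xi, y_summary + 0.35),
                    ha="center", fontsize=7)

    for row_idx, (cid, states) in enumerate(zip(layout.clone_ids,
                                                layout.glyphs)):
        y = n_rows - 1 - row_idx
        ax.plot([x[0], x[-1]], [y, y], color="0.8", lw=0.8, zorder=1)
        for xi, state in zip(x, states):
            if state == ABSENT:
                continue
            face = "black" if state == FILLED else "white"
            ax.scatter([xi], [y], s=160, facecolors=face,
                       edgecolors="black", zorder=2)
        ax.annotate(cid, (x[0], y), xytext=(-8, 0),
                    textcoords="offset points", ha="right", va="center",
                    fontsize=8)

    ax.set_yticks([])
    ax.set_xticks(x)
    ax.set_xticklabels([str(p) for p in layout.positions], fontsize=8)
    ax.set_xlabel("CpG position (bp)" if mode == "genomic" else "CpG site")
    ax.set_ylim(-1, y_summary + 1)
    for spine in ("left", "right", "top"):
        ax.spines[spine].set_visible(False)
    _save(fig, path)
    return layout


def plot_cooccurrence_matrix(m: CoOccurrenceMatrix,
                             path: str | Path) -> None:
    """Symmetric heatmap with colour bar; genomic positions on the diagonal.

    Missing-flagged (NaN) cells render in a reserved neutral grey.
    """
    values = np.ma.masked_invalid(m.values)
    cmap = matplotlib.colormaps["RdBu_r"].copy()
    cmap.set_bad("0.85")
    vmin, vmax = (-1, 1) if m.mode == "correlation" else (0, 1)
    fig = Figure(figsize=(1 + 0.6 * len(m.positions),
                          1 + 0.6 * len(m.positions)))
    ax = fig.add_subplot(111)
    im = ax.imshow(values, cmap=cmap, vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.8,
                 label=("phi correlation" if m.mode == "correlation"
                        else "shared fraction"))
    for k, pos in enumerate(m.positions):
        ax.text(k, k, str(pos), ha="center", va="center", fontsize=8,
                bbox=dict(boxstyle="round,pad=0.15", fc="white", ec="none"))
    ax.set_xticks(range(len(m.positions)))
    ax.set_yticks(range(len(m.positions)))
    ax.set_xticklabels([str(p) for p in m.positions], fontsize=7)
    ax.set_yticklabels([str(p) for p in m.positions], fontsize=7)
    _save(fig, path)


def ca_axis_labels(ca: CAResult) -> list[str]:
    """Axis labels carrying percent inertia to two decimals."""
    return [f"Component {k + 1} ({v:.2f}%)"
            for k, v in enumerate(ca.percent_inertia)]


def plot_ca_biplot(ca: CAResult, path: str | Path) -> None:
    """Joint display of clone and CpG principal coordinates.

    CpG sites as red triangles, clones as black bullets; a rank-1 result is
    rendered as a one-dimensional strip.
    """
    labels = ca_axis_labels(ca)
    ndim = ca.row_coords.shape[1]
    fig = Figure(figsize=(6, 6 if ndim >= 2 else 2.5))
    ax = fig.add_subplot(111)
    rx = ca.row_coords[:, 0]
    cx = ca.col_coords[:, 0]
    if ndim >= 2:
        ry, cy = ca.row_coords[:, 1], ca.col_coords[:, 1]
        ax.set_ylabel(labels[1])
    else:  # strip plot
        ry = np.zeros_like(rx)
        cy = np.zeros_like(cx)
        ax.set_yticks([])
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    ax.scatter(cx, cy, marker="^", color="red", label="CpG sites", zorder=3)
    ax.scatter(rx, ry, marker="o", color="black", label="clones", zorder=3)
    for x, y, cid in zip(rx, ry, ca.row_ids):
        ax.annotate(str(cid), (x, y), xytext=(4, 4),
                    textcoords="offset points", fontsize=7)
    for x, y, pos in zip(cx, cy, ca.col_ids):
        ax.annotate(str(pos), (x, y), xytext=(4, -8),
                    textcoords="offset points", fontsize=7, color="red")
    ax.set_xlabel(labels[0])
    ax.legend(fontsize=8)
    _save(fig, path)


def plot_cluster_heatmap(ds: MethylationDataset,
                         clust: BiclusterResult | None,
                         path: str | Path) -> None:
    """Methylation matrix reordered by both dendrograms, three colours.

    Methylated light, unmethylated red (matching the original display
    convention), missing grey; dendrograms on the margins.  A single-clone
    dataset renders without a row dendrogram.
    """
    from scipy.cluster import hierarchy

    if clust is not None:
        if (len(clust.row_order) != ds.n_clones
                or len(clust.col_order) != ds.n_sites):
            raise ValueError("tree/matrix size mismatch")
        row_order, col_order = clust.row_order, clust.col_order
    else:
        row_order = list(range(ds.n_clones))
        col_order = list(range(ds.n_sites))
    mat = ds.calls[np.ix_(row_order, col_order)]

    cmap = colors.ListedColormap(["#c23b22", "#fdf0d5"])  # unmeth, meth
    cmap.set_bad("0.8")
    fig = Figure(figsize=(2 + 0.5 * ds.n_sites, 2 + 0.4 * ds.n_clones))
    if clust is not None and ds.n_clones > 1:
        gs = fig.add_gridspec(2, 2, width_ratios=[1, 4],
                              height_ratios=[1, 4], hspace=0.05, wspace=0.05)
        ax_col = fig.add_subplot(gs[0, 1])
        hierarchy.dendrogram(clust.col_linkage, ax=ax_col, no_labels=True,
                             link_color_func=lambda _: "black")
        ax_col.set_axis_off()
        ax_row = fig.add_subplot(gs[1, 0])
        hierarchy.dendrogram(clust.row_linkage, ax=ax_row, no_labels=True,
                             orientation="left",
                             link_color_func=lambda _: "black")
        ax_row.set_axis_off()
        ax = fig.add_subplot(gs[1, 1])
    else:
        ax = fig.add_subplot(111)
    ax.imshow(np.ma.masked_invalid(mat), cmap=cmap, vmin=0, vmax=1,
              aspect="auto")
    ax.set_xticks(range(ds.n_sites))
    ax.set_xticklabels([str(ds.cpg_positions[j]) for j in col_order],
                       fontsize=7, rotation=90)
    ax.set_yticks(range(ds.n_clones))
    ax.set_yticklabels([ds.clone_ids[i] for i in row_order], fontsize=7)
    ax.yaxis.tick_right()
    _save(fig, path)
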