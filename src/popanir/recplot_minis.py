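"""Recruitment mini-plots: genome position x read identity density grids.

A RecPlot mini shows where on the genome reads align (x-axis, contigs
concatenated in reference order) against their percent identity (y-axis),
as a white-to-black density grid with marginal histograms on the top and
right. When the target population is robustly detected (breadth >= 10%), a
dashed horizontal line marks its ANIr and an M/A/D/B text block reports
mANIr, ANIr, depth and breadth; below detection, line and metrics are
omitted. Many minis can be arranged on a single page to match a sampling
scheme (for example ocean basin by depth).

All mapped reads are drawn in the grid — the sub-threshold cloud of a
co-occurring relative is part of the picture — while the annotated metrics
are restricted to the target population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import matplotlib

matplotlib.use("Agg")  # non-interactive; rendering must not need a display
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.figure import Figure
from matplotlib.gridspec import GridSpecFromSubplotSpec

from .alignment_io import AlignmentRecord, ReferenceIndex
from .population_metrics import PopulationMetrics

__all__ = [
    "RecplotGrid",
    "build_recplot_grid",
    "render_recplot_mini",
    "arrange_panel",
    "save_figure",
]


@dataclass(frozen=True)
class RecplotGrid:
    """Binned read counts over (genome position, identity)."""

    x_edges: np.ndarray  # concatenated-genome position bin edges
    y_edges: np.ndarray  # identity bin edges
    counts: np.ndarray  # shape (n_x_bins, n_y_bins), non-negative ints
    contig_offsets: dict[str, int]

    @property
    def x_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def y_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


def build_recplot_grid(
    records: Sequence[AlignmentRecord],
    reference: ReferenceIndex,
    n_x_bins: int = 200,
    y_bin_width: float = 0.5,
    floor: float = 70.0,
) -> RecplotGrid:
    """Bin each read once, at its alignment midpoint, into the 2-D grid.

    Contigs are concatenated in reference order with cumulative offsets, so
    x is a single coordinate over the whole genome. Binning by midpoint
    guarantees every read lands in exactly one cell.
    """
    offsets: dict[str, int] = {}
    running = 0
    for contig, length in reference.contig_lengths.items():
        offsets[contig] = running
        running += length
    x_edges = np.linspace(0, reference.total_length, n_x_bins + 1)
    n_y = int(round((100.0 - floor) / y_bin_width))
    y_edges = np.linspace(floor, 100.0, n_y + 1)
    if records:
        x = np.array(
            [offsets[r.contig_id] + 0.5 * (r.ref_start + r.ref_end) for r in records]
        )
        y = np.array([r.identity for r in records])
        counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
        counts = counts.astype(np.int64)
    else:
        counts = np.zeros((n_x_bins, n_y), dtype=np.int64)
    return RecplotGrid(x_edges=x_edges, y_edges=y_edges, counts=counts,
                       contig_offsets=offsets)


def _draw_mini(
    fig: Figure,
    subplotspec,
    grid: RecplotGrid,
    metrics: PopulationMetrics | None,
    label: str,
    log_scale: bool,
) -> None:
    inner = GridSpecFromSubplotSpec(
        2, 2, subplot_spec=subplotspec,
        width_ratios=(4, 1), height_ratios=(1, 4), wspace=0.05, hspace=0.05,
    )
    ax_main = fig.add_subplot(inner[1, 0])
    ax_top = fig.add_subplot(inner[0, 0], sharex=ax_main)
    ax_right = fig.add_subplot(inner[1, 1], sharey=ax_main)

    data = np.log1p(grid.counts) if log_scale else grid.counts.astype(float)
    ax_main.pcolormesh(grid.x_edges, grid.y_edges, data.T, cmap="Greys",
                       rasterized=True)
    ax_main.set_xlim(grid.x_edges[0], grid.x_edges[-1])
    ax_main.set_ylim(grid.y_edges[0], grid.y_edges[-1])

    x_centers = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    y_centers = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    ax_top.bar(x_centers, grid.x_marginal, width=np.diff(grid.x_edges),
               color="0.3")
    ax_right.barh(y_centers, grid.y_marginal, height=np.diff(grid.y_edges),
                  color="0.3")
    ax_top.tick_params(labelbottom=False, labelleft=False, length=0)
    ax_right.tick_params(labelbottom=False, labelleft=False, length=0)
    ax_main.tick_params(labelsize=5)

    if metrics is not None and metrics.detected:
        # Dashed line at the target population's ANIr; M/A/D/B value block.
        ax_main.axhline(metrics.anir, color="red", linestyle="--", linewidth=0.8,
                        gid="anir-line")
        block = (
            f"M: {metrics.manir:.2f}\n"
            f"A: {metrics.anir:.2f}\n"
            f"D: {metrics.depth:.2f}x\n"
            f"B: {100 * metrics.breadth:.1f}%"
        )
        ax_main.text(0.02, 0.02, block, transform=ax_main.transAxes,
                     fontsize=5, va="bottom", ha="left", gid="madb-block")
    if label:
        ax_main.text(0.98, 0.02, label, transform=ax_main.transAxes,
                     fontsize=6, va="bottom", ha="right", gid="mini-label")


def render_recplot_mini(
    grid: RecplotGrid,
    metrics: PopulationMetrics | None = None,
    label: str = "",
    log_scale: bool = True,
    figsize: tuple[float, float] = (3.0, 3.0),
) -> Figure:
    """Render one RecPlot mini as a matplotlib figure."""
    fig = plt.figure(figsize=figsize, dpi=150)
    spec = fig.add_gridspec(1, 1)[0]
    _draw_mini(fig, spec, grid, metrics, label, log_scale)
    return fig


def arrange_panel(
    plots: Mapping[
        tuple[int, int],
        tuple[RecplotGrid, PopulationMetrics | None, str],
    ],
    n_rows: int | None = None,
    n_cols: int | None = None,
    log_scale: bool = True,
    cell_size: tuple[float, float] = (2.4, 2.4),
) -> Figure:
    """Place minis at (row, col) positions on a single page.

    Positions not present in ``plots`` stay blank; a duplicate position is
    an error (enforced by the mapping type at construction, re-checked here
    for sequence inputs).
    """
    items = list(plots.items())
    positions = [pos for pos, _ in items]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate (row, col) position in panel layout")
    if not items:
        raise ValueError("empty panel layout")
    n_rows = n_rows or (1 + max(r for r, _ in positions))
    n_cols = n_cols or (1 + max(c for _, c in positions))
    for r, c in positions:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"position ({r}, {c}) outside {n_rows}x{n_cols} panel")
    fig = plt.figure(
        figsize=(cell_size[0] * n_cols, cell_size[1] * n_rows), dpi=150
    )
    outer = fig.add_gridspec(n_rows, n_cols, wspace=0.35, hspace=0.35)
    for (row, col), (grid, metrics, label) in items:
        _draw_mini(fig, outer[row, col], grid, metrics, label, log_scale)
    return fig


def save_figure(fig: Figure, path: Union[str, Path]) -> None:
    """Save PNG/PDF with empty metadata so repeated runs are byte-identical."""
    path = Path(path)
    if path.suffix.lower() == ".pdf":
        fig.savefig(path, metadata={"CreationDate": None})
    else:
        fig.savefig(path, metadata={"Software": ""})
    plt.close(fig)
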