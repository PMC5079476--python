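"""Publication-quality exports: clustered correlation heatmaps and tables.

The heatmap colour scale is always the full diverging domain [-1, 1],
never rescaled to the data, so figures from different runs and datasets
share one colour key. Undefined correlations are drawn in a distinct
"missing" grey rather than as numeric 0. Embedded file-metadata timestamps
are suppressed so identical runs produce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .correlate import CorrelationMatrix, CorrelationTable
from .io_formats import DataError

FORMATS = ("png", "svg", "pdf")
MISSING_COLOR = "#b0b0b0"
LABEL_AUTO_HIDE = 80  # above this many experiments, labels become unreadable


@dataclass
class HeatmapSpec:
    """Everything needed to draw one clustered correlation heatmap."""

    matrix: CorrelationMatrix
    cmap: str = "RdBu_r"
    labels: str = "auto"  # show | hide | auto
    label_threshold: int = LABEL_AUTO_HIDE
    highlight: str | None = None  # experiment id to mark (the user sample)
    fmt: str = "png"
    dpi: int = 150
    size: tuple[float, float] = field(default=(8.0, 8.0))

    def __post_init__(self) -> None:
        if self.fmt not in FORMATS:
            raise DataError(f"unknown figure format {self.fmt!r}; choose from {FORMATS}")
        if self.labels not in ("show", "hide", "auto"):
            raise DataError(f"label policy must be show/hide/auto, got {self.labels!r}")

    def show_labels(self) -> bool:
        if self.labels == "auto":
            return self.matrix.n <= self.label_threshold
        return self.labels == "show"


def _savefig_metadata(fmt: str) -> dict:
    # drop the embedded creation timestamp so outputs are byte-stable
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return {}


def render_heatmap(spec: HeatmapSpec, path: str | Path) -> None:
    """Draw the clustered heatmap (with dendrogram when available) to ``path``."""
    path = Path(path)
    cm = spec.matrix
    ids, vals = cm.reordered()
    n = cm.n
    masked = np.ma.masked_invalid(vals)
    cmap = plt.get_cmap(spec.cmap).copy()
    cmap.set_bad(MISSING_COLOR)

    fig = plt.figure(figsize=spec.size, dpi=spec.dpi)
    has_tree = cm.linkage is not None and len(cm.clustered) >= 2
    if has_tree:
        gs = fig.add_gridspec(
            2, 2, height_ratios=[1, 5], width_ratios=[20, 1], hspace=0.02, wspace=0.05
        )
        ax_tree = fig.add_subplot(gs[0, 0])
        ax_heat = fig.add_subplot(gs[1, 0])
        ax_cbar = fig.add_subplot(gs[1, 1])
        with plt.rc_context({"lines.linewidth": 0.8}):
            hierarchy.dendrogram(
                cm.linkage,
                ax=ax_tree,
                no_labels=True,
                color_threshold=0,
                above_threshold_color="black",
            )
        # dendrogram leaves sit at 10*i + 5; align them with heatmap cells
        ax_tree.set_xlim(0, 10 * n)
        ax_tree.axis("off")
    else:
        gs = fig.add_gridspec(1, 2, width_ratios=[20, 1], wspace=0.05)
        ax_heat = fig.add_subplot(gs[0, 0])
        ax_cbar = fig.add_subplot(gs[0, 1])

    mesh = ax_heat.imshow(
        masked,
        cmap=cmap,
        vmin=-1.0,
        vmax=1.0,  # fixed domain: one colour key for every figure
        aspect="auto",
        interpolation="nearest",
        extent=(0, n, n, 0),
    )
    fig.colorbar(mesh, cax=ax_cbar, label="Pearson r")

    if spec.show_labels():
        ax_heat.set_xticks(np.arange(n) + 0.5)
        ax_heat.set_yticks(np.arange(n) + 0.5)
        ax_heat.set_xticklabels(ids, rotation=90, fontsize=max(3, min(8, 400 // max(n, 1))))
        ax_heat.set_yticklabels(ids, fontsize=max(3, min(8, 400 // max(n, 1))))
    else:
        ax_heat.set_xticks([])
        ax_heat.set_yticks([])

    highlight = spec.highlight or cm.user_id
    if highlight is not None and highlight in ids:
        pos = ids.index(highlight)
        ax_heat.add_patch(
            plt.Rectangle((pos, 0), 1, n, fill=False, edgecolor="limegreen", linewidth=1.2)
        )
        ax_heat.add_patch(
            plt.Rectangle((0, pos), n, 1, fill=False, edgecolor="limegreen", linewidth=1.2)
        )
        if spec.show_labels():
            ax_heat.get_xticklabels()[pos].set_color("green")
            ax_heat.get_yticklabels()[pos].set_color("green")

    try:
        # fixed hashsalt keeps SVG element ids (and hence bytes) run-stable
        with plt.rc_context({"svg.hashsalt": "seqcorr"}):
            fig.savefig(path, format=spec.fmt, dpi=spec.dpi, metadata=_savefig_metadata(spec.fmt))
    except OSError as exc:
        raise DataError(f"cannot write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)


def export_table(
    table: CorrelationTable | CorrelationMatrix, path: str | Path, fmt: str | None = None
) -> None:
    """Write a ranked correlation table or a full matrix as TSV/CSV.

    Values carry 8 significant digits; undefined correlations are written
    as the literal ``NA``. Re-reading an exported table reproduces the
    ranks exactly.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "tsv"
    if fmt not in ("tsv", "csv"):
        raise DataError(f"unknown table format {fmt!r}; choose tsv or csv")
    sep = "\t" if fmt == "tsv" else ","
    frame = table.frame if isinstance(table, CorrelationTable) else table.to_frame()
    try:
        frame.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.8g")
    except OSError as exc:
        raise DataError(f"cannot write table to {path}: {exc}") from exc


def read_matrix_table(path: str | Path) -> CorrelationMatrix:
    """Load a matrix written by :func:`export_table` back into a CorrelationMatrix."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix table not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    if df.columns[0] != "experiment_id":
        raise DataError(f"{path}: first column must be experiment_id")
    ids = [str(v) for v in df["experiment_id"]]
    vals = df.drop(columns="experiment_id").to_numpy(dtype=float)
    if list(df.columns[1:]) != ids or vals.shape != (len(ids), len(ids)):
        raise DataError(f"{path}: matrix is not square with matching row/column ids")
    return CorrelationMatrix(ids=ids, values=vals)
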