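"""Chromosomally ordered summary heatmap.

Genes (rows) and miRNAs (columns) are sorted by chromosomal location
(1..22, X, Y, MT, then other contigs lexicographic).  Significant cells
are drawn on a white->red ramp scaled by the magnitude of the partial
estimate; cells that are also present in at least one target database
are a fixed dark green; everything else is background.  A TSV dump of
the per-cell color matrix accompanies the image so rendering can be
asserted deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import CorrelationGrid

logger = logging.getLogger(__name__)

BACKGROUND = "#f0f0f0"
DARK_GREEN = "#1b5e20"

_CANONICAL = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
_CHROM_RANK = {c: i for i, c in enumerate(_CANONICAL)}

Coord = tuple[str, int]  # (chromosome, start)


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    if c == "M":
        c = "MT"
    if c in _CHROM_RANK:
        return (_CHROM_RANK[c], "")
    return (len(_CANONICAL), c)


@dataclass
class ChromosomalOrder:
    """A total order over features: positional where known, input order otherwise."""

    ordered_ids: list[str]
    missing_coordinates: list[str]


def chromosomal_sort(
    ids: list[str], coordinates: dict[str, Coord]
) -> ChromosomalOrder:
    """Stable sort by (chromosome rank, start, id); unplaced features go last."""
    placed = [i for i in ids if i in coordinates]
    missing = [i for i in ids if i not in coordinates]
    placed.sort(key=lambda i: (*_chrom_key(coordinates[i][0]), coordinates[i][1], i))
    if missing:
        logger.warning("chromosomal_sort: %d features lack coordinates; placed last",
                       len(missing))
    return ChromosomalOrder(ordered_ids=placed + missing, missing_coordinates=missing)


def _red_ramp(intensity: float) -> str:
    """White->red hex ramp for intensity in [0, 1]."""
    t = float(np.clip(intensity, 0.0, 1.0))
    gb = int(round(255 * (1.0 - t)))
    return f"#ff{gb:02x}{gb:02x}"


def color_matrix(
    grid: CorrelationGrid,
    table: pd.DataFrame,
    order_rows: list[str],
    order_cols: list[str],
) -> pd.DataFrame:
    """Per-cell hex colors for the heatmap; the testable core of rendering.

    Exactly the interaction-table rows (restricted to the rendered
    columns) are colored; validated rows are dark green, the rest a red
    ramp on |partial estimate| normalized within the significant set.
    """
    colors = pd.DataFrame(BACKGROUND, index=order_rows, columns=order_cols)
    if table.empty:
        return colors
    sig = table[table["gene"].isin(order_rows) & table["mirna"].isin(order_cols)]
    if sig.empty:
        return colors
    mags = sig["partial_estimate"].abs()
    lo, hi = float(mags.min()), float(mags.max())
    span = hi - lo
    validated = (
        sig["validated_any"] if "validated_any" in sig.columns
        else pd.Series(False, index=sig.index)
    )
    for (_, row), is_val in zip(sig.iterrows(), validated):
        if is_val:
            c = DARK_GREEN
        else:
            t = (abs(row["partial_estimate"]) - lo) / span if span > 0 else 1.0
            # floor keeps the faintest significant cell distinguishable from background
            c = _red_ramp(0.15 + 0.85 * t)
        colors.loc[row["gene"], row["mirna"]] = c
    return colors


def top_expressed_mirnas(
    mi_data: pd.DataFrame, fraction: float
) -> list[str]:
    """IDs of the ``fraction`` most expressed miRNAs (highest mean expression)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, int(round(fraction * len(mi_data))))
    means = mi_data.mean(axis=1)
    ranked = sorted(mi_data.index, key=lambda i: (-means[i], i))
    return ranked[:k]


def render_heatmap(
    grid: CorrelationGrid,
    table: pd.DataFrame,
    order_rows: list[str],
    order_cols: list[str],
    out_path: str | Path,
    top_mirna_fraction: float | None = None,
    mi_data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Render the summary heatmap to PNG + SVG with a TSV color-matrix dump.

    ``out_path`` is the basename; ``.png``, ``.svg`` and ``.colors.tsv``
    suffixes are appended.  When ``top_mirna_fraction`` is given, columns
    are subset to the most expressed miRNAs (requires ``mi_data``).
    Returns the rendered color matrix.
    """
    if top_mirna_fraction is not None:
        if mi_data is None:
            raise ValueError("top_mirna_fraction requires mi_data")
        keep = set(top_expressed_mirnas(mi_data, top_mirna_fraction))
        order_cols = [c for c in order_cols if c in keep]
    colors = color_matrix(grid, table, order_rows, order_cols)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    colors.to_csv(out_path.with_suffix(".colors.tsv"), sep="\t")

    rgb = np.zeros((len(order_rows), max(len(order_cols), 1), 3))
    for i, g in enumerate(order_rows):
        for j, m in enumerate(order_cols):
            c = colors.loc[g, m]
            rgb[i, j] = [int(c[k : k + 2], 16) / 255 for k in (1, 3, 5)]
    h = max(2.0, 0.12 * len(order_rows))
    w = max(2.0, 0.12 * max(len(order_cols), 1))
    fig, ax = plt.subplots(figsize=(min(w, 12), min(h, 12)))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_xlabel("miRNAs (chromosomal order)")
    ax.set_ylabel("genes (chromosomal order)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path.with_suffix(".png"), dpi=150)
    fig.savefig(out_path.with_suffix(".svg"))
    plt.close(fig)
    return colors
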