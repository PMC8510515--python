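"""Heatmap rendering of the display matrix.

Layout: named positions as columns in N→C reference order (each position
split into its retained residue letters), receiver-domain types as rows
ordered response regulators → HHKs → unclassified by decreasing Glu-Asp
abundance at DD.  Cells are colored by quintile bin: 0% and 100% dark, the
five quintiles in between light-to-saturated.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_heatmap"]

_BIN_LEVEL = {"ZERO": 0, "Q1": 1, "Q2": 2, "Q3": 3, "Q4": 4, "Q5": 5, "FULL": 6}

_GREEK = {"a": "α", "b": "β"}


def _pretty_loop(name: str) -> str:
    # "a3b4" -> "α3β4"
    out = []
    for ch in name:
        out.append(_GREEK.get(ch, ch))
    return "".join(out)


def render_heatmap(
    display: pd.DataFrame,
    path: str | Path,
    insertion_percent: pd.DataFrame | None = None,
    tm_percent: dict[str, float] | None = None,
    title: str = "Amino-acid frequency at key receiver-domain positions",
) -> Path:
    """Render the display matrix (and optional insertion/TM columns) to an image.

    ``display`` is the long-format output of :func:`recprofiler.profiles.display_matrix`
    (columns rd_type, position, residue, fraction, bin, already ordered).
    ``insertion_percent`` may add per-type columns (loop, fraction);
    ``tm_percent`` adds a TM column.  Writes PNG or SVG by file extension.
    """
    types = list(dict.fromkeys(display["rd_type"]))
    pos_order = list(dict.fromkeys(display["position"]))
    columns: list[tuple[str, str]] = []
    for pos in pos_order:
        residues = sorted(set(display.loc[display["position"] == pos, "residue"]))
        for r in residues:
            columns.append((pos, r))

    extra: list[tuple[str, np.ndarray]] = []
    if insertion_percent is not None:
        for loop, sub in insertion_percent.groupby("loop", sort=True):
            vals = sub.set_index("rd_type")["fraction"]
            extra.append(
                (f"ins {_pretty_loop(str(loop))}",
                 np.array([vals.get(t, np.nan) for t in types]))
            )
    if tm_percent is not None:
        extra.append(("TM", np.array([tm_percent.get(t, np.nan) for t in types])))

    n_rows, n_cols = len(types), len(columns) + len(extra)
    grid = np.full((n_rows, n_cols), np.nan)
    lookup = display.set_index(["rd_type", "position", "residue"])["bin"]
    for i, t in enumerate(types):
        for j, (pos, res) in enumerate(columns):
            try:
                grid[i, j] = _BIN_LEVEL[lookup.loc[(t, pos, res)]]
            except KeyError:
                grid[i, j] = _BIN_LEVEL["ZERO"]
    from .profiles import quintile_bin

    for k, (_, vals) in enumerate(extra):
        for i, v in enumerate(vals):
            if not np.isnan(v):
                grid[i, len(columns) + k] = _BIN_LEVEL[quintile_bin(float(v))]

    fig_w = max(6.0, 0.28 * n_cols + 2.5)
    fig_h = max(3.0, 0.28 * n_rows + 2.0)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    cmap = matplotlib.colors.ListedColormap(
        ["#2b2b50", "#dce9f6", "#a9cbe8", "#6fa8d6", "#3f7fbf", "#1d5a9e", "#0b2d5c"]
    )
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=6, aspect="auto", interpolation="nearest")

    labels = [f"{pos}\n{res}" for pos, res in columns] + [name for name, _ in extra]
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(labels, fontsize=6)
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(types, fontsize=7)
    ax.set_title(title, fontsize=10)

    handles = [
        plt.Rectangle((0, 0), 1, 1, color=cmap(i / 6)) for i in range(7)
    ]
    ax.legend(
        handles,
        ["0%", "≤20%", "≤40%", "≤60%", "≤80%", "<100%", "100%"],
        loc="upper left",
        bbox_to_anchor=(1.01, 1.0),
        fontsize=6,
        title="abundance",
        title_fontsize=7,
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
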