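"""Seaborn-style visualisation of epiallele pattern tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .patterns import PatternTable

__all__ = ["pattern_heatmap"]


def pattern_heatmap(
    table: PatternTable,
    path: str | Path | None = None,
    top_k: int = 20,
    title: str | None = None,
):
    """Heatmap of the most frequent patterns: one row per pattern (descending
    frequency), one column per CpG, cells methylated/unmethylated, with the
    pattern frequency annotated on the right."""
    rows = sorted(
        ((p, c) for p, c in table.counts.items() if p != "other"),
        key=lambda pc: (-pc[1], pc[0]),
    )[:top_k]
    if not rows:
        raise ValueError("empty pattern table")
    matrix = np.array([[1 if s == "M" else 0 for s in p] for p, _ in rows])
    freqs = [c / table.total_reads for _, c in rows]

    fig, ax = plt.subplots(
        figsize=(0.4 * matrix.shape[1] + 2, 0.3 * len(rows) + 1.5)
    )
    sns.heatmap(
        matrix,
        cmap=sns.color_palette(["#f2f2f2", "#c0392b"], as_cmap=True),
        cbar=False,
        linewidths=0.5,
        linecolor="white",
        ax=ax,
    )
    ax.set_yticks(np.arange(len(rows)) + 0.5)
    ax.set_yticklabels([f"{f:.3f}" for f in freqs], rotation=0, fontsize=8)
    ax.set_ylabel("pattern frequency")
    ax.set_xlabel("CpG site")
    ax.set_xticks(np.arange(matrix.shape[1]) + 0.5)
    ax.set_xticklabels(np.arange(1, matrix.shape[1] + 1), fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
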