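"""Quadrant scatter: entropy removal vs Youden's J with threshold cutlines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .exceptions import ValidationError
from .quadrant import DEFAULT_ER_CUT, DEFAULT_J_CUT

__all__ = ["quadrant_plot"]

# stable ids/hashes so identical inputs yield byte-identical SVG output
matplotlib.rcParams["svg.hashsalt"] = "entrodx"


def quadrant_plot(
    results: pd.DataFrame,
    path: str | Path,
    j_cut: float = DEFAULT_J_CUT,
    er_cut: float = DEFAULT_ER_CUT,
) -> Path:
    """Scatter er_fraction (y) against youden_j (x) with dashed cutlines.

    The four quadrant labels are annotated in the plot corners.  Output
    format follows the file extension (.png or .svg); rendering is
    deterministic — no jitter, and SVG metadata is pinned so the same
    input produces byte-identical files.
    """
    if results.empty:
        raise ValidationError("cannot plot an empty results table")
    for col in ("youden_j", "er_fraction"):
        if col not in results.columns:
            raise ValidationError(f"results table is missing the {col!r} column")

    fig, ax = plt.subplots(figsize=(7, 5.5))
    ax.scatter(
        results["youden_j"], results["er_fraction"],
        s=18, alpha=0.65, edgecolors="none", color="#20639b", zorder=3,
    )
    ax.axvline(j_cut, linestyle="--", color="0.35", linewidth=1)
    ax.axhline(er_cut, linestyle="--", color="0.35", linewidth=1)
    label_kw = dict(fontsize=8, color="0.4", ha="center", va="center")
    ax.text((j_cut + 1) / 2, (er_cut + 1) / 2, "High Accuracy\nHigh Information", **label_kw)
    ax.text((j_cut + 1) / 2, er_cut / 2, "High Accuracy\nLow Information", **label_kw)
    ax.text((j_cut - 1) / 2, (er_cut + 1) / 2, "Low Accuracy\nHigh Information", **label_kw)
    ax.text((j_cut - 1) / 2, er_cut / 2, "Low Accuracy\nLow Information", **label_kw)
    ax.set_xlabel("Youden's J")
    ax.set_ylabel("Fraction of entropy removed")
    ax.set_title("Accuracy vs. information")
    ax.set_xlim(-1.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()

    path = Path(path)
    metadata = {"Date": None} if path.suffix.lower() == ".svg" else None
    fig.savefig(path, metadata=metadata)
    plt.close(fig)
    return path
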