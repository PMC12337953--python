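"""Secondary figure output. TSV tables are the pipeline's contract; these
matplotlib helpers mirror them for quick visual inspection."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["chcdf_scatter", "ps_curve_plot", "recall_plot"]

_QUADRANT_COLORS = {"Q1": "#2b6cb0", "Q2": "#718096", "Q3": "#c53030", "Q4": "#b7791f"}


def chcdf_scatter(points: pd.DataFrame, title: str = "", ax=None):
    """CH vs CDF scatter, coloured by quadrant, with the axis cross-hairs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for quadrant, grp in points.groupby("quadrant"):
        ax.scatter(
            grp["cdf"], grp["ch"], s=8, alpha=0.6,
            color=_QUADRANT_COLORS.get(quadrant, "k"), label=quadrant,
        )
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("CDF score (positive = ordered)")
    ax.set_ylabel("CH score (positive = disordered)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def ps_curve_plot(curves: Mapping[str, pd.DataFrame], ax=None):
    """Cumulative PS-IDR length curves, one line per proteome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve["length"], curve["percent"], label=name)
    ax.set_xlabel("PS-IDR length L (residues)")
    ax.set_ylabel("% proteins with a PS-IDR ≥ L")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=8)
    return ax


def recall_plot(x, y, auc: float, label: str = "", ax=None):
    """Recall curve of a test proteome against the reference, with its AUC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(x, y, label=f"{label} (AUC = {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("fraction of reference recalled")
    ax.set_ylabel("fraction of test proteome recalled")
    ax.legend(fontsize=8)
    return ax
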