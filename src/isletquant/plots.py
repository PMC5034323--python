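"""Optional plot rendering for the analytics outputs.

Each function draws onto a fresh figure and returns it; callers save with
``fig.savefig(path)``.  Uses the Agg-safe matplotlib API only.
"""

from __future__ import annotations

import numpy as np

from .analytics import ShapePoint, SizeHistogram
from .stereology import SelectionCurve

__all__ = ["plot_size_histogram", "plot_selection_curve", "plot_shape_scatter"]

_TYPE_COLORS = {"insulin": "tab:green", "glucagon": "tab:red",
                "somatostatin": "tab:blue", "pp": "tab:orange"}


def plot_size_histogram(hist: SizeHistogram):
    """Islet size distribution (bars) with per-bin cell-type fractions and
    the cumulative area-fraction line on a log cell-equivalent axis."""
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    width = hist.bin_edges[1] - hist.bin_edges[0]
    ax1.bar(centers, hist.counts, width=width * 0.9, color="0.7", label="islets")
    ax1.set_ylabel("islet count")
    axf = ax1.twinx()
    for t in hist.comp_mean.columns:
        color = _TYPE_COLORS.get(t, None)
        axf.errorbar(centers, hist.comp_mean[t], yerr=hist.comp_sem[t],
                     label=t, color=color, marker="o", ms=3, lw=1)
    axf.set_ylabel("cell-type fraction")
    axf.set_ylim(0, 1)
    axf.legend(loc="upper right", fontsize=8)

    ax2.bar(centers, hist.counts / hist.counts.sum(), width=width * 0.9,
            color="0.7", label="count fraction")
    ax2.plot(centers, hist.area_fraction, color="tab:red", marker="o", ms=3,
             label="area fraction")
    ax2.set_xlabel("islet size, log10 cell-equivalents")
    ax2.set_ylabel("fraction")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_selection_curve(curve: SelectionCurve):
    """Cumulative percent endocrine area vs number of selected panels, with
    the whole-section reference line."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.k_values, curve.percent, color="tab:blue", lw=1.2,
            label="islet-rich selection")
    ax.axhline(curve.reference, color="k", ls="--",
               label=f"whole section ({curve.reference:.3f}%)")
    ax.set_xlabel("panels selected (most islet-rich first)")
    ax.set_ylabel("percent endocrine area")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_shape_scatter(points: list[ShapePoint], highlight_pp: set[int] | None = None):
    """3-D size/shape scatter, density color-coded; optionally ring islets
    whose ids are in ``highlight_pp``."""
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    xs = [p.log_area for p in points]
    ys = [p.circularity for p in points]
    zs = [p.feret for p in points]
    dens = np.array([p.density for p in points])
    sc = ax.scatter(xs, ys, zs, c=dens, cmap="viridis", s=10)
    if highlight_pp:
        hp = [p for p in points if p.islet_id in highlight_pp]
        ax.scatter([p.log_area for p in hp], [p.circularity for p in hp],
                   [p.feret for p in hp], facecolors="none",
                   edgecolors="tab:orange", s=40, label="PP-containing")
        ax.legend(fontsize=8)
    fig.colorbar(sc, ax=ax, label="local density", shrink=0.6)
    ax.set_xlabel("log10 cell-equivalents")
    ax.set_ylabel("circularity")
    ax.set_zlabel("Feret diameter, µm")
    return fig
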