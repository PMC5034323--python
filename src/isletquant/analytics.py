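"""Islet size-distribution and shape analytics.

Islet sizes span four orders of magnitude, with singlets and small clusters
far outnumbering large islets, so size histograms use a logarithmic axis in
cell-equivalents: islet area divided by a nominal single endocrine cell area
(178 µm²), a dimensionless proxy for the number of cells in the structure.
Composition-by-size curves track how the cell-type makeup shifts across the
size range (in humans, the alpha-cell fraction rises with islet size), and
the area-fraction curve shows that the few large islets carry most of the
endocrine mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segment import IsletRecord

__all__ = [
    "SizeHistogram",
    "ShapePoint",
    "cell_equivalents",
    "log_size_histogram",
    "shape_scatter",
    "flag_pp_islets",
    "effective_diameter",
]

SINGLE_CELL_AREA_UM2 = 178.0
DEFAULT_BIN_WIDTH = 0.25  # log10 cell-equivalents


def cell_equivalents(islet_area: float, single_cell_area: float = SINGLE_CELL_AREA_UM2):
    """Islet area expressed as number of single-cell areas (dimensionless)."""
    if single_cell_area <= 0:
        raise ValueError("single_cell_area must be > 0")
    return islet_area / single_cell_area


def effective_diameter(area: float) -> float:
    """Diameter of the circle with the same area: 2·sqrt(area/pi)."""
    return 2.0 * np.sqrt(area / np.pi)


@dataclass
class SizeHistogram:
    """Log-binned islet size distribution with per-bin composition."""

    bin_edges: np.ndarray            # log10 cell-equivalents, len = n_bins + 1
    counts: np.ndarray               # islets per bin
    comp_mean: pd.DataFrame          # mean cell-type fraction per bin (bins × types)
    comp_sem: pd.DataFrame           # SEM of the fractions
    bin_area: np.ndarray             # summed islet area per bin, µm²
    area_fraction: np.ndarray        # bin_area / total area
    n_zero_cell_islets: int = 0      # islets without typed cells (excluded
                                     # from composition means, kept in counts)


def log_size_histogram(
    records: list[IsletRecord],
    bin_width: float = DEFAULT_BIN_WIDTH,
    single_cell_area: float = SINGLE_CELL_AREA_UM2,
    use_total_area: bool = True,
) -> SizeHistogram:
    """Histogram of islet sizes on a log10 cell-equivalent axis.

    Bin index = floor(log10(cell_equivalents) / bin_width); bins are
    contiguous from the smallest to the largest occupied index.  Composition
    fractions are averaged per islet (each islet is one sample; mean ± SEM),
    so small and large islets weigh equally within a bin.
    """
    if not records:
        raise ValueError("no islet records")
    areas = np.array([r.total_islet_area if use_total_area else r.endocrine_area
                      for r in records])
    if (areas <= 0).any():
        raise ValueError("all islet areas must be > 0")
    ce = areas / single_cell_area
    idx = np.floor(np.log10(ce) / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    n_bins = hi - lo + 1
    edges = (np.arange(lo, hi + 2)) * bin_width
    counts = np.bincount(idx - lo, minlength=n_bins)
    bin_area = np.zeros(n_bins)
    np.add.at(bin_area, idx - lo, areas)

    types = sorted({t for r in records for t in r.cell_counts})
    frac_sums = {t: [[] for _ in range(n_bins)] for t in types}
    n_zero = 0
    for r, b in zip(records, idx - lo):
        total = sum(r.cell_counts.values())
        if total == 0:
            n_zero += 1
            continue
        for t in types:
            frac_sums[t][b].append(r.cell_counts.get(t, 0) / total)
    mean = pd.DataFrame(index=range(n_bins), columns=types, dtype=float)
    sem = pd.DataFrame(index=range(n_bins), columns=types, dtype=float)
    for t in types:
        for b in range(n_bins):
            vals = np.array(frac_sums[t][b])
            if vals.size:
                mean.loc[b, t] = vals.mean()
                sem.loc[b, t] = (vals.std(ddof=1) / np.sqrt(vals.size)
                                 if vals.size > 1 else 0.0)
    return SizeHistogram(
        bin_edges=edges,
        counts=counts,
        comp_mean=mean,
        comp_sem=sem,
        bin_area=bin_area,
        area_fraction=bin_area / bin_area.sum(),
        n_zero_cell_islets=n_zero,
    )


@dataclass
class ShapePoint:
    islet_id: int
    log_area: float       # log10 cell-equivalents
    circularity: float
    feret: float          # µm
    density: float        # inverse mean kNN distance in standardized space
    flagged: bool = False


def shape_scatter(
    records: list[IsletRecord],
    k_neighbors: int = 10,
    single_cell_area: float = SINGLE_CELL_AREA_UM2,
) -> list[ShapePoint]:
    """Size/shape scatter data with a local-density score per islet.

    Features (log-area, circularity, Feret) are z-scored over the dataset so
    the density score is invariant to axis units; density = 1 / mean distance
    to the k nearest neighbors in the standardized 3-space.  With N <= k the
    N-1 available neighbors are used; a single islet gets density 0, flagged.
    """
    if not records:
        raise ValueError("no islet records")
    feats = np.array([
        [np.log10(max(r.total_islet_area / single_cell_area, 1e-12)),
         r.circularity, r.feret]
        for r in records
    ])
    n = len(records)
    if n == 1:
        return [ShapePoint(records[0].islet_id, *feats[0], density=0.0, flagged=True)]
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / std
    k = min(k_neighbors, n - 1)
    tree = cKDTree(z)
    dists, _ = tree.query(z, k=k + 1)  # first neighbor is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    density = 1.0 / (mean_d + 1e-12)
    return [
        ShapePoint(r.islet_id, feats[i, 0], feats[i, 1], feats[i, 2],
                   density=float(density[i]))
        for i, r in enumerate(records)
    ]


def flag_pp_islets(
    records: list[IsletRecord],
    min_pp_cells: int = 1,
    pp_type: str = "pp",
) -> list[IsletRecord]:
    """Set ``contains_pp`` on islets with at least ``min_pp_cells`` PP cells."""
    if not any(pp_type in r.cell_counts for r in records):
        warnings.warn(f"no {pp_type!r} cell type in any record; all flags False")
    for r in records:
        r.contains_pp = r.cell_counts.get(pp_type, 0) >= min_pp_cells
    return records
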