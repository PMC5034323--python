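"""Synthetic pancreas sections with full ground truth.

The generator emulates the tissue properties the pipeline must handle:
lobular tissue carrying scattered islets from singlet endocrine cells to
clusters of hundreds of cells (log-normal size distribution), a
size-dependent cell-type composition (the alpha-cell fraction rises with
islet size, as in human pancreas), nuclei lying inside hormone-positive
cytoplasm, optional islet-rich spatial clustering, smooth background
gradients with Gaussian noise, and signal-free exclusion regions (vessels,
ducts).  Cells are rendered as cytoplasm disks with concentric disk nuclei —
the simplest geometry that exercises perinuclear-ring classification.

Everything is deterministic given the seed; the returned ground truth is the
answer sheet against which pipeline output is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ContourSet, SectionImage
from .segment import IsletRecord, SectionSummary, summarize_section
from .stereology import BlockSummary

__all__ = [
    "SynthParams",
    "CellTruth",
    "IsletTruth",
    "GroundTruth",
    "generate_section",
    "truth_summary",
    "generate_block_percents",
    "generate_organ_blocks",
    "write_manifest",
]

# nominal single endocrine cell area of 178 µm² -> radius ~7.5 µm
DEFAULT_CELL_RADIUS_UM = float(np.sqrt(178.0 / np.pi))


@dataclass
class SynthParams:
    """Generation parameters; defaults give a realistic 4 mm² section."""

    frame_um: tuple[float, float] = (2000.0, 2000.0)
    pixel_size: float = 1.0
    n_islets: int = 40
    size_median_cells: float = 5.0       # log-normal median islet size (cells)
    size_log_sd: float = 1.1             # sd of ln(cell count)
    max_cells: int = 400
    clustering: str = "uniform"          # or "clustered"
    n_clusters: int = 3
    cluster_dispersion_um: float = 150.0
    base_fractions: dict[str, float] = field(default_factory=lambda: {
        "insulin": 0.78, "glucagon": 0.12, "somatostatin": 0.10})
    alpha_slope: float = 0.06            # d(alpha fraction)/d(log10 cells)
    alpha_type: str = "glucagon"
    beta_type: str = "insulin"
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM
    nucleus_radius_um: float = 3.0
    cyto_overlap: float = 0.1            # fractional overlap of adjacent cells
    signal_level: float = 200.0
    nucleus_level: float = 200.0
    background_level: float = 10.0
    gradient_amplitude: float = 5.0
    noise_sd: float = 10.0               # 5% of signal_level
    n_exclusions: int = 0
    exclusion_size_um: tuple[float, float] = (60.0, 160.0)
    min_islet_spacing_um: float = 15.0   # clear space between islet rims
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus radius must be smaller than cell radius")
        if self.pixel_size <= 0 or min(self.frame_um) <= 0:
            raise ValueError("dimensions must be positive")
        if any(f < 0 for f in self.base_fractions.values()) or \
                sum(self.base_fractions.values()) > 1 + 1e-9:
            raise ValueError("base fractions must be >= 0 and sum <= 1")
        if not 0 <= self.cyto_overlap < 1:
            raise ValueError("cyto_overlap must be in [0, 1)")


@dataclass
class CellTruth:
    position_um: tuple[float, float]
    cell_type: str
    nucleus_radius_um: float


@dataclass
class IsletTruth:
    islet_id: int
    center_um: tuple[float, float]
    radius_um: float
    cells: list[CellTruth]
    stained_px: int = 0   # pixels this islet paints in the hormone channels

    @property
    def cell_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cells:
            counts[c.cell_type] = counts.get(c.cell_type, 0) + 1
        return counts


@dataclass
class GroundTruth:
    params: SynthParams
    islets: list[IsletTruth]
    hormone_masks: dict[str, np.ndarray]   # noise-free signal masks
    nuclei_mask: np.ndarray
    pancreas_area_um2: float
    cluster_centers_um: list[tuple[float, float]] = field(default_factory=list)

    @property
    def stained_areas_um2(self) -> dict[str, float]:
        px2 = self.params.pixel_size**2
        return {h: float(m.sum() * px2) for h, m in self.hormone_masks.items()}

    @property
    def percent_endocrine_area(self) -> float:
        union = np.zeros_like(self.nuclei_mask, dtype=bool)
        for m in self.hormone_masks.values():
            union |= m
        endo = union.sum() * self.params.pixel_size**2
        return 100.0 * float(endo) / self.pancreas_area_um2


def _sunflower(n: int, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform points in the unit disk (phyllotaxis), random rotation."""
    if n == 1:
        return np.zeros((1, 2))
    i = np.arange(n) + 0.5
    r = np.sqrt(i / n)
    golden = np.pi * (3 - np.sqrt(5))
    theta = i * golden + rng.uniform(0, 2 * np.pi)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _pack_cells(n: int, cell_radius: float, overlap: float,
                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Cell center offsets (µm) within an islet and the islet radius."""
    pts = _sunflower(n, rng)
    if n > 1:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1].min()
        target = 2 * cell_radius * (1 - overlap)
        pts = pts * (target / nn)
    radius = float(np.hypot(pts[:, 0], pts[:, 1]).max() + cell_radius)
    return pts, radius


def _paint_disk(raster: np.ndarray, cx: float, cy: float, r: float,
                value: float) -> None:
    h, w = raster.shape
    c0, c1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    r0, r1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    if c1 <= c0 or r1 <= r0:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (xx + 0.5 - cx)**2 + (yy + 0.5 - cy)**2 <= r * r
    raster[r0:r1, c0:c1][inside] = value


def _disk_mask(shape, cx, cy, r) -> tuple[slice, slice, np.ndarray]:
    h, w = shape
    c0, c1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    r0, r1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1),
            (xx + 0.5 - cx)**2 + (yy + 0.5 - cy)**2 <= r * r)


def _type_fractions(params: SynthParams, n_cells: int) -> dict[str, float]:
    """Composition at a given islet size: alpha fraction grows with log size,
    compensated by the beta fraction."""
    fr = dict(params.base_fractions)
    if params.alpha_type in fr and params.beta_type in fr:
        shift = params.alpha_slope * np.log10(max(n_cells, 1))
        shift = min(shift, fr[params.beta_type])  # keep fractions valid
        fr[params.alpha_type] = fr[params.alpha_type] + shift
        fr[params.beta_type] = fr[params.beta_type] - shift
    total = sum(fr.values())
    if total > 1:
        fr = {k: v / total for k, v in fr.items()}
    return fr


def generate_section(params: SynthParams) -> tuple[SectionImage, ContourSet, GroundTruth]:
    """Render a synthetic multi-channel section and its ground truth."""
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    w_um, h_um = params.frame_um
    W, H = int(round(w_um / px)), int(round(h_um / px))
    hormones = list(params.base_fractions)

    # --- islet sizes, then placement with spacing rejection
    n_cells_all = np.clip(
        np.round(rng.lognormal(np.log(params.size_median_cells),
                               params.size_log_sd, params.n_islets)),
        1, params.max_cells).astype(int)

    cluster_centers: list[tuple[float, float]] = []
    if params.clustering == "clustered":
        margin = 0.15 * min(w_um, h_um)
        cluster_centers = [tuple(rng.uniform(margin, d - margin) for d in (w_um, h_um))
                           for _ in range(params.n_clusters)]

    islets: list[IsletTruth] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, radius)
    for n_cells in n_cells_all:
        offsets, radius = _pack_cells(int(n_cells), params.cell_radius_um,
                                      params.cyto_overlap, rng)
        center = None
        for _ in range(200):
            if cluster_centers:
                base = cluster_centers[rng.integers(len(cluster_centers))]
                cand = (base[0] + rng.normal(0, params.cluster_dispersion_um),
                        base[1] + rng.normal(0, params.cluster_dispersion_um))
            else:
                cand = (rng.uniform(0, w_um), rng.uniform(0, h_um))
            if not (radius < cand[0] < w_um - radius
                    and radius < cand[1] < h_um - radius):
                continue
            ok = all(np.hypot(cand[0] - x, cand[1] - y)
                     >= radius + r + params.min_islet_spacing_um
                     for x, y, r in placed)
            if ok:
                center = cand
                break
        if center is None:
            continue  # frame too crowded; ground truth reflects what was placed
        placed.append((center[0], center[1], radius))
        fractions = _type_fractions(params, int(n_cells))
        probs = np.array([fractions[h] for h in hormones])
        probs = probs / probs.sum()
        types = rng.choice(hormones, size=int(n_cells), p=probs)
        cells = [CellTruth(
            position_um=(center[0] + ox, center[1] + oy),
            cell_type=str(t),
            nucleus_radius_um=params.nucleus_radius_um,
        ) for (ox, oy), t in zip(offsets, types)]
        islets.append(IsletTruth(
            islet_id=len(islets) + 1,
            center_um=center, radius_um=radius, cells=cells))

    # --- render noise-free signal masks
    hormone_masks = {h: np.zeros((H, W), dtype=bool) for h in hormones}
    nuclei_mask = np.zeros((H, W), dtype=bool)
    r_cell_px = params.cell_radius_um / px
    r_nuc_px = params.nucleus_radius_um / px
    for islet in islets:
        local = np.zeros((H, W), dtype=bool)
        for cell in islet.cells:
            cx, cy = cell.position_um[0] / px, cell.position_um[1] / px
            sl_r, sl_c, disk = _disk_mask((H, W), cx, cy, r_cell_px)
            hormone_masks[cell.cell_type][sl_r, sl_c] |= disk
            local[sl_r, sl_c] |= disk
            sl_r, sl_c, disk = _disk_mask((H, W), cx, cy, r_nuc_px)
            nuclei_mask[sl_r, sl_c] |= disk
        islet.stained_px = int(local.sum())

    # --- exclusion rectangles (placed clear of islets)
    exclusions: list[np.ndarray] = []
    excl_mask = np.zeros((H, W), dtype=bool)
    for _ in range(params.n_exclusions):
        for _ in range(200):
            ew = rng.uniform(*params.exclusion_size_um)
            eh = rng.uniform(*params.exclusion_size_um)
            x0 = rng.uniform(0, w_um - ew)
            y0 = rng.uniform(0, h_um - eh)
            clear = all(not _rect_circle_overlap(x0, y0, ew, eh, x, y, r)
                        for x, y, r in placed)
            if clear:
                poly = np.array([[x0, y0], [x0 + ew, y0],
                                 [x0 + ew, y0 + eh], [x0, y0 + eh]]) / px
                exclusions.append(poly)
                c0, c1 = int(x0 / px), int(np.ceil((x0 + ew) / px))
                r0, r1 = int(y0 / px), int(np.ceil((y0 + eh) / px))
                xs = np.arange(c0, min(c1, W)) + 0.5
                ys = np.arange(r0, min(r1, H)) + 0.5
                sub = ((xs[None, :] * px > x0) & (xs[None, :] * px < x0 + ew) &
                       (ys[:, None] * px > y0) & (ys[:, None] * px < y0 + eh))
                excl_mask[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]] |= sub
                break

    # --- compose intensity channels
    yy, xx = np.mgrid[0:H, 0:W]
    gradient = params.gradient_amplitude * ((xx / max(W - 1, 1)) +
                                            (yy / max(H - 1, 1))) / 2.0
    channels: dict[str, np.ndarray] = {}
    order = ["nuclei"] + hormones
    for role in order:
        signal = (nuclei_mask * params.nucleus_level if role == "nuclei"
                  else hormone_masks[role] * params.signal_level)
        img = params.background_level + gradient + signal
        if params.noise_sd > 0:
            img = img + rng.normal(0, params.noise_sd, size=(H, W))
        img = np.clip(img, 0, None)
        img[excl_mask] = 0.0
        channels[role] = img.astype(np.float32)

    # exclusions carve signal-free holes out of the tissue and the truth masks
    for h in hormones:
        hormone_masks[h] &= ~excl_mask
    nuclei_mask &= ~excl_mask

    outline = np.array([[0.0, 0.0], [W, 0.0], [W, H], [0.0, H]])
    contours = ContourSet(pancreas_outline=[outline], exclusions=exclusions)
    pancreas_area = float((W * H - int(excl_mask.sum())) * px**2)
    section = SectionImage(channels=channels, pixel_size=px)
    gt = GroundTruth(
        params=params,
        islets=islets,
        hormone_masks=hormone_masks,
        nuclei_mask=nuclei_mask,
        pancreas_area_um2=pancreas_area,
        cluster_centers_um=cluster_centers,
    )
    return section, contours, gt


def _rect_circle_overlap(x0, y0, w, h, cx, cy, r) -> bool:
    nearest_x = min(max(cx, x0), x0 + w)
    nearest_y = min(max(cy, y0), y0 + h)
    return np.hypot(cx - nearest_x, cy - nearest_y) < r


def truth_summary(gt: GroundTruth) -> SectionSummary:
    """The reference answer sheet: per-islet and section-level truth."""
    px2 = gt.params.pixel_size**2
    records = []
    for islet in gt.islets:
        rec = IsletRecord(
            islet_id=islet.islet_id,
            endocrine_area=float(islet.stained_px * px2),
            total_islet_area=float(islet.stained_px * px2),
            centroid=islet.center_um,
            cell_counts=islet.cell_counts,
        )
        records.append(rec)
    if gt.pancreas_area_um2 <= 0:
        raise ValueError("empty tissue")
    return summarize_section(gt.pancreas_area_um2, gt.stained_areas_um2, records)


# ---------------------------------------------------------------------------
# lightweight parametric generators for the section/block-level designs

def generate_block_percents(
    n_sections: int,
    true_percent: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[float]:
    """Per-section percent endocrine area through one block: a constant true
    fraction plus independent sampling noise (truncated at 0)."""
    rng = np.random.default_rng(seed)
    return list(np.clip(rng.normal(true_percent, noise_sd, n_sections), 0, None))


def generate_organ_blocks(
    region_percents: dict[str, float] | None = None,
    blocks_per_region: int = 4,
    block_area_um2: float = 4e8,
    area_jitter: float = 0.2,
    percent_jitter: float = 0.1,
    seed: int = 0,
) -> list[BlockSummary]:
    """Blocks along a synthetic organ: head/body/tail with region-specific
    endocrine density (default ~1:1:2 head:body:tail, as in human pancreas
    where the PP-rich and islet-rich tail runs denser)."""
    if region_percents is None:
        region_percents = {"head": 1.0, "body": 1.0, "tail": 2.0}
    rng = np.random.default_rng(seed)
    blocks = []
    for region, pct in region_percents.items():
        for _ in range(blocks_per_region):
            blocks.append(BlockSummary(
                region=region,
                pancreas_area=float(block_area_um2 *
                                    rng.uniform(1 - area_jitter, 1 + area_jitter)),
                percent_endocrine_area=float(
                    max(0.0, rng.normal(pct, percent_jitter * pct))),
            ))
    return blocks


def write_manifest(gt: GroundTruth, path: str | Path) -> None:
    """JSON ground-truth manifest (seed, parameters, per-islet truth)."""
    doc = {
        "seed": gt.params.seed,
        "pixel_size_um": gt.params.pixel_size,
        "frame_um": list(gt.params.frame_um),
        "pancreas_area_um2": gt.pancreas_area_um2,
        "percent_endocrine_area": gt.percent_endocrine_area,
        "stained_areas_um2": gt.stained_areas_um2,
        "islets": [
            {
                "islet_id": i.islet_id,
                "center_um": list(i.center_um),
                "radius_um": i.radius_um,
                "n_cells": len(i.cells),
                "cell_counts": i.cell_counts,
                "stained_px": i.stained_px,
            }
            for i in gt.islets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
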