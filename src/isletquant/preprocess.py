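"""Background subtraction, tissue-mask construction and binarization.

The tissue mask is the normalization region for endocrine cell mass: the
manually drawn pancreas outline minus every exclusion region (vessel, duct,
fat, inter-lobe space) whose area exceeds a configurable fraction of the
outline (default 0.05%).  Smaller exclusions are deliberately left inside the
mask — they are below the resolution at which normalization is affected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .io import BinaryMask, ContourSet, SectionImage, rasterize_polygon, rasterize_polygons

DEFAULT_EXCLUSION_MIN_FRACTION = 0.0005  # exclusions must occupy >0.05% of the outline
DEFAULT_ROLLING_BALL_RADIUS = 50  # px

__all__ = [
    "ThresholdSpec",
    "TissueMask",
    "subtract_background",
    "build_tissue_mask",
    "auto_threshold",
    "binarize",
    "save_thresholds",
    "load_thresholds",
    "write_mask",
]


@dataclass
class ThresholdSpec:
    """A per-channel binarization threshold (intensity units) with its
    provenance: set manually or derived automatically (Otsu)."""

    value: float
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.provenance not in ("manual", "automatic"):
            raise ValueError(f"provenance must be manual|automatic, got {self.provenance!r}")


@dataclass
class TissueMask:
    """The pancreas-area normalization mask with its areas in µm²."""

    mask: BinaryMask
    pixel_size: float
    pancreas_area: float
    excluded_area: float
    applied_exclusions: list[int]


def _ball_structure(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r_int = int(np.ceil(radius))
    coords = np.arange(-r_int, r_int + 1)
    xx, yy = np.meshgrid(coords, coords)
    d2 = xx**2 + yy**2
    footprint = d2 <= radius**2
    heights = np.sqrt(np.clip(radius**2 - d2, 0, None))
    return footprint, heights


def _ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening by a ball: the rolling-ball background surface.

    Out-of-frame pixels are treated as +inf for the erosion and -inf for the
    dilation, i.e. the ball rolls under the frame only where there is data.
    """
    footprint, heights = _ball_structure(radius)
    r = footprint.shape[0] // 2
    big = float(np.abs(img).max() + heights.max() + 1) * 4
    padded = np.pad(img, r, constant_values=big)
    eroded = ndimage.grey_erosion(padded, footprint=footprint,
                                  structure=heights)[r:-r, r:-r]
    padded = np.pad(eroded, r, constant_values=-big)
    return ndimage.grey_dilation(padded, footprint=footprint,
                                 structure=heights)[r:-r, r:-r]


def subtract_background(channel: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background subtraction applied to the whole raster.

    Estimates the smooth background as the surface traced by a ball of the
    given radius rolled under the intensity landscape (grayscale opening
    with a ball structuring element), then subtracts it.  Output is
    everywhere >= 0 and never exceeds the input.  For radii above 16 px the
    background is estimated on a block-minimum-downscaled raster and
    upsampled bilinearly (large balls are insensitive to fine detail).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    img = channel.astype(float)
    shrink = max(1, int(radius // 8)) if radius > 16 else 1
    if shrink == 1:
        background = _ball_opening(img, radius)
    else:
        h, w = img.shape
        ph = (-h) % shrink
        pw = (-w) % shrink
        padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        small = padded.reshape(
            padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink
        ).min(axis=(1, 3))
        bg_small = _ball_opening(small, max(1.0, radius / shrink))
        background = resize(bg_small, padded.shape, order=1, mode="edge",
                            anti_aliasing=False)[:h, :w]
        background = np.minimum(background, img)
    out = img - background
    return np.clip(out, 0, None)


def build_tissue_mask(
    section: SectionImage,
    contours: ContourSet,
    exclusion_min_fraction: float = DEFAULT_EXCLUSION_MIN_FRACTION,
) -> TissueMask:
    """Rasterize the pancreas outline and subtract qualifying exclusions.

    An exclusion polygon is subtracted only if its rasterized area is
    strictly greater than ``exclusion_min_fraction`` times the rasterized
    outline area; smaller ones are ignored.
    """
    shape = section.shape
    outline = rasterize_polygons(contours.pancreas_outline, shape)
    outline_px = int(outline.sum())
    if outline_px == 0:
        raise ValueError("pancreas outline rasterizes to zero pixels")
    mask = outline.copy()
    applied: list[int] = []
    excluded_px = 0
    for i, excl in enumerate(contours.exclusions):
        excl_mask = rasterize_polygon(excl, shape)
        if excl_mask.sum() > exclusion_min_fraction * outline_px:
            removed = int((mask & excl_mask).sum())
            mask &= ~excl_mask
            applied.append(i)
            excluded_px += removed
    px2 = section.pixel_size**2
    return TissueMask(
        mask=BinaryMask(mask, label="tissue"),
        pixel_size=section.pixel_size,
        pancreas_area=float(mask.sum() * px2),
        excluded_area=float(excluded_px * px2),
        applied_exclusions=applied,
    )


def auto_threshold(channel: np.ndarray) -> ThresholdSpec:
    """Otsu threshold (maximizes between-class variance), flagged automatic."""
    channel = np.asarray(channel)
    if np.unique(channel).size < 2:
        raise ValueError("cannot threshold a constant channel")
    return ThresholdSpec(value=float(threshold_otsu(channel)), provenance="automatic")


def binarize(channel: np.ndarray, thr: ThresholdSpec, tissue: TissueMask,
             label: str = "") -> BinaryMask:
    """(channel >= threshold) AND tissue mask; pixels outside the pancreas
    area are always 0."""
    channel = np.asarray(channel)
    if channel.shape != tissue.mask.shape:
        raise ValueError(
            f"shape mismatch: channel {channel.shape} vs tissue {tissue.mask.shape}")
    return BinaryMask((channel >= thr.value) & tissue.mask.data, label=label)


# ---------------------------------------------------------------------------
# serialization

def save_thresholds(specs: dict[str, ThresholdSpec], path: str | Path) -> None:
    """Plain-text key=value threshold file (one channel per line)."""
    lines = [f"{name}={spec.value}  # {spec.provenance}" for name, spec in specs.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_thresholds(path: str | Path) -> dict[str, ThresholdSpec]:
    specs: dict[str, ThresholdSpec] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        body, _, comment = line.partition("#")
        name, _, value = body.partition("=")
        provenance = comment.strip() or "manual"
        specs[name.strip()] = ThresholdSpec(float(value), provenance)
    return specs


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (mask.data.astype(np.uint8) * 255))
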