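"""Calibrated multi-channel section images, contour sets and binary masks.

Coordinate convention used throughout the package: pixel-index space with the
origin at the top-left corner, ``x`` = column, ``y`` = row, 0-based.  Pixel
``(row, col)`` covers the unit square ``[col, col+1) x [row, row+1)`` and its
center sits at ``(col + 0.5, row + 0.5)``.  Physical coordinates in µm are
pixel coordinates multiplied by ``pixel_size``.  A pixel is inside a polygon
iff its center is inside (even-odd rule).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

NUCLEI_ROLE = "nuclei"

__all__ = [
    "SectionImage",
    "ContourSet",
    "BinaryMask",
    "read_section",
    "write_section",
    "read_contours",
    "write_contours",
    "rasterize_polygon",
    "rasterize_polygons",
    "polygon_area",
]


@dataclass
class SectionImage:
    """A calibrated multi-channel raster.

    ``channels`` maps a channel role to a 2-D intensity array.  Exactly one
    role must be ``"nuclei"``; the remaining 1-3 roles are free-text hormone
    names (e.g. ``"insulin"``, ``"glucagon"``, ``"somatostatin"``, ``"pp"``).
    ``pixel_size`` is the physical edge length of one pixel in µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        roles = list(self.channels)
        if roles.count(NUCLEI_ROLE) != 1:
            raise ValueError("exactly one channel must have role 'nuclei'")
        n_hormones = len(roles) - 1
        if not 1 <= n_hormones <= 3:
            raise ValueError(f"need 1-3 hormone channels, got {n_hormones}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for role, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2-D")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def hormone_roles(self) -> list[str]:
        return [r for r in self.channels if r != NUCLEI_ROLE]

    @property
    def nuclei(self) -> np.ndarray:
        return self.channels[NUCLEI_ROLE]

    @property
    def frame_um(self) -> tuple[float, float]:
        """(width, height) of the section frame in µm."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)


def _as_polygon(coords: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(coords, dtype=float))
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon is not simple (self-intersecting or degenerate)")
    if poly.area == 0:
        raise ValueError("polygon has zero area")
    return shapely.geometry.polygon.orient(poly)  # normalize winding to CCW


@dataclass
class ContourSet:
    """Manually drawn pancreas-area outline(s) plus exclusion polygons.

    Polygons are (N, 2) arrays of (x, y) vertices in pixel coordinates.
    Exclusions mark regions without endocrine or exocrine tissue (large
    vessels, ducts, peripancreatic fat, empty inter-lobe space).
    """

    pancreas_outline: list[np.ndarray]
    exclusions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pancreas_outline:
            raise ValueError("pancreas_outline must contain at least one polygon")
        self.pancreas_outline = [
            np.asarray(_as_polygon(p).exterior.coords[:-1], dtype=float)
            for p in self.pancreas_outline
        ]
        self.exclusions = [
            np.asarray(_as_polygon(p).exterior.coords[:-1], dtype=float)
            for p in self.exclusions
        ]


@dataclass
class BinaryMask:
    """A {0,1} raster with a semantic label (tissue / endocrine / per-hormone
    / nuclei / islet-structure), same shape as its parent section."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# rasterization

def rasterize_polygon(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon: a pixel is set iff its center is inside.

    ``coords`` is (N, 2) in (x, y) pixel coordinates; ``shape`` is (H, W).
    """
    poly = Polygon(np.asarray(coords, dtype=float))
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx - 0.5)))
    c1 = min(w, int(np.ceil(maxx + 0.5)))
    r0 = max(0, int(np.floor(miny - 0.5)))
    r1 = min(h, int(np.ceil(maxy + 0.5)))
    if c1 <= c0 or r1 <= r0:
        return out
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    out[r0:r1, c0:c1] = inside
    return out


def rasterize_polygons(polys: Sequence[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Union rasterization of several polygons."""
    out = np.zeros(shape, dtype=bool)
    for p in polys:
        out |= rasterize_polygon(p, shape)
    return out


def polygon_area(coords: np.ndarray) -> float:
    """Continuous (shoelace) polygon area in px²."""
    return Polygon(np.asarray(coords, dtype=float)).area


# ---------------------------------------------------------------------------
# TIFF image IO

def read_section(
    image_path: str | Path | None,
    channel_map: Mapping[str, int | str | Path],
    pixel_size: float,
) -> SectionImage:
    """Read a calibrated section from a multi-page TIFF or per-channel TIFFs.

    ``channel_map`` maps role → page index (multi-page TIFF at
    ``image_path``) or role → file path (per-channel files; ``image_path``
    then ignored / may be None).  Exactly one role must be ``"nuclei"``.
    Intensities are preserved bit-exactly.
    """
    channels: dict[str, np.ndarray] = {}
    for role, src in channel_map.items():
        if isinstance(src, (int, np.integer)):
            if image_path is None:
                raise ValueError("page indices in channel_map require image_path")
            path = Path(image_path)
            if not path.exists():
                raise FileNotFoundError(path)
            channels[role] = tifffile.imread(path, key=int(src))
        else:
            path = Path(src)
            if not path.exists():
                raise FileNotFoundError(path)
            channels[role] = tifffile.imread(path)
    return SectionImage(channels=channels, pixel_size=pixel_size)


def write_section(section: SectionImage, path: str | Path) -> dict[str, int]:
    """Write a section as a multi-page TIFF; returns the role → page map."""
    path = Path(path)
    arrays = list(section.channels.values())
    tifffile.imwrite(path, np.stack(arrays), photometric="minisblack", metadata={
        "roles": list(section.channels),
        "pixel_size_um": section.pixel_size,
    })
    return {role: i for i, role in enumerate(section.channels)}


# ---------------------------------------------------------------------------
# contour IO: GeoJSON (canonical) and ImageJ .roi (compatibility)

def read_contours(path: str | Path, format: str | None = None) -> ContourSet:
    """Read contours from GeoJSON (``kind`` property = ``pancreas`` |
    ``exclusion``) or ImageJ ``.roi`` polygon files.

    For ``imagej_roi``, ``path`` may be a single ``.roi`` file (treated as the
    pancreas outline) or a directory of ``.roi`` files in which file names
    beginning with ``exclusion`` are exclusion polygons.
    """
    path = Path(path)
    if format is None:
        format = "imagej_roi" if path.suffix == ".roi" or path.is_dir() else "geojson"
    if format == "geojson":
        return _read_geojson(path)
    if format == "imagej_roi":
        return _read_imagej(path)
    raise ValueError(f"unknown contour format {format!r}")


def _read_geojson(path: Path) -> ContourSet:
    with open(path) as fh:
        doc = json.load(fh)
    outlines: list[np.ndarray] = []
    exclusions: list[np.ndarray] = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        kind = feat.get("properties", {}).get("kind", "pancreas")
        (outlines if kind == "pancreas" else exclusions).append(ring)
    return ContourSet(pancreas_outline=outlines, exclusions=exclusions)


def write_contours(contours: ContourSet, path: str | Path) -> None:
    """Write a ContourSet as a GeoJSON FeatureCollection."""
    def feature(coords: np.ndarray, kind: str) -> dict:
        ring = np.vstack([coords, coords[:1]]).tolist()
        return {
            "type": "Feature",
            "properties": {"kind": kind},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        }

    doc = {
        "type": "FeatureCollection",
        "features": [feature(p, "pancreas") for p in contours.pancreas_outline]
        + [feature(p, "exclusion") for p in contours.exclusions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# Minimal ImageJ .roi polygon codec (header layout of the ImageJ ROI format;
# polygon subtype only).
_ROI_POLYGON = 0


def write_imagej_roi(coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords)
    xs = coords[:, 0].round().astype(int)
    ys = coords[:, 1].round().astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(coords)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)          # version
    struct.pack_into(">b", header, 6, _ROI_POLYGON)  # roi type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = b"".join(struct.pack(">h", x - left) for x in xs)
    body += b"".join(struct.pack(">h", y - top) for y in ys)
    Path(path).write_bytes(bytes(header) + body)


def read_imagej_roi(path: str | Path) -> np.ndarray:
    raw = Path(path).read_bytes()
    if raw[0:4] != b"Iout":
        raise ValueError(f"{path}: not an ImageJ .roi file")
    roi_type = struct.unpack_from(">b", raw, 6)[0]
    if roi_type != _ROI_POLYGON:
        raise ValueError(f"{path}: unsupported roi type {roi_type} (polygon only)")
    top, left = struct.unpack_from(">hh", raw, 8)
    n = struct.unpack_from(">H", raw, 16)[0]
    xs = np.frombuffer(raw, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(raw, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def _read_imagej(path: Path) -> ContourSet:
    if path.is_dir():
        outlines, exclusions = [], []
        for f in sorted(path.glob("*.roi")):
            coords = read_imagej_roi(f)
            (exclusions if f.stem.startswith("exclusion") else outlines).append(coords)
        return ContourSet(pancreas_outline=outlines, exclusions=exclusions)
    return ContourSet(pancreas_outline=[read_imagej_roi(path)])
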