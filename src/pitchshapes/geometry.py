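"""Convex hulls and their rasterization into binary shape images.

The team shape at an instant is the convex hull of the outfield players'
positions (QuickHull, via Qhull). The hull is rasterized into a binary
mask — pixel centers inside or on the polygon are foreground — padded with
background on every side so that later morphological dilations are never
clipped by the image border.

Coordinates are continuous metres; raster indices are 0-based (row, col)
with row 0 at minimum y.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull as _QHull
from scipy.spatial import QhullError
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import DataError, DegenerateShapeError

#: Default raster resolution, metres per pixel (a 105x68 m pitch maps to a
#: ~525x340 mask).
DEFAULT_PIXEL_SIZE = 0.2
#: Default background margin, in pixels, on each side of the raster. Sized
#: so that contour dilations up to this radius stay inside the image; at
#: the default resolution this is 32 m, beyond the inradius of any team
#: hull — dilations must reach past the shape's own scale before the
#: multiscale curve can encode physical size.
DEFAULT_PADDING_PX = 160

_AREA_EPS = 1e-9


@dataclass(frozen=True)
class ConvexPolygon:
    """A strictly convex simple polygon in metres.

    ``vertices`` are counter-clockwise with no repeated endpoint, starting
    from the lexicographically smallest vertex so outputs are comparable
    across runs.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise DegenerateShapeError("a polygon needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise DataError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)
        if self.area <= _AREA_EPS:
            raise DegenerateShapeError("polygon has (near-)zero area")

    @property
    def area(self) -> float:
        """Polygon area in m² (shoelace formula)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        """Polygon perimeter in m."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> np.ndarray:
        return _ShapelyPolygon(self.vertices).centroid.coords[0]

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Inside-or-on test via cross products against each edge."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        edge = b - a  # (k, 2)
        rel = pts[:, None, :] - a[None, :, :]  # (n, k, 2)
        cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
        return np.all(cross >= -atol, axis=1)

    def scaled(self, factor: float, about: tuple[float, float] | None = None) -> "ConvexPolygon":
        """Uniformly scale about a point (default: the centroid)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        c = np.asarray(self.centroid if about is None else about, dtype=float)
        return ConvexPolygon(_normalize_ring(c + factor * (self.vertices - c)))

    def translated(self, dx: float, dy: float) -> "ConvexPolygon":
        return ConvexPolygon(self.vertices + np.array([dx, dy]))


def _normalize_ring(vertices: np.ndarray) -> np.ndarray:
    """CCW order starting at the lexicographically smallest vertex."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        v = v[::-1]
    start = np.lexsort((v[:, 1], v[:, 0]))[0]
    return np.roll(v, -start, axis=0)


def convex_hull(points: np.ndarray) -> ConvexPolygon:
    """Convex hull of a planar point set (QuickHull).

    The hull vertices are a subset of the input points. Collinear or
    degenerate input raises :class:`DegenerateShapeError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise DegenerateShapeError("need at least 3 points for a hull")
    if not np.all(np.isfinite(pts)):
        raise DataError("points must be finite")
    try:
        hull = _QHull(pts)
    except QhullError as exc:
        raise DegenerateShapeError(f"degenerate hull (collinear input?): {exc}") from None
    # Qhull returns 2D hull vertices in counter-clockwise order.
    return ConvexPolygon(_normalize_ring(pts[hull.vertices]))


@dataclass(frozen=True)
class BinaryShapeImage:
    """A rasterized filled shape with physical metadata.

    ``mask`` is a boolean (row, col) grid; pixel (i, j)'s center sits at
    ``origin + ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.
    """

    mask: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    padding_px: int = DEFAULT_PADDING_PX

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2 or not m.any():
            raise DegenerateShapeError("mask must be 2D with nonempty foreground")

    @property
    def foreground_area(self) -> float:
        """Foreground pixel count times pixel area, in m²."""
        return float(self.mask.sum()) * self.pixel_size**2


def rasterize_polygon(
    vertices: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    padding_px: int = DEFAULT_PADDING_PX,
) -> BinaryShapeImage:
    """Rasterize any simple polygon (convex or not) by the pixel-center rule.

    A pixel is foreground iff its center lies inside or on the polygon
    boundary (the deterministic tie rule for centers exactly on an edge).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    v = np.asarray(vertices, dtype=float)
    poly = _ShapelyPolygon(v)
    xmin, ymin, xmax, ymax = poly.bounds
    # snap the grid to the world pixel lattice so that rasters of nearby
    # shapes are comparable: translating a polygon by a whole number of
    # pixels shifts its mask without resampling it
    x0 = np.floor(xmin / pixel_size) * pixel_size
    y0 = np.floor(ymin / pixel_size) * pixel_size
    ncol = int(np.ceil((xmax - x0) / pixel_size)) + 2 * padding_px
    nrow = int(np.ceil((ymax - y0) / pixel_size)) + 2 * padding_px
    origin = (x0 - padding_px * pixel_size, y0 - padding_px * pixel_size)
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cx = origin[0] + (jj + 0.5) * pixel_size
    cy = origin[1] + (ii + 0.5) * pixel_size
    # intersects == inside-or-on-boundary for points
    mask = shapely.intersects_xy(poly, cx.ravel(), cy.ravel()).reshape(nrow, ncol)
    if not mask.any():
        raise DegenerateShapeError("polygon is smaller than one pixel at this resolution")
    return BinaryShapeImage(mask=mask, pixel_size=pixel_size, origin=origin, padding_px=padding_px)


def rasterize(
    polygon: ConvexPolygon,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    padding_px: int = DEFAULT_PADDING_PX,
) -> BinaryShapeImage:
    """Rasterize a convex hull into a padded binary shape image."""
    return rasterize_polygon(polygon.vertices, pixel_size, padding_px)


_EIGHT = np.ones((3, 3), dtype=bool)


def contour_pixels(image: BinaryShapeImage | np.ndarray) -> np.ndarray:
    """Boundary pixels of the foreground: foreground pixels with at least
    one background 8-neighbour (off-image counts as background).

    Returns an (n, 2) integer array of (row, col) coordinates.
    """
    mask = image.mask if isinstance(image, BinaryShapeImage) else np.asarray(image, dtype=bool)
    if not mask.any():
        raise DegenerateShapeError("empty mask has no contour")
    interior = binary_erosion(mask, structure=_EIGHT, border_value=0)
    return np.argwhere(mask & ~interior)


def save_shape_image(image: BinaryShapeImage, path: str | Path) -> None:
    """Write a binary PNG plus a JSON sidecar with the physical metadata."""
    path = Path(path)
    iio.imwrite(path, (image.mask.astype(np.uint8) * 255))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": image.pixel_size,
                "origin": list(image.origin),
                "padding_px": image.padding_px,
            }
        )
    )


def load_shape_image(path: str | Path) -> BinaryShapeImage:
    """Read a binary PNG written by :func:`save_shape_image`."""
    path = Path(path)
    mask = np.asarray(iio.imread(path)) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    meta = json.loads(path.with_suffix(".json").read_text())
    return BinaryShapeImage(
        mask=mask,
        pixel_size=float(meta["pixel_size"]),
        origin=tuple(meta["origin"]),
        padding_px=int(meta["padding_px"]),
    )
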