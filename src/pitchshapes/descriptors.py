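"""Scalar shape descriptors and the per-image descriptor table.

Three scalars are computed analytically from the hull polygon (shoelace
area, edge-length perimeter), so they carry no raster-resolution
dependence:

- ``AP = A / P`` (metres) — scales linearly with the shape;
- ``Circularity = P^2 / A`` — dimensionless, minimum 4*pi for a disk;
- ``Rectangularity = A(shape) / A(MER)`` — area fraction of the minimum
  enclosing rectangle, in (0, 1], equal to 1 exactly for rectangles.

The MER is the minimum-area rectangle over *all* orientations (rotating
calipers); team shapes have arbitrary orientation on the pitch, so an
axis-aligned box would conflate orientation with shape. Axis-aligned mode
is available via a flag.

``AllD`` concatenates the five scalars ``[AP, FA, Circularity, MF,
Rectangularity]`` — the curve samples are not included — as raw,
unnormalized values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import DataError, DegenerateShapeError
from .geometry import BinaryShapeImage, ConvexPolygon
from .mfd import DEFAULT_DEGREE, DEFAULT_N_SAMPLES, MFCDescriptor, mfc

logger = logging.getLogger(__name__)

#: Canonical descriptor names, in the order used throughout.
DESCRIPTOR_NAMES = ("AP", "FA", "Circularity", "MF", "Rectangularity", "MFC", "AllD")
SCALAR_NAMES = ("AP", "FA", "Circularity", "MF", "Rectangularity")
#: Order of components inside the concatenated AllD vector.
ALLD_ORDER = ("AP", "FA", "Circularity", "MF", "Rectangularity")

_MFC_COLUMNS = tuple(f"MFC_{i}" for i in range(1, DEFAULT_N_SAMPLES + 1))


@dataclass(frozen=True)
class FeatureVector:
    """A named descriptor value vector for one image."""

    descriptor_name: str
    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if self.descriptor_name not in DESCRIPTOR_NAMES:
            raise DataError(f"unknown descriptor {self.descriptor_name!r}")
        if self.descriptor_name == "AllD" and len(v) != len(ALLD_ORDER):
            raise DataError("AllD must have exactly 5 components")
        if self.descriptor_name in SCALAR_NAMES and len(v) != 1:
            raise DataError(f"{self.descriptor_name} is a scalar descriptor")


def rectangularity(polygon: ConvexPolygon, axis_aligned: bool = False) -> float:
    """Area fraction of the minimum enclosing rectangle, in (0, 1]."""
    shp = _ShapelyPolygon(polygon.vertices)
    if axis_aligned:
        xmin, ymin, xmax, ymax = shp.bounds
        mer_area = (xmax - xmin) * (ymax - ymin)
    else:
        mer_area = shapely.minimum_rotated_rectangle(shp).area
    if mer_area <= 0:
        raise DegenerateShapeError("degenerate polygon: zero-area MER")
    return polygon.area / mer_area


def circularity(polygon: ConvexPolygon) -> float:
    """P²/A — dimensionless and scale-invariant; 4π for a disk, 16 for a
    square, larger for elongated shapes."""
    if polygon.area <= 0:
        raise DegenerateShapeError("degenerate polygon: zero area")
    return polygon.perimeter**2 / polygon.area


def ap_ratio(polygon: ConvexPolygon) -> float:
    """A/P in metres; scales linearly with the shape."""
    if polygon.perimeter <= 0:
        raise DegenerateShapeError("degenerate polygon: zero perimeter")
    return polygon.area / polygon.perimeter


def all_descriptors(ap: float, fa: float, circ: float, mf: float, rect: float) -> FeatureVector:
    """Concatenate the five scalars into the AllD vector
    [AP, FA, Circularity, MF, Rectangularity]."""
    values = np.array([ap, fa, circ, mf, rect], dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("AllD components must all be finite")
    return FeatureVector(descriptor_name="AllD", values=values)


def describe_shape(
    polygon: ConvexPolygon,
    image: BinaryShapeImage,
    degree: int = DEFAULT_DEGREE,
    n_samples: int = DEFAULT_N_SAMPLES,
    axis_aligned_mer: bool = False,
) -> tuple[dict[str, float], MFCDescriptor]:
    """All descriptors of one shape: the scalar dict and the MFC curve."""
    curve = mfc(image, degree=degree, n_samples=n_samples)
    scalars = {
        "AP": ap_ratio(polygon),
        "FA": curve.FA,
        "Circularity": circularity(polygon),
        "MF": curve.MF,
        "Rectangularity": rectangularity(polygon, axis_aligned=axis_aligned_mer),
    }
    return scalars, curve


def descriptor_table(
    items: Iterable[tuple[str, ConvexPolygon, BinaryShapeImage]],
    degree: int = DEFAULT_DEGREE,
    n_samples: int = DEFAULT_N_SAMPLES,
    axis_aligned_mer: bool = False,
) -> pd.DataFrame:
    """Descriptor table for a collection of shapes.

    One row per image: ``image_id``, the five scalars, and the
    ``n_samples`` MFC columns. Per-image failures (degenerate shapes) are
    logged and the row skipped; an entirely empty result raises.
    """
    mfc_cols = [f"MFC_{i}" for i in range(1, n_samples + 1)]
    rows = []
    for image_id, polygon, image in items:
        try:
            scalars, curve = describe_shape(
                polygon,
                image,
                degree=degree,
                n_samples=n_samples,
                axis_aligned_mer=axis_aligned_mer,
            )
        except (DegenerateShapeError, DataError) as exc:
            logger.warning("skipping image %s: %s", image_id, exc)
            continue
        row = {"image_id": str(image_id), **scalars}
        row.update(dict(zip(mfc_cols, curve.F)))
        rows.append(row)
    if not rows:
        raise DataError("no valid shapes in the collection")
    return pd.DataFrame(rows, columns=["image_id", *SCALAR_NAMES, *mfc_cols])


def feature_vector(table: pd.DataFrame, image_id: str, descriptor_name: str) -> FeatureVector:
    """Extract one image's feature vector for one descriptor from a table."""
    match = table.loc[table["image_id"] == str(image_id)]
    if match.empty:
        raise DataError(f"image {image_id!r} not in table")
    row = match.iloc[0]
    if descriptor_name in SCALAR_NAMES:
        values = np.array([row[descriptor_name]], dtype=float)
    elif descriptor_name == "MFC":
        cols = [c for c in table.columns if c.startswith("MFC_")]
        values = row[cols].to_numpy(dtype=float)
    elif descriptor_name == "AllD":
        values = row[list(ALLD_ORDER)].to_numpy(dtype=float)
    else:
        raise DataError(f"unknown descriptor {descriptor_name!r}")
    return FeatureVector(descriptor_name=descriptor_name, values=values, image_id=str(image_id))


def descriptor_matrix(table: pd.DataFrame, descriptor_name: str) -> tuple[np.ndarray, np.ndarray]:
    """(ids, X) for one descriptor across the whole table."""
    ids = table["image_id"].to_numpy(dtype=object)
    if descriptor_name in SCALAR_NAMES:
        X = table[[descriptor_name]].to_numpy(dtype=float)
    elif descriptor_name == "MFC":
        cols = [c for c in table.columns if c.startswith("MFC_")]
        X = table[cols].to_numpy(dtype=float)
    elif descriptor_name == "AllD":
        X = table[list(ALLD_ORDER)].to_numpy(dtype=float)
    else:
        raise DataError(f"unknown descriptor {descriptor_name!r}")
    return ids, X
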