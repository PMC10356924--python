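"""Polygon annotations, binary/label rasters and run-length-encoded masks.

Conventions used throughout the package:

* Image coordinates are ``(x = column, y = row)`` with ``y`` increasing
  downward, 0-based.  Pixel ``(row r, col c)`` covers the unit square
  ``[c, c+1] x [r, r+1]``; its center is ``(c + 0.5, r + 0.5)``.
* Rasterization sets a pixel iff its center lies inside the polygon
  (even-odd rule, interior rings subtracted); a center exactly on the
  boundary counts as inside.
* Run-length encoding numbers pixels 1-based in column-major order
  (top-to-bottom within a column, then the next column to the right),
  the submission dialect of segmentation competitions.  The runs of a
  record are maximal, sorted and non-overlapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from ftuseg.errors import (
    DegeneratePolygonError,
    MaskFormatError,
    UnsupportedGeometryError,
)

CATEGORIES = ("glomerulus", "crypt", "cortex", "medulla", "background", "other")
#: Categories counted as functional tissue units.
FTU_CATEGORIES = ("glomerulus", "crypt")

Ring = tuple[tuple[float, float], ...]


def _as_ring(coords: Iterable[Sequence[float]]) -> Ring:
    ring = tuple((float(x), float(y)) for x, y in coords)
    # GeoJSON rings repeat the first vertex at the end; store open rings.
    if len(ring) > 1 and ring[0] == ring[-1]:
        ring = ring[:-1]
    return ring


@dataclass(frozen=True)
class Annotation:
    """One labeled polygon: a single FTU or an anatomical region.

    ``ring`` is the ordered exterior boundary in pixel coordinates,
    stored open (first vertex not repeated).  ``holes`` are optional
    interior rings subtracted at rasterization.
    """

    id: str | int
    category: str
    ring: Ring
    holes: tuple[Ring, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ring", _as_ring(self.ring))
        object.__setattr__(self, "holes", tuple(_as_ring(h) for h in self.holes))
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if len(set(self.ring)) < 3:
            raise DegeneratePolygonError(
                f"annotation {self.id!r}: ring needs >= 3 distinct vertices, "
                f"got {len(set(self.ring))}"
            )

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon (exterior ring with interior holes)."""
        return Polygon(self.ring, [list(h) for h in self.holes])


@dataclass
class AnnotationSet:
    """All polygon annotations of one whole-slide image."""

    wsi_id: str
    image_shape: tuple[int, int]  # (rows, cols)
    pixel_size_um: float
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0 or rows != int(rows) or cols != int(cols):
            raise ValueError(f"image_shape must be positive integers, got {self.image_shape}")
        self.image_shape = (int(rows), int(cols))
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for ann in self.annotations:
            for x, y in ann.ring:
                if not (0 <= x <= cols and 0 <= y <= rows):
                    raise ValueError(
                        f"annotation {ann.id!r} vertex ({x}, {y}) outside "
                        f"image bounds {cols} x {rows}"
                    )

    def by_category(self, *categories: str) -> list[Annotation]:
        return [a for a in self.annotations if a.category in categories]


@dataclass
class BinaryMask:
    """Boolean raster with a physical pixel size."""

    grid: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.grid.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class LabeledMask:
    """Integer raster: 0 = background, instances labeled 1..K contiguously."""

    grid: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"label mask must be 2D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"label mask must be integer, got {self.grid.dtype}")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("label mask must be non-negative")
        labels = np.unique(self.grid)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("instance labels must be the contiguous set 1..K")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_labels(self) -> int:
        return int(self.grid.max()) if self.grid.size else 0

    def binary(self) -> BinaryMask:
        """Foreground union as a binary mask."""
        return BinaryMask(self.grid > 0, self.pixel_size_um)


@dataclass(frozen=True)
class RLERecord:
    """Run-length encoding of a binary mask (1-based, column-major)."""

    wsi_id: str
    shape: tuple[int, int]  # (rows, cols)
    runs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "runs", tuple((int(s), int(l)) for s, l in self.runs)
        )
        rows, cols = self.shape
        n = rows * cols
        prev_end = 0
        for start, length in self.runs:
            if start < 1 or length < 1:
                raise MaskFormatError(f"run ({start}, {length}) must be positive")
            if start <= prev_end:
                raise MaskFormatError(
                    f"run starting at {start} overlaps or is out of order "
                    f"(previous run ended at {prev_end})"
                )
            if start + length - 1 > n:
                raise MaskFormatError(
                    f"run ({start}, {length}) exceeds {rows} x {cols} = {n} pixels"
                )
            prev_end = start + length - 1


# ---------------------------------------------------------------------------
# annotation files (GeoJSON-style FeatureCollection)
# ---------------------------------------------------------------------------

def _category_of(props: dict) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict):
        name = str(cls.get("name", "other")).lower()
    else:
        name = str(props.get("category", "other")).lower()
    return name if name in CATEGORIES else "other"


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON-style FeatureCollection of polygon annotations.

    Each feature must carry a Polygon geometry; the category is taken
    from the ``classification.name`` property (the convention of
    pathology annotation tools) or a plain ``category`` property.
    Image shape, pixel size and WSI id are read from the top-level
    ``properties``; missing values fall back to the filename stem,
    0.5 µm/px, and the ceiling of the coordinate extent.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MaskFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict) or data.get("type") != "FeatureCollection":
        raise MaskFormatError(f"{path}: expected a FeatureCollection")

    annotations: list[Annotation] = []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype != "Polygon":
            fid = feat.get("id", i)
            raise UnsupportedGeometryError(
                f"{path}: feature {fid!r} has geometry {gtype!r}; only Polygon "
                "is supported"
            )
        coords = geom["coordinates"]
        props = feat.get("properties", {}) or {}
        annotations.append(
            Annotation(
                id=feat.get("id", props.get("id", i)),
                category=_category_of(props),
                ring=_as_ring(coords[0]),
                holes=tuple(_as_ring(h) for h in coords[1:]),
            )
        )

    props = data.get("properties", {}) or {}
    wsi_id = props.get("wsi_id", path.stem)
    pixel_size = float(props.get("pixel_size_um", 0.5))
    if "image_shape" in props:
        rows, cols = props["image_shape"]
    else:
        xs = [x for a in annotations for x, _ in a.ring]
        ys = [y for a in annotations for _, y in a.ring]
        rows = int(np.ceil(max(ys))) if ys else 1
        cols = int(np.ceil(max(xs))) if xs else 1
    return AnnotationSet(
        wsi_id=wsi_id,
        image_shape=(int(rows), int(cols)),
        pixel_size_um=pixel_size,
        annotations=annotations,
    )


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a GeoJSON FeatureCollection.

    The file is readable by :func:`read_annotations` and round-trips
    vertices bit-exactly (coordinates serialized via ``repr``).
    """

    def close(ring: Ring) -> list[list[float]]:
        pts = [list(p) for p in ring]
        pts.append(list(ring[0]))
        return pts

    features = []
    for ann in aset.annotations:
        features.append(
            {
                "type": "Feature",
                "id": ann.id,
                "properties": {"classification": {"name": ann.category}},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [close(ann.ring)] + [close(h) for h in ann.holes],
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "wsi_id": aset.wsi_id,
            "image_shape": list(aset.image_shape),
            "pixel_size_um": aset.pixel_size_um,
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# run-length encoding
# ---------------------------------------------------------------------------

def rle_encode(mask: BinaryMask, wsi_id: str = "") -> RLERecord:
    """Encode a binary mask as maximal column-major (start, length) runs."""
    flat = mask.grid.ravel(order="F").astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flat, [0]))))
    starts = edges[0::2] + 1  # 1-based
    lengths = edges[1::2] - edges[0::2]
    runs = tuple(zip(starts.tolist(), lengths.tolist()))
    return RLERecord(wsi_id=wsi_id, shape=mask.shape, runs=runs)


def rle_decode(rec: RLERecord, pixel_size_um: float = 0.5) -> BinaryMask:
    """Decode an :class:`RLERecord` back to a binary mask (inverse of encode)."""
    rows, cols = rec.shape
    flat = np.zeros(rows * cols, dtype=bool)
    for start, length in rec.runs:
        flat[start - 1 : start - 1 + length] = True
    return BinaryMask(flat.reshape((rows, cols), order="F"), pixel_size_um)


def rle_to_string(rec: RLERecord) -> str:
    return " ".join(f"{s} {l}" for s, l in rec.runs)


def rle_from_string(text: str, wsi_id: str, shape: tuple[int, int]) -> RLERecord:
    tokens = text.split()
    if len(tokens) % 2:
        raise MaskFormatError(f"RLE string for {wsi_id!r} has an odd token count")
    ints = [int(t) for t in tokens]
    runs = tuple(zip(ints[0::2], ints[1::2]))
    return RLERecord(wsi_id=wsi_id, shape=shape, runs=runs)


def write_rle_csv(records: Sequence[RLERecord], path: str | Path) -> None:
    """Write prediction masks as a CSV with columns wsi_id,height,width,rle."""
    df = pd.DataFrame(
        {
            "wsi_id": [r.wsi_id for r in records],
            "height": [r.shape[0] for r in records],
            "width": [r.shape[1] for r in records],
            "rle": [rle_to_string(r) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_rle_csv(path: str | Path) -> list[RLERecord]:
    df = pd.read_csv(path, dtype={"wsi_id": str}, keep_default_na=False)
    for col in ("wsi_id", "height", "width", "rle"):
        if col not in df.columns:
            raise MaskFormatError(f"{path}: missing column {col!r}")
    return [
        rle_from_string(str(row.rle), row.wsi_id, (int(row.height), int(row.width)))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# polygon <-> raster
# ---------------------------------------------------------------------------

def rasterize(
    ann: Annotation, shape: tuple[int, int], pixel_size_um: float = 0.5
) -> BinaryMask:
    """Rasterize one polygon annotation onto a pixel grid.

    A pixel is set iff its center lies inside the polygon (holes
    subtracted); a center exactly on the boundary counts as inside.
    """
    poly = ann.polygon
    if poly.area == 0:
        raise DegeneratePolygonError(f"annotation {ann.id!r} has zero area")
    grid = np.zeros(shape, dtype=bool)
    _paint(grid, poly)
    return BinaryMask(grid, pixel_size_um)


def _paint(grid: np.ndarray, poly: Polygon, value: object = True) -> None:
    """Set grid pixels whose centers fall inside ``poly`` (in place)."""
    rows, cols = grid.shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx - 0.5)))
    c1 = min(cols - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny - 0.5)))
    r1 = min(rows - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        return
    cc, rr = np.meshgrid(
        np.arange(c0, c1 + 1) + 0.5, np.arange(r0, r1 + 1) + 0.5
    )
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel()).reshape(cc.shape)
    grid[r0 : r1 + 1, c0 : c1 + 1][inside] = value


def vectorize(lm: LabeledMask, category: str = "other") -> list[Annotation]:
    """Convert each instance of a label mask to one polygon annotation.

    The polygon is the exact boundary of the union of the label's pixel
    squares, so rasterizing it back reproduces the pixel set exactly for
    4-connected instances (holes are preserved as interior rings).  For
    instances whose union splits into several parts (diagonal-only
    connectivity), the largest part is kept.
    """
    out: list[Annotation] = []
    grid = lm.grid
    for k in range(1, lm.n_labels + 1):
        rr, cc = np.nonzero(grid == k)
        rects = []
        # merge each row's horizontal runs into rectangles before union
        for r in np.unique(rr):
            cs = np.sort(cc[rr == r])
            breaks = np.flatnonzero(np.diff(cs) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [cs.size - 1]))
            for a, b in zip(starts, ends):
                rects.append(box(cs[a], r, cs[b] + 1, r + 1))
        geom = unary_union(rects)
        if isinstance(geom, MultiPolygon):
            geom = max(geom.geoms, key=lambda g: g.area)
        ring = _as_ring(geom.exterior.coords)
        holes = tuple(_as_ring(interior.coords) for interior in geom.interiors)
        out.append(Annotation(id=k, category=category, ring=ring, holes=holes))
    return out


# ---------------------------------------------------------------------------
# label TIFF I/O (uint16: holds the thousands of instances a WSI can carry)
# ---------------------------------------------------------------------------

def write_label_tiff(lm: LabeledMask, path: str | Path) -> None:
    if lm.n_labels > np.iinfo(np.uint16).max:
        raise ValueError(f"{lm.n_labels} labels exceed uint16 range")
    tifffile.imwrite(str(path), lm.grid.astype(np.uint16))


def read_label_tiff(path: str | Path, pixel_size_um: float = 0.5) -> LabeledMask:
    grid = tifffile.imread(str(path))
    return LabeledMask(grid.astype(np.int32), pixel_size_um)
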