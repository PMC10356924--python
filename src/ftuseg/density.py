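"""FTU area statistics and density (instances per mm² of cortex).

Density is computed per WSI from its polygon annotations: the number of
FTU polygons divided by the total cortex area.  Cortex area is the SUM
of the individual cortex-polygon areas (overlapping cortex polygons
would double-count; a union-area option is available but off by default
because the summed-area convention is the one used to produce published
density tables).  Areas are measured by the shoelace formula in px² and
converted to physical units via the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd
from shapely.ops import unary_union

from ftuseg.errors import DegeneratePolygonError, UndefinedDensityError
from ftuseg.mask_io import FTU_CATEGORIES, Annotation, AnnotationSet


@dataclass(frozen=True)
class Donor:
    """Donor metadata attached to a WSI for cohort summaries."""

    sex: str
    age: float
    bmi: float
    y_position: float  # vertical ordinate of the tissue block (sort key)


@dataclass
class DensityRecord:
    """Per-WSI FTU count, area statistics and density."""

    wsi_id: str
    n_ftu: int
    mean_ftu_area_um2: float
    cortex_area_mm2: float
    density_per_mm2: float
    donor: Donor | None = None


def polygon_area_px(ann: Annotation) -> float:
    """Shoelace area of an annotation in px², orientation-independent.

    Interior rings (holes) are subtracted.  A zero-area ring is an error.
    """
    area = ann.polygon.area
    if area == 0:
        raise DegeneratePolygonError(f"annotation {ann.id!r} has zero area")
    return float(area)


def px_area_to_um2(area_px: float, pixel_size_um: float) -> float:
    """Convert an area in px² to µm² (area × pixel edge length squared)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    return area_px * pixel_size_um**2


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ftu_density(
    aset: AnnotationSet,
    ftu_categories: Sequence[str] = FTU_CATEGORIES,
    donor: Donor | None = None,
    cortex_union: bool = False,
) -> DensityRecord:
    """Compute the FTU density of one WSI from its annotations.

    n_ftu counts the FTU-category polygons (no size filtering); cortex
    area sums the individual cortex polygons (or takes their union area
    if ``cortex_union``); density = n_ftu / cortex_area_mm².
    """
    ftus = aset.by_category(*ftu_categories)
    cortex = aset.by_category("cortex")
    if not cortex:
        raise UndefinedDensityError(
            f"{aset.wsi_id}: no cortex polygons, density undefined"
        )
    if cortex_union:
        cortex_px = unary_union([a.polygon for a in cortex]).area
    else:
        cortex_px = sum(polygon_area_px(a) for a in cortex)
    cortex_mm2 = px_area_to_um2(cortex_px, aset.pixel_size_um) / 1e6
    if cortex_mm2 <= 0:
        raise UndefinedDensityError(f"{aset.wsi_id}: cortex area is zero")
    if ftus:
        mean_area = px_area_to_um2(
            sum(polygon_area_px(a) for a in ftus) / len(ftus), aset.pixel_size_um
        )
    else:
        mean_area = 0.0
    return DensityRecord(
        wsi_id=aset.wsi_id,
        n_ftu=len(ftus),
        mean_ftu_area_um2=mean_area,
        cortex_area_mm2=cortex_mm2,
        density_per_mm2=len(ftus) / cortex_mm2,
        donor=donor,
    )


def cohort_table(records: Sequence[DensityRecord]) -> pd.DataFrame:
    """Tabulate density records sorted top-down by vertical block position.

    The sort is stable and descending in ``y_position`` (records without
    donor metadata sort last, in input order).
    """
    rows = []
    for rec in records:
        d = rec.donor
        rows.append(
            {
                "wsi_id": rec.wsi_id,
                "n_ftu": rec.n_ftu,
                "mean_ftu_area_um2": rec.mean_ftu_area_um2,
                "cortex_area_mm2": rec.cortex_area_mm2,
                "density_per_mm2": rec.density_per_mm2,
                "sex": d.sex if d else None,
                "age": d.age if d else None,
                "bmi": d.bmi if d else None,
                "y_position": d.y_position if d else float("-inf"),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("y_position", ascending=False, kind="stable").reset_index(
            drop=True
        )
    return df
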