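"""Spatial compartments around the tumor invasion front.

A slide is split into three compartments relative to the tumor boundary:
``TU_CORE`` (tumor tissue deeper than the margin width), ``MARG_500_IN``
(the tumor-side band of the invasive margin) and ``MARG_500_OUT`` (the
stroma-side band).  Coordinates are micrometers; densities are reported
in cells per mm**2 (1 mm**2 = 1e6 um**2).

Compartments are built by Euclidean buffering (erosion/dilation with
round joins).  A cell exactly on a shared boundary is assigned to the
inner-most containing compartment (core > inner margin > outer margin),
which makes assignment deterministic and order-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

log = logging.getLogger(__name__)

UM2_PER_MM2 = 1.0e6

TU_CORE = "TU_CORE"
MARG_IN = "MARG_500_IN"
MARG_OUT = "MARG_500_OUT"
#: Assignment order = tie-break order (inner-most compartment wins).
COMPARTMENTS = (TU_CORE, MARG_IN, MARG_OUT)

CELL_COLUMNS = ("slide_id", "marker", "x_um", "y_um", "cell_class")
DENSITY_COLUMNS = ("slide_id", "marker", "compartment", "count", "area_mm2", "density")


class GeometryError(ValueError):
    """Invalid or degenerate region geometry."""


@dataclass(frozen=True)
class CellRecord:
    """One detected cell: marker identity and centroid in micrometers."""

    slide_id: str
    marker: str
    x: float
    y: float
    cell_class: str = "positive"


@dataclass
class RegionAnnotation:
    """Tumor boundary (required) and optional tissue outline for one slide."""

    tumor: BaseGeometry
    tissue: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.tumor is None or self.tumor.is_empty:
            raise GeometryError("tumor polygon is empty")
        if not self.tumor.is_valid:
            raise GeometryError("tumor polygon is not a valid simple polygon")
        if self.tissue is not None:
            if not self.tissue.is_valid:
                raise GeometryError("tissue polygon is not valid")
            if not self.tissue.intersects(self.tumor):
                raise GeometryError("tissue polygon does not intersect the tumor polygon")


@dataclass
class CompartmentSet:
    """The three named compartments with geometries and areas in mm**2."""

    geoms: dict[str, BaseGeometry]
    areas_mm2: dict[str, float]
    margin_width: float

    def __getitem__(self, name: str) -> BaseGeometry:
        return self.geoms[name]

    def area(self, name: str) -> float:
        return self.areas_mm2[name]


def _clean(geom: BaseGeometry) -> BaseGeometry:
    """Resolve buffering artifacts by unioning the valid parts."""
    if geom.is_empty:
        return geom
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        geom = unary_union(polys) if polys else shapely.Polygon()
    return geom


def build_compartments(
    annotation: RegionAnnotation,
    margin_width: float = 500.0,
    quad_segs: int = 32,
) -> CompartmentSet:
    """Erode/dilate the tumor boundary into the three margin compartments.

    ``TU_CORE`` is the tumor eroded by ``margin_width``; ``MARG_500_IN`` is
    the remainder of the tumor; ``MARG_500_OUT`` is the band of the same
    width outside the tumor.  When a tissue outline is present all three
    are clipped to it.  If the erosion annihilates the tumor (maximum
    inscribed radius below the margin width) the core is returned empty
    with area 0 and a warning is logged.
    """
    if margin_width <= 0:
        raise GeometryError(f"margin_width must be positive, got {margin_width}")
    tumor = _clean(annotation.tumor)
    if tumor.is_empty or not tumor.is_valid:
        raise GeometryError("tumor polygon is empty or invalid after cleaning")

    core = _clean(tumor.buffer(-margin_width, quad_segs=quad_segs, join_style="round"))
    inner = _clean(tumor.difference(core))
    outer = _clean(
        tumor.buffer(margin_width, quad_segs=quad_segs, join_style="round").difference(tumor)
    )
    if core.is_empty:
        log.warning(
            "erosion by %.0f um annihilated the tumor core (tumor area %.3f mm2)",
            margin_width,
            tumor.area / UM2_PER_MM2,
        )

    geoms = {TU_CORE: core, MARG_IN: inner, MARG_OUT: outer}
    if annotation.tissue is not None:
        tissue = _clean(annotation.tissue)
        geoms = {name: _clean(g.intersection(tissue)) for name, g in geoms.items()}

    areas = {name: g.area / UM2_PER_MM2 for name, g in geoms.items()}
    return CompartmentSet(geoms=geoms, areas_mm2=areas, margin_width=float(margin_width))


def as_cell_table(cells: pd.DataFrame | Iterable[CellRecord]) -> pd.DataFrame:
    """Coerce cell records to the canonical cell table schema."""
    if isinstance(cells, pd.DataFrame):
        missing = [c for c in CELL_COLUMNS if c not in cells.columns]
        if missing:
            raise ValueError(f"cell table is missing columns {missing}")
        df = cells
    else:
        df = pd.DataFrame(
            [(c.slide_id, c.marker, c.x, c.y, c.cell_class) for c in cells],
            columns=list(CELL_COLUMNS),
        )
    if len(df) and not np.isfinite(df[["x_um", "y_um"]].to_numpy(float)).all():
        raise ValueError("cell coordinates must be finite")
    return df


def assign_points(x: np.ndarray, y: np.ndarray, compartments: CompartmentSet) -> np.ndarray:
    """Compartment name per point ('' for unassigned), inner-most wins ties."""
    pts = shapely.points(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))
    labels = np.full(len(pts), "", dtype=object)
    unassigned = np.ones(len(pts), dtype=bool)
    for name in COMPARTMENTS:
        geom = compartments[name]
        if geom.is_empty or not unassigned.any():
            continue
        shapely.prepare(geom)
        hit = shapely.covers(geom, pts[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        labels[idx] = name
        unassigned[idx] = False
    return labels


def assign_cells(
    cells: pd.DataFrame | Iterable[CellRecord],
    compartments: CompartmentSet,
) -> tuple[dict[str, int], int]:
    """Count positive cells per compartment.

    Returns ``(counts, unassigned)`` where counts hold one entry per
    compartment and ``unassigned`` counts positive cells outside all
    three.  Negative (``cell_class != 'positive'``) records are accepted
    and ignored with a logged tally; counts + unassigned always sum to
    the number of positive records.
    """
    df = as_cell_table(cells)
    n_negative = int((df["cell_class"] != "positive").sum())
    if n_negative:
        log.info("ignoring %d negative cell records", n_negative)
        df = df[df["cell_class"] == "positive"]
    if len(df) == 0:
        return {name: 0 for name in COMPARTMENTS}, 0
    labels = assign_points(df["x_um"].to_numpy(), df["y_um"].to_numpy(), compartments)
    counts = {name: int((labels == name).sum()) for name in COMPARTMENTS}
    return counts, int((labels == "").sum())


def compartment_densities(
    counts: Mapping[str, int], areas_mm2: Mapping[str, float]
) -> dict[str, float]:
    """Density in cells/mm**2 per compartment; NaN where the area is zero."""
    if set(counts) != set(areas_mm2):
        raise ValueError("counts and areas must share the same compartment keys")
    out: dict[str, float] = {}
    for name in counts:
        c, a = counts[name], areas_mm2[name]
        if c < 0 or a < 0:
            raise ValueError(f"negative count or area for {name}")
        out[name] = c / a if a > 0 else float("nan")
    return out


def density_table(
    cells: pd.DataFrame | Iterable[CellRecord],
    compartments_by_slide: Mapping[str, CompartmentSet],
) -> pd.DataFrame:
    """Per slide x marker x compartment density table (long format).

    Columns: slide_id, marker, compartment, count, area_mm2, density.
    Compartments with zero area carry ``count = 0`` and missing density.
    """
    df = as_cell_table(cells)
    rows = []
    for (slide, marker), sub in df.groupby(["slide_id", "marker"], sort=True):
        comps = compartments_by_slide[slide]
        counts, unassigned = assign_cells(sub, comps)
        if unassigned:
            log.info("slide %s marker %s: %d cells outside all compartments", slide, marker, unassigned)
        dens = compartment_densities(counts, comps.areas_mm2)
        for name in COMPARTMENTS:
            rows.append((slide, marker, name, counts[name], comps.areas_mm2[name], dens[name]))
    return pd.DataFrame(rows, columns=list(DENSITY_COLUMNS))


# ---------------------------------------------------------------------------
# File I/O: GeoJSON region annotations and CSV/TSV cell tables


def read_region_annotation(path: str | Path) -> RegionAnnotation:
    """Read a GeoJSON FeatureCollection with features named TUMOR / TISSUE."""
    with open(path) as fh:
        doc = json.load(fh)
    tumor = tissue = None
    features = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    for feat in features:
        name = str(feat.get("properties", {}).get("name", "")).upper()
        geom = geom_shape(feat["geometry"])
        if name == "TUMOR":
            tumor = geom if tumor is None else unary_union([tumor, geom])
        elif name == "TISSUE":
            tissue = geom if tissue is None else unary_union([tissue, geom])
    if tumor is None:
        raise GeometryError(f"{path}: no feature with property name=TUMOR")
    return RegionAnnotation(tumor=tumor, tissue=tissue)


def write_region_annotation(annotation: RegionAnnotation, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"name": "TUMOR"}, "geometry": geom_mapping(annotation.tumor)}
    ]
    if annotation.tissue is not None:
        features.append(
            {"type": "Feature", "properties": {"name": "TISSUE"}, "geometry": geom_mapping(annotation.tissue)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV cell table (delimiter auto-detected from the header)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    return as_cell_table(df)
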