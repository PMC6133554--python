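"""Shared fixtures and independent oracles.

The raster oracle rasterizes the tumor polygon with a scanline fill and
measures band membership with Euclidean distance transforms — a route
entirely independent of the polygon-buffering implementation under test.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Point
from skimage.draw import polygon2mask

from immunotopo.geometry import MARG_IN, MARG_OUT, TU_CORE, RegionAnnotation


def raster_band_areas(tumor, margin: float, resolution: float = 1.0, pad: float = 25.0) -> dict:
    """Compartment areas (mm**2) from a pixel raster at ``resolution`` um."""
    minx, miny, maxx, maxy = tumor.bounds
    minx -= margin + pad
    miny -= margin + pad
    maxx += margin + pad
    maxy += margin + pad
    nr = int((maxy - miny) / resolution)
    nc = int((maxx - minx) / resolution)
    xy = np.asarray(tumor.exterior.coords)
    verts = np.column_stack(
        [(xy[:, 1] - miny) / resolution - 0.5, (xy[:, 0] - minx) / resolution - 0.5]
    )
    inside = polygon2mask((nr, nc), verts)
    d_in = distance_transform_edt(inside) * resolution
    d_out = distance_transform_edt(~inside) * resolution
    px = resolution**2 / 1.0e6
    core = inside & (d_in > margin)
    return {
        TU_CORE: float(core.sum() * px),
        MARG_IN: float((inside & ~core).sum() * px),
        MARG_OUT: float(((~inside) & (d_out <= margin)).sum() * px),
    }


@pytest.fixture(scope="session")
def disk_annotation() -> RegionAnnotation:
    """1500 um radius disk tumor (fine polygonal approximation)."""
    return RegionAnnotation(tumor=Point(0.0, 0.0).buffer(1500.0, quad_segs=256))


@pytest.fixture(scope="session")
def disk_compartments(disk_annotation):
    from immunotopo.geometry import build_compartments

    return build_compartments(disk_annotation, margin_width=500.0)
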