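"""Distance-to-expert-range predictor.

An expert range map (e.g., an IUCN Red List polygon) encodes range-limit
knowledge — dispersal barriers, biotic constraints — that occurrence
records alone miss.  Following the distance-decay idea, the polygon is
converted into a continuous per-cell predictor: 0 inside or on the
polygon, otherwise the great-circle distance (km) to the nearest point
of the polygon boundary.  The meta-learner can then learn to discount
habitat far outside the expert range.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import EnvStack, Raster, haversine_km
from .prep import CalibrationArea

__all__ = ["densify_boundary", "distance_to_range"]


def densify_boundary(poly: BaseGeometry, max_step_deg: float = 0.05) -> np.ndarray:
    """Vertices of the polygon boundary, densified so consecutive points
    are at most ``max_step_deg`` apart (in coordinate degrees).

    Returns an (n, 2) array of lon/lat.  Densification bounds the error
    of the nearest-boundary-point distance at the package's working
    scales to well under a cell width.
    """
    boundary = shapely.segmentize(poly.boundary, max_segment_length=max_step_deg)
    return shapely.get_coordinates(boundary)


def distance_to_range(
    poly: BaseGeometry,
    env: EnvStack,
    area: CalibrationArea,
    max_step_deg: float = 0.05,
) -> Raster:
    """Per-cell distance (km) to the expert range polygon.

    Cells whose centre is inside or on the polygon get 0; other cells get
    the minimum haversine distance (R = 6371 km) to the densified polygon
    boundary.  Cells outside the calibration area are nodata.
    """
    if poly.is_empty:
        raise ValueError("empty expert range polygon")
    poly = shapely.make_valid(poly)
    grid = env.grid
    lon2d, lat2d = grid.center_mesh()
    rows, cols = np.nonzero(area.mask)
    lon = lon2d[rows, cols]
    lat = lat2d[rows, cols]

    inside = shapely.intersects(poly, shapely.points(lon, lat))
    if not inside.any():
        warnings.warn("expert range polygon contains no calibration cell centre; distance layer is all-positive")

    bpts = densify_boundary(poly, max_step_deg)
    blon, blat = bpts[:, 0], bpts[:, 1]
    dist = np.zeros(len(lon))
    out_idx = np.nonzero(~inside)[0]
    # chunked pairwise haversine: cells x boundary points
    chunk = max(1, 20_000_000 // max(len(blon), 1))
    for start in range(0, len(out_idx), chunk):
        sel = out_idx[start : start + chunk]
        d = haversine_km(lon[sel, None], lat[sel, None], blon[None, :], blat[None, :])
        dist[sel] = d.min(axis=1)

    values = np.full(grid.shape, np.nan)
    values[rows, cols] = dist
    return Raster(grid=grid, values=values, name="distance_to_expert_range_km")
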