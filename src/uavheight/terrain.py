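"""Digital terrain model estimation from bare-ground polygons.

The DTM is built from the in-season DSM itself: elevations are sampled
inside operator-digitized bare-ground polygons (alleys, field margins) and
interpolated across the field.  Each polygon contributes three ground
control points — its centroid paired with the median pixel elevation (robust
to stray vegetation pixels), plus the locations of its lowest and highest
pixel elevations, capturing the local elevation range of the zone.

Interpolation is linear over the Delaunay triangulation (TIN) of the control
points, the zero-tuning reading of "minimize overall surface curvature";
pixels outside the convex hull take the nearest control point's elevation
and are flagged in a companion quality mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError
from shapely.geometry.base import BaseGeometry

from .layout import BareGroundFeature
from .raster import ElevationRaster

__all__ = [
    "GroundControlPoint",
    "sample_ground_elevations",
    "interpolate_dtm",
    "dtm_error",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroundControlPoint:
    x: float
    y: float
    elevation_m: float
    polygon_id: str
    kind: str  # "median" | "min" | "max"


def sample_ground_elevations(
    dsm: ElevationRaster,
    bare_polygons: list[BareGroundFeature] | list[BaseGeometry],
) -> list[GroundControlPoint]:
    """Three ground control points per usable bare-ground polygon.

    Polygons covering no valid (non-nodata) pixel are skipped with a warning;
    if no polygon is usable the DTM cannot be built and an error is raised.
    """
    points: list[GroundControlPoint] = []
    skipped = 0
    for i, feature in enumerate(bare_polygons):
        if isinstance(feature, BareGroundFeature):
            poly, pid = feature.polygon, feature.polygon_id
        else:
            poly, pid = feature, f"bg{i:04d}"
        vals, xs, ys = dsm.polygon_values(poly)
        if vals.size == 0:
            logger.warning("bare-ground polygon %s has no valid pixels; skipped", pid)
            skipped += 1
            continue
        c = poly.centroid
        points.append(
            GroundControlPoint(c.x, c.y, float(np.median(vals)), pid, "median")
        )
        j_min, j_max = int(np.argmin(vals)), int(np.argmax(vals))
        points.append(
            GroundControlPoint(xs[j_min], ys[j_min], float(vals[j_min]), pid, "min")
        )
        points.append(
            GroundControlPoint(xs[j_max], ys[j_max], float(vals[j_max]), pid, "max")
        )
    if not points:
        raise ValueError(
            "no bare-ground polygon overlaps valid DSM pixels; DTM impossible"
        )
    if skipped:
        logger.warning("%d bare-ground polygon(s) skipped", skipped)
    return points


def control_points_frame(points: list[GroundControlPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "elevation_m": [p.elevation_m for p in points],
            "polygon_id": [p.polygon_id for p in points],
            "kind": [p.kind for p in points],
        }
    )


def interpolate_dtm(
    points: list[GroundControlPoint], template: ElevationRaster
) -> tuple[ElevationRaster, ElevationRaster]:
    """TIN-linear DTM on the template grid.

    Returns ``(dtm, quality_mask)`` sharing the template's grid, CRS and
    nodata convention.  Quality mask: 0 where the DTM is interpolated inside
    the convex hull of the control points, 1 where it is nearest-point
    extrapolated.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 control points for a DTM")
    xy = np.array([(p.x, p.y) for p in points])
    z = np.array([p.elevation_m for p in points])
    # collapse duplicate locations (min/max can coincide with the centroid pixel)
    xy, keep = np.unique(xy, axis=0, return_index=True)
    z = z[keep]
    if len(xy) < 3:
        raise ValueError("need at least 3 distinct control points")
    try:
        linear = LinearNDInterpolator(xy, z)
    except QhullError as err:
        raise ValueError("control points are collinear; DTM impossible") from err
    if linear.tri.nsimplex == 0:  # pragma: no cover - qhull usually raises first
        raise ValueError("control points are collinear; DTM impossible")
    xx, yy = np.meshgrid(template.x_centers(), template.y_centers())
    grid = linear(xx, yy)
    outside = np.isnan(grid)
    if outside.any():
        nearest = NearestNDInterpolator(xy, z)
        grid[outside] = nearest(xx[outside], yy[outside])
    dtm = template.like(grid)
    dtm.nodata = template.nodata
    quality = template.like(outside.astype(float))
    return dtm, quality


def dtm_error(
    dtm: ElevationRaster,
    reference: ElevationRaster | list[GroundControlPoint],
) -> dict[str, float]:
    """Error statistics of a DTM against a reference surface or held-out points.

    Returns mean bias (dtm - reference), RMSE and max absolute error in
    meters, over the valid overlap only.
    """
    if isinstance(reference, ElevationRaster):
        dtm.require_same_grid(reference)
        ok = dtm.valid_mask() & reference.valid_mask()
        if not ok.any():
            raise ValueError("no valid overlap between DTM and reference")
        err = dtm.data[ok] - reference.data[ok]
    else:
        if not reference:
            raise ValueError("no reference points")
        px = dtm.pixel_size
        err = []
        for p in reference:
            col = int((p.x - dtm.x_origin) / px)
            row = int((dtm.y_origin - p.y) / px)
            if 0 <= row < dtm.shape[0] and 0 <= col < dtm.shape[1]:
                v = dtm.data[row, col]
                if v != dtm.nodata:
                    err.append(v - p.elevation_m)
        if not err:
            raise ValueError("no valid overlap between DTM and reference points")
        err = np.asarray(err)
    return {
        "bias_m": float(np.mean(err)),
        "rmse_m": float(np.sqrt(np.mean(err**2))),
        "max_abs_m": float(np.max(np.abs(err))),
        "n": int(err.size),
    }
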