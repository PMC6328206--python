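"""Credible-ellipse correction of on-land daily location estimates.

The state-space model is not land-aware, so some daily estimates fall on
land.  Each on-land estimate is replaced by the area centroid of the ocean
portion of its 95% credible ellipse: the ellipse is centred on the
estimate, its east-west semi-axis is the 95% credible half-width in
longitude and its north-south semi-axis the half-width in latitude; the
land portion is clipped away and the centroid of what remains becomes the
corrected position.  The behavioural mode of the day is never altered.

Geometry is computed in a local equidistant planar frame about the ellipse
centre (longitude scaled by cos latitude) because degree-space areas are
anisotropic away from the equator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.affinity import scale as shapely_scale
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points, transform, unary_union

from .simulate import Coastline

logger = logging.getLogger(__name__)

#: minimum semi-axis (degrees) substituted for degenerate zero half-widths
MIN_SEMI_AXIS = 1e-4


@dataclass
class CredibleEllipse:
    """Axis-aligned 95% credible ellipse around a daily estimate.

    ``a`` is the east-west (longitude) semi-axis and ``b`` the north-south
    (latitude) semi-axis, both in degrees; no magnitude ordering between
    them is assumed.
    """

    lon: float
    lat: float
    a: float
    b: float
    n_vertices: int = 720

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.n_vertices < 8:
            raise ValueError("need >= 8 vertices to polygonise an ellipse")

    def polygon_local(self, scale_x: float) -> Polygon:
        """Polygonised ellipse in the local planar frame about its centre."""
        t = np.linspace(0.0, 2.0 * math.pi, self.n_vertices, endpoint=False)
        x = self.a * scale_x * np.cos(t)
        y = self.b * np.sin(t)
        return Polygon(np.column_stack([x, y]))


def is_on_land(lon: float, lat: float, landmask: Coastline) -> bool:
    """True iff the point is strictly inside land (boundary counts as ocean)."""
    return landmask.contains(lon, lat)


def _to_local(landmask: Coastline, lon0: float, lat0: float, sx: float):
    """Project land polygons near (lon0, lat0) into the local planar frame."""

    def fwd(x, y):
        return ((np.asarray(x) - lon0) * sx, np.asarray(y) - lat0)

    return [transform(fwd, poly) for poly in landmask.land_polygons]


def ocean_centroid(
    ellipse: CredibleEllipse,
    landmask: Coastline,
    max_inflations: int = 3,
    inflation: float = 1.5,
) -> tuple[float, float]:
    """Centroid of the ocean portion of the credible ellipse.

    If the ellipse is entirely on land, both axes are inflated by
    ``inflation`` up to ``max_inflations`` times; if ocean is still never
    reached, the nearest ocean point (land boundary) to the centre is
    returned.  If the computed centroid itself lands on land (possible for
    crescent-shaped remainders), the nearest point of the ocean remainder
    is returned instead.  The result is never strictly inside land.
    """
    sx = math.cos(math.radians(ellipse.lat))
    land_local = _to_local(landmask, ellipse.lon, ellipse.lat, sx)
    land_union = unary_union(land_local)

    water = None
    ell = ellipse.polygon_local(sx)
    for _ in range(max_inflations + 1):
        candidate = ell.difference(land_union)
        if not candidate.is_empty and candidate.area > 0:
            water = candidate
            break
        ell = shapely_scale(ell, xfact=inflation, yfact=inflation, origin=(0, 0))
    if water is None:
        # fully on land even after inflation: fall back to the nearest ocean
        # point to the centre, i.e. the nearest land boundary point
        boundary = land_union.boundary
        if boundary.is_empty:
            raise ValueError("no ocean reachable from ellipse; invalid landmask")
        near = nearest_points(Point(0.0, 0.0), boundary)[1]
        cx, cy = near.x, near.y
    else:
        cen = water.centroid
        cx, cy = cen.x, cen.y
        lon_c, lat_c = ellipse.lon + cx / sx, ellipse.lat + cy
        if is_on_land(lon_c, lat_c, landmask):
            near = nearest_points(Point(cx, cy), water)[1]
            cx, cy = near.x, near.y
    lon_c, lat_c = ellipse.lon + cx / sx, ellipse.lat + cy
    if is_on_land(lon_c, lat_c, landmask):
        raise ValueError("land correction failed to find an ocean point")
    return lon_c, lat_c


def correct_track(posterior_df: pd.DataFrame, landmask: Coastline) -> pd.DataFrame:
    """Move on-land daily estimates to their ocean-credible-ellipse centroid.

    Only on-land days change; dates and behavioural-mode means are
    untouched.  Returns a copy with added columns ``corrected`` (bool) and
    the pre-correction coordinates ``lon_raw``/``lat_raw``.  Idempotent:
    output positions are never on land.
    """
    out = posterior_df.copy()
    out["lon_raw"] = out["lon"]
    out["lat_raw"] = out["lat"]
    out["corrected"] = False
    n_corrected = 0
    for i in out.index:
        lon, lat = float(out.at[i, "lon"]), float(out.at[i, "lat"])
        if not is_on_land(lon, lat, landmask):
            continue
        ellipse = CredibleEllipse(
            lon=lon,
            lat=lat,
            a=max(float(out.at[i, "lon_hw95"]), MIN_SEMI_AXIS),
            b=max(float(out.at[i, "lat_hw95"]), MIN_SEMI_AXIS),
        )
        new_lon, new_lat = ocean_centroid(ellipse, landmask)
        out.at[i, "lon"] = new_lon
        out.at[i, "lat"] = new_lat
        out.at[i, "corrected"] = True
        n_corrected += 1
    logger.info("land correction: moved %d of %d daily estimates", n_corrected, len(out))
    return out
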