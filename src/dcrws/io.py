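"""File formats: Argos fix CSV, daily-track CSV, landmask GeoJSON.

Fix tables round-trip through CSV with ISO-8601 UTC timestamps; landmasks
round-trip through GeoJSON (WGS84, lon/lat axis order) via shapely.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .prefilter import validate_fixes
from .simulate import Coastline


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read an Argos fix CSV (columns ptt, timestamp, lc, lon, lat).

    Malformed rows raise ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"ptt": str, "lc": str})
    return validate_fixes(df)


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes.copy()
    # isoformat keeps full (nanosecond) precision for exact round-trips
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).map(
        lambda t: t.isoformat()
    )
    out.to_csv(path, index=False)


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a daily posterior-track CSV."""
    df = pd.read_csv(path)
    if "ptt" in df.columns:
        df["ptt"] = df["ptt"].astype(str)
    df["date"] = pd.to_datetime(df["date"], utc=True)
    return df


def write_track(track_df: pd.DataFrame, path: str | Path) -> None:
    out = track_df.copy()
    out["date"] = pd.to_datetime(out["date"], utc=True).map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def write_landmask(coastline: Coastline, path: str | Path) -> None:
    """Write land polygons as a GeoJSON FeatureCollection (WGS84 lon/lat)."""
    features = [
        {"type": "Feature", "properties": {"kind": "land"}, "geometry": mapping(poly)}
        for poly in coastline.land_polygons
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_landmask(path: str | Path) -> Coastline:
    """Read land polygons from GeoJSON (Polygon / MultiPolygon features)."""
    payload = json.loads(Path(path).read_text())
    polys: list[Polygon] = []
    geoms = (
        [f["geometry"] for f in payload["features"]]
        if payload.get("type") == "FeatureCollection"
        else [payload]
    )
    for geom in geoms:
        g = shape(geom)
        if isinstance(g, Polygon):
            polys.append(g)
        elif isinstance(g, MultiPolygon):
            polys.extend(g.geoms)
        else:
            raise ValueError(f"unsupported landmask geometry {g.geom_type}")
    return Coastline(polys)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
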