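"""Behavioural classification, daily travel and seasonal summaries.

Daily behavioural-mode means b in [1, 2] are classified with the standard
cutoffs: b > 1.75 is area-restricted searching (ARS), b < 1.25 is
transiting, anything else (boundaries included) is uncertain.  Consecutive
daily positions give great-circle step distances (haversine, mean Earth
radius 6,371 km) and speeds (distance / 24 h).  Calendar months split the
year into the Gulf of California's climatic seasons: December-May cool,
June-November warm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

ARS = "ARS"
TRANSITING = "transiting"
UNCERTAIN = "uncertain"
LABELS = (TRANSITING, ARS, UNCERTAIN)

COOL_MONTHS = frozenset({12, 1, 2, 3, 4, 5})


@dataclass
class BehaviorThresholds:
    """Posterior-mean-mode cutoffs for behavioural classification."""

    ars_cutoff: float = 1.75
    transit_cutoff: float = 1.25

    def __post_init__(self) -> None:
        if not 1.0 < self.transit_cutoff < self.ars_cutoff < 2.0:
            raise ValueError("need 1 < transit_cutoff < ars_cutoff < 2")


def classify_mode(b_mean: float, thresholds: BehaviorThresholds | None = None) -> str:
    """Label a posterior mode mean: ARS, transiting, or uncertain.

    Strict inequalities: values exactly at a cutoff are uncertain.
    """
    t = thresholds or BehaviorThresholds()
    if not 1.0 <= b_mean <= 2.0:
        raise ValueError(f"mode mean {b_mean} outside [1, 2]")
    if b_mean > t.ars_cutoff:
        return ARS
    if b_mean < t.transit_cutoff:
        return TRANSITING
    return UNCERTAIN


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine distance in km between (lon, lat) points, R = 6,371 km."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def assign_season(date) -> str:
    """Gulf of California climatic season: Dec-May cool, Jun-Nov warm."""
    month = pd.Timestamp(date).month
    return "cool" if month in COOL_MONTHS else "warm"


def daily_steps(
    track_df: pd.DataFrame, thresholds: BehaviorThresholds | None = None
) -> pd.DataFrame:
    """Steps between consecutive daily locations of one (corrected) track.

    One row per day pair with distance (km), speed (km/h = distance / 24),
    behaviour label and season, both taken from the step's end day.
    """
    if len(track_df) < 2:
        raise ValueError("need >= 2 daily locations")
    dates = pd.to_datetime(track_df["date"])
    gaps = dates.diff().dropna()
    if not (gaps == pd.Timedelta(days=1)).all():
        raise ValueError("daily grid must be contiguous")
    lon = track_df["lon"].to_numpy(dtype=float)
    lat = track_df["lat"].to_numpy(dtype=float)
    dist = np.array(
        [
            great_circle_km((lon[i], lat[i]), (lon[i + 1], lat[i + 1]))
            for i in range(len(lon) - 1)
        ]
    )
    b_end = track_df["b_mean"].to_numpy(dtype=float)[1:]
    labels = [classify_mode(b, thresholds) for b in b_end]
    end_dates = dates.iloc[1:]
    return pd.DataFrame(
        {
            "date": end_dates.to_numpy(),
            "start_lon": lon[:-1],
            "start_lat": lat[:-1],
            "end_lon": lon[1:],
            "end_lat": lat[1:],
            "distance_km": dist,
            "speed_kmh": dist / 24.0,
            "label": labels,
            "season": [assign_season(d) for d in end_dates],
        }
    )


SUMMARY_COLUMNS = (
    "dist_mean", "dist_sd", "dist_min", "dist_max", "dist_total",
    "speed_mean", "speed_sd", "speed_min", "speed_max",
    "speed_transiting", "speed_ars", "speed_uncertain",
)


def per_track_summary(steps: pd.DataFrame, ptt: str = "") -> pd.Series:
    """One summary row per track: distance and speed statistics.

    Per-mode mean speeds average only that mode's steps; a mode with no
    steps is reported missing (NaN).
    """
    if steps.empty:
        raise ValueError("no steps to summarise")
    d = steps["distance_km"]
    s = steps["speed_kmh"]

    def mode_speed(label: str) -> float:
        sub = steps.loc[steps["label"] == label, "speed_kmh"]
        return float(sub.mean()) if len(sub) else float("nan")

    return pd.Series(
        {
            "dist_mean": d.mean(),
            "dist_sd": d.std(ddof=1) if len(d) > 1 else 0.0,
            "dist_min": d.min(),
            "dist_max": d.max(),
            "dist_total": d.sum(),
            "speed_mean": s.mean(),
            "speed_sd": s.std(ddof=1) if len(s) > 1 else 0.0,
            "speed_min": s.min(),
            "speed_max": s.max(),
            "speed_transiting": mode_speed(TRANSITING),
            "speed_ars": mode_speed(ARS),
            "speed_uncertain": mode_speed(UNCERTAIN),
        },
        name=ptt,
    )


def aggregate_tracks(rows: pd.DataFrame) -> pd.Series:
    """Unweighted grand mean of each summary column across tracks.

    Missing per-mode entries are skipped: a per-mode column is averaged
    over the tracks that report that mode.
    """
    if rows.empty:
        raise ValueError("no track rows to aggregate")
    return rows.mean(axis=0, skipna=True)


def seasonal_mode_proportions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-season counts and fractions of daily-location behaviour labels.

    ``classified`` needs columns ``label`` and ``season``; fractions sum to
    1 within each season present.
    """
    rows = []
    for season, grp in classified.groupby("season"):
        total = len(grp)
        for label in LABELS:
            n = int((grp["label"] == label).sum())
            rows.append(
                {"season": season, "label": label, "count": n, "fraction": n / total}
            )
    return pd.DataFrame(rows)


def classify_track_locations(
    track_df: pd.DataFrame, thresholds: BehaviorThresholds | None = None
) -> pd.DataFrame:
    """Label every daily location of a track and attach its season."""
    out = track_df.copy()
    out["label"] = [classify_mode(b, thresholds) for b in out["b_mean"]]
    out["season"] = [assign_season(d) for d in pd.to_datetime(out["date"])]
    return out
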