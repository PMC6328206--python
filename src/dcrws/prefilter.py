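"""Argos location-class prefiltering.

Raw Argos fixes carry a location class (LC) in ``{3, 2, 1, 0, A, B, Z}``
ordered by decreasing positional accuracy, from better than ~200 m (LC 3)
to worse than 5 km (LC B); LC Z has unbounded error.  Before state-space
modelling three rules are applied, in order:

1. every LC Z fix is removed;
2. low-quality fixes (LC 0/A/B) received within 20 minutes of a
   high-quality fix (LC 1/2/3) of the same platform are removed;
3. duplicate fixes are collapsed to the best-LC representative.

Fixes live in a :class:`pandas.DataFrame` with columns
``ptt, timestamp, lc, lon, lat`` (see :func:`validate_fixes`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Location classes in decreasing order of accuracy.
LC_CLASSES: tuple[str, ...] = ("3", "2", "1", "0", "A", "B", "Z")

#: Quality rank: lower is better.
LC_RANK: dict[str, int] = {lc: i for i, lc in enumerate(LC_CLASSES)}

HIGH_QUALITY = frozenset({"1", "2", "3"})
LOW_QUALITY = frozenset({"0", "A", "B"})

FIX_COLUMNS = ("ptt", "timestamp", "lc", "lon", "lat")


@dataclass(frozen=True)
class ArgosFix:
    """A single raw Argos fix."""

    ptt: str
    timestamp: datetime
    lc: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if self.lc not in LC_RANK:
            raise ValueError(f"unknown location class {self.lc!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")


def fixes_to_frame(fixes: list[ArgosFix]) -> pd.DataFrame:
    """Convert a list of :class:`ArgosFix` to the canonical fix table."""
    return pd.DataFrame(
        {
            "ptt": [f.ptt for f in fixes],
            "timestamp": pd.to_datetime([f.timestamp for f in fixes], utc=True),
            "lc": pd.Series([f.lc for f in fixes], dtype=object),
            "lon": [f.lon for f in fixes],
            "lat": [f.lat for f in fixes],
        }
    )


def validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Validate a fix table, returning it with normalised dtypes.

    Raises ``ValueError`` naming the first offending row when a location
    class is unknown or a coordinate is out of range.
    """
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table missing columns {missing}")
    out = fixes.copy()
    out["lc"] = out["lc"].astype(str)
    bad_lc = ~out["lc"].isin(LC_RANK)
    if bad_lc.any():
        i = int(np.flatnonzero(bad_lc.to_numpy())[0])
        raise ValueError(
            f"row {out.index[i]}: unknown location class {out['lc'].iloc[i]!r}"
        )
    ts_col = out["timestamp"]
    if ts_col.dtype == object or pd.api.types.is_string_dtype(ts_col):
        out["timestamp"] = pd.to_datetime(ts_col, utc=True, format="mixed", errors="coerce")
    else:
        out["timestamp"] = pd.to_datetime(ts_col, utc=True, errors="coerce")
    if out["timestamp"].isna().any():
        i = int(np.flatnonzero(out["timestamp"].isna().to_numpy())[0])
        raise ValueError(f"row {out.index[i]}: unparseable timestamp")
    for col, lo, hi in (("lon", -180.0, 180.0), ("lat", -90.0, 90.0)):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {out.index[i]}: {col}={out[col].iloc[i]!r} out of range"
            )
        out[col] = vals.astype(float)
    return out


def drop_class_z(fixes: pd.DataFrame) -> pd.DataFrame:
    """Remove all LC Z fixes (unbounded location error), preserving order."""
    kept = fixes[fixes["lc"].astype(str) != "Z"]
    logger.info("drop_class_z: removed %d of %d fixes", len(fixes) - len(kept), len(fixes))
    return kept


def apply_20min_rule(
    fixes: pd.DataFrame, window: pd.Timedelta = pd.Timedelta(minutes=20)
) -> pd.DataFrame:
    """Drop low-quality fixes close in time to a high-quality fix.

    A fix with LC in {0, A, B} is removed when any LC 1/2/3 fix of the same
    platform lies within ``window`` of it, on either side, boundary
    inclusive.  High-quality fixes are never removed.
    """
    lc = fixes["lc"].astype(str)
    drop = np.zeros(len(fixes), dtype=bool)
    pos = {ix: i for i, ix in enumerate(fixes.index)}
    for _, grp in fixes.groupby("ptt", sort=False):
        ts64 = pd.to_datetime(grp["timestamp"], utc=True).to_numpy(dtype="datetime64[ns]")
        hq_mask = lc[grp.index].isin(HIGH_QUALITY).to_numpy()
        hq_times = np.sort(ts64[hq_mask])
        if hq_times.size == 0:
            continue
        low_mask = lc[grp.index].isin(LOW_QUALITY).to_numpy()
        low = grp[low_mask]
        if low.empty:
            continue
        t = ts64[low_mask]
        # distance to nearest high-quality fix via bisection
        right = np.searchsorted(hq_times, t)
        left = np.clip(right - 1, 0, hq_times.size - 1)
        right = np.clip(right, 0, hq_times.size - 1)
        nearest = np.minimum(
            np.abs(t - hq_times[left]), np.abs(t - hq_times[right])
        )
        for ix, close in zip(low.index, nearest <= window.to_timedelta64()):
            if close:
                drop[pos[ix]] = True
    kept = fixes[~drop]
    logger.info("apply_20min_rule: removed %d of %d fixes", int(drop.sum()), len(fixes))
    return kept


def drop_duplicates(fixes: pd.DataFrame) -> pd.DataFrame:
    """Collapse fixes identical in (ptt, timestamp, lon, lat).

    The representative is the fix with the best location class
    (3 > 2 > 1 > 0 > A > B > Z); remaining ties keep the first occurrence.
    Output preserves the surviving fixes' original order.
    """
    if fixes.empty:
        return fixes
    rank = fixes["lc"].astype(str).map(LC_RANK)
    order = np.arange(len(fixes))
    tmp = fixes.assign(_rank=rank.to_numpy(), _order=order)
    best = (
        tmp.sort_values(["_rank", "_order"], kind="stable")
        .groupby(["ptt", "timestamp", "lon", "lat"], sort=False)
        .head(1)
    )
    kept = best.sort_values("_order", kind="stable").drop(columns=["_rank", "_order"])
    logger.info("drop_duplicates: removed %d of %d fixes", len(fixes) - len(kept), len(fixes))
    return kept


def prefilter(fixes: pd.DataFrame) -> pd.DataFrame:
    """Apply the three filter rules in order: Z, 20-minute, duplicates.

    Idempotent; the output is always a subset of the input rows, sorted
    chronologically within each platform.
    """
    fixes = validate_fixes(fixes).sort_values(["ptt", "timestamp"], kind="stable")
    return drop_duplicates(apply_20min_rule(drop_class_z(fixes)))
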