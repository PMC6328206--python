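"""Ground-truthed synthetic telemetry.

Emulates the study conditions of a small cohort of Argos-tagged whales in a
long, narrow gulf: daily true positions from the switching CRW process,
irregular Argos-like fixes (duty-cycled transmission windows, location-class
mixture, scaled-t errors), and a synthetic gulf-with-islands coastline.
Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
from shapely.prepared import prep

from .model import ArgosErrorModel, DcrwsParams
from .prefilter import LC_CLASSES

#: default location-class mixture: weighted toward the low-quality classes
#: (0/A/B) with a minority of 1/2/3, typical of marine Argos telemetry.
DEFAULT_LC_PROBABILITIES = {
    "3": 0.03, "2": 0.05, "1": 0.08, "0": 0.22, "A": 0.25, "B": 0.34, "Z": 0.03,
}


def default_params() -> DcrwsParams:
    """Two well-separated modes: persistent transiting, tortuous searching."""
    return DcrwsParams(
        theta=np.array([0.0, math.pi / 2]),
        gamma=np.array([0.8, 0.2]),
        alpha=np.array([0.9, 0.15]),
        sigma=np.array([[0.01, 0.0], [0.0, 0.01]]),
    )


@dataclass
class DutyCycle:
    """Transmission schedule: a daily window, every other day late in life."""

    hours_per_day: float = 4.0
    start_hour: float = 10.0
    every_other_day_after: int = 90

    def active(self, day: int) -> bool:
        if day < self.every_other_day_after:
            return True
        return (day - self.every_other_day_after) % 2 == 0


@dataclass
class SimulationConfig:
    """Conditions for one synthetic tag.

    Defaults emulate the study cohort: ~1.7 fixes per day within a 4 h/day
    duty cycle (every other day after day 90), a low-quality-heavy LC
    mixture, and two-mode movement with distinct persistence.
    """

    n_days: int = 100
    params: DcrwsParams = field(default_factory=default_params)
    mean_fixes_per_day: float = 1.7
    lc_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LC_PROBABILITIES)
    )
    error_model: ArgosErrorModel = field(default_factory=ArgosErrorModel)
    duty_cycle: DutyCycle = field(default_factory=DutyCycle)
    start_lonlat: tuple[float, float] = (-111.3, 25.9)
    start_time: pd.Timestamp = pd.Timestamp("2001-03-26 00:00:00", tz="UTC")
    ptt: str = "sim001"
    seed: int = 0
    #: multiplier on the observation-error scales; 0 gives noiseless fixes
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_days < 3:
            raise ValueError("n_days must be >= 3")
        if self.mean_fixes_per_day <= 0:
            raise ValueError("mean_fixes_per_day must be positive")
        total = sum(self.lc_probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"lc_probabilities sum to {total}, not 1")
        unknown = set(self.lc_probabilities) - set(LC_CLASSES)
        if unknown:
            raise ValueError(f"unknown location classes {unknown}")


@dataclass
class SyntheticTrack:
    """Ground truth plus observed fixes for one synthetic tag."""

    true_states: np.ndarray  # (n_days, 2) lon/lat degrees, one per day
    true_modes: np.ndarray  # (n_days,) in {1, 2}
    fixes: pd.DataFrame  # canonical fix table
    start_time: pd.Timestamp
    ptt: str

    def __post_init__(self) -> None:
        if len(self.true_states) != len(self.true_modes):
            raise ValueError("one mode per daily state required")


def simulate_true_track(
    config: SimulationConfig,
    seed: int | None = None,
    modes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate daily true positions and modes from the switching CRW.

    The mode sequence follows the two-state Markov chain with switching
    probabilities ``alpha``; displacements follow
    ``d_t = gamma[b_t] T(theta[b_t]) d_{t-1} + e_t`` with ``e_t ~ N2(0, Sigma)``.
    A fixed ``modes`` sequence (values in {1, 2}, one per day) may be
    supplied instead, e.g. for block designs with known switch points.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.params
    n = config.n_days
    chol = np.linalg.cholesky(p.sigma)
    if modes is not None:
        modes = np.asarray(modes, dtype=int)
        if modes.shape != (n,) or not np.all(np.isin(modes, (1, 2))):
            raise ValueError("modes must be in {1,2}, one per day")
    else:
        modes = np.empty(n, dtype=int)
        # start the chain at its stationary distribution
        p1 = p.alpha[1] / (1.0 - p.alpha[0] + p.alpha[1])
        modes[0] = 1 if rng.random() < p1 else 2
        for t in range(1, n):
            p_to_1 = p.alpha[0] if modes[t - 1] == 1 else p.alpha[1]
            modes[t] = 1 if rng.random() < p_to_1 else 2
    x = np.empty((n, 2))
    x[0] = config.start_lonlat
    d = chol @ rng.standard_normal(2)
    x[1] = x[0] + d
    for t in range(2, n):
        b = modes[t] - 1
        c, s = math.cos(p.theta[b]), math.sin(p.theta[b])
        rot = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        d = p.gamma[b] * rot + chol @ rng.standard_normal(2)
        x[t] = x[t - 1] + d
    return x, modes


def simulate_argos_fixes(
    states: np.ndarray, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate Argos-like fixes from daily true states.

    Fix counts per active duty-cycle day are Poisson with the configured
    mean; fix times are uniform within that day's transmission window
    (restricted so every fix lies between the first and last daily state).
    Each fix interpolates its bracketing daily states linearly and adds
    component-wise scaled-t noise with its location class's scale and
    degrees of freedom.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(states)
    dc = config.duty_cycle
    lcs = list(config.lc_probabilities)
    lc_p = np.array([config.lc_probabilities[c] for c in lcs])
    rows: list[tuple] = []
    for day in range(n - 1):
        if not dc.active(day):
            continue
        count = rng.poisson(config.mean_fixes_per_day)
        if count == 0:
            continue
        w0 = day + dc.start_hour / 24.0
        w1 = min(w0 + dc.hours_per_day / 24.0, n - 1.0)
        times = np.sort(rng.uniform(w0, w1, size=count))
        for t in times:
            k = min(int(math.floor(t)), n - 2)
            frac = t - k
            pos = (1.0 - frac) * states[k] + frac * states[k + 1]
            lc = lcs[rng.choice(len(lcs), p=lc_p)]
            tau = config.noise_scale * np.array(
                [config.error_model.tau_lon[lc], config.error_model.tau_lat[lc]]
            )
            nu = config.error_model.nu[lc]
            noisy = pos + tau * rng.standard_t(nu, size=2)
            ts = config.start_time + pd.Timedelta(days=t)
            rows.append((config.ptt, ts, lc, noisy[0], noisy[1]))
    if not rows:
        return pd.DataFrame(
            {"ptt": pd.Series(dtype=object), "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
             "lc": pd.Series(dtype=object), "lon": pd.Series(dtype=float),
             "lat": pd.Series(dtype=float)}
        )
    df = pd.DataFrame(rows, columns=["ptt", "timestamp", "lc", "lon", "lat"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def simulate_track(config: SimulationConfig) -> SyntheticTrack:
    """Simulate truth and fixes together from one seeded config."""
    states, modes = simulate_true_track(config)
    fixes = simulate_argos_fixes(states, config)
    return SyntheticTrack(
        true_states=states,
        true_modes=modes,
        fixes=fixes,
        start_time=config.start_time,
        ptt=config.ptt,
    )


# ---------------------------------------------------------------------------
# synthetic coastline


@dataclass
class GulfSpec:
    """An elongated water body bounded by land strips, with islands.

    All geometry is axis-aligned in lon/lat degrees: land occupies the two
    strips between the bounding box and the channel, plus rectangular
    islands inside the channel.  The mouth (southern end) is open water.
    """

    lon_min: float = -114.8
    lon_max: float = -108.6
    lat_min: float = 22.8
    lat_max: float = 32.2
    channel_lon_min: float = -112.8
    channel_lon_max: float = -110.2
    #: (center lon, center lat, half-width lon, half-height lat)
    islands: tuple[tuple[float, float, float, float], ...] = (
        (-111.6, 26.9, 0.15, 0.25),
        (-111.1, 25.4, 0.10, 0.18),
        (-112.2, 28.8, 0.18, 0.30),
    )

    @property
    def centerline_midpoint(self) -> tuple[float, float]:
        return (
            (self.channel_lon_min + self.channel_lon_max) / 2.0,
            (self.lat_min + self.lat_max) / 2.0,
        )


class Coastline:
    """Land polygons with a strict-interior point-in-land predicate."""

    def __init__(self, land_polygons: list[Polygon]):
        for poly in land_polygons:
            if poly.area <= 0:
                raise ValueError("degenerate zero-area land polygon")
            if not poly.is_valid:
                raise ValueError("invalid (self-intersecting) land polygon")
        self.land_polygons = list(land_polygons)
        self.union = unary_union(land_polygons)
        self._prepared = prep(self.union)

    def contains(self, lon: float, lat: float) -> bool:
        """True iff the point lies strictly inside land (boundary = ocean)."""
        return bool(self._prepared.contains(Point(lon, lat)))


def make_synthetic_coastline(spec: GulfSpec | None = None) -> Coastline:
    """Build the synthetic gulf landmask: two coastal strips plus islands."""
    spec = spec or GulfSpec()
    if not spec.lon_min < spec.channel_lon_min < spec.channel_lon_max < spec.lon_max:
        raise ValueError("channel must lie strictly inside the bounding box")
    west = box(spec.lon_min, spec.lat_min, spec.channel_lon_min, spec.lat_max)
    east = box(spec.channel_lon_max, spec.lat_min, spec.lon_max, spec.lat_max)
    islands = [
        box(cx - hw, cy - hh, cx + hw, cy + hh)
        for cx, cy, hw, hh in spec.islands
    ]
    return Coastline([west, east, *islands])
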