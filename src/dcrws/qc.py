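"""MCMC convergence assessment and track-level quality control.

The visual chain checks of the original protocol (random travel of the
traces, agreement of the two chains, unimodal parameter distributions) are
implemented as quantitative proxies: running mean/SD stabilisation series,
a two-chain potential-scale-reduction ratio, and a largest-gap unimodality
screen.  Six per-track metrics are derived from the filtered Argos data

    a) mean filtered locations per day (over days with at least one fix)
    b) SD of filtered locations per day
    c) input:output ratio of Argos to daily model locations
    d) total tracking days
    e) total filtered Argos locations
    f) e / d

and the per-track deviance is regressed on each metric by ordinary least
squares; tracks with too few locations are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TrackQcMetrics:
    """The six per-track data metrics (a-f)."""

    ptt: str
    mean_locs_per_day: float  # a
    sd_locs_per_day: float  # b
    argos_ssm_ratio: float  # c
    tracking_days: int  # d
    total_locs: int  # e
    locs_per_tracking_day: float  # f

    def as_dict(self) -> dict:
        return {
            "ptt": self.ptt,
            "a_mean_locs_per_day": self.mean_locs_per_day,
            "b_sd_locs_per_day": self.sd_locs_per_day,
            "c_argos_ssm_ratio": self.argos_ssm_ratio,
            "d_tracking_days": self.tracking_days,
            "e_total_locs": self.total_locs,
            "f_locs_per_tracking_day": self.locs_per_tracking_day,
        }


@dataclass
class RegressionResult:
    """Simple OLS of deviance on one track metric."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def cumulative_stats(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running mean and running sample SD (prefix k uses the first k values).

    The SD at prefix length 1 is 0 by convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    s = pd.Series(x)
    mean = s.expanding().mean().to_numpy()
    sd = s.expanding().std(ddof=1).fillna(0.0).to_numpy()
    return mean, sd


def chain_agreement(chains: np.ndarray) -> float:
    """Two-chain potential-scale-reduction ratio (Gelman-Rubin style).

    ``chains`` is (n_chains, n_draws).  Values near 1 indicate the chains
    explore the same distribution; identical chains give
    ``sqrt((n-1)/n)`` which is 1 to within floating tolerance for long
    chains.  Ratios above ~1.1 signal disagreement.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need a (n_chains, n_draws) array with >= 2 chains")
    if np.ptp([len(ch) for ch in c]) != 0:
        raise ValueError("chains must have equal length")
    n = c.shape[1]
    within = float(np.mean(np.var(c, axis=1, ddof=1)))
    between = n * float(np.var(np.mean(c, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def unimodality_gap_ratio(draws: np.ndarray) -> float:
    """Largest-gap screen for multimodal posterior draws.

    Ratio of the largest gap between consecutive sorted draws (central 98%
    to be robust against stragglers in the tails) to the mean gap; values
    far above ~10 suggest separated modes rather than one smooth mode.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    lo, hi = int(0.01 * len(x)), max(int(0.99 * len(x)), 2)
    x = x[lo:hi]
    gaps = np.diff(x)
    if gaps.size == 0 or x[-1] == x[0]:
        return 1.0
    return float(gaps.max() / gaps.mean())


def derive_track_metrics(
    filtered_fixes: pd.DataFrame, posterior_df: pd.DataFrame, ptt: str = ""
) -> TrackQcMetrics:
    """Compute metrics a-f from filtered fixes and the daily model output.

    Metric a averages over days that received at least one filtered fix
    (Table-style locations-per-day); metric f divides the location total by
    the full tracking span, so a and f differ by construction.  Tracking
    days d is the fix-time span rounded up to whole days.
    """
    if filtered_fixes.empty:
        raise ValueError("no filtered fixes")
    ts = pd.to_datetime(filtered_fixes["timestamp"], utc=True)
    per_day = ts.dt.normalize().value_counts()
    d = int(np.ceil((ts.max() - ts.min()) / pd.Timedelta(days=1)))
    if d <= 0:
        raise ValueError("zero tracking days")
    e = int(len(filtered_fixes))
    n_ssm = len(posterior_df)
    if n_ssm == 0:
        raise ValueError("empty model output")
    counts = per_day.to_numpy(dtype=float)
    return TrackQcMetrics(
        ptt=ptt,
        mean_locs_per_day=float(counts.mean()),
        sd_locs_per_day=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        argos_ssm_ratio=e / n_ssm,
        tracking_days=d,
        total_locs=e,
        locs_per_tracking_day=e / d,
    )


def regress_deviance(metric_values: np.ndarray, deviances: np.ndarray) -> RegressionResult:
    """OLS of per-track deviance on one track metric.

    F is computed from R^2 via F = (R^2 / (1 - R^2)) (n - 2), the exact
    identity for simple linear regression.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(deviances, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = x.size
    f = np.inf if r2 >= 1.0 else (r2 / (1.0 - r2)) * (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_statistic=float(f),
        p_value=float(res.pvalue),
        n=int(n),
    )


def regression_table(
    metrics: list[TrackQcMetrics], deviances: dict[str, float]
) -> pd.DataFrame:
    """Regress deviance on each of the six metrics; one row per metric."""
    dev = np.array([deviances[m.ptt] for m in metrics])
    rows = []
    for key in (
        "a_mean_locs_per_day",
        "b_sd_locs_per_day",
        "c_argos_ssm_ratio",
        "d_tracking_days",
        "e_total_locs",
        "f_locs_per_tracking_day",
    ):
        vals = np.array([m.as_dict()[key] for m in metrics], dtype=float)
        try:
            r = regress_deviance(vals, dev)
            rows.append(
                {"metric": key, "slope": r.slope, "intercept": r.intercept,
                 "r_squared": r.r_squared, "f_statistic": r.f_statistic,
                 "p_value": r.p_value, "n": r.n}
            )
        except ValueError as exc:
            rows.append({"metric": key, "error": str(exc)})
    return pd.DataFrame(rows)


def flag_tracks(
    metrics: list[TrackQcMetrics], min_total_locs: int = 10
) -> dict[str, tuple[bool, str]]:
    """Keep/discard decision per track.

    Total filtered locations is the exclusion key (the one metric with real
    explanatory power on the deviance); tracks below ``min_total_locs`` are
    discarded.  Returns ptt -> (keep, reason).
    """
    decisions: dict[str, tuple[bool, str]] = {}
    for m in metrics:
        if m.total_locs < min_total_locs:
            decisions[m.ptt] = (
                False,
                f"only {m.total_locs} filtered locations (< {min_total_locs})",
            )
            logger.info("track %s discarded: %s", m.ptt, decisions[m.ptt][1])
        else:
            decisions[m.ptt] = (True, "passed")
    return decisions
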