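"""Switching first-difference correlated random walk (DCRWS) state-space model.

The movement process is a two-mode first-difference correlated random walk
on daily displacements.  With daily positions ``x_t`` (lon/lat degrees) and
displacements ``d_t = x_t - x_{t-1}``,

    d_t | d_{t-1}, b_t  ~  Normal2( gamma[b_t] * T(theta[b_t]) @ d_{t-1}, Sigma )

where ``T(theta)`` is the rotation matrix ``[[cos, -sin], [sin, cos]]``,
``gamma`` is the move persistence in (0, 1), ``theta`` the mean turning
angle, and ``b_t`` a two-state Markov chain over behavioural modes
(mode 1 = transiting, persistent and directed; mode 2 = area-restricted
searching, slow and tortuous).  Observations are irregular Argos fixes:
each fix is a linear interpolation of its bracketing daily states plus
component-wise scaled-t noise whose scale and degrees of freedom depend on
the Argos location class.

The posterior over states, modes and parameters is explored with a
from-scratch Metropolis-within-Gibbs sampler (`run_mcmc`): blocked
random-walk Metropolis on the daily states, direct Gibbs draws for the
modes and the switching probabilities, and scalar Metropolis for the
remaining parameters, with proposal-scale adaptation during burn-in only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .prefilter import LC_CLASSES, validate_fixes

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

#: scale (degrees) of the weak zero-mean Gaussian prior on the first displacement
FIRST_STEP_PRIOR_SD = 1.0

#: scale (degrees) of the half-Normal priors on the process SDs
SIGMA_PRIOR_SCALE = 0.5


class TrackTooShortError(ValueError):
    """Raised when a track cannot support a daily grid (span under two days)."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class DcrwsParams:
    """Movement-model parameters.

    theta : per-mode mean turning angle, radians, shape (2,)
    gamma : per-mode move persistence in (0, 1), shape (2,); identifiability
        requires ``gamma[0] > gamma[1]`` (transiting is more persistent)
    alpha : switching probabilities, ``alpha[0] = P(1->1)``,
        ``alpha[1] = P(2->1)``, both in (0, 1)
    sigma : 2x2 symmetric positive-definite process covariance, deg^2
    """

    theta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.theta.shape != (2,) or self.gamma.shape != (2,) or self.alpha.shape != (2,):
            raise ValueError("theta, gamma, alpha must each have shape (2,)")
        if not np.all((self.gamma > 0) & (self.gamma < 1)):
            raise ValueError("gamma must lie in (0, 1)")
        if not self.gamma[0] > self.gamma[1]:
            raise ValueError("identifiability requires gamma[0] > gamma[1]")
        if not np.all((self.alpha > 0) & (self.alpha < 1)):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sigma.shape != (2, 2) or not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric 2x2")
        if np.linalg.eigvalsh(self.sigma)[0] <= 0:
            raise ValueError("sigma must be positive definite")


#: default per-location-class scaled-t observation error (degrees).
#: Longitude errors run larger than latitude errors, as is characteristic of
#: Argos Doppler geolocation; magnitudes span ~0.2 km (LC 3) to ~10 km (LC B).
#: These are editable defaults, not asserted values.
DEFAULT_TAU_LON = {"3": 0.0025, "2": 0.008, "1": 0.012, "0": 0.05,
                   "A": 0.04, "B": 0.09, "Z": 0.20}
DEFAULT_TAU_LAT = {"3": 0.0015, "2": 0.004, "1": 0.008, "0": 0.025,
                   "A": 0.025, "B": 0.055, "Z": 0.20}
DEFAULT_NU = {"3": 10.0, "2": 8.0, "1": 6.0, "0": 4.0, "A": 4.0, "B": 3.0, "Z": 2.5}


@dataclass
class ArgosErrorModel:
    """Per-location-class scaled-t observation error.

    tau_lon, tau_lat : scale in degrees for each LC (must be > 0)
    nu : degrees of freedom for each LC (must be > 2)
    """

    tau_lon: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAU_LON))
    tau_lat: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAU_LAT))
    nu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NU))

    def __post_init__(self) -> None:
        for lc in LC_CLASSES:
            if self.tau_lon.get(lc, 1.0) <= 0 or self.tau_lat.get(lc, 1.0) <= 0:
                raise ValueError(f"tau must be positive (LC {lc})")
            if self.nu.get(lc, 3.0) <= 2:
                raise ValueError(f"nu must exceed 2 (LC {lc})")


@dataclass
class McmcConfig:
    """Sampler settings.

    Defaults reproduce the study protocol: two chains of 30,000 iterations,
    the first 10,000 discarded as burn-in and the rest thinned to every
    fifth draw, leaving 4,000 retained samples per chain.
    """

    n_chains: int = 2
    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    adapt: bool = True
    adapt_interval: int = 50
    target_accept: float = 0.44
    init_state_jitter: float = 0.05

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# ---------------------------------------------------------------------------
# regular daily grid


@dataclass
class RegularGrid:
    """Daily estimation grid anchored at the first fix.

    Nodes step by exactly 24 h.  Each used fix i maps to the interval
    ``[node[k_i], node[k_i + 1])`` with interpolation fraction ``frac_i``;
    a fix landing exactly on the final node is stored as ``(n_nodes - 2,
    1.0)`` so interpolation never indexes past the last node.  Fixes after
    the final node (the dropped partial day) are excluded (``used`` False).
    """

    node_times: pd.DatetimeIndex
    fix_node: np.ndarray
    fix_frac: np.ndarray
    used: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_times)


def build_regular_grid(fixes: pd.DataFrame, step_hours: float = 24.0) -> RegularGrid:
    """Build the daily grid for one platform's fixes.

    Raises :class:`TrackTooShortError` when the fixes span fewer than two
    days, in which case the track cannot be modelled.
    """
    ts = pd.to_datetime(fixes["timestamp"], utc=True).sort_values()
    t0, t_last = ts.iloc[0], ts.iloc[-1]
    step = pd.Timedelta(hours=step_hours)
    span = (t_last - t0) / step
    if len(fixes) < 2 or span < 2.0:
        raise TrackTooShortError(
            f"track spans {span:.2f} steps with {len(fixes)} fixes; need >= 2 days"
        )
    n_nodes = int(math.floor(span)) + 1
    nodes = pd.DatetimeIndex([t0 + i * step for i in range(n_nodes)])
    rel = (pd.to_datetime(fixes["timestamp"], utc=True) - t0) / step
    rel = rel.to_numpy(dtype=float)
    k = np.floor(rel).astype(int)
    frac = rel - k
    used = rel <= (n_nodes - 1) + 1e-12
    on_last = used & (k >= n_nodes - 1)
    k[on_last] = n_nodes - 2
    frac[on_last] = 1.0
    return RegularGrid(node_times=nodes, fix_node=k, fix_frac=frac, used=used)


# ---------------------------------------------------------------------------
# likelihood


def rotation_matrix(theta: float) -> np.ndarray:
    """Rotation matrix T(theta) = [[cos, -sin], [sin, cos]]."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _obs_constants(
    fixes: pd.DataFrame, grid: RegularGrid, error_model: ArgosErrorModel
) -> tuple[np.ndarray, ...]:
    """Precompute per-fix arrays (y, k, frac, tau, nu, normalising constant)."""
    sub = fixes.loc[grid.used]
    y = sub[["lon", "lat"]].to_numpy(dtype=float)
    k = grid.fix_node[grid.used]
    frac = grid.fix_frac[grid.used]
    lc = sub["lc"].astype(str).to_numpy()
    tau = np.column_stack(
        [
            np.array([error_model.tau_lon[c] for c in lc]),
            np.array([error_model.tau_lat[c] for c in lc]),
        ]
    )
    nu = np.array([error_model.nu[c] for c in lc])[:, None] * np.ones((1, 2))
    const = (
        gammaln((nu + 1) / 2)
        - gammaln(nu / 2)
        - 0.5 * np.log(nu * math.pi)
        - np.log(tau)
    )
    return y, k, frac, tau, nu, const


def _obs_terms(
    states: np.ndarray,
    y: np.ndarray,
    k: np.ndarray,
    frac: np.ndarray,
    tau: np.ndarray,
    nu: np.ndarray,
    const: np.ndarray,
) -> np.ndarray:
    """Per-fix observation log-density (both coordinates summed)."""
    pred = (1.0 - frac)[:, None] * states[k] + frac[:, None] * states[k + 1]
    z = (y - pred) / tau
    return np.sum(const - (nu + 1) / 2 * np.log1p(z * z / nu), axis=1)


def _proc_terms(
    states: np.ndarray,
    modes: np.ndarray,
    theta: np.ndarray,
    gamma: np.ndarray,
    sigma_chol_terms: tuple[float, float, float, float],
) -> np.ndarray:
    """Per-day process log-density.

    Returns length-T array: index 1 holds the weak first-displacement prior,
    indices 2..T-1 the switching-CRW terms, index 0 is zero.
    """
    sx2, sy2, rho, logdet = sigma_chol_terms
    T = len(states)
    out = np.zeros(T)
    d = np.diff(states, axis=0)
    out[1] = (
        -_LOG2PI
        - 2.0 * math.log(FIRST_STEP_PRIOR_SD)
        - 0.5 * (d[0] @ d[0]) / FIRST_STEP_PRIOR_SD**2
    )
    if T < 3:
        return out
    b = modes[2:] - 1
    g = gamma[b]
    th = theta[b]
    c, s = np.cos(th), np.sin(th)
    px = g * (c * d[:-1, 0] - s * d[:-1, 1])
    py = g * (s * d[:-1, 0] + c * d[:-1, 1])
    rx = d[1:, 0] - px
    ry = d[1:, 1] - py
    one_m_r2 = 1.0 - rho * rho
    q = (rx * rx / sx2 - 2.0 * rho * rx * ry / math.sqrt(sx2 * sy2) + ry * ry / sy2) / one_m_r2
    out[2:] = -_LOG2PI - 0.5 * logdet - 0.5 * q
    return out


def _sigma_terms(sigma: np.ndarray) -> tuple[float, float, float, float]:
    sx2, sy2 = sigma[0, 0], sigma[1, 1]
    rho = sigma[0, 1] / math.sqrt(sx2 * sy2)
    logdet = math.log(sx2 * sy2 * (1.0 - rho * rho))
    return sx2, sy2, rho, logdet


def log_likelihood(
    states: np.ndarray,
    modes: np.ndarray,
    params: DcrwsParams,
    error_model: ArgosErrorModel,
    grid: RegularGrid,
    fixes: pd.DataFrame,
) -> float:
    """Joint log-density of process and observations.

    ``states`` has one (lon, lat) row per grid day; ``modes`` one mode in
    {1, 2} per grid day.  The process part is the switching CRW density of
    daily displacements (plus a weak zero-mean prior on the first
    displacement); the observation part is the sum of component-wise
    scaled-t densities of each used fix around the linear interpolation of
    its bracketing daily states.
    """
    states = np.asarray(states, dtype=float)
    modes = np.asarray(modes)
    if states.shape != (grid.n_nodes, 2):
        raise ValueError("states must have one row per grid day")
    if modes.shape != (grid.n_nodes,) or not np.all(np.isin(modes, (1, 2))):
        raise ValueError("modes must be in {1,2}, one per grid day")
    if not grid.used.any():
        raise ValueError("no usable fixes on the grid")
    obs = _obs_constants(fixes, grid, error_model)
    proc = _proc_terms(states, modes, params.theta, params.gamma, _sigma_terms(params.sigma))
    return float(np.sum(proc) + np.sum(_obs_terms(states, *obs)))


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class McmcSamples:
    """Retained posterior draws from :func:`run_mcmc`.

    Arrays are indexed (chain, sample, ...).  ``deviance`` stores
    -2 x log_likelihood per retained draw; ``deviance_at_means`` is the
    plug-in deviance at the posterior mean states/parameters (majority
    modes), used by :func:`compute_deviance_dic`.
    """

    states: np.ndarray | None = None
    modes: np.ndarray | None = None
    theta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    alpha: np.ndarray | None = None
    sigma: np.ndarray | None = None
    deviance: np.ndarray | None = None
    deviance_at_means: float | None = None
    grid: RegularGrid | None = None
    config: McmcConfig | None = None
    accept_rates: dict | None = None

    @property
    def n_retained_per_chain(self) -> int:
        return self.deviance.shape[1]


@dataclass
class PosteriorTrack:
    """Daily posterior summary for one platform.

    ``df`` has one row per grid day with columns date, lon, lat, lon_hw95,
    lat_hw95 (95% equal-tailed credible half-widths, degrees) and b_mean
    (posterior mean behavioural-mode indicator in [1, 2]).
    """

    ptt: str
    df: pd.DataFrame
    deviance: float
    dic: float
    param_summary: dict


# ---------------------------------------------------------------------------
# the sampler


class _ChainState:
    """Mutable state of one MCMC chain plus cached likelihood terms."""

    def __init__(self, x, b, theta, gamma, alpha, sx, sy, rho):
        self.x = x
        self.b = b
        self.theta = theta
        self.gamma = gamma
        self.alpha = alpha
        self.sx = sx
        self.sy = sy
        self.rho = rho

    def sigma_terms(self):
        return (
            self.sx**2,
            self.sy**2,
            self.rho,
            math.log(self.sx**2 * self.sy**2 * (1 - self.rho**2)),
        )

    def sigma_matrix(self):
        off = self.rho * self.sx * self.sy
        return np.array([[self.sx**2, off], [off, self.sy**2]])


def _trans_log_matrix(alpha: np.ndarray) -> np.ndarray:
    """M[prev-1, next-1] = log P(next | prev) for the 2-state mode chain."""
    a1, a2 = alpha
    return np.log(np.array([[a1, 1 - a1], [a2, 1 - a2]]))


def _sd_prior_logpdf(s: float) -> float:
    return -0.5 * (s / SIGMA_PRIOR_SCALE) ** 2


def _run_one_chain(rng, obs, T, cfg, keep_iters, overdisperse):
    """Metropolis-within-Gibbs sweep for a single chain."""
    y, k, frac, tau, nu, const = obs
    n_keep = len(keep_iters)

    # --- initialisation: states from fix interpolation (first two pinned to
    # the first fix), everything else drawn overdispersed per chain
    order = np.argsort(k + frac)
    tf = (k + frac)[order]
    x = np.empty((T, 2))
    tt = np.arange(T, dtype=float)
    for c in range(2):
        x[:, c] = np.interp(tt, tf, y[order, c])
    x[0] = y[order[0]]
    x[1] = y[order[0]]
    x += rng.normal(0.0, cfg.init_state_jitter * (1.0 + overdisperse), size=x.shape)
    b = rng.integers(1, 3, size=T)
    theta = rng.uniform(-math.pi, math.pi, size=2)
    gamma = np.array([rng.uniform(0.55, 0.95), rng.uniform(0.05, 0.45)])
    alpha = rng.uniform(0.3, 0.9, size=2)
    st = _ChainState(
        x, b, theta, gamma, alpha,
        sx=rng.uniform(0.03, 0.2), sy=rng.uniform(0.03, 0.2),
        rho=rng.uniform(-0.3, 0.3),
    )

    # proposal scales, adapted during burn-in only
    s_state = 0.02
    s_par = {"theta0": 0.3, "theta1": 0.3, "gamma0": 0.1, "gamma1": 0.1,
             "sx": 0.02, "sy": 0.02, "rho": 0.1}
    acc = {key: [0, 0] for key in list(s_par) + ["state"]}

    def proc_now():
        return _proc_terms(st.x, st.b, st.theta, st.gamma, st.sigma_terms())

    def obs_now(xx):
        return _obs_terms(xx, y, k, frac, tau, nu, const)

    L = proc_now()
    O = obs_now(st.x)
    u_idx = np.arange(T)
    term_site = np.empty((3, T), dtype=int)
    obs_site = np.empty((3, len(y)), dtype=int)
    for r in range(3):
        s = u_idx - ((u_idx - r) % 3)
        term_site[r] = np.clip(s, 0, T - 1)
        obs_site[r] = np.where(k % 3 == r, k, np.where((k + 1) % 3 == r, k + 1, 0))

    out_states = np.empty((n_keep, T, 2))
    out_modes = np.empty((n_keep, T), dtype=np.int8)
    out_theta = np.empty((n_keep, 2))
    out_gamma = np.empty((n_keep, 2))
    out_alpha = np.empty((n_keep, 2))
    out_sigma = np.empty((n_keep, 3))
    out_dev = np.empty(n_keep)

    keep_pos = {it: i for i, it in enumerate(keep_iters)}
    lt_cache = np.zeros((2, T))

    for it in range(1, cfg.n_iter + 1):
        # --- states: three interleaved strata so each likelihood term is
        # touched by at most one proposed site
        for r in range(3):
            idx = np.arange(r, T, 3)
            prop = st.x.copy()
            prop[idx] += rng.normal(0.0, s_state, size=(len(idx), 2))
            Lp = _proc_terms(prop, st.b, st.theta, st.gamma, st.sigma_terms())
            Op = obs_now(prop)
            delta = np.zeros(T)
            np.add.at(delta, term_site[r], Lp - L)
            np.add.at(delta, obs_site[r], Op - O)
            accept = np.log(rng.random(len(idx))) < delta[idx]
            acc["state"][0] += int(accept.sum())
            acc["state"][1] += len(idx)
            if accept.any():
                st.x[idx[accept]] = prop[idx[accept]]
                L = proc_now()
                O = obs_now(st.x)

        # --- modes: Gibbs by parity (neighbour coupling only)
        sig_terms = st.sigma_terms()
        for m in (1, 2):
            mm = np.full(T, m)
            lt_cache[m - 1] = _proc_terms(st.x, mm, st.theta, st.gamma, sig_terms)
        lt_cache[:, :2] = 0.0  # days 0,1 carry no mode-dependent process term
        M = _trans_log_matrix(st.alpha)
        for parity in (0, 1):
            idx = np.arange(parity, T, 2)
            lp = np.zeros((len(idx), 2))
            for mi in (0, 1):
                lp[:, mi] = lt_cache[mi, idx]
                has_left = idx >= 1
                lp[has_left, mi] += M[st.b[idx[has_left] - 1] - 1, mi]
                has_right = idx <= T - 2
                lp[has_right, mi] += M[mi, st.b[idx[has_right] + 1] - 1]
            p1 = expit(lp[:, 0] - lp[:, 1])
            st.b[idx] = np.where(rng.random(len(idx)) < p1, 1, 2)
        L = proc_now()

        # --- switching probabilities: conjugate Beta draws from transition counts
        prev, nxt = st.b[:-1], st.b[1:]
        n11 = int(np.sum((prev == 1) & (nxt == 1)))
        n12 = int(np.sum((prev == 1) & (nxt == 2)))
        n21 = int(np.sum((prev == 2) & (nxt == 1)))
        n22 = int(np.sum((prev == 2) & (nxt == 2)))
        st.alpha = np.array([rng.beta(n11 + 1, n12 + 1), rng.beta(n21 + 1, n22 + 1)])

        # --- scalar parameters: random-walk Metropolis
        Lsum = float(np.sum(L))
        for name in ("theta0", "theta1", "gamma0", "gamma1", "sx", "sy", "rho"):
            step = rng.normal(0.0, s_par[name])
            prior_delta = 0.0
            if name.startswith("theta"):
                i = int(name[-1])
                old = st.theta[i]
                new = (old + step + math.pi) % (2 * math.pi) - math.pi
                st.theta[i] = new
            elif name.startswith("gamma"):
                i = int(name[-1])
                old = st.gamma[i]
                new = old + step
                if not 0.0 < new < 1.0:
                    acc[name][1] += 1
                    continue
                g = st.gamma.copy()
                g[i] = new
                if not g[0] > g[1]:
                    acc[name][1] += 1
                    continue
                st.gamma[i] = new
            elif name in ("sx", "sy"):
                old = getattr(st, name)
                new = old + step
                if new <= 1e-6:
                    acc[name][1] += 1
                    continue
                prior_delta = _sd_prior_logpdf(new) - _sd_prior_logpdf(old)
                setattr(st, name, new)
            else:  # rho
                old = st.rho
                new = old + step
                if not -0.99 < new < 0.99:
                    acc[name][1] += 1
                    continue
                st.rho = new
            Lp = proc_now()
            lsum_p = float(np.sum(Lp))
            if math.log(rng.random()) < lsum_p - Lsum + prior_delta:
                L, Lsum = Lp, lsum_p
                acc[name][0] += 1
            else:  # roll back
                if name.startswith("theta"):
                    st.theta[int(name[-1])] = old
                elif name.startswith("gamma"):
                    st.gamma[int(name[-1])] = old
                elif name in ("sx", "sy"):
                    setattr(st, name, old)
                else:
                    st.rho = old
            acc[name][1] += 1

        # --- proposal adaptation (burn-in only)
        if cfg.adapt and it <= cfg.burn_in and it % cfg.adapt_interval == 0:
            for key in acc:
                n_acc, n_try = acc[key]
                if n_try == 0:
                    continue
                rate = n_acc / n_try
                factor = math.exp(0.5 * (rate - cfg.target_accept))
                if key == "state":
                    s_state = min(max(s_state * factor, 1e-5), 2.0)
                else:
                    s_par[key] = min(max(s_par[key] * factor, 1e-5), 3.0)
                acc[key] = [0, 0]

        if it in keep_pos:
            i = keep_pos[it]
            out_states[i] = st.x
            out_modes[i] = st.b
            out_theta[i] = st.theta
            out_gamma[i] = st.gamma
            out_alpha[i] = st.alpha
            out_sigma[i] = (st.sx, st.sy, st.rho)
            out_dev[i] = -2.0 * (float(np.sum(L)) + float(np.sum(O)))

    rates = {key: (a / t if t else 0.0) for key, (a, t) in acc.items()}
    return out_states, out_modes, out_theta, out_gamma, out_alpha, out_sigma, out_dev, rates


def run_mcmc(
    fixes: pd.DataFrame,
    error_model: ArgosErrorModel | None = None,
    config: McmcConfig | None = None,
) -> McmcSamples:
    """Fit the DCRWS model to one platform's prefiltered fixes.

    Returns retained draws of daily states, modes and parameters from
    ``config.n_chains`` independently initialised chains, each keeping
    ``(n_iter - burn_in) / thin`` samples (4,000 at the default settings).
    """
    error_model = error_model or ArgosErrorModel()
    cfg = config or McmcConfig()
    fixes = validate_fixes(fixes).sort_values("timestamp", kind="stable")
    grid = build_regular_grid(fixes)
    obs = _obs_constants(fixes, grid, error_model)
    if len(obs[0]) == 0:
        raise ValueError("no usable fixes on the grid")
    T = grid.n_nodes
    keep_iters = [
        it for it in range(cfg.burn_in + cfg.thin, cfg.n_iter + 1, cfg.thin)
    ][: cfg.n_retained]
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(cfg.n_chains)
    chains = [
        _run_one_chain(np.random.default_rng(child[c]), obs, T, cfg, keep_iters, c)
        for c in range(cfg.n_chains)
    ]
    samples = McmcSamples(
        states=np.stack([c[0] for c in chains]),
        modes=np.stack([c[1] for c in chains]),
        theta=np.stack([c[2] for c in chains]),
        gamma=np.stack([c[3] for c in chains]),
        alpha=np.stack([c[4] for c in chains]),
        sigma=np.stack([c[5] for c in chains]),
        deviance=np.stack([c[6] for c in chains]),
        grid=grid,
        config=cfg,
        accept_rates={f"chain{c}": chains[c][7] for c in range(cfg.n_chains)},
    )
    samples.deviance_at_means = _plugin_deviance(samples, obs)
    if all(r == 0.0 for r in samples.accept_rates["chain0"].values()):
        logger.warning("zero acceptance after tuning; check data scaling")
    return samples


def _circular_mean(angles: np.ndarray) -> float:
    return math.atan2(float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles))))


def _posterior_point(samples: McmcSamples):
    """Posterior-mean states/params with per-day majority modes."""
    xbar = samples.states.mean(axis=(0, 1))
    bbar = samples.modes.astype(float).mean(axis=(0, 1))
    b_maj = np.where(bbar <= 1.5, 1, 2)
    theta = np.array([
        _circular_mean(samples.theta[..., i].ravel()) for i in range(2)
    ])
    gamma = samples.gamma.mean(axis=(0, 1))
    sx, sy, rho = samples.sigma.mean(axis=(0, 1))
    return xbar, b_maj, theta, gamma, (sx, sy, rho)


def _plugin_deviance(samples: McmcSamples, obs) -> float:
    xbar, b_maj, theta, gamma, (sx, sy, rho) = _posterior_point(samples)
    sig_terms = (sx**2, sy**2, rho, math.log(sx**2 * sy**2 * (1 - rho**2)))
    proc = _proc_terms(xbar, b_maj, theta, gamma, sig_terms)
    y, k, frac, tau, nu, const = obs
    o = _obs_terms(xbar, y, k, frac, tau, nu, const)
    return -2.0 * (float(np.sum(proc)) + float(np.sum(o)))


def credible_halfwidth(draws: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Half-width of the equal-tailed credible interval along axis 0."""
    lo = (1.0 - level) / 2.0
    q = np.quantile(draws, [lo, 1.0 - lo], axis=0)
    return (q[1] - q[0]) / 2.0


def summarize_posterior(samples: McmcSamples, ptt: str = "") -> PosteriorTrack:
    """Pool chains into one daily posterior summary.

    Per day: posterior mean longitude/latitude, 95% equal-tailed credible
    half-widths, and the posterior mean mode indicator b in [1, 2].
    """
    if samples.states.shape[0] * samples.states.shape[1] < 100:
        raise ValueError("need at least 100 retained samples to summarise")
    pooled = samples.states.reshape(-1, *samples.states.shape[2:])
    modes = samples.modes.reshape(-1, samples.modes.shape[-1]).astype(float)
    mean = pooled.mean(axis=0)
    hw = credible_halfwidth(pooled)
    D, dic = compute_deviance_dic(samples)
    gam = samples.gamma.reshape(-1, 2)
    df = pd.DataFrame(
        {
            "date": samples.grid.node_times,
            "lon": mean[:, 0],
            "lat": mean[:, 1],
            "lon_hw95": hw[:, 0],
            "lat_hw95": hw[:, 1],
            "b_mean": modes.mean(axis=0),
        }
    )
    param_summary = {
        "theta_mean": [
            _circular_mean(samples.theta[..., i].ravel()) for i in range(2)
        ],
        "gamma_mean": gam.mean(axis=0).tolist(),
        "gamma_ci95": [
            list(np.quantile(gam[:, i], [0.025, 0.975])) for i in range(2)
        ],
        "alpha_mean": samples.alpha.reshape(-1, 2).mean(axis=0).tolist(),
        "sigma_mean": samples.sigma.reshape(-1, 3).mean(axis=0).tolist(),
    }
    return PosteriorTrack(ptt=ptt, df=df, deviance=D, dic=dic, param_summary=param_summary)


def compute_deviance_dic(samples: McmcSamples) -> tuple[float, float]:
    """Posterior-mean deviance D and DIC = D + p_D, p_D = D - D(plug-in)."""
    D = float(np.mean(samples.deviance))
    p_d = D - float(samples.deviance_at_means)
    return D, D + p_d
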