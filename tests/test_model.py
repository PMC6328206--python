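"""Grid construction, likelihood, posterior summaries and DIC arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcrws.model import (
    ArgosErrorModel,
    DcrwsParams,
    McmcConfig,
    McmcSamples,
    TrackTooShortError,
    build_regular_grid,
    compute_deviance_dic,
    credible_halfwidth,
    log_likelihood,
    rotation_matrix,
    summarize_posterior,
)
from dcrws.prefilter import fixes_to_frame, ArgosFix

T0 = pd.Timestamp("2001-04-01 06:00:00", tz="UTC")


def fixes_at(hours, lc="1", lons=None, lats=None):
    lons = lons if lons is not None else [-111.0] * len(hours)
    lats = lats if lats is not None else [26.0] * len(hours)
    return fixes_to_frame(
        [
            ArgosFix("p", (T0 + pd.Timedelta(hours=h)).to_pydatetime(), lc, lon, lat)
            for h, lon, lat in zip(hours, lons, lats)
        ]
    )


# --- grid ------------------------------------------------------------------

def test_grid_span_three_days_gives_four_nodes():
    grid = build_regular_grid(fixes_at([0.0, 24.0, 72.0]))
    assert grid.n_nodes == 4


def test_fix_exactly_on_node_has_zero_fraction():
    grid = build_regular_grid(fixes_at([0.0, 24.0, 70.0]))
    assert grid.fix_frac[0] == 0.0 and grid.fix_node[0] == 0
    assert grid.fix_frac[1] == 0.0 and grid.fix_node[1] == 1


def test_grid_matches_floor_fraction_oracle():
    rng = np.random.default_rng(0)
    hours = np.sort(np.concatenate([[0.0], rng.uniform(0, 200, size=99)]))
    grid = build_regular_grid(fixes_at(hours))
    days = hours / 24.0
    n_nodes = int(math.floor(days[-1])) + 1
    assert grid.n_nodes == n_nodes
    for i, d in enumerate(days):
        if d > n_nodes - 1:
            assert not grid.used[i]
            continue
        k, j = int(math.floor(d)), d - math.floor(d)
        if k >= n_nodes - 1:  # boundary fix stored on the last interval
            k, j = n_nodes - 2, 1.0
        assert grid.fix_node[i] == k
        assert grid.fix_frac[i] == pytest.approx(j, abs=1e-9)


def test_short_span_rejected():
    with pytest.raises(TrackTooShortError):
        build_regular_grid(fixes_at([0.0, 40.0]))


# --- likelihood ------------------------------------------------------------

def default_params():
    return DcrwsParams(
        theta=np.array([0.0, math.pi / 2]),
        gamma=np.array([0.8, 0.2]),
        alpha=np.array([0.8, 0.2]),
        sigma=np.array([[0.01, 0.002], [0.002, 0.02]]),
    )


def test_rotation_matrix_is_orthonormal():
    for th in np.linspace(-math.pi, math.pi, 17):
        T = rotation_matrix(th)
        assert np.allclose(T.T @ T, np.eye(2), atol=1e-12)
        assert np.linalg.det(T) == pytest.approx(1.0, abs=1e-12)


def test_large_nu_matches_gaussian_observation_density():
    hours = [0.0, 20.0, 30.0, 47.0, 48.0]  # all fixes land on the grid
    grid = build_regular_grid(fixes_at(hours))
    T = grid.n_nodes
    assert grid.used.all()
    rng = np.random.default_rng(1)
    states = np.column_stack([
        np.linspace(-111.0, -111.2, T) + 0.01 * rng.standard_normal(T),
        np.linspace(26.0, 26.3, T) + 0.01 * rng.standard_normal(T),
    ])
    modes = np.ones(T, dtype=int)
    p = default_params()
    tau_lon, tau_lat = 0.012, 0.008
    # fixes scattered around the interpolated states: O(1) standardised
    # residuals, where the nu -> infinity limit is sharp
    k_u, f_u = grid.fix_node, grid.fix_frac
    pred = (1 - f_u)[:, None] * states[k_u] + f_u[:, None] * states[k_u + 1]
    y = pred + np.array([tau_lon, tau_lat]) * rng.standard_normal(pred.shape)
    fixes = fixes_at(hours, lc="1", lons=list(y[:, 0]), lats=list(y[:, 1]))
    big_nu = {c: 1e8 for c in "3210ABZ"}
    em_t = ArgosErrorModel(nu=big_nu)
    ll_t = log_likelihood(states, modes, p, em_t, grid, fixes)
    obs_gauss = (stats.norm.logpdf(y[:, 0], pred[:, 0], tau_lon).sum()
                 + stats.norm.logpdf(y[:, 1], pred[:, 1], tau_lat).sum())
    from dcrws.model import _obs_constants, _obs_terms  # term-level access
    obs_t = _obs_terms(states, *_obs_constants(fixes, grid, em_t)).sum()
    assert obs_t == pytest.approx(obs_gauss, abs=1e-6 * len(fixes))
    assert np.isfinite(ll_t)


def test_constant_velocity_line_hits_zero_residual_density():
    hours = [0.0, 20.0, 50.0, 75.0, 96.0]
    fixes = fixes_at(hours)
    grid = build_regular_grid(fixes)
    T = grid.n_nodes
    v = np.array([0.08, -0.03])
    states = np.array([-111.0, 26.0]) + np.arange(T)[:, None] * v
    p = DcrwsParams(
        theta=np.array([0.0, 0.5]), gamma=np.array([1 - 1e-13, 0.2]),
        alpha=np.array([0.5, 0.5]), sigma=np.array([[0.01, 0.0], [0.0, 0.02]]),
    )
    from dcrws.model import _proc_terms, _sigma_terms
    terms = _proc_terms(states, np.ones(T, dtype=int), p.theta, p.gamma,
                        _sigma_terms(p.sigma))
    # every CRW term equals the bivariate normal log-density at zero residual
    zero_density = stats.multivariate_normal.logpdf([0, 0], cov=p.sigma)
    assert np.allclose(terms[2:], zero_density, atol=1e-9)


def test_log_likelihood_matches_term_by_term_oracle():
    rng = np.random.default_rng(2)
    hours = np.sort(rng.uniform(0, 5 * 24, size=9))
    hours[0] = 0.0
    fixes = fixes_at(hours, lc="A",
                     lons=list(-111 + 0.1 * rng.standard_normal(9)),
                     lats=list(26 + 0.1 * rng.standard_normal(9)))
    grid = build_regular_grid(fixes)
    T = grid.n_nodes
    states = np.column_stack([
        -111 + 0.1 * rng.standard_normal(T), 26 + 0.1 * rng.standard_normal(T)
    ])
    modes = rng.integers(1, 3, size=T)
    p = default_params()
    em = ArgosErrorModel()
    got = log_likelihood(states, modes, p, em, grid, fixes)

    # independent sum-of-terms oracle built from scipy densities
    from dcrws.model import FIRST_STEP_PRIOR_SD
    expect = stats.multivariate_normal.logpdf(
        states[1] - states[0], mean=[0, 0], cov=FIRST_STEP_PRIOR_SD**2 * np.eye(2)
    )
    for t in range(2, T):
        b = modes[t] - 1
        Tm = rotation_matrix(p.theta[b])
        mean = p.gamma[b] * Tm @ (states[t - 1] - states[t - 2])
        expect += stats.multivariate_normal.logpdf(
            states[t] - states[t - 1], mean=mean, cov=p.sigma
        )
    y = fixes[["lon", "lat"]].to_numpy()
    for i in range(len(fixes)):
        if not grid.used[i]:
            continue
        k, j = grid.fix_node[i], grid.fix_frac[i]
        pred = (1 - j) * states[k] + j * states[k + 1]
        nu = em.nu["A"]
        expect += stats.t.logpdf(y[i, 0], nu, loc=pred[0], scale=em.tau_lon["A"])
        expect += stats.t.logpdf(y[i, 1], nu, loc=pred[1], scale=em.tau_lat["A"])
    assert got == pytest.approx(expect, rel=1e-10)


def test_log_likelihood_input_validation():
    fixes = fixes_at([0.0, 30.0, 60.0])
    grid = build_regular_grid(fixes)
    p = default_params()
    with pytest.raises(ValueError, match="one row per grid day"):
        log_likelihood(np.zeros((2, 2)), np.ones(2, dtype=int), p,
                       ArgosErrorModel(), grid, fixes)
    with pytest.raises(ValueError, match="modes"):
        log_likelihood(np.zeros((grid.n_nodes, 2)),
                       np.full(grid.n_nodes, 3), p, ArgosErrorModel(), grid, fixes)


# --- posterior summaries ---------------------------------------------------

def synthetic_samples(states, modes, deviance, deviance_at_means=None, grid=None):
    n_keep, T = modes.shape[1], modes.shape[2]
    return McmcSamples(
        states=states, modes=modes,
        theta=np.zeros((states.shape[0], n_keep, 2)),
        gamma=np.tile([0.8, 0.2], (states.shape[0], n_keep, 1)),
        alpha=np.tile([0.5, 0.5], (states.shape[0], n_keep, 1)),
        sigma=np.tile([0.1, 0.1, 0.0], (states.shape[0], n_keep, 1)),
        deviance=deviance, deviance_at_means=deviance_at_means, grid=grid,
    )


def grid_of(T):
    hours = [24.0 * t for t in range(T)]
    return build_regular_grid(fixes_at(hours))


def test_degenerate_posterior_has_zero_halfwidth_and_constant_mode():
    T = 5
    grid = grid_of(T)
    states = np.tile(np.array([[-111.0, 26.0]]), (T, 1))
    samples = synthetic_samples(
        states=np.tile(states, (2, 60, 1, 1)),
        modes=np.full((2, 60, T), 2, dtype=np.int8),
        deviance=np.full((2, 60), 5.0), deviance_at_means=5.0, grid=grid,
    )
    post = summarize_posterior(samples)
    assert np.all(post.df["lon_hw95"] == 0.0)
    assert np.all(post.df["lat_hw95"] == 0.0)
    assert np.all(post.df["b_mean"] == 2.0)


def test_halfwidth_matches_normal_quantiles():
    rng = np.random.default_rng(3)
    sigma = 0.37
    draws = rng.normal(2.0, sigma, size=200_000)
    hw = credible_halfwidth(draws)
    assert hw == pytest.approx(1.959964 * sigma, rel=0.01)


def test_alternating_modes_average_to_1p5():
    T = 4
    grid = grid_of(T)
    modes = np.empty((1, 200, T), dtype=np.int8)
    modes[:, ::2] = 1
    modes[:, 1::2] = 2
    samples = synthetic_samples(
        states=np.zeros((1, 200, T, 2)), modes=modes,
        deviance=np.zeros((1, 200)), deviance_at_means=0.0, grid=grid,
    )
    post = summarize_posterior(samples)
    assert np.all(post.df["b_mean"] == 1.5)


def test_b_mean_always_within_unit_interval(small_samples):
    post = summarize_posterior(small_samples)
    assert ((post.df["b_mean"] >= 1.0) & (post.df["b_mean"] <= 2.0)).all()
    assert (post.df[["lon_hw95", "lat_hw95"]] >= 0).all().all()
    # posterior means lie inside the convex hull of sampled values
    pooled = small_samples.states.reshape(-1, *small_samples.states.shape[2:])
    assert np.all(post.df["lon"].to_numpy() <= pooled[..., 0].max(axis=0) + 1e-12)
    assert np.all(post.df["lon"].to_numpy() >= pooled[..., 0].min(axis=0) - 1e-12)


# --- deviance / DIC --------------------------------------------------------

def test_dic_arithmetic_by_definition():
    s = McmcSamples(deviance=np.array([[10.0, 12.0, 14.0]]), deviance_at_means=11.0)
    D, dic = compute_deviance_dic(s)
    assert D == 12.0 and dic == 13.0


def test_degenerate_posterior_dic_equals_deviance():
    s = McmcSamples(deviance=np.full((2, 10), 7.5), deviance_at_means=7.5)
    D, dic = compute_deviance_dic(s)
    assert D == 7.5 and dic == 7.5


def test_stored_deviance_matches_likelihood_recomputation(small_samples, small_filtered):
    from dcrws.prefilter import validate_fixes
    fixes = validate_fixes(small_filtered).sort_values("timestamp", kind="stable")
    c, s = 0, 17
    p = DcrwsParams(
        theta=small_samples.theta[c, s],
        gamma=small_samples.gamma[c, s],
        alpha=small_samples.alpha[c, s],
        sigma=_sigma_from(small_samples.sigma[c, s]),
    )
    ll = log_likelihood(
        small_samples.states[c, s], small_samples.modes[c, s], p,
        ArgosErrorModel(), small_samples.grid, fixes,
    )
    assert small_samples.deviance[c, s] == pytest.approx(-2 * ll, rel=1e-9)


def _sigma_from(triple):
    sx, sy, rho = triple
    off = rho * sx * sy
    return np.array([[sx**2, off], [off, sy**2]])
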