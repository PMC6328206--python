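# Methods

## The movement process

The latent track is a regular daily sequence of positions
`x_t = (lon_t, lat_t)` in degrees. Displacements `d_t = x_t − x_{t−1}`
follow a switching first-difference correlated random walk:

    d_t = γ_{b_t} T(θ_{b_t}) d_{t−1} + ε_t,   ε_t ~ N₂(0, Σ)

with `T(θ)` the plane rotation by the mean turning angle θ, γ the move
persistence, and `b_t ∈ {1,2}` a two-state Markov chain with switching
probabilities `α₁ = P(1→1)` and `α₂ = P(2→1)`. Mode 1 (transiting) is the
more persistent, directed mode; mode 2 (area-restricted searching, ARS) is
slower and more tortuous. The first displacement, which has no predecessor,
gets a weak zero-mean Gaussian prior with SD 1° so the posterior stays
proper before the observations anchor it.

The model is deliberately formulated in raw longitude/latitude degrees;
distances and speeds are computed afterwards on the sphere. This keeps the
estimation step in the coordinate convention the model family has always
used, at the cost of mild anisotropy away from the equator (a degree of
longitude shrinks with cos latitude). At the mid-latitudes of the intended
use (~23–32° N) the distortion is far smaller than Argos location error;
at high latitudes it would not be, and that is a known limitation.

## Observations

Argos fixes arrive irregularly, each with a location class (LC) from
{3, 2, 1, 0, A, B, Z} in decreasing order of accuracy. The estimation grid
steps 24 h from the first retained fix; the trailing partial day is
dropped. A fix at fractional position `j ∈ [0,1)` inside day interval `k`
observes `(1−j)·x_k + j·x_{k+1}` with independent scaled-t errors per
coordinate, using an LC-specific scale τ (separately for lon and lat,
longitude errors being characteristically larger) and degrees of freedom ν.
The shipped τ/ν defaults span roughly 0.2 km (LC 3) to 10 km (LC B)
expressed in degrees; they are ordinary config entries, editable per
deployment, and are not asserted to be any published calibration. Days with
no fixes are handled naturally: their states are informed only through the
process model.

## Prefiltering

Three rules, in order: (1) all LC Z fixes are dropped (unbounded error);
(2) LC 0/A/B fixes within 20 minutes — two-sided, boundary inclusive — of
any LC 1/2/3 fix of the same platform are dropped; (3) fixes identical in
(platform, timestamp, lon, lat) collapse to the best-LC representative,
first occurrence on ties. The window and its inclusivity are configurable;
the composition is idempotent and never fabricates or reorders fixes.

## Sampler

A Metropolis-within-Gibbs sweep per iteration:

- **States.** Random-walk Metropolis on the daily positions in three
  interleaved strata (sites t ≡ r mod 3). Any process term involves at
  most three consecutive days and any fix at most two, so within a stratum
  each likelihood term is touched by exactly one proposed site and all
  sites of the stratum can be accepted or rejected independently from one
  vectorised evaluation.
- **Modes.** Exact Gibbs by parity (even then odd days): the full
  conditional of `b_t` combines the day's process density under each mode
  with the Markov factors to its neighbours.
- **Switching probabilities.** Conjugate Beta draws from the mode
  transition counts (uniform priors).
- **θ, γ, process covariance.** Scalar random-walk Metropolis. Priors:
  θ_k uniform on (−π, π] (proposals wrap); γ_k uniform on (0,1) with the
  ordering γ₁ > γ₂ enforced by rejection, which fixes the mode labelling;
  half-Normal(0.5°) on the process SDs and uniform(−1,1) on the
  correlation.

Proposal scales adapt every 50 iterations toward 44% acceptance during
burn-in only, so the retained chain is a fixed Markov kernel. Chains are
initialised overdispersed: states at the linear interpolation of the fixes
(the first two days pinned to the first fix) plus per-chain jitter, and
parameters drawn from wide ranges. Defaults are two chains × 30,000
iterations, 10,000 burn-in, thin 5 → 4,000 retained draws per chain. All
randomness flows from one integer seed through `numpy.random.SeedSequence`,
so identical (data, config, seed) gives bit-identical samples.

With ~100 tracking days and ~170 fixes an iteration costs about a
millisecond, so a default fit is a couple of minutes per track; the test
suite and the acceptance script use shortened chains (3,000–5,000
iterations) and 40–120-day tracks, which the recovery results below show
are already well mixed for these data sizes.

## Deviance and DIC

The per-draw deviance is `−2 ×` (process + observation log-density) at the
drawn states, modes and parameters, excluding the Markov mode-prior
factors; `D` is its posterior mean. `DIC = D + p_D` with
`p_D = D − D(plug-in)`, the plug-in evaluated at posterior-mean states and
parameters (circular mean for θ) and per-day majority modes. Because the
density is evaluated on the degree scale, deviances are typically strongly
negative; they are comparable across configurations of the same track, and
the absolute scale carries no meaning on its own.

## Convergence QC

The protocol's visual chain checks are implemented as quantitative proxies:
running mean/SD series per parameter (stabilisation), a two-chain
potential-scale-reduction ratio (values ≳1.1 flag disagreement; identical
chains give √((n−1)/n) ≈ 1), and a largest-gap screen on sorted draws for
multimodality. Six per-track data metrics are derived from the filtered
fixes: (a) mean fixes per day over days with at least one fix, (b) its SD,
(c) the ratio of Argos to daily model locations, (d) total tracking days,
(e) total filtered fixes, (f) e/d. Metric (a) deliberately uses
fix-bearing days as denominator so that (a) and (f) measure different
things; (d) is the fix-time span rounded up to whole days, the reading
consistent with both per-track tabulations and the e = f·d identity.
Per-track deviance is regressed on each metric by OLS, with
`F = (R²/(1−R²))(n−2)` exactly; in practice only the total location count
has real explanatory power, so track exclusion defaults to a minimum of 10
filtered locations, configurable.

## Land correction

The state-space model is not land-aware. For each daily estimate strictly
inside a land polygon (boundaries count as ocean), an axis-aligned ellipse
is centred on it with the 95% equal-tailed credible half-widths in
longitude and latitude as east-west and north-south semi-axes — half-width,
because an interval of total span 2h around the mean is exactly `mean ± h`.
No ordering between the axes is assumed: the method needs the axis
assignment, not a major/minor convention. The ellipse is polygonised (720
vertices; centroid error orders of magnitude below location uncertainty)
in a local planar frame about its centre with longitude scaled by
cos(latitude), since raw degree-space areas are anisotropic; the land is
clipped away and the area centroid of the ocean remainder, mapped back to
degrees, replaces the estimate. Edge cases: an ellipse entirely on land is
inflated ×1.5 up to three times, after which the nearest ocean point to the
centre is used; a centroid that itself falls on land (possible for
crescent-shaped remainders) is replaced by the nearest point of the ocean
remainder. The result is therefore never on land, the correction is
idempotent, and dates and behavioural modes are never altered. Degenerate
zero half-widths are floored at 10⁻⁴ degrees.

## Movement summaries

Consecutive daily locations give great-circle step distances (haversine on
a sphere of radius 6,371 km; a geodesic-on-ellipsoid alternative would
change distances by <0.5%) and speeds distance/24 h. A step takes its
behavioural label and season from its end day — behaviour is attached to
locations, so a step needs one convention; start-day is available in
config. Classification uses strict inequalities (`b̄ > 1.75` ARS,
`b̄ < 1.25` transiting, boundary values uncertain). Seasons split the
calendar into December–May (cool) and June–November (warm), the climatic
seasons of the gulf system this design emulates. Per-track summaries
average within track; cohort rows are unweighted means across tracks,
skipping tracks that have no steps of a given mode — the arithmetic that
reproduces the published cohort table from its per-track rows.

## Synthetic data

The generator emulates the study conditions: daily true positions from the
exact process above (default γ = (0.8, 0.2), θ = (0, π/2),
α = (0.9, 0.15), Σ = 0.01°·I, i.e. ~11 km daily process noise), fixes from
a per-day Poisson count (mean 1.7) placed uniformly inside a 4 h/day
transmission window that switches to every other day after day 90,
location classes drawn from a mixture weighted toward 0/A/B with a minority
of 1/2/3 and a few Z, and scaled-t errors from the same error model the
fitter uses. The synthetic coastline is an axis-aligned gulf: two coastal
strips flanking a ~2.6°-wide channel with rectangular islands inside, open
at the south.

What this does not emulate: real Argos error is correlated with satellite
pass geometry and is not symmetric in lon/lat per pass; real fix counts
cluster within passes rather than arriving as a homogeneous process; real
coastlines are not rectangles; and the generator shares its error-model
family with the fitter, so tests demonstrate correct inference under the
model, not robustness to misspecification. Passing recovery tests
therefore validate the implementation and the identifiability of the
two-mode structure at these data densities — not field performance on any
particular real deployment.

## Numerical and design notes

- Mode Gibbs probabilities go through a numerically safe sigmoid; process
  densities use the closed-form bivariate normal with correlation rather
  than matrix factorisations in the inner loop.
- A fix landing exactly on the final grid node is stored on the last
  interval with fraction 1.0 so interpolation never indexes past the grid.
- Tracks whose fixes span under two days cannot support a daily grid and
  are rejected as unmodelable before fitting.
- The pipeline derives each track's chain seed deterministically from the
  global seed and the platform's sorted index, stamps every output with the
  seed and a hash of the analytic configuration (file paths excluded), and
  is byte-reproducible for identical (config, seed).
- Per-mode cohort speed cells with no steps are missing values, preserved
  as such through aggregation.
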