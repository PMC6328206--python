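# dcrws — switching-CRW state-space analysis of Argos animal telemetry

`dcrws` is a Python library (plus a thin CLI) for the classic marine-megafauna
telemetry workflow: take raw Argos satellite fixes from tagged animals,
filter them by location class, fit a Bayesian two-mode switching
first-difference correlated random walk (DCRWS) state-space model by MCMC to
get one estimated location per day, screen the fits with convergence
diagnostics, push on-land estimates back into the ocean, and summarise daily
travel by behavioural mode and season. It was built around the study design
of a small fin-whale cohort tracked in a long, narrow gulf — few tags, one
to three fixes per day, heavy low-quality location classes, and a coastline
with islands that daily location estimates routinely land on.

Because raw telemetry of that kind is rarely public, the package ships a
first-class synthetic-data module that simulates ground-truthed tags under
the same conditions (duty-cycled transmissions, location-class mixtures,
scaled-t errors) and a synthetic gulf coastline, so every stage is testable
end to end.

## The model

Daily positions `x_t` (lon/lat degrees) move by first differences
`d_t = x_t − x_{t−1}` according to

    d_t | d_{t−1}, b_t ~ N₂( γ_{b_t} · T(θ_{b_t}) · d_{t−1}, Σ )

where `T(θ)` is the rotation matrix `[[cos θ, −sin θ], [sin θ, cos θ]]`,
`γ_k ∈ (0,1)` is the move persistence and `θ_k` the mean turning angle of
behavioural mode `k`, and `b_t ∈ {1, 2}` follows a two-state Markov chain
(mode 1 = transiting: persistent, directed; mode 2 = area-restricted
searching: slow, tortuous; identifiability via `γ₁ > γ₂`). Each Argos fix
observes the linear interpolation of its two bracketing daily states with
component-wise scaled-t noise whose scale and degrees of freedom depend on
the fix's location class (3, 2, 1, 0, A, B).

The posterior over states, modes and parameters is sampled by a
from-scratch Metropolis-within-Gibbs scheme: blocked random-walk Metropolis
on daily states, exact Gibbs draws for modes and switching probabilities,
scalar Metropolis for `θ, γ, Σ`, with proposal adaptation during burn-in
only. Defaults mirror the original protocol — two chains × 30,000
iterations, 10,000 burn-in, thinning to every fifth draw, 4,000 retained
samples per chain — and report the posterior mean deviance `D` and
`DIC = D + p_D`. Per-day posterior mode means `b̄_t ∈ [1, 2]` are
classified as transiting (`b̄ < 1.25`), area-restricted searching
(`b̄ > 1.75`) or uncertain.

## Worked example

Fit one synthetic 60-day tag whose first 30 days are transiting and last 30
are area-restricted searching (`examples/03_fit_track.py`, short demo
chains):

```text
sim001: 105 filtered fixes over 60 days
estimated days: 59,  deviance D = -1072.1,  DIC = -931.4
move persistence: transiting gamma1 = 0.89 (95% CI 0.70-1.00), searching gamma2 = 0.59 (95% CI 0.19-0.84)
simulated truth : gamma1 = 0.8, gamma2 = 0.2
mode mean b over true transiting days: 1.39; over true searching days: 1.50
```

The 95% credible intervals cover the simulated persistences, and the
posterior mode mean sits higher across the searching block than the
transiting block — the signal the 1.25/1.75 classification cutoffs act on.
The deviance is strongly negative because the model's densities live on the
degree scale, where daily displacements are small numbers.

The other scripts in `examples/` each demonstrate one capability:
simulation, prefiltering, land correction, movement summaries, and the full
pipeline (`run_pipeline` or `dcrws run-all config.yaml`), which writes
per-track daily estimates, QC reports, the cohort movement table, and
seasonal behavioural proportions, all stamped with the seed and a config
hash for byte-exact reproducibility.

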