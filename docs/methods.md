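# Methods

## Setting and notation

A stepped-wedge cluster randomized trial with `m` clusters and `s = m` steps
is simulated over the window `(t_S, t_E)` with equally spaced switch times

    W_i = t_S + i · W_d,      W_d = (t_E − t_S) / (m + 1),   i = 1..m.

An optional follow-up period of `F` steps extends observation to
`t_F = t_E + W_d·F`. Subjects form an open cohort: subject `j` of cluster
`i` enters at

    d_ij = t_S + (t_end − t_S) · e / E,     e ~ U(0, 1),

where `t_end` is `t_F` when entry is allowed into the follow-up period and
`t_E` otherwise, and `E ≥ 1` concentrates entry toward the start of the
trial (`E = 1` is uniform over the whole window). The distance from entry to
the switch is `w_ij = max(W_i − d_ij, 0)`; the intervention indicator is the
time-dependent covariate `Z(t) = 1{t ≥ w_ij}` on the subject's own clock.
`W_d` is held at full floating precision; printed spacings such as 33 and 17
days for 10 and 20 steps are display rounding of 360/11 and 360/21.

One cluster switches per step and cluster sizes are equal (`n = N/m`,
non-integer totals are rejected rather than silently truncated, since that
would change the effective sample size).

## Event generation

Each subject carries up to three latent recurrent-event times, generated by
inverting a piecewise cumulative hazard that multiplies by `exp(β_t)` at the
switch. With `u ~ U(0,1)` and Λ the cumulative hazard, the sampled duration
is `T* = Λ⁻¹(−log u)`; both branches of the closed-form inverse agree at the
branch threshold, and the test suite verifies the round trip
`Λ(T*) = −log u` to nine digits.

- **Poisson**: constant hazard `λ·exp(β'x + τ_i + τ_j)` before the switch,
  multiplied by `exp(β_t)` after it. Three iid uniforms are inverted with
  the common total-time distance `w_ij`, and the resulting durations are
  sorted ascending, so the event times are the order statistics of three
  iid draws from entry. (Sorting the transformed durations, rather than the
  uniforms, is the only reading under which event times increase.)
- **Mixed-Poisson**: as Poisson with a subject-level normal random effect
  `τ_j` on the log hazard (inter-individual variability).
- **Weibull (constant/change)**: sequential gap times with baseline hazard
  `λ_k ν_k t^(ν_k−1)`; the clock restarts at each event, and the `k`-th gap
  uses `(λ_k, ν_k)`. "Constant" shares one (scale, shape) across all three
  recurrences; "change" gives the first recurrence its own pair and the
  second and third a common different pair.

The cluster effect `τ_i ~ N(0, σ²)` is drawn once per cluster per
replicate and enters every linear predictor; the subject effect
`τ_j ~ N(0, σ_s²)` is drawn once per subject and enters the exponential
models only (the Weibull linear predictors contain `τ_i` alone). The fixed
covariate term `β'x` is threaded through all formulas but defaults to 0.

**Switch basis.** For the second and third recurrences the distance to the
switch can be measured two ways: from trial entry (`w_ij`, on each
segment's own clock) or re-measured from the previous event
(`w_ijk = max(W_i − T_{ij,k−1}, 0)`, which keeps the switch calendar-aligned
at `W_i`). The package implements both (`SwitchBasis.ENTRY` /
`SwitchBasis.RECURRENCE`) in the generator and in the gap-time layout. The
default is `ENTRY`: it is the basis under which the package reproduces the
published operating characteristics of the simulation study its parameters
come from — most sharply the positive gap-time bias under (mixed-)Poisson
generation and the large AG/total-time biases under the Weibull generators,
which vanish almost entirely under the `RECURRENCE` basis. Under `ENTRY`
the effective intervention start for recurrence `k ≥ 2` is the gap time
`w_ij` after the previous event rather than the calendar switch `W_i`; this
mismatch with the calendar-defined switch is precisely what drives those
biases, and it is retained deliberately as the study condition being
emulated.

**Terminal event.** An independent terminal time (emulating death) is drawn
as `C = d + C*` with `C*` Weibull. The printed parameterization
`S(t) = exp{−(t/λ_c)^{ν_c}}` with `λ_c = 0.003674` (days) makes the scale
0.0037 days and kills essentially everyone instantly, contradicting the
~31% one-year mortality the parameters were fitted to; the default is
therefore the rate-form cumulative hazard `(λ_c·t)^{ν_c}`
(`TerminalParam.CUM_HAZ_POW`), which yields a 30–40% terminal fraction over
a 360-day window with uniform entry. Both literal readings remain
selectable. Subjects are observed up to `H = min(C, trial end)`: latent
events at or before `H` are observed (at most three), a subject with three
observed events ends follow-up at the third event, and otherwise follow-up
is censored at `H` — by the terminal event if `C` precedes the trial end,
administratively otherwise.

### Parameters (fitted to the motivating palliative-care trial)

| parameter | value | meaning |
|---|---|---|
| λ (Poisson) | 0.003281 /day | hospitalisation rate, first three admissions |
| σ_s | 0.3455 | SD of the subject effect τ_j (mixed-Poisson) |
| λ_k, ν_k (Weibull constant) | 0.004703, 1.1219 | common gap scale/shape |
| λ_1, ν_1 (Weibull change) | 0.003599, 1.5122 | first recurrence |
| λ_2=λ_3, ν_2=ν_3 (change) | 0.009910, 0.9108 | later recurrences |
| λ_c, ν_c (terminal) | 0.003674, 1.7191 | death time Weibull |
| β_t | −0.264 = ln(4.3/5.6) | protective log hazard ratio (and 0 for the null) |

The printed subject-heterogeneity value 0.3455 is described in its source
as an estimate of a standard deviation even though the symbol is a
variance; the SD reading is the default here because it reproduces the
published mixed-Poisson operating characteristics (the variance reading
roughly doubles the gap-time bias and drops its coverage from ~0.85 to
~0.66), and the variance reading stays available via
`subject_effect_is_sd=False`.

## Analysis models

Observed histories become `(start, stop]` counting-process intervals with
`Z` constant per row (rows are split at the switch point; zero-length rows
arising from boundary ties are dropped with a warning):

- **AG**: one continuous at-risk spell per subject from entry to end of
  follow-up on the *time-since-entry* scale; common baseline hazard across
  recurrences.
- **PWP-TT**: the same time axis, but the subject is at risk for recurrence
  `k` only between events `k−1` and `k` (delayed entry), with baseline
  hazards stratified by `k`.
- **PWP-GT**: the clock restarts at each event; stratum-`k` rows run from 0
  to the gap length.

The total-time axis is time since entry rather than calendar time: the
intervention indicator is defined against the subject-specific distance
`w_ij`, and on the calendar axis every subject in a cluster would share one
switch time, making `Z` a deterministic function of stratum and time under
cluster stratification — every risk set would be condition-homogeneous and
the stratified fits unidentifiable. Each layout can additionally stratify
by cluster (separate baseline hazard per cluster), the recommended policy
for handling cluster effects; an event falling exactly on a switch boundary
(probability zero under continuous generation) is labelled with the
pre-switch condition.

The single coefficient is estimated by Newton-Raphson with step-halving on
the stratified Breslow partial likelihood (ties have measure zero here;
Breslow is also the convention of the standard fitting software).
Convergence requires a score below 1e-9 or a step below 1e-10, within 50
iterations. Because `Z` is binary, the risk-set sum at an event time
reduces to `n_0(t) + e^β n_1(t)` with at-risk counts obtained by binary
search; the counts are precomputed once, making each full trial fit run in
milliseconds. Degenerate inputs are reported, never fitted through: no
events; no covariate variation inside any informative risk set (this also
catches one-subject-per-stratum layouts, whose likelihood is flat);
monotone likelihoods (separation), flagged when the estimate runs beyond
|β| = 15 while the score decays; and iteration exhaustion.

Two standard errors are computed: the model-based SE (inverse observed
information) and the subject-clustered robust sandwich SE
`I⁻¹(Σ_s U_s²)I⁻¹` from summed score residuals, the standard correction for
within-subject correlation in recurrent-event Cox models; the sandwich is
validated against `survival::coxph(..., cluster(id))` to seven digits. The
95% Wald interval and hence the coverage probabilities default to the
model-based SE: where the two disagree materially (the AG model under the
changing-hazard Weibull generator), only the model-based interval
reproduces the published coverage values (e.g. null-effect coverage 0.99
rather than 0.95), indicating that the published intervals were the naive
ones. `fit(..., ci_se="robust")` selects the sandwich interval instead.

## Operating characteristics

Over `R` converged replicates: bias `= mean(β̂) − β_t` (positive means the
protective effect is underestimated), `MSE = bias² + Var(β̂)` (population
variance, so the identity is exact by construction), and CP = fraction of
95% CIs containing `exp(β_t)`. Non-converged replicates are excluded from
the moments and reported as counts. Replicates are seeded by spawning
independent child streams from one root seed, so every table is
deterministic given its `ScenarioSpec`.

## Problem sizes

The package's own reproduction runs (`scripts/acceptance.py` and the
end-to-end tests) use the full study sample size N = 2000 with R = 300
replicates per cell, giving a binomial SE of ≈ 0.013 on coverage estimates
and a Monte-Carlo SE of ≈ 0.004 on bias estimates — tight enough to
separate nominal coverage from every collapse pattern of interest while
keeping a full 24-cell grid under a minute of CPU. The null-calibration
check uses R = 1000.

## What the generator does and does not emulate

The generator reproduces the study conditions: staggered unidirectional
switches, open-cohort entry with optional concentration and follow-up,
at most three recurrences, an independent terminal event, and the four
hazard families above. It does **not** emulate: informative (event-
dependent) terminal hazards or competing-risk structure (death is
non-informative censoring); discontinuous risk intervals during hospital
stays (risk intervals are continuous, as in the simulation being
reproduced); covariate effects beyond the intervention indicator; multiple
facilities per cluster; or more than three recurrences. Passing tests
therefore demonstrate correctness of the estimators *under these
conditions*, not robustness to informative dropout or competing risks in
real data.

## Known limitations

- The Cox engine is specialised to one binary covariate; the scalar algebra
  would need generalising for covariate vectors.
- The `ENTRY` switch basis intentionally reproduces a published simulation
  whose gap-time switch placement disagrees with the calendar switch for
  later recurrences; analyses of real data should prefer the `RECURRENCE`
  basis, which keeps the intervention start calendar-aligned.
- Coverage in the AG/changing-Weibull collapse cell is highly sensitive to
  small bias and SE differences; reproductions agree that coverage
  collapses (< 0.25) but the exact collapsed value wobbles by several
  points across seeds.
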