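# swrecur

Simulation and extended-Cox analysis of **recurrent events in stepped-wedge
cluster randomized trials (SWCRTs) with open-cohort entry**.

In a stepped-wedge trial every cluster starts under the control condition and
switches to the intervention at a staggered, scheduled step; in an open
cohort, subjects enter (and leave) the trial at arbitrary times, so many are
observed under both conditions. When the outcome is a recurrent event — for
example repeated hospital admissions of care-home residents — the intervention
effect can be estimated with extended Cox models in counting-process form,
using the unidirectional switch as a binary time-dependent covariate
`Z_ij(t) = 1{t ≥ w_ij}`, where `w_ij = max(W_i − d_ij, 0)` is the distance
from subject `j`'s entry `d_ij` to its cluster's switch time `W_i`.

`swrecur` provides the full Monte-Carlo machinery to study which estimator to
trust in this setting:

- **trial geometry** (`swrecur.design`): equally spaced switch times
  `W_i = t_S + i·(t_E − t_S)/(m+1)`, an optional follow-up period
  `t_F = t_E + W_d·F`, and entry-time sampling
  `d = t_S + (t_end − t_S)·e/E` with `e ~ U(0,1)` (larger `E` concentrates
  entry at the start of the trial);
- **event generation** (`swrecur.simulate`): inverse-transform sampling of up
  to three recurrent-event times per subject from piecewise hazards that jump
  by `exp(β_t)` at the switch — a homogeneous Poisson process, a
  mixed-Poisson process with a log-normal subject frailty, and Weibull
  gap-time models with constant or per-recurrence-changing (scale, shape);
  plus an independent Weibull terminal event and administrative censoring;
- **risk-set layouts** (`swrecur.layouts`): counting-process `(start, stop]`
  intervals, split at the switch so `Z` is constant within each row, for the
  Andersen-Gill (AG) model, the Prentice-Williams-Peterson total-time
  (PWP-TT) and gap-time (PWP-GT) models, with or without stratification by
  cluster;
- **Cox engine** (`swrecur.cox`): Newton-Raphson maximization of the
  stratified Breslow partial likelihood for the single intervention
  coefficient, with model-based and subject-clustered robust (sandwich)
  standard errors and 95% Wald intervals (validated coefficient-for-
  coefficient against `lifelines` and R `survival::coxph` + `cluster()`);
- **scenario runner and CLI** (`swrecur.runner`, `swrecur.cli`): replicated
  simulate-and-fit experiments, per-cell **bias** `mean(β̂) − β_t`, **MSE**
  `bias² + Var(β̂)` and **coverage probability** (fraction of 95% CIs
  containing `exp(β_t)`), and a preset library of the six study scenarios
  (number of steps, cluster heterogeneity, follow-up period × entry window,
  entry concentration).

## Worked example

Twenty replicates of the reference setting (m = 5 clusters, N = 2000
subjects, 360-day step period, uniform entry, no follow-up, true effect
β_t = ln(4.3/5.6) = −0.264) under the Poisson generator:

```python
import swrecur as sw

spec = sw.reference_scenario("poisson", beta_t=-0.264, replications=20, root_seed=7)
results = sw.run_scenario(spec)
print(sw.summarize(results, beta_true=-0.264).table.round(4).to_string(index=False))
```

```
 model   bias    mse   cp  n_converged  mean_events  terminal_prop  ctrl_int_ratio
    ag 0.0281 0.0041 0.95           20       0.8849         0.3692          0.5355
pwp-gt 0.0318 0.0066 0.90           20       0.8849         0.3692          0.5355
pwp-tt 0.0052 0.0042 0.90           20       0.8849         0.3692          0.5355
```

Subjects experience 0.88 events on average; 37% are censored mid-trial by
the terminal event; the cohort spends roughly one control day for every two
intervention days. The positive AG and PWP-GT biases (≈ +0.03: the
protective effect is underestimated) against the near-unbiased PWP-TT are
the pattern this design produces under Poisson generation.

A single trial can also be simulated and analysed directly:

```python
data = sw.simulate_trial(spec.design, spec.event_config, seed=1)
iv = sw.build_layout(data, sw.LayoutPolicy(sw.ModelKind.PWP_GT))
res = sw.fit(iv)
print(f"HR={res.hr:.3f}  95% CI=({res.ci_low:.3f}, {res.ci_high:.3f})")
# HR=0.840  95% CI=(0.746, 0.947)
```

Or from the shell:

```bash
swrecur presets                      # list the scenario library
swrecur run --preset I_m5_poisson_bt-0.264 --reps 100 --seed 1 --out out/
swrecur summarize out/replicates.tsv --beta-true -0.264
```

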