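# Methods

## Model structure

`listlite` is a deterministic cohort-projection model. A projection is a
pure function of a profile and a scenario; there is no Monte Carlo inside
the engine, and no uncertainty intervals are produced.

For each year *t* (0 = baseline), outcome group *g* and cause *c*:

```
deaths_baseline(t, g, c) = denominator(g, t) * base_rate(g) * cause_fraction(g, c)
deaths_scenario(t, g, c) = deaths_baseline(t, g, c)
                           * prod_i m_i(t, g, c)          # direct effects
                           * prod_r M_r(t, g, c)          # risk-factor paths
lives_saved(t, g, c)     = deaths_baseline - deaths_scenario
```

Baseline rates and cause fractions are held constant for the whole horizon:
the model's central assumption is that secular mortality change is captured
through intervention coverage, not through exogenous rate trends. The
denominators may still change over time (population growth enters linearly),
so "baseline deaths" can grow even while rates are flat.

### Direct effects: the residual-mortality multiplier

An intervention with efficacy *E* and affected fraction *AF*, moving from
(quality-adjusted) baseline coverage `c0` to coverage `ct`, multiplies its
target cause's deaths by

```
m = 1 - E*AF*(ct - c0) / (1 - E*AF*c0)
```

The denominator is the residual-mortality correction: the baseline death
count already excludes deaths averted at baseline coverage, so an increment
of coverage removes `E*AF*dc` deaths out of a pool that is only
`1 - E*AF*c0` of the unprotected total. Properties that follow and are
tested: `m = 1` when `ct = c0`; `m = 0` at `E = AF = 1`, `c0 = 0`,
`ct = 1`; `m > 1` when coverage is lost (permitted, logged as a warning);
`E*AF*c0 >= 1` is a saturation error (the profile claims baseline coverage
already removes every amenable death, so there is no residual to act on).

Multipliers from distinct interventions (and risk-factor paths) acting on
the same cause combine as a plain product — an independence assumption. The
affected-fraction field is the modeller's guard against double counting:
two interventions that act on the same deaths should carry fractions that
reflect the overlap.

### Risk-factor mediation

A risk factor is a categorical exposure whose last state is the reference
(non-exposed) state. Interventions targeting it shrink the harmful states:
a fraction `f = 1 - prod_i m_i` of each harmful state's *baseline*
prevalence moves to the reference state (the shift is recomputed from
baseline every year, not compounded iteratively, so it is a function of the
current coverage level alone). The mortality multiplier for each (group,
cause) the factor modulates is the comparative-risk ratio

```
M = sum_s p_t(s) * RR(s) / sum_s p_0(s) * RR(s)
```

with missing RR entries defaulting to 1. When every state carries the same
RR the function returns exactly 1.0 (short-circuited, so flat risks cannot
leak rounding noise into the deaths loop). A zero denominator — positive
prevalence mass but all of it on RR = 0 states — is a degenerate-risk
error.

### Effective coverage

`effective_coverage(u, r) = u * r` (readiness optional). In the engine, the
coverage entering the multiplier at year *t* is
`c(t) * utilization(t) * readiness(t)` with a missing series treated as 1,
*including year 0*: the baseline coverage is quality-adjusted by the
baseline-year series values. Consequences: a flat readiness of 0.5 exactly
halves an intervention's impact, and improving quality at constant crude
coverage produces lives saved on its own. This wiring — quality series as
multiplicative discounts on the interpolated coverage path — was a design
choice; the alternative (treating the utilization series as the coverage
path itself) would have disconnected scenarios from the quality-adjusted
interventions entirely.

### Coverage interpolation

Linear only. The path holds `c0` strictly before `scale_up_start`, takes
its first step at `start`, reaches the target at `end`, and holds it
thereafter: `c(t) = c0 + (target - c0) * (t - start + 1) / (end - start + 1)`
inside the ramp. `start == end` is a step; year 0 is never altered, so every
scenario shows zero lives saved in the baseline year by construction.

### Attribution

Within each (year, group, cause) cell, intervention *i* receives the share
`(1 - m_i) / sum_j (1 - m_j)` of the cell's total lives saved, where `m_i`
is its combined multiplier: its direct effects, times, for each risk-factor
path it feeds, `1 - share_i * (1 - M_r)` with `share_i` the same
proportional-deficit rule applied among the path's feeders. When no
intervention moves a cell (`sum_j (1 - m_j) = 0`) everyone gets zero. This
proportional rule was chosen over sequential/marginal attribution because it
is order-free, symmetric for identical interventions, and conserves the cell
total exactly (to float rounding; the conservation tolerance used in checks
is 1e-6 absolute, measured ~1e-13 in practice). It is a declared reporting
convention, not a causal decomposition.

### Missed opportunities

Each intervention is scaled alone from its baseline to a standard target
(default 0.9, a conventional "high coverage" value, overridable) linearly
from year 1 to the horizon, and the *final-year* lives saved are recorded.
Ties are broken lexicographically by intervention id. A saturated
intervention is reported with 0 and a warning rather than aborting the
ranking.

### Modeled vs. measured

`compare_to_measured` converts scenario deaths back to a rate in the
group's units and reports absolute and relative gaps per overlapping year.
No interpolation of missing years and no statistical testing: the table is
a learning device. The relative gap is a fraction of the measured rate
(−0.05 means the model sits 5% below the measurement).

## Units and conventions

| Quantity | Units | Default |
| --- | --- | --- |
| maternal base rate | deaths per 100,000 live births | — |
| stillbirth base rate | per 1,000 pregnancies | — |
| neonatal / child base rate | per 1,000 live births | — |
| pregnancies | count per year | live_births × 1.03 |
| coverage, efficacy, AF, prevalence | proportions in [0, 1] | — |
| scale-up schedule | year offsets, 1 ≤ start ≤ end ≤ horizon | — |

Two child age bands only (neonatal, 1–59 months); finer bands, herd effects
of vaccines, demographic feedback from family planning, costing and
uncertainty intervals are deliberately out of scope. All rate-to-death
conversion happens once, at the envelope boundary; the engine works in
absolute deaths throughout.

Validation is strict rather than forgiving: any out-of-range value,
sum-to-one failure (tolerance 1e-9), dangling effect target, duplicate id or
wrong-length series raises a named error at load time; the engine itself
never clips or repairs inputs.

## Synthetic profiles

The generator emulates the role of a country input database so that every
operation is testable offline. Distributions are fixed and documented:
cause fractions from a symmetric Dirichlet; efficacies U[0.1, 0.9];
affected fractions U[0.3, 1.0]; baseline coverages U[0.05, 0.8]; harmful
relative risks log-uniform on [1, 4] with reference RR 1; baseline rates
drawn from per-group ranges typical of high-burden settings (child
30–100/1,000, neonatal 15–45/1,000, maternal 100–800/100,000, stillbirth
8–30/1,000 pregnancies); births grow geometrically at U[0%, 3%] per year.
About 30% of interventions target a risk factor when one exists; 20% carry
a constant utilization or readiness series. Everything is a pure function
of one integer seed.

What the generator does *not* emulate: correlations between coverage and
mortality across settings, time trends in baseline rates, multi-effect
intervention packages, seasonality, or any real country's values. Passing
property suites on generated profiles therefore demonstrates the engine's
algebraic contracts (conservation, monotonicity, order invariance, oracle
agreement), not predictive validity for real programs.

The `demo_profile` preset is anchored on a single published order of
magnitude — an under-five-scale child mortality rate of 60 per 1,000 live
births — and every other value in it (neonatal rate 25/1,000, cause
fractions, the breastfeeding factor's states and RRs, the five
interventions' coverages and efficacies) is invented for illustration.

## Numerical choices

* Conservation checks: 1e-6 absolute per cell (observed error ~1e-13).
* Oracle-equivalence and parameter-recovery tolerance: 1e-9 relative.
* Monotonicity assertions allow a 1e-9 absolute slack for rounding.
* Flat-RR multipliers return exactly 1.0 by short-circuit.
* Degenerate inputs: empty intervention lists project cleanly to zero lives
  saved; an empty result table saves as a header-only CSV; a horizon-0
  projection is impossible by schema (horizon ≥ 1).

## Problem sizes used in checks

The test suite and the acceptance script run at desk scale: tiny oracle
profiles (≤ 3 interventions, ≤ 2 causes per group, ≤ 3 years, 200 draws),
100-profile conservation and recovery sweeps, and 1,000 monotonicity
perturbations over 100 profiles — sizes chosen because the engine's
contracts are scale-free (linearity in the denominator is itself one of the
tested properties), so small problems exercise every code path.

## Known limitations

* The independence-product combination ignores genuine effect interactions;
  affected fractions are the only guard against double counting.
* Attribution is a convention; different defensible rules (Shapley,
  sequential) give different per-intervention splits with the same totals.
* Constant baseline rates mean long horizons extrapolate today's cause
  structure unchanged.
* The risk-factor shift always moves mass to the single reference state;
  graded shifts between harmful states are not modelled.
* Coverage loss (target below baseline) raises mortality through the same
  formula; this is permitted and logged but only lightly exercised by the
  property suites, which focus on scale-up.
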