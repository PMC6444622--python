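# switchadjust

Adjusting for treatment switching (crossover) in randomised survival
trials, with a focus on what happens **after** the two-stage adjustment:
re-censor, don't re-censor, or reweight.

In many oncology trials, control-arm patients are allowed to start the
experimental therapy after disease progression.  An intention-to-treat
analysis then over-states control-arm survival, which matters wherever
the estimand is the counterfactual "what would control survival have
been without switching" — most prominently in health technology
assessment.  Two-stage estimation (TSE) addresses this by

1. **Stage 1** — fitting a Weibull accelerated-failure-time model to
   post-progression survival among progressed control patients, with the
   switch indicator as a time-dependent covariate and prognostic
   covariates measured at the secondary baseline (progression).  This
   yields the switching time-ratio `exp(-psi)`.
2. **Stage 2** — reconstructing each switcher's counterfactual time
   `U = T_A + exp(psi) * T_B`, where `T_A` is time from randomisation to
   switch and `T_B` the remaining observed time.

Because the transform shrinks censoring times for switchers only, the
counterfactual dataset has informative censoring.  The package
implements the three ways of handling it:

* **TSE** — re-censor every control patient at
  `D* = min(C, C * exp(psi))` (valid, but discards late follow-up);
* **TSEnr** — leave the counterfactual times alone;
* **TSEipcw** — keep all follow-up and weight it by inverse probability
  of censoring weights from discrete-time (21-day interval) pooled
  logistic models, stabilised or unstabilised.

Control-arm restricted mean survival time (RMST) at 548 days is then
estimated with a flexible parametric model — a restricted cubic spline
for the log cumulative hazard in log time — extrapolating linearly in
`ln t` beyond the last knot, so that re-censored and full-follow-up
analyses are compared like with like.

A full synthetic-trial generator is included: a joint longitudinal
(biomarker) and survival (two-component mixture Weibull with
time-dependent treatment effect) model, 500 patients randomised 2:1,
21-day visit schedules, staggered uniform entry over 183 days,
administrative censoring at 548 days, progression at a Beta(5,10)
fraction of survival time, and logistic progression-triggered switching
with a configurable benefit `omega` applied to post-switch survival.
A performance harness computes percent bias, empirical SE, RMSE,
bootstrap coverage, convergence and Monte-Carlo errors per method.

## Worked example

```python
from switchadjust import (shipped_scenario, simulate_trial, apply_switching,
                          estimate_all_methods, true_values)

params = shipped_scenario("scenario20")      # printed parameter set
truth = true_values(params, N=200_000, seed=20, fit_n=0)
print(f"true control RMST {truth.control_rmst:.1f} days")

ns = simulate_trial(params, seed=42)         # one 500-patient trial
sw = apply_switching(ns, params, seed=43)    # progression-triggered switching
for est in estimate_all_methods(ns, sw):
    print(f"{est.method:12s} RMST {est.rmst:6.1f}  converged={est.converged}")
```

Output:

```
true control RMST 356.8 days
NoSwitching  RMST  350.5  converged=True
ITT          RMST  370.5  converged=True
TSE          RMST  326.9  converged=True
TSEnr        RMST  359.0  converged=True
TSEipcw      RMST  357.4  converged=True
```

The true control RMST under this scenario is ~357 days.  In this
replicate the naive ITT analysis of the switched data over-estimates it
(370.5), the re-censored TSE under-shoots (326.9), TSE without
re-censoring over-shoots slightly (359.0), and the weighted variant
lands closest (357.4) — the qualitative pattern the simulation study is
designed to quantify.

The same pipeline is available from the shell:

```bash
switchadjust simulate --scenario scenario20 --seed 1 --out out/
switchadjust adjust --survival out/trial_survival.csv --visits out/trial_visits.csv --out out/
switchadjust run-scenario --scenario scenario28 --n-sims 250 --seed 7 --out results/
```

Scenario definitions are flat YAML files (see
`src/switchadjust/configs/`); `scenario20` carries the published
parameter values, while `scenario01` and `scenario28` are calibrated
variants produced by the shipped calibration routines
(`calibrate_switching` for switch proportions; see `docs/methods.md`
for the severity and effect-size calibration).

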