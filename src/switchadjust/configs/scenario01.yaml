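# Simple single-Weibull scenario: no biomarker or time-dependent effect in
# the hazard (alpha = eta = 0), low constant treatment effect
# (log HR -0.223 -> AF 0.8^(-1/2) ~ 1.12), Weibull scale calibrated so
# control-arm RMST at 548 days is ~357, switch intercept calibrated to
# ~25% of progressed control patients switching.
beta0: 20.0
sigma0_sq: 1.0
beta1: 0.04
beta2: -0.02
beta3: 2.5
sigma_err: 1.0
delta1: -0.22314355
delta2: 0.3
alpha: 0.0
eta: 0.0
lambda1: 4.505733e-06
gamma1: 2.0
lambda2: 1.0e-05
gamma2: 0.8
mixp: 1.0
omega: 1.13
badprog_prev: 0.5
n_patients: 500
alloc_ratio: 2.0
visit_interval: 21.0
entry_max: 183.0
max_admin: 548.0
prog_beta_a: 5.0
prog_beta_b: 10.0
switch_logit: [-8.6063, 0.005, 0.2]
n_switch_visits: 3
scenario_id: scenario01
provenance: calibrated
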