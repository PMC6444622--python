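# High disease severity variant of scenario 20 (calibrated): Weibull
# scales raised so control-arm RMST at 548 days is ~228 and the control
# administrative censoring proportion is ~17%, switch benefit set to the
# high-effect acceleration factor 1.85, switch intercept calibrated to
# ~57% of progressed control patients switching.  All other parameters
# as scenario 20.
beta0: 20.0
sigma0_sq: 1.0
beta1: 0.04
beta2: -0.02
beta3: 2.5
sigma_err: 1.0
delta1: -1.3
delta2: 0.3
alpha: 0.01
eta: 0.003
lambda1: 2.407194e-05
gamma1: 2.0
lambda2: 3.462220e-03
gamma2: 0.8
mixp: 0.5
omega: 1.85
badprog_prev: 0.5
n_patients: 500
alloc_ratio: 2.0
visit_interval: 21.0
entry_max: 183.0
max_admin: 548.0
prog_beta_a: 5.0
prog_beta_b: 10.0
switch_logit: [-6.3421, 0.005, 0.2]
n_switch_visits: 3
scenario_id: scenario28
provenance: calibrated
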