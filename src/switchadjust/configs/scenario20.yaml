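beta0: 20.0
sigma0_sq: 1.0
beta1: 0.04
beta2: -0.02
beta3: 2.5
sigma_err: 1.0
delta1: -1.3
delta2: 0.3
alpha: 0.01
eta: 0.003
lambda1: 1.0e-05
gamma1: 2.0
lambda2: 1.0e-05
gamma2: 0.8
mixp: 0.5
omega: 1.53
badprog_prev: 0.5
n_patients: 500
alloc_ratio: 2.0
visit_interval: 21.0
entry_max: 183.0
max_admin: 548.0
prog_beta_a: 5.0
prog_beta_b: 10.0
switch_logit: [-6.6632, 0.005, 0.2]
n_switch_visits: 3
scenario_id: scenario20
provenance: printed
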