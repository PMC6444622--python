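"""Trial simulator: baseline model arithmetic, hazard inversion against an
independent quadrature oracle, and the trial-design invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from switchadjust import (ScenarioParams, baseline_mixture_survival,
                          baseline_hazard, patient_hazard, analytic_survival,
                          invert_survival_time, simulate_trial, true_values)
from switchadjust.simulate import _ArmInverter, _lp_const, _lp_slope


class TestBaselineMixture:
    @pytest.mark.parametrize("t,params,expected", [
        # survival at the origin is 1 for any parameter set
        (0.0, ScenarioParams(), 1.0),
        # single-Weibull closed form: exp(-1e-5 * 100^2) = exp(-0.1)
        (100.0, ScenarioParams(mixp=1.0, lambda1=1e-5, gamma1=2.0),
         math.exp(-0.1)),
        # printed mixture parameters at the administrative horizon
        (548.0, ScenarioParams(), 0.524),
    ])
    def test_survival_values(self, t, params, expected):
        assert baseline_mixture_survival(t, params) == pytest.approx(
            expected, abs=5e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            baseline_mixture_survival(-1.0, ScenarioParams())

    def test_hazard_consistent_with_survival_derivative(self):
        p = ScenarioParams()
        t = np.linspace(10.0, 500.0, 20)
        eps = 1e-4
        num = -(np.log(baseline_mixture_survival(t + eps, p))
                - np.log(baseline_mixture_survival(t - eps, p))) / (2 * eps)
        assert np.allclose(baseline_hazard(t, p), num, rtol=1e-5)


class TestPatientHazard:
    def test_null_linear_predictor_reduces_to_baseline(self):
        p = ScenarioParams(delta1=0.0, delta2=0.0, alpha=0.0, eta=0.0)
        t = np.array([5.0, 50.0, 400.0])
        assert np.allclose(patient_hazard(t, 1, 1, 23.0, p),
                           baseline_hazard(t, p))

    def test_control_good_prognosis_without_biomarker_effect(self):
        p = ScenarioParams(alpha=0.0, eta=0.0)
        t = np.array([30.0, 300.0])
        assert np.allclose(patient_hazard(t, 0, 0, 19.0, p),
                           baseline_hazard(t, p))

    def test_log2_intercept_shift_doubles_hazard(self):
        p = ScenarioParams()
        b0 = 20.0
        h1 = patient_hazard(0.5, 0, 0, b0, p)
        h2 = patient_hazard(0.5, 0, 0, b0 + math.log(2) / p.alpha, p)
        assert h2 == pytest.approx(2.0 * h1, rel=1e-10)


class TestInversion:
    def test_single_weibull_closed_form(self):
        p = ScenarioParams(mixp=1.0, lambda1=1e-5, gamma1=2.0,
                           delta1=0.0, delta2=0.0, alpha=0.0, eta=0.0)
        t = invert_survival_time(0.5, 0, 0, 20.0, p)
        assert t == pytest.approx(math.sqrt(math.log(2) / 1e-5), rel=1e-6)

    def test_monotone_in_uniform_draw(self, scenario20):
        ts = [invert_survival_time(u, 0, 1, 20.5, scenario20)
              for u in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_u_out_of_range_rejected(self, scenario20):
        for u in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                invert_survival_time(u, 0, 0, 20.0, scenario20)

    def test_draws_match_quadrature_survivor(self, scenario20):
        """KS distance between 1e5 simulated draws for one covariate
        profile and the numerically integrated survivor is below 0.01."""
        p = scenario20
        arm, bad, b0 = 0, 1, 21.0
        inv = _ArmInverter(_lp_slope(arm, p), p)
        rng = np.random.default_rng(123)
        u = rng.uniform(size=100_000)
        c0 = np.full(u.size, _lp_const(arm, bad, b0, p))
        draws = inv.times_from_uniform(u, c0)
        assert np.isfinite(draws).all()
        grid = np.linspace(1.0, 2500.0, 120)
        surv = analytic_survival(grid, arm, bad, b0, p)
        emp = 1.0 - np.searchsorted(np.sort(draws), grid) / draws.size
        assert np.max(np.abs(emp - surv)) < 0.01


class TestSimulateTrial:
    def test_deterministic_allocation(self, scenario20):
        ds = simulate_trial(scenario20, seed=0)
        arm = ds.survival["arm"]
        assert (arm.sum(), (1 - arm).sum()) == (333, 167)

    def test_too_small_trial_rejected(self, scenario20):
        with pytest.raises(ValueError):
            simulate_trial(scenario20.with_(n_patients=1), seed=0)
        with pytest.raises(ValueError):
            ScenarioParams(n_patients=2)

    def test_admin_censoring_window(self, trial_pair):
        ns, _ = trial_pair
        admin = ns.patients["admin_censor"]
        assert admin.between(365.0, 548.0).all()

    def test_event_iff_death_before_admin_censoring(self, trial_pair):
        ns, _ = trial_pair
        pat = ns.patients
        surv = ns.survival
        expect = (pat["T_noswitch"] < pat["admin_censor"]).astype(int)
        assert (surv["event"].to_numpy() == expect.to_numpy()).all()
        assert np.allclose(surv["time"],
                           np.minimum(pat["T_noswitch"], pat["admin_censor"]))

    def test_progression_precedes_death_with_beta_mean(self, scenario20):
        ds = simulate_trial(scenario20.with_(n_patients=20_000), seed=5)
        pat = ds.patients
        frac = pat["prog_time"] / pat["T_noswitch"]
        assert ((frac > 0) & (frac < 1)).all()
        # Beta(5, 10) has mean 1/3
        assert frac.mean() == pytest.approx(1.0 / 3.0, abs=3 * frac.std()
                                            / math.sqrt(len(frac)))

    def test_visit_grid(self, trial_pair):
        ns, _ = trial_pair
        v = ns.visits
        assert (np.mod(v["day"], 21.0) == 0).all()
        lim = ns.survival.set_index("id")["time"]
        assert (v["day"] <= v["id"].map(lim) + 1e-9).all()

    def test_progression_observed_at_first_visit_after_progression(self, trial_pair):
        ns, _ = trial_pair
        obs = ns.patients.dropna(subset=["obs_prog_day"])
        assert (obs["obs_prog_day"] >= obs["prog_time"]).all()
        assert (obs["obs_prog_day"] - obs["prog_time"] < 21.0).all()

    def test_same_seed_reproduces_dataset(self, scenario20):
        a = simulate_trial(scenario20, seed=99)
        b = simulate_trial(scenario20, seed=99)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_csv_round_trip(self, trial_pair, tmp_path):
        ns, _ = trial_pair
        s, v = ns.to_csv(tmp_path)
        back = type(ns).from_csv(s, v)
        pd.testing.assert_frame_equal(
            back.survival, ns.survival, check_exact=False, rtol=1e-12)


class TestTruth:
    def test_saturated_rmst(self):
        # all survival beyond the horizon restricts to the horizon
        t = np.full(100, 600.0)
        assert np.minimum(t, 548.0).mean() == 548.0

    def test_proportional_hazards_case_recovers_delta1(self):
        """With no biomarker or time effects (and no prognosis frailty)
        the working average HR equals exp(delta1)."""
        p = ScenarioParams(mixp=1.0, alpha=0.0, eta=0.0, delta2=0.0,
                           delta1=-0.5, lambda1=4.5e-6)
        tr = true_values(p, N=40_000, seed=3, fit_n=None)
        assert tr.converged
        assert tr.avg_hr == pytest.approx(math.exp(-0.5), abs=0.025)
        assert tr.psi == pytest.approx(-0.25, abs=0.03)  # AF = HR^(-1/gamma)
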