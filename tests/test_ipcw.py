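"""Censoring weights: person-interval expansion, restricted-cubic-spline
basis against a brute-force oracle, weight arithmetic and diagnostics, and
bias correction on a synthetic informative-censoring benchmark."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from switchadjust.ipcw import (expand_to_intervals, time_spline_basis,
                               make_censoring_knots, fit_censoring_models,
                               compute_weights, weight_diagnostics,
                               CensoringModels, V_COLUMNS, L_COLUMNS)
from switchadjust.splines import rcs_basis, rcs_basis_deriv


# ---------------------------------------------------------------------------
# person-interval expansion
# ---------------------------------------------------------------------------

def _tiny_cf(U, event):
    return pd.DataFrame({
        "id": np.arange(1, len(U) + 1), "arm": 0, "badprog": 0,
        "entry_day": 0.0, "time": U, "event": event, "switched": 0,
        "switch_day": np.nan, "U": U, "event_cf": event,
        "recensored": False, "psi_used": 0.0,
    })


def _tiny_visits(ids, n_days=30):
    frames = []
    for i in ids:
        days = np.arange(0.0, 548.0 + 1, 21.0)[:n_days]
        frames.append(pd.DataFrame({
            "id": i, "day": days, "biomarker": 20.0 + 0.04 * days,
            "progression_observed": 0}))
    return pd.concat(frames, ignore_index=True)


class TestExpansion:
    def test_death_and_censoring_interval_counts(self):
        cf = _tiny_cf([100.0, 110.0], [1, 0])
        pit = expand_to_intervals(cf, _tiny_visits([1, 2]))
        g1 = pit[pit["id"] == 1]
        assert list(g1["k"]) == [0, 1, 2, 3, 4]
        assert g1["censored"].sum() == 0
        assert g1["died"].tolist() == [0, 0, 0, 0, 1]
        g2 = pit[pit["id"] == 2]
        assert len(g2) == 6
        assert g2["censored"].tolist() == [0, 0, 0, 0, 0, 1]

    def test_row_count_is_ceil_time_over_width(self, big_trial_pair):
        _, sw = big_trial_pair
        from switchadjust.tse import counterfactual_times
        cf = counterfactual_times(sw.survival, -0.4)
        pit = expand_to_intervals(cf, sw.visits)
        counts = pit.groupby("id").size()
        ctrl = cf[cf["arm"] == 0].set_index("id")
        expect = np.ceil(ctrl["U"] / 21.0).astype(int)
        assert (counts == expect.loc[counts.index]).all()

    def test_covariates_use_information_at_interval_start(self, big_trial_pair):
        _, sw = big_trial_pair
        from switchadjust.tse import counterfactual_times
        cf = counterfactual_times(sw.survival, -0.4)
        pit = expand_to_intervals(cf, sw.visits)
        prog_rows = pit[pit["progressed"] == 1]
        assert (prog_rows["obs_prog_day"] <= prog_rows["start"]).all()
        pre = pit[pit["progressed"] == 0]
        assert (pre["obs_prog_day"] == 0).all()


# ---------------------------------------------------------------------------
# restricted cubic spline basis
# ---------------------------------------------------------------------------

def _truncated_power_oracle(x, knots):
    """Independent natural-spline construction from the raw truncated
    power basis: cubic spline constrained to be linear outside the
    boundary knots."""
    x = np.asarray(x, dtype=float)
    K = len(knots)
    kK, kK1 = knots[-1], knots[-2]
    cols = [x]
    for kj in knots[:-2]:
        pj = np.clip(x - kj, 0, None) ** 3
        pK1 = np.clip(x - kK1, 0, None) ** 3
        pK = np.clip(x - kK, 0, None) ** 3
        cols.append(pj - pK1 * (kK - kj) / (kK - kK1)
                    + pK * (kK1 - kj) / (kK - kK1))
    return np.column_stack(cols)


class TestSplineBasis:
    def test_matches_truncated_power_oracle(self):
        rng = np.random.default_rng(0)
        cens = rng.uniform(50.0, 500.0, size=200)
        x = rng.uniform(0.0, 600.0, size=100)
        knots = make_censoring_knots(cens)
        assert np.allclose(time_spline_basis(x, cens),
                           _truncated_power_oracle(x, knots), atol=1e-9)

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([1.0, 2.0, 3.0, 4.0])
        for lo, hi in [(-3.0, 0.9), (4.1, 9.0)]:
            x = np.linspace(lo, hi, 7)
            B = rcs_basis(x, knots)
            # second differences vanish for a linear function
            assert np.allclose(np.diff(B, n=2, axis=0), 0.0, atol=1e-9)

    def test_continuity_of_value_and_derivatives_at_knots(self):
        knots = np.array([0.0, 1.0, 2.5, 4.0])
        for k in knots:
            lo, hi = k - 1e-7, k + 1e-7
            assert np.allclose(rcs_basis(lo, knots), rcs_basis(hi, knots),
                               atol=1e-5)
            assert np.allclose(rcs_basis_deriv(lo, knots),
                               rcs_basis_deriv(hi, knots), atol=1e-4)

    def test_two_knots_give_affine_basis(self):
        x = np.linspace(0, 10, 11)
        B = rcs_basis(x, [2.0, 8.0])
        assert B.shape == (11, 1)
        assert np.allclose(B[:, 0], x)

    def test_knot_rule_centiles(self):
        cens = np.linspace(100.0, 200.0, 101)
        knots = make_censoring_knots(cens)
        assert knots[0] == 100.0 and knots[-1] == 200.0
        assert np.allclose(knots[1:3], [133.0, 167.0])

    def test_degenerate_censoring_times_rejected(self):
        with pytest.raises(ValueError):
            make_censoring_knots([100.0, 100.0])


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class _ConstModel:
    def __init__(self, p):
        self.p = p

    def predict(self, X):
        return np.full(len(X), self.p)


def _pit_one_patient(n_int):
    return pd.DataFrame({
        "id": 1, "k": range(n_int), "start": 21.0 * np.arange(n_int),
        "stop": 21.0 * (np.arange(n_int) + 1),
        "censored": 0, "died": 0, "badprog": 0.0, "biomarker0": 20.0,
        "progressed": 0.0, "obs_prog_day": 0.0, "biomarker_k": 20.0,
    })


class TestComputeWeights:
    def test_constant_hazard_closed_form(self):
        models = CensoringModels(knots=np.array([0.0, 63.0]),
                                 denominator=_ConstModel(0.1), numerator=None,
                                 stabilised=False, converged=True,
                                 den_columns=V_COLUMNS + L_COLUMNS)
        wt = compute_weights(models, _pit_one_patient(3))
        assert wt["weight"].iloc[-1] == pytest.approx(1.0 / 0.9 ** 3)

    def test_numerator_equal_denominator_gives_unit_weights(self):
        models = CensoringModels(knots=np.array([0.0, 63.0]),
                                 denominator=_ConstModel(0.07),
                                 numerator=_ConstModel(0.07),
                                 stabilised=True, converged=True,
                                 den_columns=V_COLUMNS + L_COLUMNS,
                                 num_columns=V_COLUMNS)
        wt = compute_weights(models, _pit_one_patient(5))
        assert np.allclose(wt["weight"], 1.0)

    def test_unstabilised_weights_nondecreasing(self, big_trial_pair):
        _, sw = big_trial_pair
        from switchadjust.tse import counterfactual_times
        cf = counterfactual_times(sw.survival, -0.4)
        pit = expand_to_intervals(cf, sw.visits)
        models = fit_censoring_models(pit, stabilised=False)
        assert models.converged
        wt = compute_weights(models, pit)
        assert (wt["weight"] >= 1.0 - 1e-9).all()
        diffs = wt.groupby("id")["weight"].diff().dropna()
        assert (diffs >= -1e-9).all()

    def test_zero_censoring_gives_unit_weights(self):
        pit = _pit_one_patient(4)
        pit.loc[3, "died"] = 1
        models = fit_censoring_models(pit)
        assert models.degenerate and models.converged
        wt = compute_weights(models, pit)
        assert np.allclose(wt["weight"], 1.0)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(1)
        pit = pd.concat([_pit_one_patient(4).assign(id=i)
                         for i in range(1, 41)], ignore_index=True)
        pit["biomarker_k"] = rng.normal(20, 1, size=len(pit))
        # censoring happens exactly when the separating covariate is high
        pit["censored"] = (pit["biomarker_k"] > 21.0).astype(int)
        models = fit_censoring_models(pit)
        assert not models.converged


class TestDiagnostics:
    def test_unit_weights(self):
        wt = pd.DataFrame({"id": [1, 1, 2], "weight": [1.0, 1.0, 1.0]})
        d = weight_diagnostics(wt)
        assert d.cv == 0.0 and d.max_weight == 1.0
        assert not d.max_gt_100 and not d.max_gt_1000

    def test_two_point_cv(self):
        wt = pd.DataFrame({"id": [1, 2], "weight": [1.0, 3.0]})
        d = weight_diagnostics(wt)
        assert d.cv == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            weight_diagnostics(pd.DataFrame({"id": [], "weight": []}))


# ---------------------------------------------------------------------------
# synthetic informative-censoring benchmarks
# ---------------------------------------------------------------------------

def _informative_pit(n, strength, seed=0, beta_surv=0.9):
    """Discrete-time synthetic cohort: a baseline covariate drives both
    death and censoring, making censoring informative."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=n)
    rows = []
    for i in range(n):
        alive, k = True, 0
        while alive and k < 26:
            p_die = expit(-3.2 + beta_surv * z[i])
            p_cens = expit(-3.0 + strength * z[i])
            died = rng.uniform() < p_die
            cens = (not died) and rng.uniform() < p_cens
            rows.append((i + 1, k, 21.0 * k, 21.0 * (k + 1), int(cens),
                         int(died), 0.0, z[i], 0.0, 0.0, z[i]))
            alive = not (died or cens)
            k += 1
    return pd.DataFrame(rows, columns=["id", "k", "start", "stop", "censored",
                                       "died"] + V_COLUMNS + L_COLUMNS), z


def test_noninformative_censoring_gives_stabilised_weights_near_one():
    pit, _ = _informative_pit(800, strength=0.0, seed=3)
    models = fit_censoring_models(pit, stabilised=True)
    assert models.converged
    wt = compute_weights(models, pit)
    assert np.abs(np.log(wt["weight"])).max() < 0.2


def test_weighted_survival_closer_to_truth_under_informative_censoring():
    """The weighted discrete product-limit estimate must beat the
    unweighted one in integrated squared distance to the censoring-free
    truth when censoring depends on a survival-related covariate."""
    pit, z = _informative_pit(2500, strength=1.5, seed=4)
    models = fit_censoring_models(pit, stabilised=False)
    wt = compute_weights(models, pit)
    pit = pit.assign(w=wt["weight"].to_numpy())

    # censoring-free truth by direct computation from the generative model
    ks = np.arange(26)
    p_die = expit(-3.2 + 0.9 * z)[:, None]
    S_true = np.mean(np.cumprod(np.ones((len(z), 26)) * (1 - p_die), axis=1),
                     axis=0)

    def product_limit(weights):
        s = np.ones(26)
        for k in ks:
            rows = pit[pit["k"] == k]
            n_at = np.sum(weights[rows.index])
            d = np.sum(weights[rows.index] * rows["died"].to_numpy())
            s[k] = (s[k - 1] if k else 1.0) * (1.0 - d / n_at)
        return s

    unw = product_limit(np.ones(len(pit)))
    wgt = product_limit(pit["w"].to_numpy())
    ise_unw = np.sum((unw - S_true) ** 2)
    ise_wgt = np.sum((wgt - S_true) ** 2)
    assert ise_wgt < ise_unw


def test_weight_dispersion_grows_with_censoring_strength():
    cvs, maxes = [], []
    for strength in (0.4, 1.0, 1.6):
        pit, _ = _informative_pit(1200, strength=strength, seed=5)
        models = fit_censoring_models(pit, stabilised=False)
        wt = compute_weights(models, pit)
        d = weight_diagnostics(wt)
        cvs.append(d.cv)
        maxes.append(d.max_weight)
    assert cvs[0] < cvs[1] < cvs[2]
    assert maxes[0] < maxes[1] < maxes[2]
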