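"""Run the adjustment estimators on simulated trial pairs and compute
simulation-study performance measures.

Methods, all targeting control-arm RMST at 548 days via the flexible
parametric model:

* ``NoSwitching`` — fit to the pre-switch control data (gold standard,
  not feasible in practice);
* ``ITT`` — fit to the switched control data as observed;
* ``TSE`` — stage-1 Weibull AFT, counterfactual reconstruction, then
  re-censoring at min(C, C e^psi);
* ``TSEnr`` — the same without re-censoring;
* ``TSEipcw`` — the TSEnr counterfactual dataset weighted by unstabilised
  inverse probability of censoring weights;
* ``TSEipcw_stab`` (optional) — stabilised weights, with baseline
  covariates in the survival model and regression standardisation.

Performance per method over converged replicates: percent bias of RMST,
empirical SE of percent bias, RMSE = sqrt(bias^2 + empSE^2), coverage of
bootstrap intervals, convergence rate, and Monte-Carlo standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .simulate import TrialDataset
from .tse import build_secondary_baseline, fit_stage1, counterfactual_times, recensor
from .ipcw import (expand_to_intervals, fit_censoring_models, compute_weights,
                   weight_diagnostics, V_COLUMNS)
from .rmst import make_knots, fit_rp, rmst

__all__ = ["METHODS", "MethodEstimate", "estimate_all_methods",
           "bootstrap_ci", "summarise_performance"]

METHODS = ["NoSwitching", "ITT", "TSE", "TSEnr", "TSEipcw", "TSEipcw_stab"]


@dataclass
class MethodEstimate:
    scenario: str
    sim: int
    method: str
    rmst: float
    converged: bool
    psi_hat: float = np.nan
    weight_cv: float = np.nan
    weight_cv_terminal: float = np.nan
    max_weight: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan


def _ctrl_rmst_plain(surv: pd.DataFrame, tstar: float, method: str,
                     time_col: str = "time", event_col: str = "event"):
    ctrl = surv[surv["arm"] == 0]
    df = pd.DataFrame({"stop": ctrl[time_col].to_numpy(float),
                       "event": ctrl[event_col].to_numpy(int)})
    fit = fit_rp(df)
    return rmst(fit, tstar, method=method)


def estimate_all_methods(noswitch: TrialDataset, switched: TrialDataset,
                         scenario: str = "", sim: int = 0,
                         tstar: float = 548.0, stabilised: bool = False,
                         methods: list[str] | None = None
                         ) -> list[MethodEstimate]:
    """Apply every requested estimator to one simulation replicate.

    Any failure inside a method (stage-1 non-convergence, separation in
    the censoring models, non-finite weights, spline-fit failure) marks
    that method non-converged for this replicate; other methods proceed.
    """
    wanted = list(methods) if methods is not None else [
        m for m in METHODS if m != "TSEipcw_stab" or stabilised]
    out = []

    def emit(method, est=None, psi=np.nan, diag=None):
        rec = MethodEstimate(scenario=scenario, sim=sim, method=method,
                             rmst=np.nan, converged=False, psi_hat=psi)
        if est is not None and est.converged and np.isfinite(est.rmst):
            rec.rmst = est.rmst
            rec.converged = True
        if diag is not None:
            rec.weight_cv = diag.cv
            rec.weight_cv_terminal = diag.cv_terminal
            rec.max_weight = diag.max_weight
        out.append(rec)

    if "NoSwitching" in wanted:
        try:
            emit("NoSwitching", _ctrl_rmst_plain(noswitch.survival, tstar,
                                                 "NoSwitching"))
        except Exception:
            emit("NoSwitching")
    if "ITT" in wanted:
        try:
            emit("ITT", _ctrl_rmst_plain(switched.survival, tstar, "ITT"))
        except Exception:
            emit("ITT")

    tse_wanted = [m for m in wanted if m.startswith("TSE")]
    if not tse_wanted:
        return out

    admin = switched.admin_censor_times()
    try:
        sb = build_secondary_baseline(switched)
        s1 = fit_stage1(sb)
        if not s1.converged:
            raise RuntimeError("stage 1 non-convergence")
        cf_nr = counterfactual_times(switched.survival, s1.psi)
    except Exception:
        for m in tse_wanted:
            emit(m)
        return out

    if "TSE" in wanted:
        try:
            cf = recensor(cf_nr, s1.psi, admin)
            emit("TSE", _ctrl_rmst_plain(cf, tstar, "TSE", "U", "event_cf"),
                 psi=s1.psi)
        except Exception:
            emit("TSE", psi=s1.psi)
    if "TSEnr" in wanted:
        try:
            emit("TSEnr", _ctrl_rmst_plain(cf_nr, tstar, "TSEnr", "U",
                                           "event_cf"), psi=s1.psi)
        except Exception:
            emit("TSEnr", psi=s1.psi)

    pit = None
    for m, stab in (("TSEipcw", False), ("TSEipcw_stab", True)):
        if m not in wanted:
            continue
        try:
            if pit is None:
                pit = expand_to_intervals(cf_nr, switched.visits)
            models = fit_censoring_models(pit, stabilised=stab)
            if not models.converged:
                raise RuntimeError("censoring model non-convergence")
            wt = compute_weights(models, pit)
            diag = weight_diagnostics(wt)
            df = pit[["start", "stop"]].copy()
            df["event"] = pit["died"].to_numpy(int)
            ctrl_knots = make_knots(
                cf_nr.loc[cf_nr["arm"] == 0, "U"].to_numpy(float),
                cf_nr.loc[cf_nr["arm"] == 0, "event_cf"].to_numpy(int))
            if stab:
                for c in V_COLUMNS:
                    df[c] = pit[c].to_numpy(float)
                fit = fit_rp(df, weights=wt["weight"].to_numpy(),
                             knots=ctrl_knots, covariates=V_COLUMNS)
                Xstd = (pit.groupby("id")[V_COLUMNS].first().reset_index(drop=True))
                est = rmst(fit, tstar, X=Xstd, method=m)
            else:
                fit = fit_rp(df, weights=wt["weight"].to_numpy(),
                             knots=ctrl_knots)
                est = rmst(fit, tstar, method=m)
            emit(m, est, psi=s1.psi, diag=diag)
        except Exception:
            emit(m, psi=s1.psi)
    return out


def _resample_dataset(ds: TrialDataset, rng) -> TrialDataset:
    """Cluster bootstrap: resample patients with replacement within each
    arm at the original arm sizes, relabelling ids."""
    surv = ds.survival
    picked = []
    for a in (0, 1):
        ids = surv.loc[surv["arm"] == a, "id"].to_numpy()
        picked.append(rng.choice(ids, size=ids.size, replace=True))
    picked = np.concatenate(picked)
    new_ids = np.arange(1, picked.size + 1)
    surv_i = surv.set_index("id")
    new_surv = surv_i.loc[picked].reset_index()
    new_surv["id"] = new_ids
    vis_g = dict(tuple(ds.visits.groupby("id")))
    frames = []
    for nid, oid in zip(new_ids, picked):
        v = vis_g[oid].copy()
        v["id"] = nid
        frames.append(v)
    new_vis = pd.concat(frames, ignore_index=True)
    pats = None
    if ds.patients is not None:
        pat_i = ds.patients.set_index("id")
        pats = pat_i.loc[picked].reset_index()
        pats["id"] = new_ids
    return TrialDataset(survival=new_surv, visits=new_vis, patients=pats,
                       params=ds.params)


def bootstrap_ci(noswitch: TrialDataset, switched: TrialDataset, method: str,
                 B: int = 200, seed=0, tstar: float = 548.0,
                 stabilised: bool = False):
    """Percentile bootstrap CI for one method's control-arm RMST.

    Patients are resampled with replacement, clustered by patient and
    stratified by arm, and the entire adjustment pipeline reruns per
    sample.  Returns (2.5th, 97.5th) percentiles over converged samples;
    more than 50% non-convergence invalidates the interval.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap samples")
    rng = np.random.default_rng(seed)
    vals = []
    for b in range(B):
        ns_b = _resample_dataset(noswitch, rng) if method == "NoSwitching" \
            else noswitch
        sw_b = _resample_dataset(switched, rng) if method != "NoSwitching" \
            else switched
        ests = estimate_all_methods(ns_b, sw_b, sim=b, tstar=tstar,
                                    stabilised=stabilised, methods=[method])
        est = ests[0]
        vals.append(est.rmst if est.converged else np.nan)
    vals = np.asarray(vals, dtype=float)
    ok = np.isfinite(vals)
    if ok.mean() < 0.5:
        return np.nan, np.nan, False
    lo, hi = np.percentile(vals[ok], [2.5, 97.5])
    return float(lo), float(hi), True


def summarise_performance(estimates: pd.DataFrame, true_rmst: float,
                          max_weight_filter: float | None = None
                          ) -> pd.DataFrame:
    """Per-method performance summary over converged replicates.

    Percent bias = (mean RMST - truth)/truth x 100; empirical SE is the
    sample SD of per-replicate percent bias; RMSE is the bias/empSE
    quadrature sum (the decomposition used for the tabulated triples);
    coverage is the share of intervals containing the truth, over
    replicates with an interval.  Monte-Carlo SEs: empSE/sqrt(n) for
    bias, empSE/sqrt(2(n-1)) for empSE, sqrt(c(1-c)/n)*100 for coverage.
    An optional filter drops replicates whose maximum weight exceeds the
    threshold before summarising.
    """
    if isinstance(estimates, list):
        estimates = pd.DataFrame([asdict(e) for e in estimates])
    rows = []
    for method, grp in estimates.groupby("method", sort=False):
        n_all = len(grp)
        if max_weight_filter is not None and grp["max_weight"].notna().any():
            grp = grp[~(grp["max_weight"] > max_weight_filter)]
        conv = grp[grp["converged"] & np.isfinite(grp["rmst"])]
        n = len(conv)
        if n < 2:
            rows.append({"method": method, "n_converged": n,
                         "convergence_pct": 100.0 * n / max(n_all, 1),
                         "flag": "too few converged replicates"})
            continue
        pb = (conv["rmst"].to_numpy(float) - true_rmst) / true_rmst * 100.0
        bias = float(pb.mean())
        emp_se = float(pb.std(ddof=1))
        rmse = math.sqrt(bias ** 2 + emp_se ** 2)
        rec = {
            "method": method, "n_converged": n,
            "pct_bias": bias, "emp_se": emp_se, "rmse": rmse,
            "convergence_pct": 100.0 * n / n_all,
            "bias_mcse": emp_se / math.sqrt(n),
            "emp_se_mcse": emp_se / math.sqrt(2.0 * (n - 1)),
        }
        has_ci = conv[np.isfinite(conv["ci_low"]) & np.isfinite(conv["ci_high"])]
        if len(has_ci):
            c = float(((has_ci["ci_low"] <= true_rmst)
                       & (true_rmst <= has_ci["ci_high"])).mean())
            rec["coverage_pct"] = 100.0 * c
            rec["coverage_mcse"] = 100.0 * math.sqrt(
                c * (1.0 - c) / len(has_ci))
        if grp["weight_cv"].notna().any():
            rec["mean_weight_cv"] = float(grp["weight_cv"].mean())
            rec["mean_weight_cv_terminal"] = float(
                grp["weight_cv_terminal"].mean())
            rec["prop_max_gt_100"] = float((grp["max_weight"] > 100).mean())
            rec["prop_max_gt_1000"] = float((grp["max_weight"] > 1000).mean())
        rows.append(rec)
    return pd.DataFrame(rows)
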