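"""Two-stage estimation (TSE) of the switching effect and counterfactual
survival-time reconstruction.

Stage 1 fits a Weibull accelerated-failure-time model to post-progression
follow-up in progressed control patients, with the switch indicator as a
time-dependent covariate: a patient who switches at offset *s* (days from
the secondary baseline) contributes the likelihood of the back-transformed
time ``u(t) = min(t, s) + exp(psi) * max(0, t - s)``, with a Jacobian
factor ``exp(psi)`` on post-switch event densities.  ``exp(-psi)`` is the
time ratio associated with switching (values above 1 mean switching
extends survival).

Stage 2 maps each control patient's observed time to the counterfactual
scale, ``U = T_A + exp(psi) * T_B``, for events and censorings alike; the
optional re-censoring operator then censors every control patient at
``D* = min(C, C * exp(psi))`` to remove the informative censoring that the
transform induces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import TrialDataset

__all__ = ["Stage1Fit", "build_secondary_baseline", "fit_stage1",
           "counterfactual_times", "recensor"]

#: stage-1 covariates measured at (or before) the secondary baseline
STAGE1_COVARIATES = ["badprog", "biomarker0", "obs_prog_day", "biomarker_prog"]


@dataclass
class Stage1Fit:
    psi: float
    se_psi: float
    coef: dict
    weibull_shape: float
    converged: bool
    loglik: float


def build_secondary_baseline(dataset: TrialDataset) -> pd.DataFrame:
    """Secondary-baseline table: one row per progressed control patient.

    Columns: ``t`` post-progression follow-up (days from the observed
    progression visit), ``event``, ``s`` switch offset (NaN for
    non-switchers) and the stage-1 covariates (baseline prognosis group,
    observed biomarker at day 0, observed time-to-progression, observed
    biomarker at the progression visit).
    """
    surv = dataset.survival
    visits = dataset.visits
    prog = (visits[visits["progression_observed"] == 1]
            .groupby("id")["day"].min().rename("obs_prog_day"))
    bm0 = (visits[visits["day"] == 0].set_index("id")["biomarker"]
           .rename("biomarker0"))
    bm_at = visits.set_index(["id", "day"])["biomarker"]

    df = surv[surv["arm"] == 0].merge(prog, on="id", how="inner")
    df = df.merge(bm0, on="id", how="left")
    df["biomarker_prog"] = [
        bm_at.get((i, d), np.nan)
        for i, d in zip(df["id"], df["obs_prog_day"])]
    if df[["biomarker0", "biomarker_prog"]].isna().any().any():
        raise ValueError("missing biomarker at baseline or progression visit")
    df["t"] = df["time"] - df["obs_prog_day"]
    df["s"] = df["switch_day"] - df["obs_prog_day"]
    df = df[df["t"] > 0].reset_index(drop=True)
    bad = df["s"].notna() & (df["s"] >= df["t"])
    if bad.any():
        raise ValueError("switch offset at or beyond follow-up time")
    return df[["id", "t", "event", "s"] + STAGE1_COVARIATES]


def _stage1_negll_grad(par, t, d, s_off, post_any, Z):
    """Negative log-likelihood and gradient of the stage-1 Weibull AFT.

    Parameter vector: (psi, mu, log_shape, theta...).  ``u`` is the
    back-transformed post-progression time; events carry ``ln h(u) +
    psi*[t>s]`` (density Jacobian), censorings carry ``ln S(u)``.
    """
    psi, mu, logk = par[0], par[1], par[2]
    theta = par[3:]
    k = math.exp(logk)
    ep = math.exp(psi)
    tb = np.where(post_any, t - s_off, 0.0)          # post-switch exposure
    ta = np.where(post_any, s_off, t)
    u = ta + ep * tb
    ub = ep * tb
    lin = mu + Z @ theta
    z = k * (np.log(u) - lin)
    ez = np.exp(z)
    post = post_any.astype(float)

    ll = np.sum(d * (logk - np.log(u) + psi * post) + d * z - ez)

    r = d - ez                                       # score common factor
    ub_over_u = ub / u
    g_psi = np.sum(d * (-ub_over_u + post) + r * k * ub_over_u)
    g_mu = -k * np.sum(r)
    g_logk = np.sum(d + r * z)
    g_theta = -k * (Z.T @ r)
    grad = np.concatenate([[g_psi, g_mu, g_logk], g_theta])
    return -ll, -grad


def fit_stage1(data: pd.DataFrame,
               covariates: list[str] | None = None) -> Stage1Fit:
    """Fit the stage-1 Weibull AFT with a time-dependent switch indicator.

    Runs a quasi-Newton optimiser from multiple starting values of psi
    ({-0.5, 0, 0.5}) and reports the best; the model-based SE of psi comes
    from a finite-difference Hessian at the optimum.  A dataset with no
    switchers leaves psi undefined and is flagged non-converged.
    """
    covariates = STAGE1_COVARIATES if covariates is None else covariates
    t = data["t"].to_numpy(float)
    d = data["event"].to_numpy(float)
    s = data["s"].to_numpy(float)
    switched = np.isfinite(s)
    if not switched.any() or not (~switched).any():
        return Stage1Fit(np.nan, np.nan, {}, np.nan, False, np.nan)
    if d.sum() < 2:
        return Stage1Fit(np.nan, np.nan, {}, np.nan, False, np.nan)
    s_off = np.where(switched, s, np.inf)
    post_any = switched & (t > s_off)

    Zraw = data[covariates].to_numpy(float)
    zm, zs = Zraw.mean(0), Zraw.std(0)
    zs[zs == 0] = 1.0
    Z = (Zraw - zm) / zs

    args = (t, d, s_off, post_any, Z)
    best = None
    for psi0 in (-0.5, 0.0, 0.5):
        x0 = np.concatenate([[psi0, np.log(np.median(t)), 0.0],
                             np.zeros(Z.shape[1])])
        res = optimize.minimize(_stage1_negll_grad, x0, args=args, jac=True,
                                method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    res = best
    grad_ok = np.linalg.norm(res.jac) < 1e-3 * max(1.0, abs(res.fun))
    converged = bool(res.success or grad_ok)

    # model-based SE via central-difference Hessian of the negative ll
    se_psi = np.nan
    try:
        hess = _numeric_hessian(lambda p: _stage1_negll_grad(p, *args)[0], res.x)
        cov = np.linalg.inv(hess)
        if cov[0, 0] > 0:
            se_psi = math.sqrt(cov[0, 0])
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    theta_orig = res.x[3:] / zs                      # undo standardisation
    coef = dict(zip(covariates, theta_orig))
    return Stage1Fit(psi=float(res.x[0]), se_psi=float(se_psi), coef=coef,
                     weibull_shape=float(math.exp(res.x[2])),
                     converged=converged, loglik=float(-res.fun))


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    hs = eps * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += hs[i]; xpp[j] += hs[j]
            xpm = x.copy(); xpm[i] += hs[i]; xpm[j] -= hs[j]
            xmp = x.copy(); xmp[i] -= hs[i]; xmp[j] += hs[j]
            xmm = x.copy(); xmm[i] -= hs[i]; xmm[j] -= hs[j]
            H[i, j] = H[j, i] = ((f(xpp) - f(xpm) - f(xmp) + f(xmm))
                                 / (4.0 * hs[i] * hs[j]))
    return H


def counterfactual_times(survival: pd.DataFrame, psi: float) -> pd.DataFrame:
    """Map observed control-arm times to the counterfactual scale.

    Switchers (events and censorings alike) get ``U = T_A + exp(psi)*T_B``
    with ``T_A`` the time from randomisation to switch and ``T_B`` the
    remaining observed time; non-switchers keep their observed time.
    Experimental-arm rows pass through unchanged.  Adds columns ``U``,
    ``event_cf``, ``recensored`` and ``psi_used``.
    """
    out = survival.copy()
    ctrl = out["arm"] == 0
    sw = ctrl & (out["switched"] == 1)
    tb = out.loc[sw, "time"] - out.loc[sw, "switch_day"]
    if (tb < 0).any():
        raise ValueError("negative post-switch time")
    out["U"] = out["time"].astype(float)
    out.loc[sw, "U"] = out.loc[sw, "switch_day"] + math.exp(psi) * tb
    out["event_cf"] = out["event"].astype(int)
    out["recensored"] = False
    out["psi_used"] = psi
    return out


def recensor(cf: pd.DataFrame, psi: float,
             admin_censor: pd.Series) -> pd.DataFrame:
    """Re-censor every control patient at D* = min(C, C*exp(psi)).

    ``admin_censor`` maps patient id to the administrative censoring time
    C.  Where D* falls below the counterfactual time the record becomes a
    censoring at D*; nothing is ever lengthened and no censoring becomes
    an event.
    """
    out = cf.copy()
    ctrl = out["arm"] == 0
    C = out.loc[ctrl, "id"].map(admin_censor)
    if C.isna().any():
        raise ValueError("missing administrative censoring time for some patients")
    dstar = np.minimum(C, C * math.exp(psi))
    hit = out.loc[ctrl].index[dstar.to_numpy() < out.loc[ctrl, "U"].to_numpy()]
    out.loc[hit, "U"] = dstar.loc[hit]
    out.loc[hit, "event_cf"] = 0
    out.loc[hit, "recensored"] = True
    return out
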