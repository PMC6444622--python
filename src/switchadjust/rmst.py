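"""Flexible parametric survival modelling on the log cumulative hazard
scale and restricted mean survival time (RMST).

The model is ln H(t) = s(ln t) [+ X beta], with s a restricted cubic
spline: boundary knots at the log of the smallest and largest uncensored
times and (by default) 3 interior knots at the 25th/50th/75th centiles of
the log uncensored times.  Because the spline is linear beyond the
boundary knots, survivor prediction past the last knot is a linear
extrapolation of log cumulative hazard in log time.  Fitting maximises
the (optionally weighted, optionally left-truncated) log likelihood

    sum_i w_i [ d_i ln h(t_i) - H(t_i) + H(t0_i) ]

and RMST at t* is the integral of the fitted survivor function over
[0, t*] by adaptive quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .splines import rcs_basis, rcs_basis_deriv, knots_from_quantiles

__all__ = ["RPKnots", "RPFit", "RMSTEstimate", "make_knots", "fit_rp",
           "predict_survival", "rmst"]

log = logging.getLogger(__name__)


@dataclass
class RPKnots:
    """Spline knots on the log-time scale."""

    knots: np.ndarray              # increasing, >= 2, includes boundaries

    @property
    def boundary(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def n_interior(self) -> int:
        return max(0, self.knots.size - 2)


def make_knots(times, events, n_interior: int = 3,
               interior_on: str = "uncensored") -> RPKnots:
    """Knot placement: boundaries at log min/max of uncensored times,
    interior knots at equally spaced centiles of the log survival times.

    ``interior_on`` selects whether the interior-centile distribution is
    the uncensored times (default, consistent with the boundary rule) or
    all times.  With too few distinct uncensored times the interior count
    is reduced, with a logged warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    unc = times[events]
    if np.unique(unc).size < 2:
        raise ValueError("need at least 2 distinct uncensored times")
    if interior_on == "uncensored":
        pool = unc
    elif interior_on == "all":
        pool = times
    else:
        raise ValueError("interior_on must be 'uncensored' or 'all'")
    logu = np.log(unc)
    for ni in range(n_interior, -1, -1):
        if ni < n_interior:
            log.warning("reducing interior knots to %d (ties)", ni)
        q = [(j + 1) / (ni + 1) for j in range(ni)]
        try:
            knots = knots_from_quantiles(np.log(pool), q)
            knots = np.unique(np.concatenate([[logu.min()], knots[1:-1],
                                              [logu.max()]]))
            if np.all(np.diff(knots) > 1e-12) and knots.size >= 2:
                return RPKnots(knots=knots)
        except ValueError:
            continue
    raise ValueError("could not place strictly increasing knots")


@dataclass
class RPFit:
    knots: RPKnots
    coef: np.ndarray               # intercept + spline columns
    cov_coef: np.ndarray | None
    covariate_names: list = field(default_factory=list)
    covariate_coef: np.ndarray = field(default_factory=lambda: np.zeros(0))
    loglik: float = np.nan
    converged: bool = False


def _spline_terms(logt, knots: RPKnots):
    # cubic columns are rescaled by the squared boundary span, which keeps
    # the design well conditioned for quasi-Newton fitting
    kn = knots.knots
    scale = max((kn[-1] - kn[0]) ** 2, 1e-8)
    B = rcs_basis(logt, kn)
    dB = rcs_basis_deriv(logt, kn)
    B[:, 1:] /= scale
    dB[:, 1:] /= scale
    return (np.column_stack([np.ones(len(logt)), B]),
            np.column_stack([np.zeros(len(logt)), dB]))


def _rp_negll_grad(par, Bstop, dBstop, d, w, Bstart, has_start, X):
    p_spl = Bstop.shape[1]
    beta = par[:p_spl]
    bx = par[p_spl:]
    eta = Bstop @ beta + (X @ bx if X is not None else 0.0)
    ds = dBstop @ beta                      # d s / d ln t (spline part only)
    if np.any(ds[d > 0] <= 1e-12):
        return np.inf, np.zeros_like(par)
    with np.errstate(over="ignore"):
        H = np.exp(np.minimum(eta, 500.0))
    ll = np.sum(w * (d * (eta + np.log(np.where(d > 0, ds, 1.0))) - H))
    gH = w * (d - H)
    g_beta = Bstop.T @ gH + dBstop.T @ (w * d / np.where(ds > 0, ds, 1.0))
    g_bx = X.T @ gH if X is not None else np.zeros(0)
    if has_start is not None:
        eta0 = Bstart @ beta + (X[has_start] @ bx if X is not None else 0.0)
        H0 = np.exp(np.minimum(eta0, 500.0))
        w0 = w[has_start]
        ll += np.sum(w0 * H0)
        g_beta += Bstart.T @ (w0 * H0)
        if X is not None:
            g_bx += X[has_start].T @ (w0 * H0)
    return -ll, -np.concatenate([g_beta, g_bx])


def _init_coef(df, knots: RPKnots, w):
    """Starting values from a weighted Nelson-Aalen estimate regressed on
    the spline basis at event times."""
    stop = df["stop"].to_numpy(float)
    start = df.get("start", pd.Series(np.zeros(len(df)))).to_numpy(float)
    d = df["event"].to_numpy(float)
    order = np.argsort(stop, kind="stable")
    H = {}
    cum = 0.0
    ts, ds_, ws_, ss_ = stop[order], d[order], w[order], start[order]
    for i, t in enumerate(ts):
        if ds_[i] > 0:
            at_risk = np.sum(ws_[(ss_ < t) & (ts >= t)])
            if at_risk > 0:
                cum += ws_[i] / at_risk
                H[t] = cum
    tt = np.array(sorted(H))
    if tt.size < 2:
        return None
    y = np.log(np.array([H[t] for t in tt]))
    B, _ = _spline_terms(np.log(tt), knots)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return coef


def fit_rp(surv_data: pd.DataFrame, weights=None, knots: RPKnots | None = None,
           covariates: list[str] | None = None) -> RPFit:
    """Fit the spline-on-log-cumulative-hazard model.

    ``surv_data`` needs columns ``stop`` (or ``time``) and ``event``;
    an optional ``start`` column gives left-truncated (person-interval)
    rows, which is how time-varying censoring weights enter.  ``weights``
    defaults to 1.  Optional ``covariates`` act proportionally on the
    log cumulative hazard (used for stabilised-weight analyses).
    Non-convergence is retried from perturbed starts and flagged.
    """
    df = surv_data.copy()
    if "stop" not in df.columns:
        df = df.rename(columns={"time": "stop"})
    if (df["stop"] <= 0).any():
        raise ValueError("all survival times must be positive")
    w = (np.ones(len(df)) if weights is None
         else np.asarray(weights, dtype=float))
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if knots is None:
        knots = make_knots(df["stop"].to_numpy(), df["event"].to_numpy())

    d = df["event"].to_numpy(float)
    Bstop, dBstop = _spline_terms(np.log(df["stop"].to_numpy(float)), knots)
    if "start" in df.columns and (df["start"].to_numpy(float) > 0).any():
        start = df["start"].to_numpy(float)
        has_start = start > 0
        Bstart, _ = _spline_terms(np.log(start[has_start]), knots)
    else:
        has_start, Bstart = None, None
    X = df[covariates].to_numpy(float) if covariates else None

    args = (Bstop, dBstop, d, w, Bstart, has_start, X)
    x0 = _init_coef(df, knots, w)
    if x0 is None:
        x0 = np.zeros(Bstop.shape[1])
        x0[1] = 1.0
    if covariates:
        x0 = np.concatenate([x0, np.zeros(len(covariates))])
    if not np.isfinite(_rp_negll_grad(x0, *args)[0]):
        # spline init infeasible (negative slope at an event time): drop to
        # the Weibull-like linear-in-log-time start, which always is
        x0lin = np.zeros_like(x0)
        x0lin[:2] = _init_coef(df, RPKnots(knots.knots[[0, -1]]), w) \
            if knots.knots.size > 2 else x0[:2]
        x0lin[1] = max(x0lin[1], 0.1)
        x0 = x0lin

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        start_par = x0 if attempt == 0 else x0 * (1 + 0.05 * rng.standard_normal(x0.size))
        res = optimize.minimize(_rp_negll_grad, start_par, args=args, jac=True,
                                method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.fun < np.inf and res.success:
            break
    converged = best is not None and np.isfinite(best.fun) and (
        best.success or np.linalg.norm(best.jac) < 1e-3 * max(1.0, abs(best.fun)))

    p_spl = Bstop.shape[1]

    # the fitted cumulative hazard must be non-decreasing over the data
    # range; if the unconstrained optimum wiggles below zero slope in a
    # sparse region, refit as a constrained ML problem on that boundary
    lo, hi = float(df["stop"].min()), float(df["stop"].max())
    _, dBg = _spline_terms(np.log(np.linspace(lo, hi, 200)), knots)
    dBg_full = np.hstack([dBg, np.zeros((dBg.shape[0], len(covariates or [])))])
    if converged and np.any(dBg_full @ best.x < -1e-8):
        cons = {"type": "ineq", "fun": lambda b: dBg_full @ b,
                "jac": lambda b: dBg_full}
        start_c = best.x if np.isfinite(_rp_negll_grad(best.x, *args)[0]) else x0
        resc = optimize.minimize(_rp_negll_grad, start_c, args=args, jac=True,
                                 method="SLSQP", constraints=[cons],
                                 options={"maxiter": 300, "ftol": 1e-10})
        if np.isfinite(resc.fun) and np.all(dBg_full @ resc.x >= -1e-6):
            best = resc
        else:
            converged = False

    coef = best.x[:p_spl] if best is not None else np.full(p_spl, np.nan)
    fit = RPFit(knots=knots, coef=coef, cov_coef=None,
                covariate_names=list(covariates) if covariates else [],
                covariate_coef=best.x[p_spl:] if best is not None else np.zeros(0),
                loglik=float(-best.fun) if best is not None else np.nan,
                converged=bool(converged))
    return fit


def _loghaz_eta(fit: RPFit, t, xrow=None):
    logt = np.log(np.atleast_1d(np.asarray(t, dtype=float)))
    B, _ = _spline_terms(logt, fit.knots)
    eta = B @ fit.coef
    if xrow is not None and fit.covariate_coef.size:
        eta = eta + np.asarray(xrow, dtype=float) @ fit.covariate_coef
    return eta


def predict_survival(fit: RPFit, t, xrow=None):
    """S(t) = exp(-exp(s(ln t))); S(0) = 1 by convention.  Beyond the
    boundary knots the spline continues linearly, giving the log-time
    linear extrapolation of the log cumulative hazard."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.ones_like(t_arr)
    pos = t_arr > 0
    if pos.any():
        eta = _loghaz_eta(fit, t_arr[pos], xrow)
        out[pos] = np.exp(-np.exp(np.minimum(eta, 500.0)))
    return out if np.ndim(t) else float(out[0])


@dataclass
class RMSTEstimate:
    method: str
    rmst: float
    tstar: float
    converged: bool
    ci_low: float = np.nan
    ci_high: float = np.nan


def rmst(fit: RPFit, tstar: float = 548.0, X: pd.DataFrame | None = None,
         method: str = "", epsabs: float = 0.01) -> RMSTEstimate:
    """RMST at t* by adaptive quadrature of the fitted survivor function.

    With baseline covariates in the model, the marginal RMST is obtained
    by regression standardisation: the survivor function is averaged over
    the empirical covariate distribution ``X`` before integrating.
    """
    if not fit.converged:
        return RMSTEstimate(method=method, rmst=np.nan, tstar=tstar,
                            converged=False)
    if fit.covariate_names and X is None:
        raise ValueError("covariate model needs X for standardisation")
    if fit.covariate_names:
        Xm = X[fit.covariate_names].to_numpy(float)

        def surv(t):
            eta = _loghaz_eta(fit, [t])[0] - fit.coef[0]
            etas = fit.coef[0] + eta + Xm @ fit.covariate_coef
            return float(np.mean(np.exp(-np.exp(np.minimum(etas, 500.0)))))
    else:
        def surv(t):
            return predict_survival(fit, t)

    val, _ = integrate.quad(surv, 0.0, tstar, epsabs=epsabs, limit=200)
    return RMSTEstimate(method=method, rmst=float(val), tstar=tstar,
                        converged=True)
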