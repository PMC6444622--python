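"""Inverse probability of censoring weighting on the counterfactual
control-arm dataset.

Follow-up is split into 21-day person-intervals and discrete-time pooled
logistic models predict censoring in each interval: the denominator model
conditions on a restricted-cubic-spline of interval start time, baseline
covariates V (prognosis group, biomarker at day 0) and time-updated
covariates L(k) (progression indicator, observed time-to-progression,
latest biomarker); the numerator model (stabilised weights only) drops
L(k).  All censoring on the counterfactual scale — switchers and
non-switchers — is treated as potentially informative.  Treatment history
is omitted: every counterfactual control record is untreated by
construction.  Weights are the cumulative products of interval ratios of
uncensored probabilities; unstabilised weights use numerator 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import rcs_basis, knots_from_quantiles

__all__ = ["CensoringModels", "WeightDiagnostics", "expand_to_intervals",
           "time_spline_basis", "make_censoring_knots",
           "fit_censoring_models", "compute_weights", "weight_diagnostics"]

V_COLUMNS = ["badprog", "biomarker0"]
L_COLUMNS = ["progressed", "obs_prog_day", "biomarker_k"]


def expand_to_intervals(cf: pd.DataFrame, visits: pd.DataFrame,
                        width: float = 21.0) -> pd.DataFrame:
    """Expand counterfactual control records into person-interval rows.

    Each patient contributes intervals k = 0..ceil(U/width)-1; the terminal
    interval carries the censoring indicator (if the counterfactual record
    is censored) or the death indicator.  Counterfactual times are not
    rounded: the terminal interval is simply the one containing U.
    Time-updated covariates use the last consultation at or before the
    interval start; pre-progression rows code time-to-progression as 0
    with the progression indicator carrying the information.
    """
    ctrl = cf[cf["arm"] == 0]
    if (ctrl["U"] <= 0).any():
        raise ValueError("non-positive counterfactual time")
    ids = ctrl["id"].to_numpy()
    U = ctrl["U"].to_numpy(float)
    ev = ctrl["event_cf"].to_numpy(int)
    K = np.ceil(U / width).astype(int)
    K[K == 0] = 1

    rid = np.repeat(ids, K)
    rk = np.concatenate([np.arange(k) for k in K])
    rU = np.repeat(U, K)
    rev = np.repeat(ev, K)
    start = rk * width
    stop = np.minimum(start + width, rU)
    last = np.concatenate([np.arange(k) == k - 1 for k in K])
    rows = pd.DataFrame({
        "id": rid, "k": rk, "start": start, "stop": stop,
        "censored": (last & (rev == 0)).astype(int),
        "died": (last & (rev == 1)).astype(int),
    })

    vis = visits[visits["id"].isin(ids)].sort_values(["id", "day"])
    bm0 = vis[vis["day"] == 0].set_index("id")["biomarker"]
    if not set(ids).issubset(bm0.index):
        raise ValueError("missing day-0 biomarker for some control patients")
    prog_day = (vis[vis["progression_observed"] == 1]
                .groupby("id")["day"].min())
    bad = cf.set_index("id")["badprog"]

    rows["badprog"] = rows["id"].map(bad).astype(float)
    rows["biomarker0"] = rows["id"].map(bm0)
    pd_ = rows["id"].map(prog_day)
    rows["progressed"] = (pd_.notna() & (pd_ <= rows["start"])).astype(float)
    rows["obs_prog_day"] = np.where(rows["progressed"] == 1, pd_, 0.0)
    # carry the latest biomarker observation forward to the interval start
    right = (vis[["id", "day", "biomarker"]]
             .rename(columns={"day": "start", "biomarker": "biomarker_k"})
             .sort_values("start", kind="stable"))
    rows = pd.merge_asof(rows.sort_values("start", kind="stable"), right,
                         on="start", by="id", direction="backward")
    if rows["biomarker_k"].isna().any():
        raise ValueError("covariate gap: no biomarker observation at or "
                         "before some interval start")
    return (rows.sort_values(["id", "k"], kind="stable")
            .reset_index(drop=True))


def make_censoring_knots(censoring_times) -> np.ndarray:
    """Spline knots for interval time: boundaries at min/max of the
    censoring times, interior knots at their 33rd and 67th centiles."""
    ct = np.asarray(censoring_times, dtype=float)
    if np.unique(ct).size < 2:
        raise ValueError("need at least 2 distinct censoring times")
    return knots_from_quantiles(ct, [0.33, 0.67])


def time_spline_basis(t, censoring_times) -> np.ndarray:
    """Restricted cubic spline basis of time with the censoring-knot rule."""
    return rcs_basis(t, make_censoring_knots(censoring_times))


@dataclass
class CensoringModels:
    knots: np.ndarray
    denominator: object | None
    numerator: object | None          # None for unstabilised weights
    stabilised: bool
    converged: bool
    degenerate: bool = False          # no censoring events at all
    den_columns: list = field(default_factory=list)
    num_columns: list = field(default_factory=list)


def _design(pit: pd.DataFrame, knots, columns) -> np.ndarray:
    tb = rcs_basis(pit["start"].to_numpy(float), knots)
    X = np.column_stack([np.ones(len(pit)), tb, pit[columns].to_numpy(float)])
    return X


def _fit_pooled_logistic(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
        except Exception:
            return None, False
    ok = (res.converged and np.all(np.isfinite(res.params))
          and np.max(np.abs(res.params)) < 50.0)
    return res, bool(ok)


def fit_censoring_models(pit: pd.DataFrame,
                         stabilised: bool = False) -> CensoringModels:
    """Fit pooled logistic censoring models to the person-interval table.

    With no censoring events the models are degenerate (predicted
    censoring probability 0, all weights 1) — flagged but converged.
    Separation or IRLS failure marks the run non-converged.
    """
    y = pit["censored"].to_numpy(float)
    if y.sum() == 0:
        return CensoringModels(knots=np.array([0.0, 1.0]), denominator=None,
                               numerator=None, stabilised=stabilised,
                               converged=True, degenerate=True)
    # knot rule: censoring times on the counterfactual scale
    cens_times = pit.loc[pit["censored"] == 1, "stop"].to_numpy(float)
    if np.unique(cens_times).size < 2:
        knots = np.array([pit["start"].min(), pit["stop"].max()])
    else:
        knots = make_censoring_knots(cens_times)
    Xd = _design(pit, knots, V_COLUMNS + L_COLUMNS)
    den, ok_d = _fit_pooled_logistic(y, Xd)
    num, ok_n = None, True
    if stabilised:
        Xn = _design(pit, knots, V_COLUMNS)
        num, ok_n = _fit_pooled_logistic(y, Xn)
    return CensoringModels(knots=knots, denominator=den, numerator=num,
                           stabilised=stabilised,
                           converged=bool(ok_d and ok_n),
                           den_columns=V_COLUMNS + L_COLUMNS,
                           num_columns=V_COLUMNS)


def compute_weights(models: CensoringModels, pit: pd.DataFrame) -> pd.DataFrame:
    """Cumulative inverse probability of censoring weights per interval.

    W(k) = prod_{j<=k} Pr_num(uncensored at j) / Pr_den(uncensored at j);
    the numerator probability is 1 for unstabilised weights.
    """
    out = pit[["id", "k", "start", "stop", "censored", "died"]].copy()
    if models.degenerate:
        out["factor"] = 1.0
        out["weight"] = 1.0
        return out
    if not models.converged or models.denominator is None:
        raise ValueError("censoring models did not converge")
    p_den = models.denominator.predict(_design(pit, models.knots,
                                               models.den_columns))
    if models.stabilised:
        p_num = models.numerator.predict(_design(pit, models.knots,
                                                 models.num_columns))
    else:
        p_num = np.zeros_like(p_den)
    with np.errstate(divide="ignore", over="ignore"):
        factor = (1.0 - p_num) / (1.0 - p_den)
    out["factor"] = factor
    out["weight"] = out.groupby("id")["factor"].cumprod()
    if not np.all(np.isfinite(out["weight"])):
        raise ValueError("non-finite inverse probability weights")
    return out


@dataclass
class WeightDiagnostics:
    cv: float                  # over person-interval cumulative weights
    cv_terminal: float         # over per-patient terminal weights
    max_weight: float
    max_gt_100: bool
    max_gt_1000: bool


def weight_diagnostics(wt: pd.DataFrame) -> WeightDiagnostics:
    """Coefficient of variation (sample SD / mean) and maximum of the
    cumulative weights, over all person-intervals and over per-patient
    terminal weights."""
    if len(wt) == 0:
        raise ValueError("empty weight table")
    w = wt["weight"].to_numpy(float)
    term = wt.groupby("id")["weight"].last().to_numpy(float)

    def cv(x):
        return float(np.std(x, ddof=1) / np.mean(x)) if x.size > 1 else 0.0

    mx = float(w.max())
    return WeightDiagnostics(cv=cv(w), cv_terminal=cv(term), max_weight=mx,
                             max_gt_100=mx > 100.0, max_gt_1000=mx > 1000.0)
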