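"""Scenario definitions for the treatment-switching simulation study.

A scenario bundles every generative parameter of one simulated trial:
the longitudinal biomarker model, the mixture-Weibull survival model and
its linear predictor, the trial-design constants (size, allocation,
visit grid, staggered entry, administrative censoring) and the switching
mechanism.  Scenarios are stored as flat YAML key-value files, one file
per scenario; the files shipped with the package live in
``switchadjust/configs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ScenarioParams", "load_scenario", "save_scenario", "shipped_scenario",
           "list_shipped_scenarios"]


@dataclass(frozen=True)
class ScenarioParams:
    """Generative parameters of one simulation scenario.

    Longitudinal biomarker model (units are biomarker units and days):
    the underlying biomarker of patient *i* at time *t* is
    ``b0i + beta1*t + beta2*t*trt + beta3*badprog`` with random intercept
    ``b0i ~ N(beta0, sigma0_sq)``; observed values add independent
    ``N(0, sigma_err**2)`` measurement error on the 21-day visit grid.

    Survival model: baseline survival is a two-component mixture Weibull
    ``S0(t) = p*exp(-lambda1*t**gamma1) + (1-p)*exp(-lambda2*t**gamma2)``
    and the patient hazard multiplies the baseline hazard by
    ``exp(delta1*trt + eta*t*trt + delta2*badprog + alpha*biomarker(t))``
    using the error-free biomarker.

    Switching: control-arm patients may start the experimental therapy
    at one of ``n_switch_visits`` consultations from the visit at which
    progression is first observed, with per-visit probability
    ``logistic(switch_logit . [1, observed progression day, observed
    biomarker at the progression visit])``.  A switcher at day *s* has
    survival time ``s + omega*(T - s)`` where *T* is the latent
    no-switching time.
    """

    # biomarker model
    beta0: float = 20.0
    sigma0_sq: float = 1.0
    beta1: float = 0.04
    beta2: float = -0.02
    beta3: float = 2.5
    sigma_err: float = 1.0
    # survival linear predictor
    delta1: float = -1.30
    delta2: float = 0.3
    alpha: float = 0.01
    eta: float = 0.003
    # mixture-Weibull baseline
    lambda1: float = 1e-5
    gamma1: float = 2.0
    lambda2: float = 1e-5
    gamma2: float = 0.8
    mixp: float = 0.5
    # switching benefit (time multiplier applied post-switch)
    omega: float = 1.53
    # trial design
    badprog_prev: float = 0.5
    n_patients: int = 500
    alloc_ratio: float = 2.0          # experimental : control
    visit_interval: float = 21.0
    entry_max: float = 183.0
    max_admin: float = 548.0
    prog_beta_a: float = 5.0
    prog_beta_b: float = 10.0
    # switching mechanism: intercept, coef on observed progression day,
    # coef on observed biomarker at the progression visit
    switch_logit: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    n_switch_visits: int = 3
    # bookkeeping
    scenario_id: str = "custom"
    provenance: str = "custom"        # "printed" | "calibrated" | "custom"

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("Weibull scale parameters must be positive")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("Weibull shape parameters must be positive")
        if not 0.0 <= self.mixp <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.omega <= 0:
            raise ValueError("switch benefit omega must be positive")
        if not 0.0 <= self.badprog_prev <= 1.0:
            raise ValueError("badprog_prev must lie in [0, 1]")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if self.entry_max >= self.max_admin:
            raise ValueError("entry_max must be below max_admin")
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients for a 2:1 trial")
        if len(self.switch_logit) != 3:
            raise ValueError("switch_logit must have 3 coefficients")

    # -- derived quantities -------------------------------------------------

    @property
    def n_experimental(self) -> int:
        """Deterministic allocation: floor(n * r / (r + 1)) experimental."""
        r = self.alloc_ratio
        return math.floor(self.n_patients * r / (r + 1.0))

    @property
    def n_control(self) -> int:
        return self.n_patients - self.n_experimental

    @property
    def psi_generative(self) -> float:
        """Log time-ratio implied by the switch benefit: psi = -ln(omega)."""
        return -math.log(self.omega)

    def with_(self, **kwargs) -> "ScenarioParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["switch_logit"] = list(self.switch_logit)
        return d


def save_scenario(params: ScenarioParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioParams:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scenario file not found: {path}")
    d = yaml.safe_load(path.read_text())
    if not isinstance(d, dict):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    d["switch_logit"] = tuple(d.get("switch_logit", (-1.0, 0.0, 0.0)))
    known = ScenarioParams.__dataclass_fields__
    unknown = set(d) - set(known)
    if unknown:
        raise ValueError(f"unknown scenario keys in {path}: {sorted(unknown)}")
    return ScenarioParams(**d)


def shipped_scenario(scenario_id: str) -> ScenarioParams:
    """Load one of the scenario files shipped inside the package."""
    ref = resources.files("switchadjust") / "configs" / f"{scenario_id}.yaml"
    with resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError(f"no shipped scenario '{scenario_id}'")
        return load_scenario(p)


def list_shipped_scenarios() -> list[str]:
    ref = resources.files("switchadjust") / "configs"
    return sorted(p.name[:-5] for p in ref.iterdir() if p.name.endswith(".yaml"))
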