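"""Multi-replicate scenario orchestration.

Runs the full pipeline — simulate, switch, estimate with every requested
method, optionally bootstrap — over ``n_sims`` replicates of one or more
scenarios, with a deterministic seed chain (per-replicate seeds are
spawned from the base seed, the scenario id and the replicate index), a
truth cache keyed by the scenario parameters, and CSV outputs for the
per-replicate estimates and the per-scenario performance summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import ScenarioParams, load_scenario
from .simulate import simulate_trial, apply_switching, true_values, TruthRecord
from .performance import estimate_all_methods, bootstrap_ci, summarise_performance

__all__ = ["RunConfig", "run_scenario", "scenario_truth"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scenario_files: list = field(default_factory=list)
    n_sims: int = 100
    base_seed: int = 1
    methods: list = field(default_factory=lambda: ["NoSwitching", "ITT",
                                                   "TSE", "TSEnr", "TSEipcw"])
    stabilised: bool = False
    bootstrap: bool = False
    bootstrap_B: int = 200
    max_weight_filters: list = field(default_factory=list)
    out_dir: str = "results"
    truth_n: int = 200_000
    tstar: float = 548.0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if self.bootstrap and self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be at least 2")


def _sim_seed(base_seed: int, scenario_id: str, sim: int, salt: int = 0):
    """Deterministic, collision-resistant per-replicate seed sequence."""
    h = int.from_bytes(hashlib.sha256(scenario_id.encode()).digest()[:4], "big")
    return np.random.SeedSequence([base_seed, h, sim, salt])


def _params_hash(params: ScenarioParams, truth_n: int, seed: int) -> str:
    blob = json.dumps({**params.to_dict(), "_N": truth_n, "_seed": seed},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def scenario_truth(params: ScenarioParams, truth_n: int, seed: int,
                   cache_dir: Path | None = None) -> TruthRecord:
    """Scenario truth, cached on disk keyed by parameters, N and seed."""
    key = _params_hash(params, truth_n, seed)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        f = cache_dir / f"truth_{key}.json"
        if f.exists():
            return TruthRecord(**json.loads(f.read_text()))
    tr = true_values(params, N=truth_n, seed=seed)
    if cache_dir is not None:
        f.write_text(json.dumps(asdict(tr)))
    return tr


def run_scenario(config: RunConfig) -> pd.DataFrame:
    """Run every configured scenario; returns the combined summary table."""
    out_dir = Path(config.out_dir)
    params_list = []
    for pf in config.scenario_files:
        params_list.append(load_scenario(pf))      # pre-flight I/O check
    out_dir.mkdir(parents=True, exist_ok=True)

    summaries = []
    for params in params_list:
        sid = params.scenario_id
        log.info("scenario %s: computing truth (N=%d)", sid, config.truth_n)
        truth = scenario_truth(params, config.truth_n,
                               int(config.base_seed),
                               cache_dir=out_dir / "cache")
        log.info("scenario %s truth: control RMST %.1f, experimental %.1f",
                 sid, truth.control_rmst, truth.experimental_rmst)

        records = []
        for sim in range(config.n_sims):
            ss = _sim_seed(config.base_seed, sid, sim)
            s_sim, s_switch, s_boot = ss.spawn(3)
            ns = simulate_trial(params, s_sim)
            sw = apply_switching(ns, params, s_switch)
            ests = estimate_all_methods(
                ns, sw, scenario=sid, sim=sim, tstar=config.tstar,
                stabilised=config.stabilised, methods=config.methods)
            if config.bootstrap:
                boot_seeds = s_boot.spawn(len(ests))
                for est, bs in zip(ests, boot_seeds):
                    if not est.converged:
                        continue
                    lo, hi, ok = bootstrap_ci(
                        ns, sw, est.method, B=config.bootstrap_B, seed=bs,
                        tstar=config.tstar, stabilised=config.stabilised)
                    if ok:
                        est.ci_low, est.ci_high = lo, hi
            records.extend(ests)
            nc = [e.method for e in ests if not e.converged]
            if nc:
                log.warning("scenario %s sim %d: non-converged: %s",
                            sid, sim, ",".join(nc))
        est_df = pd.DataFrame([asdict(e) for e in records])
        est_df.to_csv(out_dir / f"{sid}_estimates.csv", index=False)

        summ = summarise_performance(est_df, truth.control_rmst)
        summ.insert(0, "scenario", sid)
        summ.insert(1, "true_control_rmst", truth.control_rmst)
        frames = [summ]
        for thr in config.max_weight_filters:
            fs = summarise_performance(est_df, truth.control_rmst,
                                       max_weight_filter=thr)
            fs.insert(0, "scenario", sid)
            fs.insert(1, "true_control_rmst", truth.control_rmst)
            fs.insert(2, "max_weight_filter", thr)
            frames.append(fs)
        full = pd.concat(frames, ignore_index=True)
        full.to_csv(out_dir / f"{sid}_summary.csv", index=False)
        summaries.append(full)
    return pd.concat(summaries, ignore_index=True)
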