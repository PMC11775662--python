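"""Experiment campaigns: parameter perturbation, heterogeneity and imbalance.

Three preset scenarios mirror the robustness studies of the companion
analysis workflow:

``perturbation``  deterministic aggregate-model runs with the target
                  parameters redrawn per run (n=10, sigma = 0.1*nominal),
                  120 cells split equally among the populations;
``cv_sweep``      heterogeneous per-cell runs with growth/division and
                  per-division parameter redraws over a CV grid, metrics
                  on the W=60 moving-average of the mean target output;
``imbalance``     controller-fraction sweep at N=20 with growth off.

Each campaign consumes a seed and records it; replicate seeds are spawned
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hetero import (
    CONTROLLER_ACTIVATION,
    TARGET_ACTIVATION,
    ChamberConfig,
    draw_perturbed_params,
    make_consortium,
    run_hetero,
    run_imbalance,
)
from .metrics import (
    RequirementSpec,
    evaluate_run,
    moving_average,
    summarize_campaign,
)
from .model import simulate
from .params import ARCHITECTURES, ConsortiumParams, ControlGains

__all__ = [
    "CampaignResult",
    "perturbation_campaign",
    "cv_sweep_campaign",
    "imbalance_campaign",
]

_METRICS = ("e_pct", "ts", "o")


@dataclass
class CampaignResult:
    """Tidy per-run table plus per-group box-plot summaries."""

    runs: pd.DataFrame
    summary: dict
    seed: int
    kind: str

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "runs": self.runs.to_dict(orient="records"),
            "summary": self.summary,
        }


def _summaries(runs: pd.DataFrame, by: list[str]) -> dict:
    out: dict = {}
    for key, grp in runs.groupby(by):
        k = key if isinstance(key, str) else "/".join(str(x) for x in key)
        out[k] = {m: summarize_campaign(grp[m].to_numpy()) for m in _METRICS}
    return out


def perturbation_campaign(
    params: ConsortiumParams,
    gains: ControlGains,
    *,
    n: int = 10,
    cv: float = 0.10,
    seed: int = 0,
    archs=("P", "PD", "PI", "PID"),
    n_cells_total: int = 120,
    t_end: float = 2880.0,
    spec: RequirementSpec = RequirementSpec(),
) -> CampaignResult:
    """Deterministic aggregate runs with per-run perturbed target parameters."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for lab in archs:
        arch = ARCHITECTURES[lab]
        p_arch = params.with_(N=max(1, n_cells_total // arch.M))
        rng = np.random.default_rng(ss.spawn(1)[0])
        for k in range(n):
            p_run = draw_perturbed_params(p_arch, cv, rng, TARGET_ACTIVATION)
            traj = simulate("full", p_run, gains, arch, (0.0, t_end), dt=2.0)
            y = traj.output(p_run)
            rep = evaluate_run(traj.times, y, p_run.mu * p_run.Yd, spec)
            rows.append({
                "arch": lab, "run": k,
                "e_pct": rep.e_inf * 100.0, "ts": rep.ts, "o": rep.o,
                "y_inf": rep.y_inf, "passed": rep.passed,
            })
    runs = pd.DataFrame(rows)
    return CampaignResult(runs, _summaries(runs, ["arch"]), seed, "perturbation")


def cv_sweep_campaign(
    params: ConsortiumParams,
    gains: ControlGains,
    *,
    cv_grid=(0.05, 0.10, 0.15),
    n: int = 20,
    seed: int = 0,
    archs=("P", "PD", "PI", "PID"),
    n_cells: int = 20,
    t_end: float = 3000.0,
    filter_window: int = 60,
    dt_out: float = 5.0,
    rtol: float = 1e-5,
    atol: float = 1e-7,
    spec: RequirementSpec = RequirementSpec(),
) -> CampaignResult:
    """Heterogeneous growth/division runs over a coefficient-of-variation grid.

    Both the targets' and the controllers' activation parameters (and the
    nonzero control gains) are redrawn at every division; metrics are taken
    on the moving-average-filtered mean target output.
    """
    ss = np.random.SeedSequence(seed)
    subset = TARGET_ACTIVATION + CONTROLLER_ACTIVATION
    chamber = ChamberConfig(capacity=n_cells, growth=True, division_step=20.0)
    rows = []
    set_point = params.mu * params.Yd
    W = max(1, int(round(filter_window / dt_out)))
    for lab in archs:
        arch = ARCHITECTURES[lab]
        for cv in cv_grid:
            n_eff = 1 if cv == 0 else n
            for k in range(n_eff):
                rng = np.random.default_rng(ss.spawn(1)[0])
                # at cv = 0 every redraw reproduces the nominal cell, so
                # growth/division leaves the population means unchanged;
                # run the cheaper growth-off equivalent
                cham_run = (chamber if cv > 0 else
                            ChamberConfig(capacity=n_cells, growth=False))
                cells = make_consortium(
                    arch, n_cells, params, gains, cv=cv, rng=rng,
                    subset=subset, perturb_gains=True, chamber=cham_run)
                res = run_hetero(
                    cells, cham_run, params, gains, t_end, rng,
                    cv=cv, subset=subset, perturb_gains=True, dt_out=dt_out,
                    rtol=rtol, atol=atol)
                y = moving_average(res.output(params), W)
                rep = evaluate_run(res.times, y, set_point, spec)
                rows.append({
                    "arch": lab, "cv": cv, "run": k,
                    "e_pct": rep.e_inf * 100.0, "ts": rep.ts, "o": rep.o,
                    "y_inf": rep.y_inf, "passed": rep.passed,
                    "flags": "; ".join(res.flags),
                })
    runs = pd.DataFrame(rows)
    return CampaignResult(runs, _summaries(runs, ["arch", "cv"]), seed, "cv_sweep")


def imbalance_campaign(
    params: ConsortiumParams,
    gains: ControlGains,
    *,
    rho_grid=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_total: int = 20,
    seed: int = 0,
    archs=("P", "PD", "PI", "PID"),
    t_end: float = 2880.0,
    spec: RequirementSpec = RequirementSpec(),
) -> CampaignResult:
    """Controller-fraction sweep (growth off) for each architecture."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for lab in archs:
        arch = ARCHITECTURES[lab]
        rng = np.random.default_rng(ss.spawn(1)[0])
        recs = run_imbalance(arch, rho_grid, params, gains,
                             n_total=n_total, t_end=t_end, spec=spec, rng=rng)
        for rec in recs:
            rep = rec["report"]
            rows.append({
                "arch": lab, "rho_c": rec["rho_c"],
                "n_controllers": rec["n_controllers"],
                "e_pct": rep.e_inf * 100.0, "ts": rep.ts, "o": rep.o,
                "y_inf": rep.y_inf, "passed": rep.passed,
                "success": rec["success"],
            })
    runs = pd.DataFrame(rows)
    summary = {
        lab: {
            "successful_rho": sorted(
                runs.query("arch == @lab and success")["rho_c"].tolist())
        }
        for lab in archs
    }
    return CampaignResult(runs, summary, seed, "imbalance")
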