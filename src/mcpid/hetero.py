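"""Multi-cell consortium simulation with per-cell heterogeneity.

A well-mixed stand-in for agent-based chamber experiments: every cell
carries its own parameter set (optionally drawn around the nominal values
with a given coefficient of variation), integrates its own copy of the
population ODEs, and is coupled to the other cells only through the shared
extracellular QS pool.  Growth is modelled as periodic division with
parameter redraws for both daughters and random washout at the chamber
capacity; spatial mechanics are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .metrics import RequirementSpec, evaluate_run
from .model import SimulationError
from .params import Architecture, ConsortiumParams, ControlGains

__all__ = [
    "Cell",
    "ChamberConfig",
    "CampaignConfig",
    "HeteroResult",
    "TARGET_ACTIVATION",
    "CONTROLLER_ACTIVATION",
    "draw_perturbed_params",
    "draw_perturbed_gains",
    "make_consortium",
    "run_hetero",
    "run_imbalance",
]

CELL_SPECIES = {
    "t": ("X1", "Xc", "Qx", "Qu"),
    "p": ("Qx", "Qu"),
    "i": ("Z1", "Z2", "Qx", "Qu"),
    "d": ("A", "M", "Qx", "Qu"),
}

# activation-rate subsets used by the perturbation campaigns
TARGET_ACTIVATION = ("beta_u", "beta_c", "beta_x")
CONTROLLER_ACTIVATION = ("mu", "theta", "beta_a", "beta_m")


@dataclass
class Cell:
    """One cell: population label, private parameters/gains and state."""

    label: str
    params: ConsortiumParams
    gains: ControlGains
    state: np.ndarray
    birth_time: float = 0.0
    division_period: float = math.inf
    next_division: float = math.inf

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float)
        want = len(CELL_SPECIES[self.label])
        if self.state.shape != (want,):
            raise ValueError(
                f"{self.label}-cell state must have {want} components"
            )
        if np.min(self.state) < 0:
            raise ValueError("cell state must be nonnegative")


@dataclass(frozen=True)
class ChamberConfig:
    """Chamber capacity and growth/division settings."""

    capacity: int = 120
    growth: bool = True
    division_period: float | None = None  # default ln2/gamma
    division_jitter: float = 0.10
    division_step: float = 5.0  # divisions are applied on this time grid
    washout: str = "balanced"  # "balanced" | "uniform" removal at capacity

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")


@dataclass(frozen=True)
class CampaignConfig:
    """Replicated-experiment settings for heterogeneity campaigns."""

    n: int = 20
    cv: float = 0.0
    seed: int = 0
    arch: str = "PID"
    subset: tuple[str, ...] = TARGET_ACTIVATION + CONTROLLER_ACTIVATION
    perturb_gains: bool = True

    def __post_init__(self) -> None:
        if self.n < 1 or self.cv < 0:
            raise ValueError("need n >= 1 and cv >= 0")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) resampled until strictly positive."""
    if sd == 0:
        return mean
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)


def draw_perturbed_params(
    nominal: ConsortiumParams,
    cv: float,
    rng: np.random.Generator,
    subset=None,
) -> ConsortiumParams:
    """Draw each parameter in *subset* from Normal(rho, cv*rho), truncated positive."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return nominal
    subset = TARGET_ACTIVATION if subset is None else subset
    kw = {name: _positive_normal(rng, getattr(nominal, name), cv * getattr(nominal, name))
          for name in subset}
    return replace(nominal, **kw)


def draw_perturbed_gains(
    nominal: ControlGains, cv: float, rng: np.random.Generator
) -> ControlGains:
    """Perturb the nonzero control gains the same way."""
    if cv == 0:
        return nominal
    kw = {}
    for name in ("beta_P", "beta_I", "beta_D"):
        v = getattr(nominal, name)
        kw[name] = _positive_normal(rng, v, cv * v) if v > 0 else 0.0
    return ControlGains(**kw)


def _controller_counts(arch: Architecture, n_controllers: int) -> dict[str, int]:
    """Split controller cells as evenly as possible, remainder order p, i, d."""
    ctrl = [pop for pop in ("p", "i", "d") if pop in arch.members]
    base, rem = divmod(n_controllers, len(ctrl))
    counts = {pop: base for pop in ctrl}
    for pop in ctrl[:rem]:
        counts[pop] += 1
    return counts


def make_consortium(
    arch: Architecture,
    n_total: int,
    params: ConsortiumParams,
    gains: ControlGains,
    *,
    rho_c: float | None = None,
    cv: float = 0.0,
    rng: np.random.Generator | None = None,
    subset=None,
    perturb_gains: bool = False,
    chamber: ChamberConfig = ChamberConfig(growth=False),
    t0: float = 0.0,
) -> list[Cell]:
    """Build the initial cell list (zero internal state).

    With ``rho_c`` given, ``round(rho_c*n_total)`` controller cells are
    split evenly among the architecture's controller populations and the
    rest are targets; otherwise all populations get an equal share.
    """
    rng = np.random.default_rng() if rng is None else rng
    gains = gains.for_architecture(arch)
    if rho_c is None:
        base, rem = divmod(n_total, arch.M)
        counts = {pop: base for pop in arch.members}
        for pop in list(arch.members)[:rem]:
            counts[pop] += 1
    else:
        if not 0 <= rho_c <= 1:
            raise ValueError("rho_c must be in [0, 1]")
        nc = int(round(rho_c * n_total))
        counts = {"t": n_total - nc}
        counts.update(_controller_counts(arch, nc))
        if counts["t"] < 1:
            raise ValueError("need at least one target cell")
    period = chamber.division_period
    if period is None:
        period = math.log(2.0) / params.gamma
    cells: list[Cell] = []
    for pop in arch.members:
        for _ in range(counts.get(pop, 0)):
            p_c = draw_perturbed_params(params, cv, rng, subset)
            g_c = draw_perturbed_gains(gains, cv, rng) if perturb_gains else gains
            nd = t0 + rng.uniform(0.0, period) if chamber.growth else math.inf
            cells.append(
                Cell(pop, p_c, g_c, np.zeros(len(CELL_SPECIES[pop])),
                     birth_time=t0, division_period=period, next_division=nd)
            )
    return cells


class _Packed:
    """Index/parameter arrays for the coupled per-cell ODE system."""

    def __init__(self, cells: list[Cell], env_params: ConsortiumParams):
        self.cells = cells
        self.env = env_params
        self.groups: dict[str, dict] = {}
        off = 2  # y[0] = Qx_e, y[1] = Qu_e
        offsets = []
        for c in cells:
            offsets.append(off)
            off += len(CELL_SPECIES[c.label])
        self.n = off
        for pop in ("t", "p", "i", "d"):
            members = [(c, o) for c, o in zip(cells, offsets) if c.label == pop]
            if not members:
                continue
            spec = CELL_SPECIES[pop]
            idx = {name: np.array([o + spec.index(name) for _, o in members])
                   for name in spec}
            par = {f: np.array([getattr(c.params, f) for c, _ in members])
                   for f in ("beta_u", "beta_c", "beta_x", "mu", "theta", "beta_a",
                             "beta_m", "gamma", "gamma_a", "gamma_m", "gamma_z",
                             "eta", "K_a", "K_m", "Yd")}
            par["beta_P"] = np.array([c.gains.beta_P for c, _ in members])
            par["beta_I"] = np.array([c.gains.beta_I for c, _ in members])
            par["beta_D"] = np.array([c.gains.beta_D for c, _ in members])
            self.groups[pop] = {"idx": idx, "par": par}

    def pack(self, env_state) -> np.ndarray:
        y = np.empty(self.n)
        y[0], y[1] = env_state
        off = 2
        for c in self.cells:
            k = len(CELL_SPECIES[c.label])
            y[off:off + k] = c.state
            off += k
        return y

    def unpack(self, y) -> None:
        off = 2
        for c in self.cells:
            k = len(CELL_SPECIES[c.label])
            # clip solver round-off excursions below zero
            c.state = np.maximum(np.array(y[off:off + k]), 0.0)
            off += k

    def jac_sparsity(self):
        """Sparsity pattern: cells couple internally and to the environment."""
        from scipy.sparse import lil_matrix

        S = lil_matrix((self.n, self.n), dtype=np.int8)
        S[0, 0] = S[1, 1] = S[0, 1] = S[1, 0] = 1
        off = 2
        for c in self.cells:
            k = len(CELL_SPECIES[c.label])
            S[off:off + k, off:off + k] = 1
            S[off:off + k, 0:2] = 1
            S[0:2, off:off + k] = 1
            off += k
        return S.tocsr()

    def rhs(self, t, y):
        dy = np.zeros_like(y)
        Qxe, Que = y[0], y[1]
        flux_x = 0.0
        flux_u = 0.0
        for pop, grp in self.groups.items():
            ix, par = grp["idx"], grp["par"]
            g, eta = par["gamma"], par["eta"]
            Qx, Qu = y[ix["Qx"]], y[ix["Qu"]]
            dQx = eta * (Qxe - Qx) - g * Qx
            dQu = eta * (Que - Qu) - g * Qu
            if pop == "t":
                X1, Xc = y[ix["X1"]], y[ix["Xc"]]
                dy[ix["X1"]] = par["beta_u"] * Qu - g * X1
                dy[ix["Xc"]] = par["beta_c"] * X1 - g * Xc
                dQx = dQx + par["beta_x"] * Xc
            elif pop == "p":
                r = par["mu"] * par["Yd"]
                dQu = dQu + par["beta_P"] * par["Yd"] * r / (r + par["theta"] * Qx)
            elif pop == "i":
                Z1, Z2 = y[ix["Z1"]], y[ix["Z2"]]
                ann = par["gamma_z"] * Z1 * Z2
                dy[ix["Z1"]] = par["mu"] * par["Yd"] - ann
                dy[ix["Z2"]] = par["theta"] * Qx - ann
                dQu = dQu + par["beta_I"] * Z1
            else:  # derivative cells
                A, M = y[ix["A"]], y[ix["M"]]
                dy[ix["A"]] = (par["beta_a"] * M
                               - par["gamma_a"] * Qx * A / (par["K_a"] + A)
                               - g * A)
                dy[ix["M"]] = (par["beta_m"] * par["Yd"]
                               - par["gamma_m"] * A * M / (par["K_m"] + M))
                dQu = dQu + par["beta_D"] * A
            dy[ix["Qx"]] = dQx
            dy[ix["Qu"]] = dQu
            flux_x += float(np.sum(eta * (Qx - Qxe)))
            flux_u += float(np.sum(eta * (Qu - Que)))
        dy[0] = flux_x - self.env.gamma_e * Qxe
        dy[1] = flux_u - self.env.gamma_e * Que
        return dy


@dataclass
class HeteroResult:
    """Per-population mean trajectories, environment and bookkeeping."""

    times: np.ndarray
    env: dict[str, np.ndarray]                 # Qx_e, Qu_e
    mean: dict[str, dict[str, np.ndarray]]     # pop -> species -> mean over cells
    counts: dict[str, np.ndarray]              # pop -> cell count over time
    cells: list[Cell]
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def output(self, params: ConsortiumParams) -> np.ndarray:
        """Regulated signal theta * <Qx over target cells>."""
        return params.theta * self.mean["t"]["Qx"]

    def to_frame(self):
        import pandas as pd

        cols = {"time": self.times, "Qx_e": self.env["Qx_e"], "Qu_e": self.env["Qu_e"]}
        for pop, d in self.mean.items():
            for sp, v in d.items():
                cols[f"{pop}.{sp}"] = v
            cols[f"{pop}.count"] = self.counts[pop]
        return pd.DataFrame(cols)

    def cells_to_frame(self):
        """Per-cell states in long format (time, cell_id, population,
        species, value).  Available for growth-off runs only."""
        import pandas as pd

        if "cell_states" not in self.meta:
            raise ValueError("per-cell recording requires growth-off runs")
        states = self.meta["cell_states"]  # (T, n_states) incl. env
        rows = []
        off = 2
        for cid, c in enumerate(self.cells):
            for j, sp in enumerate(CELL_SPECIES[c.label]):
                for ti, t in enumerate(self.times):
                    rows.append((t, cid, c.label, sp, states[ti, off + j]))
            off += len(CELL_SPECIES[c.label])
        return pd.DataFrame(
            rows, columns=["time", "cell_id", "population", "species", "value"])


def run_hetero(
    cells: list[Cell],
    chamber: ChamberConfig,
    params: ConsortiumParams,
    gains: ControlGains,
    t_end: float,
    rng: np.random.Generator | None = None,
    *,
    cv: float = 0.0,
    subset=None,
    perturb_gains: bool = False,
    dt_out: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    record_cells: bool = False,
) -> HeteroResult:
    """Integrate the coupled per-cell system, with optional growth/division.

    Divisions are applied on the chamber's ``division_step`` grid: at each
    step boundary every cell whose scheduled division time has passed is
    split; daughters inherit the mother's concentrations and both receive
    freshly drawn parameters (and gains, when ``perturb_gains``).  Cells
    beyond capacity are washed out uniformly at random.
    """
    if not cells:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng() if rng is None else rng
    cells = list(cells)
    pops = sorted({c.label for c in cells})
    arch = _arch_of(cells)
    base_gains = gains.for_architecture(arch)
    n0 = len(cells)
    frac0 = {pop: max(sum(1 for c in cells if c.label == pop), 1) / n0
             for pop in pops}
    out_times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    rec_env = {k: np.full(out_times.size, np.nan) for k in ("Qx_e", "Qu_e")}
    rec_mean = {pop: {sp: np.full(out_times.size, np.nan) for sp in CELL_SPECIES[pop]}
                for pop in pops}
    rec_counts = {pop: np.zeros(out_times.size, dtype=int) for pop in pops}
    flags: list[str] = []

    env_state = (0.0, 0.0)
    t = 0.0
    next_out = 0  # index of next output sample to fill
    step = chamber.division_step if chamber.growth else t_end
    if record_cells and chamber.growth:
        raise ValueError("per-cell recording requires growth off")
    cell_states = (np.full((out_times.size, 0), np.nan) if record_cells else None)

    def record(sol_t, sol_y, packed):
        nonlocal next_out, cell_states
        lo = next_out
        while next_out < out_times.size and out_times[next_out] <= sol_t[-1] + 1e-9:
            next_out += 1
        if next_out == lo:
            return
        sel = np.searchsorted(sol_t, out_times[lo:next_out])
        sel = np.clip(sel, 0, sol_t.size - 1)
        cols = sol_y[:, sel]
        if cell_states is not None:
            if cell_states.shape[1] == 0:
                cell_states = np.full((out_times.size, packed.n), np.nan)
            cell_states[lo:next_out] = cols.T
        rec_env["Qx_e"][lo:next_out] = cols[0]
        rec_env["Qu_e"][lo:next_out] = cols[1]
        for pop in pops:
            grp = packed.groups.get(pop)
            n_pop = sum(1 for c in packed.cells if c.label == pop)
            rec_counts[pop][lo:next_out] = n_pop
            if grp is None:
                continue
            for sp in CELL_SPECIES[pop]:
                rec_mean[pop][sp][lo:next_out] = cols[grp["idx"][sp]].mean(axis=0)

    while t < t_end - 1e-9:
        t_stop = min(t_end, t + step)
        packed = _Packed(cells, params)
        y0 = packed.pack(env_state)
        sol = solve_ivp(packed.rhs, (t, t_stop), y0, method="BDF",
                        jac_sparsity=packed.jac_sparsity(),
                        dense_output=False, rtol=rtol, atol=atol,
                        t_eval=np.unique(np.concatenate(
                            [out_times[(out_times >= t - 1e-9) & (out_times <= t_stop + 1e-9)],
                             [t, t_stop]])))
        if not sol.success:
            raise SimulationError(f"hetero solver failed: {sol.message}",
                                  last_time=float(sol.t[-1]) if sol.t.size else t)
        record(sol.t, sol.y, packed)
        packed.unpack(sol.y[:, -1])
        env_state = (float(sol.y[0, -1]), float(sol.y[1, -1]))
        t = t_stop

        if chamber.growth and t < t_end - 1e-9:
            newborn: list[Cell] = []
            for c in cells:
                while c.next_division <= t:
                    jit = 1.0 + chamber.division_jitter * rng.uniform(-1.0, 1.0)
                    c.next_division += c.division_period * jit
                    # both daughters: fresh parameters, inherited concentrations
                    c.params = draw_perturbed_params(params, cv, rng, subset)
                    if perturb_gains:
                        c.gains = draw_perturbed_gains(base_gains, cv, rng)
                    d_jit = 1.0 + chamber.division_jitter * rng.uniform(-1.0, 1.0)
                    newborn.append(Cell(
                        c.label,
                        draw_perturbed_params(params, cv, rng, subset),
                        (draw_perturbed_gains(base_gains, cv, rng)
                         if perturb_gains else c.gains),
                        np.array(c.state),
                        birth_time=t,
                        division_period=c.division_period,
                        next_division=t + c.division_period * d_jit,
                    ))
            cells.extend(newborn)
            while len(cells) > chamber.capacity:
                if chamber.washout == "uniform":
                    k = int(rng.integers(len(cells)))
                else:
                    # balanced: remove from the population most above its
                    # initial share (small chambers would otherwise lose
                    # whole populations to neutral drift)
                    counts = {pop: 0 for pop in frac0}
                    for c in cells:
                        counts[c.label] += 1
                    worst = max(frac0, key=lambda pop: counts[pop] / frac0[pop])
                    members = [i for i, c in enumerate(cells) if c.label == worst]
                    k = members[int(rng.integers(len(members)))]
                cells.pop(k)
            present = {c.label for c in cells}
            for pop in pops:
                if pop not in present:
                    flags.append(f"population {pop} washed out at t={t:.0f} min")

    meta = {"t_end": t_end, "cv": cv, "growth": chamber.growth,
            "capacity": chamber.capacity}
    if cell_states is not None:
        meta["cell_states"] = cell_states
    return HeteroResult(
        times=out_times, env=rec_env, mean=rec_mean, counts=rec_counts,
        cells=cells, flags=flags, meta=meta,
    )


def _arch_of(cells: list[Cell]) -> Architecture:
    """Smallest architecture containing the populations present."""
    present = {c.label for c in cells}
    lab = "P" + ("I" if "i" in present else "") + ("D" if "d" in present else "")
    return Architecture(lab)


def run_imbalance(
    arch: Architecture,
    rho_grid,
    params: ConsortiumParams,
    gains: ControlGains,
    *,
    n_total: int = 20,
    t_end: float = 2880.0,
    spec: RequirementSpec = RequirementSpec(),
    rng: np.random.Generator | None = None,
    dt_out: float = 2.0,
):
    """Sweep the controller fraction rho_c with growth off; metrics per point.

    Returns a list of dicts with the rho_c value, the per-run performance
    report and the success flag against *spec* (no-control points are
    flagged failed).
    """
    rng = np.random.default_rng() if rng is None else rng
    chamber = ChamberConfig(capacity=n_total, growth=False)
    out = []
    set_point = params.mu * params.Yd
    for rho in np.asarray(rho_grid, dtype=float):
        cells = make_consortium(arch, n_total, params, gains, rho_c=float(rho),
                                rng=rng, chamber=chamber)
        res = run_hetero(cells, chamber, params, gains, t_end, rng, dt_out=dt_out)
        y = res.output(params)
        rep = evaluate_run(res.times, y, set_point, spec)
        n_ctrl = sum(1 for c in cells if c.label != "t")
        success = rep.passed and n_ctrl > 0
        out.append({"rho_c": float(rho), "n_controllers": n_ctrl,
                    "report": rep, "success": bool(success)})
    return out
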