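"""Aggregate consortium models: full ODEs, reduced model and equilibria.

The *full* model tracks, for each population present in the architecture,
its internal species plus its intracellular copies of the two QS molecules,
together with the shared extracellular pool.  The *reduced* model is the
timescale-separated limit (fast QS diffusion, fast annihilation, fast
derivative module): two target species ``X1, Xc`` plus — when integral
cells are present — the annihilation mismatch ``zeta = Z1 - Z2``, with the
QS molecules and the derivative species slaved to their quasi-steady
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import Architecture, ConsortiumParams, ControlGains

__all__ = [
    "ModelOptions",
    "Trajectory",
    "SimulationError",
    "state_labels",
    "full_rhs",
    "reduced_rhs",
    "simulate",
    "equilibrium",
    "EquilibriumReport",
    "proportional_production",
]


@dataclass(frozen=True)
class ModelOptions:
    """Optional model variants (all off by default).

    m_dilution
        Add a ``-gamma*M`` dilution term to the derivative species M (the
        base formulation keeps M free of dilution).
    z_dilution
        Add ``-gamma*Z`` dilution to the annihilation pair (the base
        integral module is annihilation-only).
    clamp_A
        Clamp the reduced-model quasi-steady-state value of A at zero
        before it enters the control signal.
    """

    m_dilution: bool = False
    z_dilution: bool = False
    clamp_A: bool = False


_POP_SPECIES = {
    "t": ("X1", "Xc", "Qx_t", "Qu_t"),
    "p": ("Qu_p", "Qx_p"),
    "i": ("Z1", "Z2", "Qu_i", "Qx_i"),
    "d": ("A", "M", "Qu_d", "Qx_d"),
}


def state_labels(arch: Architecture, model: str = "full") -> tuple[str, ...]:
    """Ordered state-component labels for *arch* under the given model."""
    if model == "full":
        labels: list[str] = []
        for pop in arch.members:
            labels.extend(_POP_SPECIES[pop])
        labels.extend(("Qx_e", "Qu_e"))
        return tuple(labels)
    if model == "reduced":
        return ("X1", "Xc", "zeta") if arch.has_integral else ("X1", "Xc")
    raise ValueError(f"unknown model {model!r}")


def proportional_production(Qx, params: ConsortiumParams, gains: ControlGains):
    """Production rate of Qu in the proportional cells (nM/min).

    ``beta_P * Yd * mu*Yd / (mu*Yd + theta*Qx)`` — a repression Hill term
    whose slope at the set point ``theta*Qx = mu*Yd`` is ``-beta_P*theta/(4*mu)``.
    """
    r = params.mu * params.Yd
    num = gains.beta_P * params.Yd * r
    den = r + params.theta * Qx
    safe = np.where(den == 0, 1.0, den)
    return np.where(den == 0, 0.0, num / safe)


def _index(arch: Architecture) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(state_labels(arch, "full"))}


def full_rhs(
    state,
    t: float,
    params: ConsortiumParams,
    gains: ControlGains,
    arch: Architecture,
    options: ModelOptions = ModelOptions(),
):
    """Time derivative of the full aggregate model at ``state``.

    Raises on dimension mismatch, and rejects states with meaningfully
    negative components (a sign the solver escaped the invariant region).
    """
    state = np.asarray(state)
    labels = state_labels(arch, "full")
    if state.shape != (len(labels),):
        raise ValueError(
            f"state has shape {state.shape}, expected ({len(labels)},) for {arch.label}"
        )
    if np.min(np.real(state)) < -1e-7:
        bad = labels[int(np.argmin(np.real(state)))]
        raise ValueError(f"negative state component {bad} = {np.min(np.real(state))}")
    return _full_rhs(state, t, params, gains, arch, options)


def _full_rhs(state, t, params, gains, arch, options=ModelOptions()):
    p = params
    idx = _index(arch)
    s = state
    d = np.zeros_like(s)
    Qxe = s[idx["Qx_e"]]
    Que = s[idx["Qu_e"]]

    # target cells
    X1, Xc, Qxt, Qut = (s[idx[k]] for k in ("X1", "Xc", "Qx_t", "Qu_t"))
    d[idx["X1"]] = p.beta_u * Qut - p.gamma * X1
    d[idx["Xc"]] = p.beta_c * X1 - p.gamma * Xc
    d[idx["Qx_t"]] = p.beta_x * Xc + p.eta * (Qxe - Qxt) - p.gamma * Qxt
    d[idx["Qu_t"]] = p.eta * (Que - Qut) - p.gamma * Qut

    # proportional cells
    Qup, Qxp = s[idx["Qu_p"]], s[idx["Qx_p"]]
    d[idx["Qu_p"]] = (
        proportional_production(Qxp, p, gains) + p.eta * (Que - Qup) - p.gamma * Qup
    )
    d[idx["Qx_p"]] = p.eta * (Qxe - Qxp) - p.gamma * Qxp

    # integral cells: antithetic pair Z1/Z2 annihilating at rate gamma_z
    if arch.has_integral:
        Z1, Z2, Qui, Qxi = (s[idx[k]] for k in ("Z1", "Z2", "Qu_i", "Qx_i"))
        ann = p.gamma_z * Z1 * Z2
        dil = p.gamma if options.z_dilution else 0.0
        d[idx["Z1"]] = p.mu * p.Yd - ann - dil * Z1
        d[idx["Z2"]] = p.theta * Qxi - ann - dil * Z2
        d[idx["Qu_i"]] = gains.beta_I * Z1 + p.eta * (Que - Qui) - p.gamma * Qui
        d[idx["Qx_i"]] = p.eta * (Qxe - Qxi) - p.gamma * Qxi

    # derivative cells: Michaelis–Menten incoherent module
    if arch.has_derivative:
        A, M, Qud, Qxd = (s[idx[k]] for k in ("A", "M", "Qu_d", "Qx_d"))
        d[idx["A"]] = p.beta_a * M - p.gamma_a * Qxd * A / (p.K_a + A) - p.gamma * A
        dM = p.beta_m * p.Yd - p.gamma_m * A * M / (p.K_m + M)
        if options.m_dilution:
            dM -= p.gamma * M
        d[idx["M"]] = dM
        d[idx["Qu_d"]] = gains.beta_D * A + p.eta * (Que - Qud) - p.gamma * Qud
        d[idx["Qx_d"]] = p.eta * (Qxe - Qxd) - p.gamma * Qxd

    # shared environment
    sum_Qx = sum(s[idx[f"Qx_{pop}"]] for pop in arch.members)
    sum_Qu = sum(s[idx[f"Qu_{pop}"]] for pop in arch.members)
    Mpop = arch.M
    d[idx["Qx_e"]] = p.eta * p.N * (sum_Qx - Mpop * Qxe) - p.gamma_e * Qxe
    d[idx["Qu_e"]] = p.eta * p.N * (sum_Qu - Mpop * Que) - p.gamma_e * Que
    return d


def reduced_qss(state, params: ConsortiumParams, gains: ControlGains,
                arch: Architecture, options: ModelOptions = ModelOptions()):
    """Quasi-steady-state values (Qx, A, Qu) slaved to the reduced state."""
    p = params
    Gamma = arch.Gamma(p)
    X1, Xc = state[0], state[1]
    Qx = p.beta_x * Xc / Gamma
    u = proportional_production(Qx, p, gains)
    A = 0.0
    if arch.has_derivative:
        Xc_dot = p.beta_c * X1 - p.gamma * Xc
        A = (
            -(p.gamma_a * p.beta_x) / (Gamma * p.beta_a * p.gamma_m) * Xc_dot
            + p.beta_m * p.Yd / p.gamma_m
        )
        if options.clamp_A:
            A = max(A, 0.0)
        u = u + gains.beta_D * A
    if arch.has_integral:
        u = u + gains.beta_I * state[2]
    return Qx, A, u / Gamma


def reduced_rhs(
    state,
    t: float,
    params: ConsortiumParams,
    gains: ControlGains,
    arch: Architecture,
    options: ModelOptions = ModelOptions(),
):
    """Time derivative of the reduced (timescale-separated) model."""
    state = np.asarray(state)
    n = 3 if arch.has_integral else 2
    if state.shape != (n,):
        raise ValueError(f"state has shape {state.shape}, expected ({n},)")
    p = params
    Qx, _, Qu = reduced_qss(state, p, gains, arch, options)
    d = np.zeros_like(state)
    d[0] = p.beta_u * Qu - p.gamma * state[0]
    d[1] = p.beta_c * state[0] - p.gamma * state[1]
    if arch.has_integral:
        d[2] = p.mu * p.Yd - p.theta * Qx
    return d


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """A simulated trajectory: time grid, state matrix and provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_states)
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.labels)):
            raise ValueError("trajectory shape does not match times/labels")

    def series(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def output(self, params: ConsortiumParams) -> np.ndarray:
        """The regulated signal ``theta*Qx`` (nM/min units of mu*Yd)."""
        if "Qx_t" in self.labels:
            return params.theta * self.series("Qx_t")
        arch = self.meta["arch"]
        Gamma = arch.Gamma(params)
        return params.theta * params.beta_x * self.series("Xc") / Gamma

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    model: str,
    params: ConsortiumParams,
    gains: ControlGains,
    arch: Architecture,
    t_span: tuple[float, float] = (0.0, 2880.0),
    init: Sequence[float] | None = None,
    *,
    t_eval: np.ndarray | None = None,
    dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    options: ModelOptions = ModelOptions(),
) -> Trajectory:
    """Integrate the full or reduced model and return a dense Trajectory.

    The default initial condition is the all-zero state (populations grown
    separately before the experiment starts).  A stiff-capable solver is
    used; failures raise :class:`SimulationError` with diagnostics.
    """
    gains = gains.for_architecture(arch)
    labels = state_labels(arch, model)
    if init is None:
        y0 = np.zeros(len(labels))
    else:
        y0 = np.asarray(init, dtype=float)
        if y0.shape != (len(labels),):
            raise ValueError(f"init has shape {y0.shape}, expected ({len(labels)},)")
        lo = np.copy(y0)
        if arch.has_integral and model == "reduced":
            lo[labels.index("zeta")] = 0.0  # zeta may be negative
        if np.min(lo) < 0:
            raise ValueError("initial state must be nonnegative")
    if not np.isfinite(t_span).all():
        raise ValueError("t_span must be finite")
    if t_eval is None:
        t_eval = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)

    rhs: Callable = _full_rhs if model == "full" else reduced_rhs
    if model not in ("full", "reduced"):
        raise ValueError(f"unknown model {model!r}")

    sol = solve_ivp(
        lambda t, y: rhs(y, t, params, gains, arch, options),
        t_span,
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_span[0]
        raise SimulationError(f"solver failed: {sol.message}", last_time=last)
    if not np.isfinite(sol.y).all():
        raise SimulationError("non-finite state encountered", last_time=float(sol.t[-1]))
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        labels=labels,
        meta={
            "model": model,
            "arch": arch,
            "params": params,
            "gains": gains,
            "solver": {"method": method, "rtol": rtol, "atol": atol},
        },
    )


@dataclass
class EquilibriumReport:
    """Reduced-model equilibrium and the existence/stability bookkeeping."""

    state: dict[str, float]
    exists: bool
    unique: bool
    condition_lhs: float
    condition_satisfied: bool
    arch_label: str

    @property
    def output(self) -> float:
        return self.state["theta_Qx"]


def equilibrium(
    params: ConsortiumParams, gains: ControlGains, arch: Architecture
) -> EquilibriumReport:
    """Equilibrium of the reduced model for the given architecture.

    For PI/PID the integral action pins ``theta*Qx* = mu*Yd`` exactly and
    zeta* closes the actuation balance; existence of a physical (Z1 >= 0)
    equilibrium is equivalent to the gain condition reported in
    ``condition_lhs <= 0``.  For P/PD the fixed point solves a scalar
    quadratic in the regulated output.
    """
    from .linear import aggregate_gains, check_equilibrium_condition

    gains = gains.for_architecture(arch)
    p = params
    Gamma = arch.Gamma(p)
    r = p.mu * p.Yd
    kappa = aggregate_gains(p, gains, arch)
    lhs, satisfied = check_equilibrium_condition(kappa, p, arch)

    A_star = p.beta_m * p.Yd / p.gamma_m if arch.has_derivative else 0.0
    if arch.has_integral:
        v = r  # theta*Qx* = mu*Yd
        Qx = v / p.theta
        Xc = Gamma * Qx / p.beta_x
        X1 = p.gamma * Xc / p.beta_c
        Qu = p.gamma * X1 / p.beta_u
        uP = proportional_production(Qx, p, gains)
        if gains.beta_I <= 0:
            raise ValueError("integral architecture requires beta_I > 0")
        zeta = (Gamma * Qu - uP - gains.beta_D * A_star) / gains.beta_I
        exists = bool(satisfied)  # zeta* >= 0 iff the gain condition holds
        state = {
            "X1": X1, "Xc": Xc, "zeta": zeta, "Qx": Qx, "Qu": Qu, "A": A_star,
            "theta_Qx": p.theta * Qx,
        }
        return EquilibriumReport(state, exists, True, lhs, bool(satisfied), arch.label)

    # P / PD: v^2 + (r - K*D)v - K*r*(beta_P*Yd + D) = 0, v = theta*Qx*
    K = p.theta * p.beta_c * p.beta_u * p.beta_x / (Gamma**2 * p.gamma**2)
    D = gains.beta_D * p.beta_m * p.Yd / p.gamma_m
    b = r - K * D
    c = -K * r * (gains.beta_P * p.Yd + D)
    disc = b * b - 4 * c
    v = 0.5 * (-b + np.sqrt(disc))
    v = max(v, 0.0)
    Qx = v / p.theta
    Xc = Gamma * Qx / p.beta_x
    X1 = p.gamma * Xc / p.beta_c
    Qu = p.gamma * X1 / p.beta_u
    state = {
        "X1": X1, "Xc": Xc, "Qx": Qx, "Qu": Qu, "A": A_star, "theta_Qx": v,
    }
    return EquilibriumReport(state, True, True, lhs, bool(satisfied), arch.label)
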