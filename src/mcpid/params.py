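"""Parameter sets, control gains and consortium architectures.

The consortium couples a *target* population (the process to be regulated)
with up to three *controller* populations — proportional, integral and
derivative cells — through two orthogonal quorum-sensing (QS) molecules:
``Qu`` broadcasts the actuation signal from the controllers to the targets,
``Qx`` broadcasts the measured output back.  All rates are first-order
unless noted otherwise and are expressed in ``min^-1``; concentrations in
``nM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "ConsortiumParams",
    "ControlGains",
    "Architecture",
    "ARCHITECTURES",
    "load_params",
    "nominal_params",
    "nominal_gains",
]


@dataclass(frozen=True)
class ConsortiumParams:
    """Biochemical rates and constants shared by the consortium models.

    Attributes
    ----------
    beta_u, beta_c, beta_x : float
        Activation rates inside the target cells: ``Qu -> X1 -> Xc -> Qx``.
    mu, theta : float
        Reference and measurement scaling rates.  The regulated signal is
        ``theta*Qx`` and the set point is ``mu*Yd``, so the desired output
        concentration is ``Qd = mu*Yd/theta``.
    beta_a, beta_m : float
        Activation rates of the derivative-cell species ``A`` and ``M``.
    gamma : float
        Dilution rate common to every intracellular species (growth).
    gamma_a, gamma_m : float
        Active degradation rates in the derivative module.
    gamma_z : float
        Annihilation rate constant of the integral pair ``Z1 + Z2 -> 0``
        (units ``nM^-1 min^-1``).
    gamma_e : float
        Degradation rate of QS molecules in the external environment.
    eta : float
        Membrane diffusion rate of the QS molecules.
    K_a, K_m : float
        Michaelis constants of the derivative module (nM).
    N : int
        Number of cells per population in the aggregate model.
    Yd : float
        Reference signal (nM).
    """

    beta_u: float
    beta_c: float
    beta_x: float
    mu: float
    theta: float
    beta_a: float
    beta_m: float
    gamma: float
    gamma_a: float
    gamma_m: float
    gamma_z: float
    gamma_e: float
    eta: float
    K_a: float
    K_m: float
    N: int = 30
    Yd: float = 60.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "N":
                if v < 1:
                    raise ValueError("N must be >= 1")
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")
        if self.gamma <= 0:
            raise ValueError("gamma must be strictly positive")
        if self.K_a <= 0 or self.K_m <= 0:
            raise ValueError("Michaelis constants must be strictly positive")

    @property
    def desired_output(self) -> float:
        """Desired Qx concentration ``Qd = mu*Yd/theta`` (nM)."""
        return self.mu * self.Yd / self.theta

    def with_(self, **kw) -> "ConsortiumParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class ControlGains:
    """Production rates of the control molecule Qu in the controller cells.

    ``beta_P``/``beta_I``/``beta_D`` play the role of the proportional,
    integral and derivative gains (min^-1).  Gains of populations that are
    absent from an architecture must be zero.
    """

    beta_P: float = 0.0
    beta_I: float = 0.0
    beta_D: float = 0.0

    def __post_init__(self) -> None:
        if min(self.beta_P, self.beta_I, self.beta_D) < 0:
            raise ValueError("control gains must be nonnegative")

    def for_architecture(self, arch: "Architecture") -> "ControlGains":
        """Zero out the gains of populations not present in *arch*."""
        return ControlGains(
            beta_P=self.beta_P,
            beta_I=self.beta_I if "i" in arch.members else 0.0,
            beta_D=self.beta_D if "d" in arch.members else 0.0,
        )

    def check(self, arch: "Architecture") -> None:
        if "i" not in arch.members and self.beta_I != 0:
            raise ValueError(f"beta_I must be 0 for the {arch.label} architecture")
        if "d" not in arch.members and self.beta_D != 0:
            raise ValueError(f"beta_D must be 0 for the {arch.label} architecture")


@dataclass(frozen=True)
class Architecture:
    """One of the four consortium layouts: P, PD, PI or PID.

    ``members`` lists the populations present: the target ``t`` and the
    proportional cells ``p`` are always in the consortium; integral ``i``
    and derivative ``d`` cells are added per label.  ``M = len(members)``
    enters the QS attenuation constant ``Gamma = M*gamma``.
    """

    label: str
    members: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        table = {
            "P": ("t", "p"),
            "PD": ("t", "p", "d"),
            "PI": ("t", "p", "i"),
            "PID": ("t", "p", "i", "d"),
        }
        if self.label not in table:
            raise ValueError(f"unknown architecture {self.label!r}")
        object.__setattr__(self, "members", table[self.label])

    @property
    def M(self) -> int:
        return len(self.members)

    def Gamma(self, params: ConsortiumParams) -> float:
        """QS attenuation constant ``Gamma_l = M*gamma``."""
        return self.M * params.gamma

    @property
    def has_integral(self) -> bool:
        return "i" in self.members

    @property
    def has_derivative(self) -> bool:
        return "d" in self.members


ARCHITECTURES: dict[str, Architecture] = {
    lab: Architecture(lab) for lab in ("P", "PD", "PI", "PID")
}


def _params_from_mapping(doc: dict) -> tuple[ConsortiumParams, ControlGains]:
    pnames = {f.name for f in fields(ConsortiumParams)}
    p = {k: v for k, v in doc.items() if k in pnames}
    g = {k: doc[k] for k in ("beta_P", "beta_I", "beta_D") if k in doc}
    return ConsortiumParams(**p), ControlGains(**g)


def load_params(path) -> tuple[ConsortiumParams, ControlGains]:
    """Load a parameter fixture file (YAML, ``key: value``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _params_from_mapping(doc)


def _load_fixture(name: str) -> dict:
    ref = resources.files("mcpid").joinpath(f"data/{name}_params.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def nominal_params(**overrides) -> ConsortiumParams:
    """The canonical nominal parameter set shipped with the package."""
    p, _ = _params_from_mapping(_load_fixture("nominal"))
    return p.with_(**overrides) if overrides else p


def nominal_gains() -> ControlGains:
    """The nominal PID gain triple (used for every architecture)."""
    _, g = _params_from_mapping(_load_fixture("nominal"))
    return g


def fixture_names() -> Iterable[str]:
    return ("nominal",)
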