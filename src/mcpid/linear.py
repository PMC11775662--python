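"""Linearized closed-loop analysis.

Everything here operates on the transfer function of the reduced model
linearized at the desired set point ``theta*Qx = mu*Yd``,

    G(s) = theta*beta_c * ((3*kP + cD*kD)*s + kI)
           / (s^3 + (2g + t*bc*kD)s^2 + (g^2 + t*bc*kP)s + t*bc*kI),

with ``cD = beta_a*beta_m*theta/(gamma_a*mu)`` (the derivative cells'
Yd feed-through; verified symbolically against the reduced model).

with the aggregated gains kP, kI, kD absorbing the pathway parameters and
``Gamma_l = M*gamma`` the QS attenuation of an M-population consortium.
The denominator is the basis of all pole analysis; root *contours* sweep
one aggregated gain while the others are held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.optimize import linear_sum_assignment

from .params import Architecture, ConsortiumParams, ControlGains

__all__ = [
    "AggregatedGains",
    "TransferFunction",
    "PoleSet",
    "RootContour",
    "aggregate_gains",
    "closed_loop_tf",
    "static_gain",
    "check_equilibrium_condition",
    "check_stability",
    "StabilityReport",
    "poles",
    "root_contour",
    "dominant_pole_bound",
    "tune_fastest",
    "TuneResult",
    "predict_metrics_from_poles",
    "analysis_report",
]


@dataclass(frozen=True)
class AggregatedGains:
    """Composite control gains of the linearized loop (plus Gamma_l)."""

    kappa_P: float = 0.0
    kappa_I: float = 0.0
    kappa_D: float = 0.0
    Gamma: float = 0.0

    def replace(self, **kw) -> "AggregatedGains":
        d = {"kappa_P": self.kappa_P, "kappa_I": self.kappa_I,
             "kappa_D": self.kappa_D, "Gamma": self.Gamma}
        d.update(kw)
        return AggregatedGains(**d)


def aggregate_gains(
    params: ConsortiumParams, gains: ControlGains, arch: Architecture
) -> AggregatedGains:
    """Aggregate the biochemical rates into (kappa_P, kappa_I, kappa_D).

    kappa_P = bP*bu*bx/(4*Gamma^2*mu), kappa_I = bI*bu*bx/Gamma^2,
    kappa_D = bD*bu*bx*ga/(Gamma^2*ba*gm*theta), Gamma = M*gamma.
    """
    gains = gains.for_architecture(arch)
    p = params
    Gamma = arch.Gamma(p)
    bux = p.beta_u * p.beta_x
    kP = kI = kD = 0.0
    if gains.beta_P > 0:
        if p.mu == 0:
            raise ZeroDivisionError("kappa_P requires mu > 0")
        kP = gains.beta_P * bux / (4 * Gamma**2 * p.mu)
    if gains.beta_I > 0:
        kI = gains.beta_I * bux / Gamma**2
    if gains.beta_D > 0:
        if min(p.beta_a, p.gamma_m, p.theta) == 0:
            raise ZeroDivisionError("kappa_D requires beta_a, gamma_m, theta > 0")
        kD = gains.beta_D * bux * p.gamma_a / (Gamma**2 * p.beta_a * p.gamma_m * p.theta)
    return AggregatedGains(kP, kI, kD, Gamma)


@dataclass(frozen=True)
class TransferFunction:
    """Rational transfer function; coefficients in descending powers of s."""

    num: tuple[float, ...]
    den: tuple[float, ...]

    def __call__(self, s):
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def minimal(self) -> "TransferFunction":
        """Cancel common trailing-zero coefficients (common factors of s)."""
        num = np.trim_zeros(np.asarray(self.num, dtype=float), "f")
        den = np.trim_zeros(np.asarray(self.den, dtype=float), "f")
        if num.size == 0:
            return TransferFunction((0.0,), tuple(den))
        k = 0
        while k < num.size - 1 and k < den.size - 1 and num[-1 - k] == 0 and den[-1 - k] == 0:
            k += 1
        if k:
            num, den = num[:-k], den[:-k]
        return TransferFunction(tuple(num), tuple(den))


def closed_loop_tf(kappa: AggregatedGains, params: ConsortiumParams) -> TransferFunction:
    """Closed-loop transfer function from mu*Yd to theta*Qx.

    The P/PD/PI variants are obtained by zeroing the corresponding kappa.
    """
    p = params
    tb = p.theta * p.beta_c
    cD = p.beta_a * p.beta_m * p.theta / (p.gamma_a * p.mu)
    num = (tb * (3 * kappa.kappa_P + cD * kappa.kappa_D), tb * kappa.kappa_I)
    den = (
        1.0,
        2 * p.gamma + tb * kappa.kappa_D,
        p.gamma**2 + tb * kappa.kappa_P,
        tb * kappa.kappa_I,
    )
    return TransferFunction(num, den)


def static_gain(tf: TransferFunction) -> float:
    """lim_{s->0} tf(s), after cancelling common factors of s.

    Returns ``math.inf`` when a pole at the origin survives cancellation.
    """
    m = tf.minimal()
    num, den = np.asarray(m.num), np.asarray(m.den)
    if not num.any():
        return 0.0
    if den[-1] == 0:
        return math.inf
    if num[-1] == 0:
        return 0.0
    return float(num[-1] / den[-1])


def check_equilibrium_condition(
    kappa: AggregatedGains,
    params: ConsortiumParams,
    arch: Architecture | None = None,
) -> tuple[float, bool]:
    """Gain condition governing set-point consistency of the equilibrium.

    lhs = kD + kP*2*ga*mu/(ba*bm*theta) - g^2*ga*mu/(bc*ba*bm*theta^2).
    For P/PD, ``lhs == 0`` is the unitary-static-gain tuning identity; for
    PI/PID, ``lhs <= 0`` is the existence condition of the (unique)
    physical equilibrium.  ``satisfied`` reports the inequality (default)
    or the equality when *arch* is a P/PD architecture.
    """
    p = params
    c = p.gamma_a * p.mu / (p.beta_a * p.beta_m * p.theta)
    lhs = kappa.kappa_D + 2 * kappa.kappa_P * c - p.gamma**2 * c / (p.beta_c * p.theta)
    scale = p.gamma**2 * c / (p.beta_c * p.theta)
    if arch is not None and not arch.has_integral:
        return lhs, bool(abs(lhs) <= 1e-9 * max(scale, 1.0))
    return lhs, bool(lhs <= 1e-12 * max(scale, 1.0))


@dataclass(frozen=True)
class StabilityReport:
    printed: bool
    routh: bool
    agree: bool


def check_stability(kappa: AggregatedGains, params: ConsortiumParams) -> StabilityReport:
    """Simplified design inequality vs the Routh–Hurwitz criterion.

    The simplified condition ``kI < (2g + kD*t*bc)(g^2 + kP*t*bc)``
    (reported as ``printed``) omits a 1/(theta*beta_c) factor relative to
    Routh–Hurwitz on the characteristic cubic; both are evaluated and the
    Routh verdict is authoritative for pole locations.  A disagreement
    triggers a warning.
    """
    p = params
    tb = p.theta * p.beta_c
    a2 = 2 * p.gamma + kappa.kappa_D * tb
    a1 = p.gamma**2 + kappa.kappa_P * tb
    a0 = tb * kappa.kappa_I
    printed = kappa.kappa_I < a2 * a1
    if kappa.kappa_I > 0:
        routh = (a2 > 0) and (a1 > 0) and (a0 > 0) and (a2 * a1 > a0)
    else:
        routh = (a2 > 0) and (a1 > 0)  # after cancelling the origin root
    agree = printed == routh
    if not agree:
        warnings.warn(
            "simplified stability inequality disagrees with Routh-Hurwitz; "
            "the Routh verdict is authoritative",
            stacklevel=2,
        )
    return StabilityReport(bool(printed), bool(routh), bool(agree))


@dataclass
class PoleSet:
    """Closed-loop poles with the dominant subset flagged."""

    poles: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.poles = np.asarray(self.poles, dtype=complex)
        # sort: descending real part, then ascending |imag| (dominance order)
        order = np.lexsort((np.abs(self.poles.imag), -self.poles.real))
        self.poles = self.poles[order]

    @property
    def dominant(self) -> complex:
        return complex(self.poles[0])

    @property
    def dominant_pair(self) -> np.ndarray:
        d = self.dominant
        if abs(d.imag) > 0:
            return np.array([d, d.conjugate()])
        return np.array([d])

    def damping(self) -> np.ndarray:
        """xi = -a/sqrt(a^2+b^2) per pole (1 for real stable poles)."""
        mag = np.abs(self.poles)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = np.where(mag > 0, -self.poles.real / mag, 1.0)
        return xi


def poles(tf: TransferFunction) -> PoleSet:
    """Roots of the (minimal) denominator."""
    m = tf.minimal()
    den = np.asarray(m.den, dtype=float)
    rts = np.roots(den) if den.size > 1 else np.array([], dtype=complex)
    warns: list[str] = []
    if rts.size > 1:
        d = np.abs(rts[:, None] - rts[None, :])
        np.fill_diagonal(d, np.inf)
        scale = max(np.max(np.abs(rts)), 1e-30)
        if np.min(d) < 1e-10 * scale:
            warns.append("nearly coincident roots; locations may be ill-conditioned")
    return PoleSet(rts, warns)


@dataclass
class RootContour:
    """Pole paths under a one-parameter gain sweep."""

    grid: np.ndarray
    swept: str
    pole_sets: list[PoleSet]
    branches: np.ndarray  # (len(grid), n_poles), branch-continuous ordering

    @property
    def dominant_real(self) -> np.ndarray:
        return np.array([ps.dominant.real for ps in self.pole_sets])

    def to_frame(self):
        import pandas as pd

        rows = []
        for g, row, ps in zip(self.grid, self.branches, self.pole_sets):
            order = {z: i for i, z in enumerate(ps.poles)}
            for b, z in enumerate(row):
                rows.append((g, order.get(z, b), z.real, z.imag, b))
        return pd.DataFrame(rows, columns=["gain", "pole_index", "re", "im",
                                           "branch"])


def root_contour(
    params: ConsortiumParams,
    arch: Architecture,
    kappa: AggregatedGains,
    swept: str,
    grid,
) -> RootContour:
    """Sweep one aggregated gain and track the closed-loop pole branches.

    Branches are matched between consecutive grid points by optimal
    assignment in the complex plane, so each branch is a continuous path.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("grid must be strictly increasing with >= 1 point")
    if swept not in ("kappa_P", "kappa_I", "kappa_D"):
        raise ValueError(f"unknown swept gain {swept!r}")

    sets: list[PoleSet] = []
    for g in grid:
        tf = closed_loop_tf(kappa.replace(**{swept: float(g)}), params)
        sets.append(poles(tf))
    n = max(ps.poles.size for ps in sets)
    if any(ps.poles.size != n for ps in sets):
        raise ValueError("pole count changes along the sweep (degenerate grid)")
    branches = np.empty((grid.size, n), dtype=complex)
    branches[0] = sets[0].poles
    for k in range(1, grid.size):
        prev, cur = branches[k - 1], sets[k].poles
        cost = np.abs(prev[:, None] - cur[None, :])
        ri, ci = linear_sum_assignment(cost)
        branches[k, ri] = cur[ci]
    return RootContour(grid, swept, sets, branches)


def dominant_pole_bound(
    arch: Architecture, kappa: AggregatedGains, params: ConsortiumParams
) -> float:
    """Lower bound on the dominant pole's real part for the architecture.

    sbP = -g;  sbPD = -sqrt(g^2 + t*bc*kP);  sbPI = -(2/3)g;
    sbPID = -(2/3)g - (1/3)t*bc*kD.
    """
    p = params
    tb = p.theta * p.beta_c
    if arch.label == "P":
        return -p.gamma
    if arch.label == "PD":
        return -math.sqrt(p.gamma**2 + tb * kappa.kappa_P)
    if arch.label == "PI":
        return -(2.0 / 3.0) * p.gamma
    return -(2.0 / 3.0) * p.gamma - tb * kappa.kappa_D / 3.0


@dataclass
class TuneResult:
    swept: str
    gain: float
    kappa: AggregatedGains
    pole_set: PoleSet
    coincident: bool
    message: str = ""


def _cubic_discriminant(a2: float, a1: float, a0: float) -> float:
    return (
        18 * a2 * a1 * a0 - 4 * a2**3 * a0 + a2**2 * a1**2 - 4 * a1**3 - 27 * a0**2
    )


def tune_fastest(
    arch: Architecture, params: ConsortiumParams, kappa: AggregatedGains
) -> TuneResult:
    """Gain value giving coincident dominant real poles (fastest response).

    PD: sweeps kappa_D for the double real pole of the quadratic factor.
    PI/PID: sweeps kappa_I to the discriminant-zero point of the cubic
    that maximises |Re| of the dominant pole.  The search is numeric; the
    resulting pole set is returned alongside the tuned gain.
    """
    p = params
    tb = p.theta * p.beta_c
    if arch.label == "P":
        raise ValueError("the P architecture has no free gain to tune for speed")

    if arch.label == "PD":
        # (2g + tb*kD)^2 = 4(g^2 + tb*kP): unique kD >= 0 when kP > 0
        target = 4 * (p.gamma**2 + tb * kappa.kappa_P)

        def f(kD):
            return (2 * p.gamma + tb * kD) ** 2 - target

        if f(0.0) >= 0:
            k = kappa.replace(kappa_D=0.0, kappa_I=0.0)
            ps = poles(closed_loop_tf(k, params))
            return TuneResult("kappa_D", 0.0, k, ps, f(0.0) == 0,
                              "no positive kappa_D produces coincident poles")
        hi = 1.0
        while f(hi) < 0:
            hi *= 10
        kD = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
        k = kappa.replace(kappa_D=float(kD), kappa_I=0.0)
        return TuneResult("kappa_D", float(kD), k, poles(closed_loop_tf(k, params)), True)

    # PI / PID: cubic s^3 + a2 s^2 + a1 s + a0, a0 = tb*kappa_I swept
    a2 = 2 * p.gamma + tb * (kappa.kappa_D if arch.has_derivative else 0.0)
    a1 = p.gamma**2 + tb * kappa.kappa_P
    # discriminant is quadratic in a0
    A = -27.0
    B = 18 * a2 * a1 - 4 * a2**3
    C = a2**2 * a1**2 - 4 * a1**3
    disc = B * B - 4 * A * C
    scale = abs(B * B) + abs(4 * A * C)
    if disc < 0 and abs(disc) <= 1e-9 * max(scale, 1e-300):
        disc = 0.0  # triple-root degeneracy: the two tuning points merge
    candidates: list[float] = []
    if disc >= 0:
        for a0 in ((-B + math.sqrt(disc)) / (2 * A), (-B - math.sqrt(disc)) / (2 * A)):
            if a0 > 0:
                candidates.append(a0)
    best: TuneResult | None = None
    for a0 in candidates:
        kI = a0 / tb
        kD = kappa.kappa_D if arch.has_derivative else 0.0
        k = kappa.replace(kappa_I=float(kI), kappa_D=kD)
        ps = poles(closed_loop_tf(k, params))
        if ps.dominant.real >= 0:
            continue
        if best is None or ps.dominant.real < best.pole_set.dominant.real:
            best = TuneResult("kappa_I", float(kI), k, ps, True)
    if best is not None:
        return best
    # fallback: scan for the best achievable dominant pole
    kIs = np.geomspace(1e-8, a2 * a1 / tb, 400)
    recs = []
    for kI in kIs:
        k = kappa.replace(kappa_I=float(kI),
                          kappa_D=kappa.kappa_D if arch.has_derivative else 0.0)
        ps = poles(closed_loop_tf(k, params))
        recs.append((ps.dominant.real, float(kI), k, ps))
    re, kI, k, ps = min(recs, key=lambda r: r[0])
    return TuneResult("kappa_I", kI, k, ps, False,
                      "no coincident-pole point found; best achievable returned")


def predict_metrics_from_poles(pole_set: PoleSet, chi: float = 0.10):
    """Settling-time estimate ``|ln(chi)|/|Re(dominant)|`` and damping.

    Raises ``ValueError`` when the dominant pole does not decay.
    """
    a = pole_set.dominant.real
    if a >= 0:
        raise ValueError("dominant pole has nonnegative real part: non-settling")
    ts = abs(math.log(chi)) / abs(a)
    d = pole_set.dominant
    xi = 1.0 if d.imag == 0 else -d.real / abs(d)
    return ts, xi


def analysis_report(
    params: ConsortiumParams, gains: ControlGains, arch: Architecture
) -> dict:
    """JSON-ready summary of the linearized closed loop."""
    kappa = aggregate_gains(params, gains, arch)
    tf = closed_loop_tf(kappa, params)
    ps = poles(tf)
    stab = check_stability(kappa, params)
    lhs, ok = check_equilibrium_condition(kappa, params, arch)
    return {
        "architecture": arch.label,
        "kappa": {"P": kappa.kappa_P, "I": kappa.kappa_I, "D": kappa.kappa_D},
        "gamma_ell": kappa.Gamma,
        "static_gain": static_gain(tf),
        "poles": [(z.real, z.imag) for z in ps.poles],
        "stability": {"printed": stab.printed, "routh": stab.routh,
                      "agree": stab.agree},
        "equilibrium_condition": {"lhs": lhs, "satisfied": ok},
        "dominant_pole_bound": dominant_pole_bound(arch, kappa, params),
    }
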