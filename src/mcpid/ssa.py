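"""Per-cell stochastic simulation (Gillespie direct method).

The reaction network is read off the per-cell rate laws: every additive
term of the deterministic equations becomes a propensity.  Mass-action
terms scale with the system size ``Omega`` (molecules per nM); the Hill
and Michaelis–Menten terms are used as nonlinear rate laws on counts.
Growth, division and spatial effects are disabled; cells couple through
the shared extracellular pool exactly as in the deterministic per-cell
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetero import CELL_SPECIES, Cell
from .params import ConsortiumParams

__all__ = ["SSAResult", "build_reactions", "ssa_run"]


@dataclass
class _Reaction:
    kind: str          # const | linear | bilinear | hill_p | mm
    rate: float        # rate constant (units per kind)
    sidx: tuple[int, ...]   # species the propensity depends on
    changes: tuple[tuple[int, int], ...]  # (species index, +/- count)
    aux: tuple[float, ...] = ()


@dataclass
class SSAResult:
    """Counts sampled on a uniform grid, with nM conversion helpers."""

    times: np.ndarray
    counts: np.ndarray        # (T, n_species) integer counts
    labels: tuple[str, ...]
    omega: float
    meta: dict

    def concentration(self, label: str) -> np.ndarray:
        return self.counts[:, self.labels.index(label)] / self.omega

    def mean_concentration(self, pop: str, species: str) -> np.ndarray:
        cols = [i for i, lab in enumerate(self.labels)
                if lab.startswith(f"{pop}") and lab.endswith(f".{species}")]
        return self.counts[:, cols].mean(axis=1) / self.omega


def build_reactions(cells: list[Cell], env: ConsortiumParams, omega: float):
    """Reaction list + species labels for the given consortium.

    Reactions with a zero rate constant are dropped (they can never fire).
    """
    labels: list[str] = ["Qx_e", "Qu_e"]
    rxns: list[_Reaction] = []
    IQXE, IQUE = 0, 1

    # external degradation
    rxns.append(_Reaction("linear", env.gamma_e, (IQXE,), ((IQXE, -1),)))
    rxns.append(_Reaction("linear", env.gamma_e, (IQUE,), ((IQUE, -1),)))

    for ci, c in enumerate(cells):
        p = c.params
        base = len(labels)
        spec = CELL_SPECIES[c.label]
        labels.extend(f"{c.label}{ci}.{sp}" for sp in spec)
        ix = {sp: base + j for j, sp in enumerate(spec)}
        QX, QU = ix["Qx"], ix["Qu"]

        # QS exchange with the environment and dilution, common to all cells
        for q, qe in ((QX, IQXE), (QU, IQUE)):
            rxns.append(_Reaction("linear", p.eta, (q,), ((q, -1), (qe, +1))))
            rxns.append(_Reaction("linear", p.eta, (qe,), ((qe, -1), (q, +1))))
            rxns.append(_Reaction("linear", p.gamma, (q,), ((q, -1),)))

        if c.label == "t":
            X1, XC = ix["X1"], ix["Xc"]
            rxns += [
                _Reaction("linear", p.beta_u, (QU,), ((X1, +1),)),
                _Reaction("linear", p.gamma, (X1,), ((X1, -1),)),
                _Reaction("linear", p.beta_c, (X1,), ((XC, +1),)),
                _Reaction("linear", p.gamma, (XC,), ((XC, -1),)),
                _Reaction("linear", p.beta_x, (XC,), ((QX, +1),)),
            ]
        elif c.label == "p":
            # production with the repression Hill law on the sensed Qx
            rxns.append(_Reaction(
                "hill_p", c.gains.beta_P * p.Yd, (QX,), ((QU, +1),),
                aux=(p.mu * p.Yd, p.theta)))
        elif c.label == "i":
            Z1, Z2 = ix["Z1"], ix["Z2"]
            rxns += [
                _Reaction("const", p.mu * p.Yd, (), ((Z1, +1),)),
                _Reaction("linear", p.theta, (QX,), ((Z2, +1),)),
                _Reaction("bilinear", p.gamma_z, (Z1, Z2), ((Z1, -1), (Z2, -1))),
                _Reaction("linear", c.gains.beta_I, (Z1,), ((QU, +1),)),
            ]
        else:  # derivative cells
            A, M = ix["A"], ix["M"]
            rxns += [
                _Reaction("linear", p.beta_a, (M,), ((A, +1),)),
                _Reaction("mm", p.gamma_a, (QX, A), ((A, -1),), aux=(p.K_a,)),
                _Reaction("linear", p.gamma, (A,), ((A, -1),)),
                _Reaction("const", p.beta_m * p.Yd, (), ((M, +1),)),
                _Reaction("mm", p.gamma_m, (A, M), ((M, -1),), aux=(p.K_m,)),
            ]
    rxns = [r for r in rxns if r.rate > 0]
    return rxns, tuple(labels)


class _PropensityTable:
    """Vectorized propensity evaluation, grouped by rate-law kind."""

    def __init__(self, rxns: list[_Reaction], omega: float):
        self.m = len(rxns)
        self.omega = omega

        def select(kind):
            return [(k, r) for k, r in enumerate(rxns) if r.kind == kind]

        lin = select("linear")
        self.lin_k = np.array([k for k, _ in lin], dtype=int)
        self.lin_rate = np.array([r.rate for _, r in lin])
        self.lin_i = np.array([r.sidx[0] for _, r in lin], dtype=int)

        con = select("const")
        self.con_k = np.array([k for k, _ in con], dtype=int)
        self.con_a = np.array([r.rate * omega for _, r in con])

        bil = select("bilinear")
        self.bil_k = np.array([k for k, _ in bil], dtype=int)
        self.bil_rate = np.array([r.rate / omega for _, r in bil])
        self.bil_i = np.array([r.sidx[0] for _, r in bil], dtype=int)
        self.bil_j = np.array([r.sidx[1] for _, r in bil], dtype=int)

        hil = select("hill_p")
        self.hil_k = np.array([k for k, _ in hil], dtype=int)
        self.hil_num = np.array([omega * r.rate * r.aux[0] for _, r in hil])
        self.hil_r0 = np.array([r.aux[0] for _, r in hil])
        self.hil_th = np.array([r.aux[1] / omega for _, r in hil])
        self.hil_i = np.array([r.sidx[0] for _, r in hil], dtype=int)

        mm = select("mm")
        self.mm_k = np.array([k for k, _ in mm], dtype=int)
        self.mm_rate = np.array([r.rate for _, r in mm])
        self.mm_i = np.array([r.sidx[0] for _, r in mm], dtype=int)
        self.mm_j = np.array([r.sidx[1] for _, r in mm], dtype=int)
        self.mm_K = np.array([r.aux[0] * omega for _, r in mm])

    def __call__(self, n, out):
        if self.lin_k.size:
            out[self.lin_k] = self.lin_rate * n[self.lin_i]
        if self.con_k.size:
            out[self.con_k] = self.con_a
        if self.bil_k.size:
            out[self.bil_k] = self.bil_rate * n[self.bil_i] * n[self.bil_j]
        if self.hil_k.size:
            out[self.hil_k] = self.hil_num / (self.hil_r0 + self.hil_th * n[self.hil_i])
        if self.mm_k.size:
            out[self.mm_k] = (self.mm_rate * n[self.mm_i] * n[self.mm_j]
                              / (self.mm_K + n[self.mm_j]))
        return out


def ssa_run(
    cells: list[Cell],
    params: ConsortiumParams,
    omega: float,
    t_end: float,
    rng: np.random.Generator,
    *,
    dt_out: float = 1.0,
    init_counts: np.ndarray | None = None,
    max_events: int = 50_000_000,
) -> SSAResult:
    """Gillespie direct-method simulation of the consortium.

    ``omega`` converts concentrations to counts (molecules per nM).  Counts
    are recorded on a uniform grid; a zero total propensity simply jumps to
    ``t_end``.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    rxns, labels = build_reactions(cells, params, omega)
    table = _PropensityTable(rxns, omega)
    changes = [r.changes for r in rxns]
    n = np.zeros(len(labels), dtype=np.int64)
    if init_counts is not None:
        n[:] = np.asarray(init_counts)
        if (n < 0).any():
            raise ValueError("initial counts must be nonnegative integers")
    times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    rec = np.zeros((times.size, n.size), dtype=np.int64)
    a = np.zeros(len(rxns))
    t = 0.0
    next_rec = 0
    events = 0
    exp_draw = rng.exponential
    uni = rng.random
    while t < t_end and events < max_events:
        table(n, a)
        cum = np.cumsum(a)
        total = cum[-1]
        if total <= 0 or not np.isfinite(total):
            break
        t += exp_draw(1.0 / total)
        while next_rec < times.size and times[next_rec] < t:
            rec[next_rec] = n
            next_rec += 1
        if t >= t_end:
            break
        k = int(np.searchsorted(cum, uni() * total, side="right"))
        for i, dn in changes[k]:
            n[i] += dn
        events += 1
    while next_rec < times.size:
        rec[next_rec] = n
        next_rec += 1
    return SSAResult(times, rec, labels, omega,
                     {"events": events, "t_end": t_end})
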