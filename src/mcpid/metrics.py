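"""Performance metrics on regulation trajectories and campaigns.

Conventions: the steady-state value is the mean of the output over the
final 600 minutes; the settling time is the *last* time the signal leaves
the ±chi band around that value (robust to transient re-entries); the
overshoot is the peak excursion above the steady state, in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RequirementSpec",
    "PerformanceReport",
    "moving_average",
    "steady_state_value",
    "settling_time",
    "overshoot",
    "error_percent",
    "error_bar",
    "evaluate_run",
    "summarize_campaign",
]


@dataclass(frozen=True)
class RequirementSpec:
    """Control requirements: error bound, settling bound, overshoot bound."""

    epsilon: float = 0.10      # |e_inf| / set point
    tau: float = 1440.0        # settling bound, min
    varpi: float = 20.0        # overshoot bound, %
    chi: float = 0.10          # settling band, fraction of y_inf

    def __post_init__(self) -> None:
        if min(self.epsilon, self.tau, self.varpi, self.chi) <= 0:
            raise ValueError("requirement bounds must be strictly positive")


@dataclass
class PerformanceReport:
    """Per-run metrics and pass flags against a RequirementSpec."""

    y_inf: float
    e_inf: float           # relative steady-state error (fraction)
    ts: float              # settling time, min
    o: float               # overshoot, %
    settled: bool
    pass_e: bool
    pass_ts: bool
    pass_o: bool

    @property
    def passed(self) -> bool:
        return self.pass_e and self.pass_ts and self.pass_o

    def to_dict(self) -> dict:
        return {
            "y_inf": self.y_inf, "e_inf": self.e_inf, "ts": self.ts, "o": self.o,
            "settled": self.settled, "pass_e": self.pass_e,
            "pass_ts": self.pass_ts, "pass_o": self.pass_o,
        }


def moving_average(signal, W: int):
    """Centred moving average of width *W*; edges use a shrunk window."""
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValueError("signal must have at least one sample")
    if W < 1:
        raise ValueError("window width must be >= 1")
    if W == 1:
        return x.copy()
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - (W - 1) // 2, 0)
    hi = np.minimum(i + W // 2 + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def steady_state_value(times, signal, window: float = 600.0) -> float:
    """Mean of *signal* over the final *window* minutes."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(signal, dtype=float)
    if t[-1] - t[0] < window:
        raise ValueError("trajectory shorter than the averaging window")
    mask = t >= t[-1] - window
    return float(np.trapezoid(x[mask], t[mask]) / (t[mask][-1] - t[mask][0]))


def settling_time(times, signal, y_inf: float, chi: float = 0.10):
    """Last exit time from the band ``y_inf*(1±chi)``.

    Returns ``(ts, settled)``; ``ts = 0`` if the signal never leaves the
    band, and ``settled`` is False when the final sample is outside it.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(signal, dtype=float)
    if y_inf == 0:
        if np.any(x != 0):
            raise ValueError("settling time undefined for y_inf = 0")
        return 0.0, True
    outside = np.abs(x - y_inf) > chi * abs(y_inf)
    if not outside.any():
        return 0.0, True
    if outside[-1]:
        return float(t[-1]), False
    last = np.max(np.nonzero(outside)[0])
    return float(t[last + 1]), True


def overshoot(signal, y_inf: float) -> float:
    """Peak excursion above y_inf, percent: max(0, (max y - y_inf)/y_inf)*100."""
    if y_inf <= 0:
        raise ValueError("overshoot undefined for y_inf <= 0")
    x = np.asarray(signal, dtype=float)
    return float(max(0.0, (x.max() - y_inf) / y_inf) * 100.0)


def error_percent(times_list, signals_list, Qd: float, window: float = 600.0) -> float:
    """Campaign steady-state error: mean over runs of |Qhat_k - Qd|/Qd * 100.

    Qhat_k is the last-``window``-minute average of run k; Qd the desired
    output value.
    """
    if Qd == 0:
        raise ValueError("Qd must be nonzero")
    if len(times_list) < 1:
        raise ValueError("need at least one run")
    errs = [
        abs(steady_state_value(t, x, window) - Qd) / abs(Qd) * 100.0
        for t, x in zip(times_list, signals_list)
    ]
    return float(np.mean(errs))


def error_bar(times, error_signal, ts_cut: float = 1440.0, tf: float | None = None) -> float:
    """Time-average of the signed error from ts_cut to tf (trapezoidal)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(error_signal, dtype=float)
    if tf is None:
        tf = float(t[-1])
    if tf <= ts_cut:
        raise ValueError("tf must exceed ts_cut")
    mask = (t >= ts_cut) & (t <= tf)
    if mask.sum() < 2:
        raise ValueError("insufficient samples in the averaging window")
    tm, em = t[mask], e[mask]
    return float(np.trapezoid(em, tm) / (tm[-1] - tm[0]))


def evaluate_run(
    times,
    output,
    set_point: float,
    spec: RequirementSpec = RequirementSpec(),
    ss_window: float = 600.0,
) -> PerformanceReport:
    """Full per-run report: y_inf, e_inf, ts, overshoot and pass flags."""
    if not np.all(np.isfinite(output)):
        return PerformanceReport(
            y_inf=math.nan, e_inf=math.nan, ts=math.nan, o=math.nan,
            settled=False, pass_e=False, pass_ts=False, pass_o=False)
    y_inf = steady_state_value(times, output, ss_window)
    if set_point == 0:
        e_inf = 0.0 if y_inf == 0 else math.inf
    else:
        e_inf = abs(y_inf - set_point) / abs(set_point)
    if y_inf <= 0:  # collapsed output: no settling/overshoot defined
        return PerformanceReport(
            y_inf=y_inf, e_inf=e_inf, ts=math.nan, o=0.0, settled=False,
            pass_e=bool(e_inf <= spec.epsilon), pass_ts=False, pass_o=False)
    ts, settled = settling_time(times, output, y_inf, spec.chi)
    o = overshoot(output, y_inf)
    return PerformanceReport(
        y_inf=y_inf, e_inf=e_inf, ts=ts, o=o, settled=settled,
        pass_e=bool(e_inf <= spec.epsilon),
        pass_ts=bool(settled and ts <= spec.tau),
        pass_o=bool(o <= spec.varpi),
    )


def summarize_campaign(values) -> dict:
    """Box-plot statistics with the Tukey 1.5*IQR outlier rule.

    Returns median, quartiles, whisker endpoints (min/max excluding
    outliers) and the outlier list.
    """
    x = np.asarray(values, dtype=float)
    n_bad = int(np.sum(~np.isfinite(x)))
    x = np.sort(x[np.isfinite(x)])
    if x.size < 1:
        raise ValueError("need at least one finite value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    outliers = x[(x < lo) | (x > hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(v) for v in outliers],
        "n": int(x.size),
        "n_dropped": n_bad,
    }
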