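"""Homogenization metrics: global mixing index, mixing times, probe traces.

The global mixing index is the variance-based homogenization indicator

.. math::

    M_{global}(t) = 1 - \\frac{1}{V} \\sum_i V_i
        \\left( \\frac{c_i(t)}{c_\\infty} - 1 \\right)^2

which equals 1 iff the tracer field is perfectly homogeneous and can be
strongly negative early on near the injection.  Mixing times use the
last-crossing convention: the earliest time after which the criterion holds
permanently, which is robust to transient re-crossings of the threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixingCurve",
    "ProbeTrace",
    "mixing_index_global",
    "mixing_time_global",
    "mixing_time_probe",
    "relative_error",
    "read_trace_csv",
    "write_trace_csv",
    "mixing_time_report",
    "NOT_SETTLED",
]

#: Sentinel for "criterion never met within the curve horizon".
NOT_SETTLED = math.inf


@dataclass
class MixingCurve:
    """Global mixing index versus time for one tracer experiment."""

    times: np.ndarray
    index: np.ndarray
    c_inf: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if self.times.shape != self.index.shape or self.times.ndim != 1:
            raise ValueError("times and index must be congruent 1D arrays")


@dataclass
class ProbeTrace:
    """Local probe signal (concentration or conductivity) versus time.

    ``dead_time`` is the transport delay to an external sensor (e.g. tubing
    dead volume of a pumped conductivity loop); it is subtracted before the
    mixing time is evaluated.
    """

    times: np.ndarray
    signal: np.ndarray
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be congruent 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")


def mixing_index_global(
    concentrations: np.ndarray, volumes: np.ndarray, c_inf: float
) -> float:
    """Volume-weighted squared-deviation homogenization index (<= 1)."""
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if c.shape != v.shape:
        raise ValueError("concentrations and volumes must be congruent")
    if c_inf <= 0:
        raise ValueError("c_inf must be positive")
    return float(1.0 - np.sum(v * (c / c_inf - 1.0) ** 2) / np.sum(v))


def _last_crossing_time(
    times: np.ndarray, ok: np.ndarray, level_curve: np.ndarray, level: float
) -> float:
    """Earliest time after which ``ok`` holds permanently, interpolating the
    crossing of ``level_curve`` through ``level`` on the last violating step."""
    if not ok[-1]:
        return NOT_SETTLED
    if ok.all():
        return float(times[0])
    i = int(np.nonzero(~ok)[0][-1])  # last violating sample
    t0, t1 = times[i], times[i + 1]
    y0, y1 = level_curve[i], level_curve[i + 1]
    if y1 == y0:
        return float(t1)
    frac = (level - y0) / (y1 - y0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t0 + frac * (t1 - t0))


def mixing_time_global(curve: MixingCurve, criterion: float = 0.95) -> float:
    """Mixing time: earliest time with M_global >= criterion for all later t.

    Linear interpolation between curve samples; returns :data:`NOT_SETTLED`
    (``inf``) if the criterion is not met at the end of the curve.
    """
    if not 0 < criterion < 1:
        raise ValueError("criterion must be in (0, 1)")
    if curve.times.size == 0:
        raise ValueError("empty mixing curve")
    ok = curve.index >= criterion
    return _last_crossing_time(curve.times, ok, curve.index, criterion)


def mixing_time_probe(
    trace: ProbeTrace, band: float = 0.95, final_value: float | None = None
) -> float:
    """Mixing time from a local probe signal.

    Returns the earliest (dead-time-corrected) time after which the signal
    stays within ``±(1 - band)`` of ``final_value`` (two-sided band; default
    final value is the last sample).  Raises if the trace never settles.
    """
    if not 0 < band < 1:
        raise ValueError("band must be in (0, 1)")
    final = float(trace.signal[-1]) if final_value is None else float(final_value)
    if final <= 0:
        raise ValueError("final value must be positive")
    dev = np.abs(trace.signal / final - 1.0)
    tol = 1.0 - band
    ok = dev <= tol
    t = _last_crossing_time(trace.times, ok, -dev, -tol)
    if not np.isfinite(t):
        raise ValueError("probe trace never settles within the band")
    return max(t - trace.dead_time, 0.0)


def relative_error(experimental: float, simulated: float) -> float:
    """Percent deviation of a simulated value from an experimental one."""
    if experimental <= 0:
        raise ValueError("experimental value must be positive")
    return 100.0 * abs(experimental - simulated) / experimental


def read_trace_csv(path) -> ProbeTrace:
    """Read a probe trace from CSV with columns ``time_s, signal``."""
    df = pd.read_csv(path)
    missing = {"time_s", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return ProbeTrace(times=df["time_s"].to_numpy(), signal=df["signal"].to_numpy())


def write_trace_csv(trace: ProbeTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "signal": trace.signal}).to_csv(
        path, index=False
    )


def mixing_time_report(criterion: float, mixing_time_s: float) -> str:
    """JSON mixing-time report (criterion, value, crossing convention)."""
    return json.dumps(
        {
            "criterion": criterion,
            "mixing_time_s": mixing_time_s if math.isfinite(mixing_time_s) else None,
            "convention": "last-crossing",
        }
    )
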