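"""Sampled cardiac-cycle time series and the flow/pressure operations on them.

A :class:`Waveform` holds one cardiac cycle of a scalar quantity (volumetric
flow rate, pressure, or a velocity trace) on a strictly increasing time grid.
Everything downstream — stroke volume, Windkessel pressures, transvalvular
gradients — consumes this container, so its quadrature conventions (composite
trapezoid, linear interpolation at window endpoints) are fixed here once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "UNIT_FLOW",
    "UNIT_PRESSURE",
    "UNIT_VELOCITY",
    "integrate",
    "detect_systole",
    "zero_diastole",
    "stroke_volume",
    "resample",
    "read_waveform_csv",
    "write_waveform_csv",
]

UNIT_FLOW = "flow_mL_per_s"
UNIT_PRESSURE = "pressure_mmHg"
UNIT_VELOCITY = "velocity_m_per_s"
_VALID_UNITS = frozenset({UNIT_FLOW, UNIT_PRESSURE, UNIT_VELOCITY})

MIN_SAMPLES = 8


class NoSystoleError(ValueError):
    """Raised when a flow waveform has no positive lobe to detect."""


@dataclass(frozen=True)
class Waveform:
    """One cardiac cycle of a sampled scalar signal.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, spanning one cycle.
    values
        Sample values; the physical meaning is carried by ``unit``.
    period
        Cycle period T in seconds. The time grid need not reach exactly
        ``times[0] + period``; the period is authoritative for cycle means.
    unit
        One of ``flow_mL_per_s``, ``pressure_mmHg``, ``velocity_m_per_s``.
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    unit: str = UNIT_FLOW

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples per cycle, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {sorted(_VALID_UNITS)}")

    @property
    def n(self) -> int:
        return self.times.size

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolant of the samples (no extrapolation)."""
        return np.interp(t, self.times, self.values)

    def mean(self) -> float:
        """Cycle-averaged value: trapezoid integral over the grid divided by T."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def with_values(self, values: np.ndarray) -> "Waveform":
        return replace(self, values=np.asarray(values, dtype=float))


def integrate(w: Waveform, t0: float, t1: float) -> float:
    """Trapezoidal integral of ``w`` over the window ``[t0, t1]``.

    The waveform is treated as piecewise linear; values at the window
    endpoints are obtained by linear interpolation, so the result is exact
    for the piecewise-linear representation.
    """
    if not t0 < t1:
        raise ValueError(f"require t0 < t1, got ({t0}, {t1})")
    if t0 < w.times[0] or t1 > w.times[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] outside sampled range [{w.times[0]}, {w.times[-1]}]"
        )
    inside = (w.times > t0) & (w.times < t1)
    tt = np.concatenate(([t0], w.times[inside], [t1]))
    vv = np.concatenate(([w.value_at(t0)], w.values[inside], [w.value_at(t1)]))
    return float(np.trapezoid(vv, tt))


def detect_systole(w: Waveform, threshold_frac: float = 0.01) -> tuple[float, float]:
    """Locate the ejection window of a flow waveform.

    Returns ``(t_bs, t_es)``: the times of the first and last samples whose
    value exceeds ``threshold_frac * max(Q)``. Detection is resolved to the
    sampling grid — no sub-sample root finding — so a sharp-edged pulse
    reports its exact sample edges.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    peak = float(np.max(w.values))
    if peak <= 0:
        raise NoSystoleError("waveform has no positive flow; cannot detect systole")
    above = w.values > threshold_frac * peak
    idx = np.flatnonzero(above)
    t_bs = float(w.times[idx[0]])
    t_es = float(w.times[idx[-1]])
    if not t_bs < t_es:
        raise NoSystoleError("systolic window degenerate (single sample above threshold)")
    return t_bs, t_es


def zero_diastole(w: Waveform, threshold_frac: float = 0.01) -> Waveform:
    """Clamp all samples outside the detected systolic window to exactly zero.

    Mirrors the common inlet-conditioning assumption that diastolic flow
    through a closed (competent) valve is negligible. Idempotent.
    """
    t_bs, t_es = detect_systole(w, threshold_frac)
    out = w.values.copy()
    out[(w.times < t_bs) | (w.times > t_es)] = 0.0
    return w.with_values(out)


def stroke_volume(w: Waveform, threshold_frac: float = 0.01) -> float:
    """Stroke volume in mL: flow integrated over the detected systole."""
    t_bs, t_es = detect_systole(w, threshold_frac)
    return integrate(w, t_bs, t_es)


def resample(w: Waveform, n: int) -> Waveform:
    """Linear resampling onto ``n`` uniform samples over ``[times[0], times[-1]]``."""
    if n < MIN_SAMPLES:
        raise ValueError(f"n must be >= {MIN_SAMPLES}, got {n}")
    tt = np.linspace(w.times[0], w.times[-1], n)
    return replace(w, times=tt, values=w.value_at(tt))


def read_waveform_csv(path: str | Path, period: float, unit: str = UNIT_FLOW) -> Waveform:
    """Read a two-column ``time_s,value`` CSV (header row required)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(f"expected columns ['time_s', 'value'], got {list(df.columns)}")
    return Waveform(df["time_s"].to_numpy(float), df["value"].to_numpy(float), period, unit)


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": w.times, "value": w.values}).to_csv(path, index=False)
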