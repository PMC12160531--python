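"""Valve performance metrics and plane-based velocity analysis.

Implements the clinical/engineering indices used to grade aortic-valve
function from solver or 4D-flow-style data:

* EOA — effective orifice area from energy conservation (Gorlin-type):
  ``EOA = Q_RMS / (51.6 * sqrt(dP_mean / rho_f))`` with Q_RMS in mL/s, the
  mean positive transvalvular pressure difference in mmHg, rho_f in g/cm^3
  and the result in cm^2. The formula is evaluated verbatim in this mixed
  clinical unit system (the 51.6 constant absorbs the conversions).
* AVA — continuity-equation area, stroke volume / velocity-time integral.
* TPG — time-mean systolic pressure difference between ventricular and
  aortic sampling stations.
* MPG — Bernoulli mean gradient, the sample mean of 4*v_max^2 (v in m/s,
  result in mmHg) over the valve-open time points.
* plane-based flow rate, mean and max speed on a disc section of a
  structured-grid velocity volume (the 4D-flow comparison quantities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .waveforms import Waveform, integrate

__all__ = [
    "PlaneSection",
    "VelocityVolume",
    "eoa",
    "ava",
    "tpg",
    "mpg",
    "vti",
    "plane_flow_rate",
    "plane_velocity_stats",
]


@dataclass(frozen=True)
class PlaneSection:
    """A sampling disc: origin (mm), unit normal, and radius bound (mm)."""

    origin: np.ndarray
    normal: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)
        if o.shape != (3,) or n.shape != (3,):
            raise ValueError("origin and normal must be length-3 vectors")
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
            raise ValueError("normal must be a unit vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(self.normal, ref)
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(self.normal, e1)


@dataclass(frozen=True)
class VelocityVolume:
    """Velocity snapshots on a structured axis-aligned grid.

    ``axes`` are the three monotonically increasing coordinate vectors in mm
    (uniform spacing per axis); ``frames`` has shape (nt, nx, ny, nz, 3) in
    m/s with NaN marking out-of-lumen points; ``times`` in seconds.
    """

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        fr = np.asarray(self.frames, dtype=float)
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "times", t)
        shape = tuple(a.size for a in axes)
        if fr.ndim != 5 or fr.shape[1:4] != shape or fr.shape[4] != 3:
            raise ValueError(f"frames must be (nt, {shape[0]}, {shape[1]}, {shape[2]}, 3)")
        if fr.shape[0] != t.size:
            raise ValueError("frame count must equal time count")
        for a in axes:
            d = np.diff(a)
            if a.size < 2 or not np.all(d > 0) or not np.allclose(d, d[0]):
                raise ValueError("grid axes must be uniform and increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def eoa(Q: Waveform, dP: Waveform, rho_f: float = 1.06) -> float:
    """Effective orifice area (cm^2) from flow (mL/s) and pressure drop (mmHg).

    The averaging window is the maximal contiguous interval of positive
    transvalvular pressure difference containing the pressure-difference
    maximum. Q_RMS and the mean difference are trapezoid-based time means
    over that window.
    """
    if not np.array_equal(Q.times, dP.times):
        raise ValueError("flow and pressure difference must share a time grid")
    pos = dP.values > 0
    if not np.any(pos):
        raise ValueError("no positive pressure-difference window: EOA undefined")
    i_peak = int(np.argmax(dP.values))
    lo = i_peak
    while lo > 0 and pos[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < dP.n - 1 and pos[hi + 1]:
        hi += 1
    if hi == lo:
        raise ValueError("positive pressure-difference window degenerate")
    t0, t1 = float(dP.times[lo]), float(dP.times[hi])
    dur = t1 - t0
    q_rms = float(np.sqrt(integrate(Q.with_values(Q.values**2), t0, t1) / dur))
    dp_mean = integrate(dP, t0, t1) / dur
    if dp_mean <= 0:
        raise ValueError("mean pressure difference non-positive over window")
    return q_rms / (51.6 * np.sqrt(dp_mean / rho_f))


def ava(sv: float, vti_cm: float) -> float:
    """Continuity-equation aortic valve area (cm^2) = SV (mL) / VTI (cm)."""
    if sv <= 0 or vti_cm <= 0:
        raise ValueError("stroke volume and VTI must be positive")
    return sv / vti_cm


def tpg(p_lv: Waveform, p_ao: Waveform, t_bs: float, t_es: float) -> float:
    """Mean systolic transvalvular pressure gradient (mmHg).

    Trapezoid time-mean of the ventricular-minus-aortic pressure difference
    over the systolic window ``[t_bs, t_es]``.
    """
    if not np.array_equal(p_lv.times, p_ao.times):
        raise ValueError("pressure traces must share a time grid")
    if not t_bs < t_es:
        raise ValueError("require t_bs < t_es")
    diff = p_lv.with_values(p_lv.values - p_ao.values)
    return integrate(diff, t_bs, t_es) / (t_es - t_bs)


def mpg(v_max: Waveform, open_interval: tuple[float, float]) -> float:
    """Bernoulli mean pressure gradient (mmHg) from the peak-velocity trace.

    Sample mean (not time integral) of ``4 v^2`` over the time points inside
    the valve-open interval, matching the discrete echocardiographic sum.
    """
    t0, t1 = open_interval
    if not t0 < t1:
        raise ValueError("open interval must be non-empty")
    inside = (v_max.times >= t0) & (v_max.times <= t1)
    if not np.any(inside):
        raise ValueError("no samples inside the valve-open interval: MPG undefined")
    v = v_max.values[inside]
    return float(np.mean(4.0 * v**2))


def vti(v_max: Waveform, window: tuple[float, float]) -> float:
    """Velocity-time integral (cm) of the peak-velocity trace (m/s) over a window."""
    t0, t1 = window
    return integrate(v_max, t0, t1) * 100.0  # m -> cm


def _disc_samples(plane: PlaneSection, n_r: int, n_theta: int):
    """Midpoint polar quadrature nodes and area weights (mm^2) on the disc."""
    e1, e2 = plane.basis()
    dr = plane.radius / n_r
    r = (np.arange(n_r) + 0.5) * dr
    th = (np.arange(n_theta) + 0.5) * (2.0 * np.pi / n_theta)
    rr, tt = np.meshgrid(r, th, indexing="ij")
    pts = (plane.origin[None, :]
           + (rr * np.cos(tt)).ravel()[:, None] * e1
           + (rr * np.sin(tt)).ravel()[:, None] * e2)
    w = (rr * dr * (2.0 * np.pi / n_theta)).ravel()  # ring-sector areas, sum = pi R^2
    return pts, w


def _interp_frame(vol: VelocityVolume, frame: int, pts: np.ndarray) -> np.ndarray:
    if not 0 <= frame < vol.n_frames:
        raise IndexError(f"frame {frame} out of range")
    for k in range(3):
        if pts[:, k].min() < vol.axes[k][0] or pts[:, k].max() > vol.axes[k][-1]:
            raise ValueError("sampling plane extends outside the velocity grid")
    f = RegularGridInterpolator(vol.axes, vol.frames[frame], bounds_error=True)
    return f(pts)


def plane_flow_rate(
    vol: VelocityVolume,
    plane: PlaneSection,
    frame: int = 0,
    resolution: tuple[int, int] = (64, 64),
) -> float:
    """Volumetric flow rate (mL/s) through the plane disc at one frame.

    Integrates the normal velocity component over the disc with a midpoint
    polar quadrature and trilinear interpolation of the grid velocities.
    Samples that interpolate into out-of-lumen (NaN) regions carry no flow.
    """
    pts, w = _disc_samples(plane, *resolution)
    v = _interp_frame(vol, frame, pts)
    vn = v @ plane.normal
    valid = np.isfinite(vn)
    # (m/s)·mm^2 = 1000 mm^3/s = 1 cm^3/s, so the unit factors cancel exactly
    return float(np.sum(vn[valid] * w[valid]))


def plane_velocity_stats(
    vol: VelocityVolume,
    plane: PlaneSection,
    frame: int = 0,
    resolution: tuple[int, int] = (64, 64),
) -> tuple[float, float]:
    """Area-weighted mean and maximum speed (m/s) over the in-lumen disc samples."""
    pts, w = _disc_samples(plane, *resolution)
    v = _interp_frame(vol, frame, pts)
    speed = np.linalg.norm(v, axis=1)
    valid = np.isfinite(speed)
    if not np.any(valid):
        return 0.0, 0.0
    mean = float(np.sum(speed[valid] * w[valid]) / np.sum(w[valid]))
    return mean, float(np.max(speed[valid]))
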