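r"""Wall-shear-stress metrics on labelled surface meshes.

Given the WSS vector tau(t) on each face of a surface mesh over one cardiac
cycle of period T, the standard time-averaged descriptors are

    TAWSS = (1/T) \int_0^T |tau| dt
    OSI   = 0.5 * (1 - |\int_0^T tau dt| / \int_0^T |tau| dt)
    RRT   = 1 / ((1 - 2*OSI) * TAWSS)

OSI measures directional oscillation (0 = unidirectional, 0.5 = perfect
reversal over the cycle); RRT is a near-wall residence-time surrogate that
diverges at full reversal. All cycle integrals here use periodic trapezoid
quadrature (the last-to-first frame wrap is included: tau is cyclic, and
dropping the wrap term biases OSI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .valve_geometry import SurfaceMesh

__all__ = [
    "WSSFieldSeries",
    "RRT_CAP",
    "tawss",
    "osi",
    "rrt",
    "pwss",
    "regional_average",
]

RRT_CAP = 1e6  # Pa^-1 sentinel for faces at/near full shear reversal
_RRT_FLOOR = 1e-6  # Pa floor on (1 - 2 OSI) * TAWSS below which RRT is capped
MIN_FRAMES = 8


@dataclass(frozen=True)
class WSSFieldSeries:
    """Per-face WSS vectors across uniformly meaningful cycle frames.

    ``tau`` has shape (n_frames, n_faces, 3) in Pa; ``times`` spans one cycle
    of period ``period`` (the closing ``t = t0 + T`` frame is implied by
    periodicity, not stored). ``side_label`` optionally tags the sampled
    surface side ('ventricular' or 'aortic').
    """

    mesh: SurfaceMesh
    times: np.ndarray
    tau: np.ndarray
    period: float
    side_label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "tau", tau)
        if t.size < MIN_FRAMES:
            raise ValueError(f"need at least {MIN_FRAMES} frames, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.period <= 0 or t[-1] - t[0] >= self.period:
            raise ValueError("frames must fit strictly inside one period")
        if tau.shape != (t.size, len(self.mesh.triangles), 3):
            raise ValueError("tau must be (n_frames, n_faces, 3)")
        if not np.all(np.isfinite(tau)):
            raise ValueError("tau contains non-finite entries")
        if self.side_label is not None and self.side_label not in ("ventricular", "aortic"):
            raise ValueError("side_label must be 'ventricular' or 'aortic'")


def _cycle_integral(f: WSSFieldSeries, values: np.ndarray) -> np.ndarray:
    """Periodic trapezoid integral over one cycle of per-frame arrays."""
    t = np.concatenate([f.times, [f.times[0] + f.period]])
    v = np.concatenate([values, values[:1]], axis=0)
    return np.trapezoid(v, t, axis=0)


def tawss(f: WSSFieldSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per face (Pa)."""
    return _cycle_integral(f, np.linalg.norm(f.tau, axis=2)) / f.period


def osi(f: WSSFieldSeries) -> np.ndarray:
    """Oscillatory shear index per face, in [0, 0.5]; NaN where tau is all-zero."""
    mag_int = _cycle_integral(f, np.linalg.norm(f.tau, axis=2))
    vec_int = np.linalg.norm(_cycle_integral(f, f.tau), axis=1)
    out = np.full(mag_int.shape, np.nan)
    ok = mag_int > 0
    out[ok] = 0.5 * (1.0 - vec_int[ok] / mag_int[ok])
    return np.clip(out, 0.0, 0.5)


def rrt(f: WSSFieldSeries) -> tuple[np.ndarray, np.ndarray]:
    """Relative residence time per face (Pa^-1) and a capped-face flag.

    Faces where ``(1 - 2 OSI) * TAWSS`` falls below a small floor (i.e. at or
    near full shear reversal, where RRT diverges) report the sentinel
    ``RRT_CAP`` and are flagged True. Faces with undefined OSI report NaN.
    """
    ta = tawss(f)
    o = osi(f)
    denom = (1.0 - 2.0 * o) * ta
    out = np.full(ta.shape, np.nan)
    flag = np.zeros(ta.shape, dtype=bool)
    defined = np.isfinite(denom)
    capped = defined & (denom < _RRT_FLOOR)
    normal = defined & ~capped
    out[normal] = 1.0 / denom[normal]
    out[capped] = RRT_CAP
    flag[capped] = True
    return out, flag


def pwss(f: WSSFieldSeries, t_peak: float) -> np.ndarray:
    """WSS magnitude per face (Pa) at peak systole.

    The vector field is linearly interpolated in time between the two frames
    bracketing ``t_peak`` (with periodic wrap up to ``t0 + T``), then its
    magnitude is taken.
    """
    t0 = float(f.times[0])
    if not t0 <= t_peak <= t0 + f.period:
        raise ValueError(f"t_peak {t_peak} outside the cycle [{t0}, {t0 + f.period}]")
    t = np.concatenate([f.times, [t0 + f.period]])
    tau = np.concatenate([f.tau, f.tau[:1]], axis=0)
    i = int(np.searchsorted(t, t_peak, side="right") - 1)
    i = min(i, t.size - 2)
    w = (t_peak - t[i]) / (t[i + 1] - t[i])
    return np.linalg.norm((1.0 - w) * tau[i] + w * tau[i + 1], axis=1)


def regional_average(values: np.ndarray, mesh: SurfaceMesh, label) -> float:
    """Area-weighted mean of a per-face scalar over one labelled region.

    Faces carrying a missing value (NaN) are skipped; weights are triangle
    areas.
    """
    if mesh.face_labels is None:
        raise ValueError("mesh carries no face labels")
    values = np.asarray(values, dtype=float)
    if values.shape != (len(mesh.triangles),):
        raise ValueError("values must be per-face scalars")
    sel = mesh.face_labels == label
    if not np.any(sel):
        raise ValueError(f"region {label!r} not present in face labels")
    a = mesh.face_areas()[sel]
    v = values[sel]
    ok = np.isfinite(v)
    if not np.any(ok):
        raise ValueError(f"region {label!r} has no defined values")
    return float(np.sum(a[ok] * v[ok]) / np.sum(a[ok]))
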