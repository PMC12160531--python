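"""Closed-form solver-output stand-ins with exactly known ground truth.

An FSI solution of valve haemodynamics is far beyond desk scale, so every
analysis stage in this package is exercised on constructed data whose target
quantities are known exactly: an idealised LVOT inflow with a half-sine
systolic lobe and zero diastolic flow, paired ventricular/aortic pressure
traces with a prescribed mean systolic gradient, per-face WSS vector series
with prescribed TAWSS/OSI, Poiseuille duct velocity volumes with prescribed
flow rate, and opening/closing free-edge circuits with prescribed peak
orifice area. Generators are closed-form (no ODE/PDE solves) and
deterministic for a fixed seed.

Default magnitudes are physiologic for an adult with a well-functioning
25 mm bioprosthesis: stroke volume 99.48 mL, period 1 s with a 0.35 systolic
fraction, peak transvalvular jet near 2.2 m/s and peak orifice area near
2.3 cm^2. They are realistic scales for the study conditions, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hemodynamic_metrics import VelocityVolume, tpg
from .valve_geometry import SurfaceMesh
from .waveforms import UNIT_FLOW, UNIT_PRESSURE, Waveform, stroke_volume
from .wss_metrics import WSSFieldSeries

__all__ = [
    "GeneratorSpec",
    "gen_lvot_waveform",
    "gen_coronary_template",
    "gen_pressure_pair",
    "gen_wss_series",
    "gen_velocity_volume",
    "gen_valve_kinematics",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth targets and discretisation for the synthetic generators."""

    seed: int = 0
    period: float = 1.0  # s
    sv_target: float = 99.48  # mL
    systole_fraction: float = 0.35
    tpg_target: float = 5.82  # mmHg
    wss_targets: dict = field(default_factory=dict)  # region -> (TAWSS Pa, OSI)
    grid_shape: tuple[int, int, int] = (40, 40, 8)
    n_samples: int = 256
    noise_sd: float = 0.0  # relative

    def __post_init__(self) -> None:
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.period <= 0 or self.sv_target <= 0:
            raise ValueError("period and sv_target must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _time_grid(spec: GeneratorSpec) -> np.ndarray:
    # one open cycle: the t = T sample is the periodic image of t = 0
    return np.linspace(0.0, spec.period, spec.n_samples, endpoint=False)


def gen_lvot_waveform(spec: GeneratorSpec) -> Waveform:
    """Idealised LVOT inflow: half-sine systolic lobe, zero diastole.

    The lobe spans ``[0, systole_fraction * period]``; its amplitude is
    normalised through the package's own ``stroke_volume`` measurement so
    that the measured stroke volume equals ``sv_target`` exactly (to
    round-off), whatever the sampling density.
    """
    t = _time_grid(spec)
    ts = spec.systole_fraction * spec.period
    raw = np.where(t < ts, np.sin(np.pi * np.clip(t, 0.0, ts) / ts), 0.0)
    w = Waveform(t, raw, spec.period, UNIT_FLOW)
    sv_raw = stroke_volume(w)
    return w.with_values(raw * (spec.sv_target / sv_raw))


def gen_coronary_template(
    spec: GeneratorSpec,
    systole_fraction: float = 0.4,
    diastolic_dominant: bool = True,
) -> tuple[Waveform, tuple[float, float]]:
    """A smooth positive template coronary waveform and its phase window.

    Coronary perfusion is predominantly diastolic (the myocardium relaxes and
    its microvasculature opens), so the default template carries a small
    systolic lobe and a larger diastolic one. Because the template's cardiac
    phase cannot be read off its values, its systolic window
    ``(0, systole_fraction * period)`` is returned alongside; the template's
    systole fraction deliberately differs from the generator's inlet one so
    that the time-axis remap is exercised.
    """
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must lie in (0, 1)")
    t = _time_grid(spec)
    ts = systole_fraction * spec.period
    sys_lobe = np.where(t < ts, np.sin(np.pi * np.clip(t, 0.0, ts) / ts), 0.0)
    dia = np.where(t >= ts, np.sin(np.pi * np.clip(t - ts, 0.0, None) / (spec.period - ts)), 0.0)
    a_sys, a_dia = (0.4, 1.0) if diastolic_dominant else (1.0, 0.4)
    values = 0.05 + a_sys * sys_lobe + a_dia * dia
    return Waveform(t, values, spec.period, UNIT_FLOW), (0.0, ts)


def gen_pressure_pair(
    spec: GeneratorSpec, systole: tuple[float, float]
) -> tuple[Waveform, Waveform]:
    """Paired LV/aortic pressure traces with a prescribed mean systolic gradient.

    Both traces are smooth physiologic-looking curves around a diastolic
    baseline; their difference over the supplied systolic window is shaped as
    a half-sine and scaled so that the trapezoid time-mean over that window
    equals ``tpg_target`` exactly (noise off). With ``noise_sd > 0``,
    independent Gaussian noise of that relative magnitude is added to both
    traces after construction.
    """
    t = _time_grid(spec)
    t_bs, t_es = systole
    if not 0 <= t_bs < t_es <= spec.period:
        raise ValueError("systole window must lie inside the cycle")
    # aortic trace: 80 mmHg baseline with a systolic bulge to ~120
    ts = spec.systole_fraction * spec.period
    bulge = np.sin(np.pi * np.clip(t, 0.0, ts) / ts) ** 2 * np.where(t < ts, 1.0, 0.0)
    p_ao = 80.0 + 40.0 * bulge
    # LV-minus-aortic difference: half-sine over the systolic window
    inside = (t >= t_bs) & (t <= t_es)
    diff = np.where(inside, np.sin(np.pi * (t - t_bs) / (t_es - t_bs)), 0.0)
    lv = Waveform(t, p_ao + diff, spec.period, UNIT_PRESSURE)
    ao = Waveform(t, p_ao, spec.period, UNIT_PRESSURE)
    mean_raw = tpg(lv, ao, t_bs, t_es)
    diff *= spec.tpg_target / mean_raw
    p_lv = p_ao + diff
    if spec.noise_sd > 0:
        rng = spec.rng()
        p_lv = p_lv + rng.normal(0.0, spec.noise_sd * np.mean(np.abs(p_lv)), t.size)
        p_ao = p_ao + rng.normal(0.0, spec.noise_sd * np.mean(np.abs(p_ao)), t.size)
    return (Waveform(t, p_lv, spec.period, UNIT_PRESSURE),
            Waveform(t, p_ao, spec.period, UNIT_PRESSURE))


def _osi_cone_angle(osi_target: float, n_frames: int) -> float:
    """Swing amplitude phi_max such that the discrete direction pattern
    cos(phi_i), phi_i = phi_max*sin(2*pi*i/N), has mean exactly 1 - 2*OSI."""
    if not 0 <= osi_target < 0.5:
        raise ValueError("OSI target must lie in [0, 0.5)")
    if osi_target == 0:
        return 0.0
    i = np.arange(n_frames)
    s = np.sin(2.0 * np.pi * i / n_frames)
    target = 1.0 - 2.0 * osi_target

    def g(phi):
        return float(np.mean(np.cos(phi * s))) - target

    # mean cos decreases from 1 toward ~J0's first root region; bracket there
    return brentq(g, 0.0, 2.4048255576957724, xtol=1e-15, rtol=1e-15)


def gen_wss_series(spec: GeneratorSpec, mesh: SurfaceMesh) -> WSSFieldSeries:
    """Per-face WSS vector series hitting prescribed TAWSS/OSI per region.

    Each face receives a constant-magnitude vector whose direction swings
    within the plane spanned by two seeded orthonormal vectors:
    ``tau_i = A [cos(phi_i) u + sin(phi_i) w]`` with
    ``phi_i = phi_max sin(2 pi i / N)``. The magnitude ``A`` is the TAWSS
    target outright (discrete periodic trapezoid of a constant is exact) and
    ``phi_max`` is solved so the discrete vector-mean magnitude gives the OSI
    target to round-off. Requires ``wss_targets[region] = (tawss, osi)`` for
    every region label on the mesh.
    """
    if mesh.face_labels is None:
        raise ValueError("mesh must carry face labels matching wss_targets")
    regions = set(np.unique(mesh.face_labels).tolist())
    missing = regions - set(spec.wss_targets)
    if missing:
        raise ValueError(f"wss_targets missing for regions: {sorted(map(str, missing))}")
    n = spec.n_samples
    t = _time_grid(spec)
    rng = spec.rng()
    n_faces = len(mesh.triangles)
    tau = np.empty((n, n_faces, 3))
    phases = np.sin(2.0 * np.pi * np.arange(n) / n)
    for region in regions:
        ta_target, osi_target = spec.wss_targets[region]
        if ta_target <= 0:
            raise ValueError("TAWSS targets must be positive")
        phi_max = _osi_cone_angle(float(osi_target), n)
        sel = np.flatnonzero(mesh.face_labels == region)
        for fidx in sel:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            w = rng.normal(size=3)
            w -= (w @ u) * u
            w /= np.linalg.norm(w)
            phi = phi_max * phases
            tau[:, fidx, :] = ta_target * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * w)
    return WSSFieldSeries(mesh, t, tau, spec.period)


def gen_velocity_volume(
    spec: GeneratorSpec,
    duct_radius: float,
    Q: float,
    n_frames: int = 1,
    modulate: bool = False,
) -> VelocityVolume:
    """Axial Poiseuille flow in a straight circular duct on a structured grid.

    The duct axis is z; the axial velocity is ``v_z(r) = 2 V (1 - r^2/R^2)``
    with the bulk velocity ``V`` chosen so the exact flow rate is ``Q``
    (mL/s). Points outside the duct are NaN (out of lumen). ``duct_radius``
    in mm. With ``modulate=True`` the frames follow the half-sine systolic
    shape of the LVOT generator; otherwise all frames are the steady profile.
    """
    nx, ny, nz = spec.grid_shape
    if Q < 0 or duct_radius <= 0:
        raise ValueError("need duct_radius > 0 and Q >= 0")
    half = 1.25 * duct_radius
    if nx < 2 or ny < 2 or nz < 2:
        raise ValueError("grid too small")
    x = np.linspace(-half, half, nx)
    y = np.linspace(-half, half, ny)
    z = np.linspace(0.0, 4.0 * duct_radius, nz)
    if half < duct_radius:
        raise ValueError("duct larger than the grid")
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r2 = (xx**2 + yy**2) / duct_radius**2
    # Q [mL/s] = V [m/s] * pi R^2 [mm^2]: the unit factors cancel exactly,
    # matching the plane_flow_rate convention
    v_bulk = Q / (np.pi * duct_radius**2)
    # two grid cells of explicit zero-velocity wall padding outside the duct,
    # NaN (out of lumen) beyond: keeps near-wall interpolation defined so the
    # disc quadrature sees the no-slip wall instead of a masked band
    pad = 1.0 + 2.0 * max(x[1] - x[0], y[1] - y[0]) / duct_radius
    prof = np.where(r2 <= pad**2, np.maximum(2.0 * v_bulk * (1.0 - r2), 0.0), np.nan)
    frame = np.zeros((nx, ny, nz, 3))
    frame[..., 2] = prof[:, :, None]
    frame[np.isnan(prof)] = np.nan  # whole out-of-lumen column, all components
    times = np.linspace(0.0, spec.period, n_frames, endpoint=False) if n_frames > 1 else np.array([0.0])
    if modulate and n_frames > 1:
        ts = spec.systole_fraction * spec.period
        amp = np.where(times < ts, np.sin(np.pi * times / ts), 0.0)
    else:
        amp = np.ones(times.size)
    frames = frame[None, ...] * amp[:, None, None, None, None]
    return VelocityVolume((x, y, z), frames, times)


def gen_valve_kinematics(
    spec: GeneratorSpec,
    goa_max: float,
    n_frames: int = 32,
    n_points_per_edge: int = 100,
    height: float = 10.0,
) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Opening/closing free-edge circuits with a prescribed peak orifice area.

    Returns ``(times, frames)`` where each frame holds three 120-degree arc
    polylines (mm) forming a closed circuit at height ``height``. The orifice
    is circular with radius ``s(t) * sqrt(goa_max/pi)``; the opening factor
    ``s(t)`` rises and falls as a half-sine over the systolic window and is
    zero in diastole (valve closed, arcs collapsed to the centre point). GOA
    is unimodal in time by construction and equals ``goa_max`` at peak
    systole up to polygonal discretisation of the circle.
    """
    if goa_max <= 0:
        raise ValueError("goa_max must be positive")
    r_max = np.sqrt(goa_max * 100.0 / np.pi)  # cm^2 -> mm^2 -> mm
    times = np.linspace(0.0, spec.period, n_frames, endpoint=False)
    ts = spec.systole_fraction * spec.period
    s = np.where(times < ts, np.sin(np.pi * np.clip(times, 0, ts) / ts), 0.0)
    # pin the frame nearest peak systole to the exactly fully open state so
    # the prescribed goa_max is attained at a stored frame
    s[int(np.argmin(np.abs(times - ts / 2.0)))] = 1.0
    frames: list[list[np.ndarray]] = []
    for sk in s:
        r = r_max * sk
        leaflets = []
        for j in range(3):
            th = np.deg2rad(np.linspace(120.0 * j, 120.0 * (j + 1), n_points_per_edge))
            arc = np.column_stack([r * np.cos(th), r * np.sin(th), np.full(th.size, height)])
            leaflets.append(arc)
        frames.append(leaflets)
    return times, frames
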