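"""Inlet/outlet boundary-condition construction for aortic-root flow models.

Covers the four desk computations that set up a patient-specific simulation:

* mean arterial pressure from a systolic/diastolic cuff pair,
* the Hagen–Poiseuille pressure drop across an artificial outlet extension,
* estimation of three-element Windkessel (3EWK) outlet parameters from the
  mean pressure and mean flow, and the dynamic pressure response of that
  model to a periodic flow waveform,
* two-step scaling of a template coronary flow waveform (time-axis remap to
  the case's systolic/diastolic phase, then amplitude normalisation to a
  prescribed fraction of the inlet flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .waveforms import UNIT_FLOW, UNIT_PRESSURE, Waveform, detect_systole

__all__ = [
    "MMHG_TO_PA",
    "WindkesselParams",
    "CoronaryTargets",
    "mean_arterial_pressure",
    "hagen_poiseuille_loss",
    "estimate_3ewk",
    "windkessel_pressure",
    "scale_coronary_waveform",
]

MMHG_TO_PA = 133.322387415


@dataclass(frozen=True)
class WindkesselParams:
    """3EWK outlet parameters in SI units.

    ``Rp``/``Rd`` in kg/(m^4·s), ``C`` in m^4·s^2/kg. ``Rp`` is the proximal
    (characteristic) resistance in series with the parallel ``Rd``–``C`` pair.
    """

    Rp: float
    Rd: float
    C: float

    def __post_init__(self) -> None:
        if self.Rp < 0 or self.Rd <= 0 or self.C <= 0:
            raise ValueError("require Rp >= 0, Rd > 0, C > 0")

    @property
    def tau(self) -> float:
        """Distal RC time constant Rd*C in seconds."""
        return self.Rd * self.C

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"Rp_kg_per_m4_s": self.Rp, "Rd_kg_per_m4_s": self.Rd,
                        "C_m4_s2_per_kg": self.C}, indent=2)
        )


@dataclass(frozen=True)
class CoronaryTargets:
    """Target time-averaged coronary flows as fractions of the inlet flow."""

    lca_fraction: float = 0.031
    rca_fraction: float = 0.0065

    def __post_init__(self) -> None:
        for f in (self.lca_fraction, self.rca_fraction):
            if not 0 < f < 0.1:
                raise ValueError("coronary fractions must lie in (0, 0.1)")


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP in mmHg from the standard one-third pulse-pressure rule."""
    if not sbp > dbp > 0:
        raise ValueError("require sbp > dbp > 0")
    return dbp + (sbp - dbp) / 3.0


def hagen_poiseuille_loss(mu: float, L: float, d: float, Q: float) -> float:
    """Pressure drop (Pa) of fully developed laminar flow in a straight tube.

    ``mu`` in Pa·s, length ``L`` and diameter ``d`` in metres, flow ``Q`` in
    m^3/s (``Q = 0`` is allowed and returns 0).
    """
    if mu <= 0 or L <= 0 or d <= 0 or Q < 0:
        raise ValueError("require mu, L, d > 0 and Q >= 0")
    return 128.0 * mu * L * Q / (np.pi * d**4)


def estimate_3ewk(
    P_mean_mmHg: float,
    Q_mean: float,
    proximal_fraction: float = 0.06,
    tau: float = 1.68,
) -> WindkesselParams:
    """Estimate 3EWK parameters from mean pressure and mean flow.

    The total resistance is fixed by the DC balance ``Rp + Rd = P_mean/Q_mean``
    (pressure converted to Pa, ``Q_mean`` in m^3/s); ``proximal_fraction``
    apportions it to the proximal element, and the compliance follows from a
    prescribed distal decay time ``tau = Rd*C``. The defaults (6% proximal
    split, tau = 1.68 s) are typical descending-aorta values.
    """
    if P_mean_mmHg <= 0 or tau <= 0:
        raise ValueError("require positive mean pressure and tau")
    if Q_mean <= 0:
        raise ValueError("mean flow must be positive")
    if not 0 <= proximal_fraction < 1:
        raise ValueError("proximal_fraction must lie in [0, 1)")
    R_total = P_mean_mmHg * MMHG_TO_PA / Q_mean
    Rp = proximal_fraction * R_total
    Rd = R_total - Rp
    return WindkesselParams(Rp=Rp, Rd=Rd, C=tau / Rd)


def windkessel_pressure(
    params: WindkesselParams,
    Q: Waveform,
    n_cycles: int = 10,
    *,
    return_history: bool = False,
) -> Waveform | tuple[Waveform, list[np.ndarray]]:
    """Outlet pressure response of the 3EWK model to a periodic flow waveform.

    The model splits as ``P = Rp*Q + Pc`` with the distal store obeying
    ``C dPc/dt = Q - Pc/Rd``. That linear ODE is advanced with an exact
    exponential update assuming ``Q`` piecewise linear between samples, so the
    integration is unconditionally stable for arbitrarily stiff RC products
    and exact for the waveform's piecewise-linear representation. The store is
    initialised at its DC value ``Rd * mean(Q)`` and ``n_cycles`` cycles are
    run to wash out the remaining transient; the final cycle is returned as a
    pressure waveform in mmHg.

    ``Q`` must be in SI units (m^3/s). A waveform whose first and last values
    disagree by more than 1% of its range is not periodic; a warning is
    emitted and the first value is used for the wrap.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    import warnings

    q = Q.values
    rng_q = float(np.ptp(q))
    # the grid excludes the t = T sample, so a periodic signal still shows a
    # one-sample slope gap between q[-1] and q[0]; only flag gross mismatch
    if rng_q > 0 and abs(q[0] - q[-1]) > 0.05 * rng_q:
        warnings.warn("flow waveform endpoints differ; treating as periodic anyway", stacklevel=2)

    Rp, Rd, C = params.Rp, params.Rd, params.C
    tau = Rd * C
    t = Q.times - Q.times[0]
    # one-cycle grid closed at t = T for the periodic wrap
    tt = np.concatenate([t, [Q.period]])
    qq = np.concatenate([q, [q[0]]])
    dt = np.diff(tt)
    if np.any(dt <= 0):
        raise ValueError("waveform must fit inside one period")
    decay = np.exp(-dt / tau)
    slope = np.diff(qq) / dt

    q_mean = float(np.trapezoid(qq, tt) / Q.period)
    pc = Rd * q_mean
    history: list[np.ndarray] = []
    pc_cycle = np.empty(t.size)
    for _ in range(n_cycles):
        for i in range(dt.size):
            pc_cycle[i] = pc
            # exact step: particular solution for linear Q plus decaying homogeneous part
            p_part_end = Rd * (qq[i + 1] - tau * slope[i])
            p_part_start = Rd * (qq[i] - tau * slope[i])
            pc = p_part_end + (pc - p_part_start) * decay[i]
        history.append(pc_cycle.copy())
    p_mmHg = (Rp * q + pc_cycle) / MMHG_TO_PA
    out = Waveform(Q.times, p_mmHg, Q.period, UNIT_PRESSURE)
    return (out, history) if return_history else out


def scale_coronary_waveform(
    template: Waveform,
    lvot: Waveform,
    fraction: float,
    *,
    template_systole: tuple[float, float] | None = None,
    threshold_frac: float = 0.01,
) -> Waveform:
    """Adapt a template coronary flow waveform to a specific inlet flow.

    Two steps, mirroring common boundary-condition practice:

    1. *time remap* — a two-segment piecewise-linear map of the template's
       cycle onto the inlet cycle so that the template's systolic and
       diastolic durations match those detected on ``lvot``;
    2. *amplitude scale* — one uniform factor so that the time-averaged
       output flow is exactly ``fraction`` times the time-averaged inlet flow.

    ``template_systole`` gives the template's own ejection window (its phase
    timing); by default it is detected from the template with the same rule
    used on the inlet, which is appropriate when the template is aligned with
    the flow phases. The output lives on the ``lvot`` time grid.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if template.mean() <= 0:
        raise ValueError("cannot scale a template with non-positive mean flow")

    t_bs, t_es = detect_systole(lvot, threshold_frac)
    if template_systole is None:
        template_systole = detect_systole(template, threshold_frac)
    a, b = template_systole
    T_t = template.period
    t0_t = float(template.times[0])
    if not t0_t <= a < b <= t0_t + T_t:
        raise ValueError("template systole window outside the template cycle")

    t0 = float(lvot.times[0])
    T = lvot.period
    # map output time -> template time: [t0, t_bs] -> [t0_t, a] pre-systolic,
    # [t_bs, t_es] -> [a, b] systole, [t_es, t0+T] -> [b, t0_t+T_t] diastole
    out_knots = np.array([t0, t_bs, t_es, t0 + T])
    tpl_knots = np.array([t0_t, a, b, t0_t + T_t])
    keep = np.concatenate([[True], np.diff(out_knots) > 0])
    src_t = np.interp(lvot.times, out_knots[keep], tpl_knots[keep])
    # sample the template periodically (wrap the closing segment)
    tpl_t = np.concatenate([template.times, [t0_t + T_t]])
    tpl_v = np.concatenate([template.values, [template.values[0]]])
    vals = np.interp(np.clip(src_t, t0_t, t0_t + T_t), tpl_t, tpl_v)

    remapped = Waveform(lvot.times, vals, T, UNIT_FLOW)
    m = remapped.mean()
    if m <= 0:
        raise ValueError("remapped template has non-positive mean flow")
    scale = fraction * lvot.mean() / m
    return remapped.with_values(vals * scale)
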