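"""Quantitative comparison report and the end-to-end pipeline driver.

The report mirrors the simulation-versus-measurement comparison tables used
when validating valve models against 4D-flow MRI: each entry pairs a
reference (measurement-role) value with a candidate (model-role) value and a
percent difference, with the reference in the denominator.

``run_pipeline`` orchestrates the full synthetic study: inflow conditioning,
Windkessel outlet construction, coronary scaling, performance metrics (SV,
EOA, AVA, TPG, MPG, GOA), plane-based velocity statistics and WSS metrics,
with every stage logged and its parameters echoed to a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import boundary_conditions as bc
from . import hemodynamic_metrics as hm
from . import synthetic_data as sd
from . import valve_geometry as vg
from . import wss_metrics as wm
from .waveforms import Waveform, detect_systole, stroke_volume, zero_diastole

__all__ = ["MetricsReport", "percent_difference", "run_pipeline", "load_config"]

log = logging.getLogger("valvemetrics")


def percent_difference(reference: float, candidate: float) -> float:
    """Signed percent difference, reference in the denominator."""
    if reference == 0:
        raise ValueError("percent difference undefined for a zero reference")
    return 100.0 * (candidate - reference) / reference


@dataclass
class MetricsReport:
    """Comparison table plus provenance of the run that produced it."""

    entries: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, reference: float, candidate: float, unit: str) -> None:
        self.entries.append({
            "name": name,
            "reference": reference,
            "candidate": candidate,
            "unit": unit,
            "percent_difference": percent_difference(reference, candidate),
        })

    def to_text(self) -> str:
        lines = [f"{'Parameter':<38}{'Reference':>12}{'Candidate':>12}{'Diff (%)':>10}  Unit"]
        for e in self.entries:
            lines.append(
                f"{e['name']:<38}{e['reference']:>12.4g}{e['candidate']:>12.4g}"
                f"{e['percent_difference']:>10.2f}  {e['unit']}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"entries": self.entries, "provenance": self.provenance}, indent=2))


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "period": 1.0,
    "sv_target": 99.48,
    "systole_fraction": 0.35,
    "tpg_target": 5.82,
    "goa_max": 2.28,
    "jet_peak": 2.20,
    "duct_radius_mm": 12.5,
    "plane_flow_target": 300.0,
    "coronary": {"lca_fraction": 0.031, "rca_fraction": 0.0065},
    "windkessel": {"mean_pressure_mmHg": 93.33, "mean_flow_m3_s": 7.431e-5,
                   "proximal_fraction": 0.05996, "tau_s": 1.683},
    "wss": {"targets": {"LCL": [21.58, 0.21], "RCL": [25.94, 0.24], "NCL": [24.32, 0.24]}},
    "n_samples": 256,
}


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> MetricsReport:
    """Run the full synthetic study and return the comparison report.

    Stages whose configuration section is absent (e.g. ``wss``) are skipped;
    the run is deterministic given the configuration (which includes the
    seed). If ``out_dir`` is given, the report text, a full-precision JSON
    sidecar and the Windkessel parameter echo are written there.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    missing = [k for k in ("seed", "period", "sv_target", "systole_fraction") if k not in cfg]
    if missing:
        raise ValueError(f"configuration missing required keys: {missing}")

    spec = sd.GeneratorSpec(
        seed=int(cfg["seed"]), period=float(cfg["period"]),
        sv_target=float(cfg["sv_target"]),
        systole_fraction=float(cfg["systole_fraction"]),
        tpg_target=float(cfg["tpg_target"]),
        wss_targets={k: tuple(v) for k, v in cfg.get("wss", {}).get("targets", {}).items()},
        n_samples=int(cfg.get("n_samples", 256)),
    )
    report = MetricsReport(provenance={"config_hash": _config_hash(cfg), "config": cfg})

    log.info("stage 1: inflow conditioning (seed=%d)", spec.seed)
    lvot = zero_diastole(sd.gen_lvot_waveform(spec))
    t_bs, t_es = detect_systole(lvot)
    sv = stroke_volume(lvot)
    report.add("Stroke volume", spec.sv_target, sv, "mL")

    log.info("stage 2: outlet boundary construction")
    wk_cfg = cfg.get("windkessel")
    if wk_cfg:
        params = bc.estimate_3ewk(wk_cfg["mean_pressure_mmHg"], wk_cfg["mean_flow_m3_s"],
                                  wk_cfg["proximal_fraction"], wk_cfg["tau_s"])
        lvot_si = lvot.with_values(lvot.values * 1e-6)  # mL/s -> m^3/s
        p_out = bc.windkessel_pressure(params, lvot_si, n_cycles=10)
        report.add("Windkessel cycle-mean pressure",
                   (params.Rp + params.Rd) * lvot_si.mean() / bc.MMHG_TO_PA,
                   p_out.mean(), "mmHg")
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            params.to_json(Path(out_dir) / "windkessel_params.json")
        log.info("  3EWK: Rp=%.4g Rd=%.4g C=%.4g (SI)", params.Rp, params.Rd, params.C)

    cor = cfg.get("coronary")
    if cor:
        template, tpl_systole = sd.gen_coronary_template(spec)
        for name, frac in (("LCA", cor["lca_fraction"]), ("RCA", cor["rca_fraction"])):
            scaled = bc.scale_coronary_waveform(template, lvot, frac,
                                                template_systole=tpl_systole)
            report.add(f"{name} mean-flow fraction", 100.0 * frac,
                       100.0 * scaled.mean() / lvot.mean(), "%")

    log.info("stage 3: performance metrics")
    p_lv, p_ao = sd.gen_pressure_pair(spec, (t_bs, t_es))
    tpg_val = hm.tpg(p_lv, p_ao, t_bs, t_es)
    report.add("Transvalvular pressure gradient", spec.tpg_target, tpg_val, "mmHg")

    # peak-velocity trace: half-sine lobe over systole, like the inflow
    jet_peak = float(cfg.get("jet_peak", 2.20))
    t = lvot.times
    lobe = np.where(t <= t_es, np.sin(np.pi * np.clip(t, 0, t_es) / max(t_es, 1e-12)), 0.0)
    v_trace = Waveform(t, jet_peak * lobe, spec.period, "velocity_m_per_s")
    # closed-form references for the constructed half-sine trace
    vti_ref = 2.0 * jet_peak * t_es / np.pi * 100.0  # cm
    vti_val = hm.vti(v_trace, (t_bs, t_es))
    report.add("Aortic valve area (continuity)", sv / vti_ref, hm.ava(sv, vti_val), "cm^2")
    mpg_val = hm.mpg(v_trace, (t_bs, t_es))
    report.add("Mean pressure gradient (Bernoulli)", 2.0 * jet_peak**2, mpg_val, "mmHg")

    dp = p_lv.with_values(p_lv.values - p_ao.values)
    eoa_val = hm.eoa(lvot, dp)
    q_peak = float(np.max(lvot.values))
    eoa_ref = (q_peak / np.sqrt(2.0)) / (51.6 * np.sqrt(spec.tpg_target / 1.06))
    report.add("Effective orifice area", eoa_ref, eoa_val, "cm^2")

    goa_max = float(cfg.get("goa_max", 2.28))
    times_k, frames_k = sd.gen_valve_kinematics(spec, goa_max)
    goa_series = [vg.goa_from_free_edges(fr) for fr in frames_k]
    report.add("Peak geometric orifice area", goa_max, max(goa_series), "cm^2")

    log.info("stage 4: plane-based velocity statistics")
    q_target = float(cfg.get("plane_flow_target", 300.0))
    radius = float(cfg.get("duct_radius_mm", 12.5))
    vol = sd.gen_velocity_volume(spec, radius, q_target)
    plane = hm.PlaneSection(np.array([0.0, 0.0, 2.0 * radius]), np.array([0.0, 0.0, 1.0]), radius)
    q_meas = hm.plane_flow_rate(vol, plane)
    report.add("Plane flow rate", q_target, q_meas, "mL/s")
    mean_v, max_v = hm.plane_velocity_stats(vol, plane)
    report.add("Plane max/mean speed ratio", 2.0, max_v / mean_v, "-")

    if spec.wss_targets:
        log.info("stage 5: WSS metrics")
        leaflet = vg.build_leaflet(vg.default_design(), resolution=(12, 12))
        valve = vg.assemble_valve(leaflet)
        series = sd.gen_wss_series(spec, valve)
        ta = wm.tawss(series)
        oo = wm.osi(series)
        for region, (ta_t, osi_t) in spec.wss_targets.items():
            report.add(f"TAWSS {region}", ta_t,
                       wm.regional_average(ta, valve, region), "Pa")
            report.add(f"OSI {region}", osi_t,
                       wm.regional_average(oo, valve, region), "-")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(report.to_text())
        report.to_json(out / "report.json")
        log.info("report written to %s", out)
    return report
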