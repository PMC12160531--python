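# valvemetrics

Haemodynamic performance analysis for bioprosthetic aortic valves (BPAV).

After surgical aortic valve replacement, the long-term fate of a pericardial
bioprosthesis is tied to the blood flow it creates: the orifice it opens, the
pressure it drops, and the shear stresses its leaflets and the aortic root
experience over the cardiac cycle. Patient-specific fluid–structure
interaction (FSI) models and 4D-flow MRI both produce the raw fields —
flow/pressure waveforms, velocity volumes, wall-shear-stress vectors — but the
clinically meaningful numbers come from a well-defined layer of downstream
computations. `valvemetrics` implements that layer as a tested, reusable
Python package for simulation engineers and imaging researchers who need the
same metrics computed the same way on either kind of data.

## What it computes

**Valve performance indices** (flow Q in mL/s, pressures in mmHg,
velocities in m/s):

- Effective orifice area (energy conservation, Gorlin-type):
  `EOA = Q_RMS / (51.6 · √(ΔP̄/ρ_f))` [cm²], with `Q_RMS` and the mean
  pressure difference `ΔP̄` taken over the positive differential-pressure
  period and `ρ_f` in g/cm³.
- Aortic valve area (continuity): `AVA = SV / VTI_AV` [cm²].
- Mean transvalvular pressure gradient over systole:
  `TPG = ∫ (P_LV − P_AO) dt / (t_es − t_bs)` [mmHg].
- Bernoulli mean gradient: `MPG = (Σ 4 v_max²) / N_tp` [mmHg] over the
  valve-open time points.
- Geometric orifice area from the projection of the three leaflet free
  edges onto the cross-sectional plane (shoelace area).
- Plane-based quantities on structured-grid velocity volumes: volumetric
  flow rate, max jet speed, and spatial mean speed on a disc section.

**Wall-shear-stress metrics** on labelled surface meshes, per face over one
cycle of period T:

- `TAWSS = (1/T)∫|τ|dt`,
- `OSI = ½(1 − |∫τ dt| / ∫|τ|dt)` ∈ [0, 0.5],
- `RRT = 1 / ((1−2·OSI)·TAWSS)`,
- peak-systolic WSS, and area-weighted regional averages.

**Boundary-condition construction**: mean arterial pressure from a cuff
pair, Hagen–Poiseuille extension losses, three-element Windkessel (3EWK)
parameter estimation and its exact dynamic pressure response, and two-step
scaling of template coronary waveforms (time-axis remap to the case's
systolic/diastolic phase, amplitude normalisation to a target flow fraction).

**Constitutive laws**: Bird–Carreau shear-thinning blood viscosity and the
incompressible second-order Ogden model for pericardial leaflets, with their
standard published constants as defaults.

**Parametric valve geometry**: a tri-leaflet pericardial valve built from
free-edge and attachment (directrix) curves — spline loft, thickness offset,
cylinder trim, 120° assembly, rigid placement — exported as STL.

**Synthetic data generators** produce solver-output stand-ins with exactly
known ground truth (stroke volume, gradients, WSS targets, duct flow rates,
orifice areas), so the whole pipeline is testable without an FSI solver.

## Worked example

Run the full synthetic study from the command line:

```bash
valvemetrics pipeline --seed 1 --out results/demo
```

which prints (abridged):

```
Parameter                                Reference   Candidate  Diff (%)  Unit
Stroke volume                                99.48       99.48      0.00  mL
LCA mean-flow fraction                         3.1         3.1      0.00  %
RCA mean-flow fraction                        0.65        0.65     -0.00  %
Transvalvular pressure gradient               5.82        5.82      0.00  mmHg
Peak geometric orifice area                   2.28        2.28     -0.01  cm^2
Plane flow rate                                300       299.6     -0.15  mL/s
TAWSS LCL                                    21.58       21.58     -0.00  Pa
OSI LCL                                       0.21        0.21     -0.00  -
```

Each row pairs a generator ground-truth target (reference) with the value the
analysis pipeline recovered from the generated data (candidate); the percent
difference uses the reference in the denominator. A physiologic stroke volume
of 99.48 mL is recovered exactly because the inflow generator normalises its
amplitude through the same stroke-volume measurement; plane flow rate and
orifice area carry small discretisation residuals from disc quadrature and
polygonal projection.

The same workflow from Python:

```python
from valvemetrics import GeneratorSpec, stroke_volume, tpg, detect_systole
from valvemetrics.synthetic_data import gen_lvot_waveform, gen_pressure_pair

spec = GeneratorSpec(seed=1, sv_target=99.48, tpg_target=5.82)
lvot = gen_lvot_waveform(spec)
systole = detect_systole(lvot)
p_lv, p_ao = gen_pressure_pair(spec, systole)
print(stroke_volume(lvot))          # 99.48
print(tpg(p_lv, p_ao, *systole))    # 5.82
```

## Layout

- `src/valvemetrics/waveforms.py` — cycle time-series container, quadrature,
  systole detection
- `src/valvemetrics/constitutive.py` — Bird–Carreau and Ogden laws
- `src/valvemetrics/boundary_conditions.py` — MAP, Hagen–Poiseuille, 3EWK,
  coronary scaling
- `src/valvemetrics/valve_geometry.py` — parametric leaflets, assembly,
  placement, orifice projection
- `src/valvemetrics/hemodynamic_metrics.py` — EOA/AVA/TPG/MPG/VTI, plane
  analysis
- `src/valvemetrics/wss_metrics.py` — TAWSS/OSI/RRT/PWSS, regional averages
- `src/valvemetrics/synthetic_data.py` — ground-truth generators
- `src/valvemetrics/report.py`, `cli.py` — comparison report, pipeline, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
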