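# Methods

This note records the models implemented in `valvemetrics`, the conventions
and numerical choices behind them, what the synthetic data do and do not
emulate, and the package's known limitations.

## Scope and intended use

The package implements the *analysis layer* of a patient-specific
bioprosthetic-aortic-valve haemodynamics study: everything that surrounds an
FSI solve or a 4D-flow MRI acquisition, but not the solve itself. It consumes
flow/pressure time series (CSV), per-face WSS vector series on triangulated
surfaces (CSV frames + STL), and structured-grid velocity snapshots (ASCII
legacy-VTK structured points), and produces clinical performance indices,
surface shear metrics and a comparison report. CT segmentation, two-way FSI
coupling, finite-element leaflet dynamics, contact mechanics and turbulence
modelling are deliberately out of scope.

## Waveforms and quadrature

A `Waveform` is one cardiac cycle of a sampled scalar signal on a strictly
increasing grid (≥ 8 samples) with an explicit period and unit tag. All time
integrals are composite trapezoids with linear interpolation at window
endpoints: the sampled representation *is* piecewise linear, so trapezoid
quadrature is exact for it and no higher-order rule would add information.

Systole detection uses a threshold at 1% of peak flow: the ejection window
runs from the first to the last sample strictly above the threshold. The
threshold default is a package choice — clinical practice does not prescribe
an ejection-window rule for these metrics — and detection is resolved to the
sampling grid (no sub-sample root finding), so a sharp-edged pulse reports
its exact sample edges while a smooth waveform's window carries an
uncertainty of one sample spacing. Both the stroke-volume window and the VTI
ejection window use this same rule.

Multi-cycle recordings must be split by the caller; every operation assumes
one cycle, which matches the usual practice of analysing a single converged
cycle.

## Constitutive models

Blood: Bird–Carreau,
μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2), with defaults
μ∞ = 3.5 mPa·s, μ0 = 56 mPa·s, n = 0.3568, λ = 3.313 s, ρ_f = 1060 kg/m³ —
the standard whole-blood fit used in valve simulations. The function is
bounded in [μ∞, μ0] and non-increasing; both are property-tested.

Leaflets: incompressible isotropic second-order Ogden,
Ψ = Σᵢ (2μᵢ/αᵢ²)(λ̄1^αᵢ + λ̄2^αᵢ + λ̄3^αᵢ − 3), defaults
μ1 = 19.58 kPa, α1 = 67.74, μ2 = 260.56 kPa, α2 = 27.47, density
1100 kg/m³ — a published fit to biaxial tests on glutaraldehyde-treated
bovine pericardium. Incompressibility is enforced by construction of the
stretch triple (the uniaxial helper uses λ, λ^−½, λ^−½), not by a penalty
term, because the energy is written in modified principal stretches and the
tissue is treated as exactly incompressible. The uniaxial Cauchy stress
σ = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − λ^(−αᵢ/2)) is verified against a central finite
difference of the energy (σ = λ dΨ/dλ on the incompressible path) to 1e-6
relative over λ ∈ [0.8, 1.2]; its small-strain slope is 3Σμᵢ. The μᵢ are
taken literally as printed in the source fit (the shear-modulus-like
convention some FE codes use); nothing downstream depends on that reading.
A Rayleigh mass-damping coefficient (200 s⁻¹) is stored with the material
parameters for completeness but enters no computation here — damping acts
only inside a dynamic FE solver.

## Boundary conditions

*Mean arterial pressure* uses the one-third pulse-pressure rule
MAP = DBP + (SBP − DBP)/3; 120/80 mmHg gives 93.33 mmHg.

*Extension losses* for an artificial outlet extension use Hagen–Poiseuille,
ΔP = 128 μ L Q / (π d⁴), evaluated at the high-shear viscosity.

*3EWK estimation.* The total resistance is fixed by the DC balance
R_p + R_d = P̄/Q̄; a proximal fraction splits it and a prescribed distal
decay time τ = R_d·C sets the compliance. Defaults: 6% proximal split and
τ = 1.68 s, typical descending-aorta values. The estimation closure
(split + τ) is a package design choice; published parameter sets for this
kind of model are consistent with a split near 0.06 and τ near 1.68 s, and
the identities R_p + R_d = P̄/Q̄ and τ = R_d·C are asserted in tests.

*3EWK response.* With P = R_p Q + P_c and C dP_c/dt = Q − P_c/R_d, the
store is advanced by an exact exponential update that assumes Q piecewise
linear between samples. This is unconditionally stable for arbitrarily stiff
RC products and *exact* for the waveform's piecewise-linear representation —
the same property the trapezoid quadrature gives the metrics — so no
time-step refinement is ever needed. The store is initialised at its DC
value R_d·Q̄ and ten cycles are integrated by default; the transient decays
geometrically at e^(−T/τ) per cycle and the final cycle is returned. The
implementation matches the analytic impedance
Z(ω) = R_p + R_d/(1 + iωR_dC) to better than 0.1% at 1–3 Hz.

*Coronary scaling* adapts a template coronary waveform in two steps: a
two-segment piecewise-linear time remap aligning the template's systolic and
diastolic durations with those detected on the inlet waveform, then one
uniform amplitude factor making the time-averaged output exactly the target
fraction of the time-averaged inlet flow (3.1% LCA, 0.65% RCA by default).
The remap is two-segment because only the phase durations are known; any
smoother remap would invent information. Because coronary flow is
diastolic-dominant, the template's own phase cannot be detected from its
values; the generator therefore returns the template's systolic window
alongside the waveform, and callers should pass it explicitly.

## Valve geometry

A leaflet mid-surface is the ruled loft S(u,v) = (1−v)F(u) + vD(u) between
cubic splines through the free-edge (F) and directrix/attachment (D) control
points, both chord-length parametrised with natural end conditions. The loft
reading of "sweep the free edge along the directrix" is the one consistent
with pericardial leaflet construction (a membrane spanning free edge to
attachment scallop) and has the useful property that planar curve pairs give
exactly planar surfaces, which anchors the slab-volume test. The shell is the
pair of ±t/2 normal offsets of the mid-surface with a stitched rim,
watertight and consistently wound by construction; an offset that folds
(thickness exceeding the local curvature radius) raises an error rather than
producing a self-intersecting shell. Trimming against the stent's inner
profile — whose true surface is proprietary — is approximated by radial
clamping onto the nominal-diameter cylinder and documented as such.

The default 25 mm design (0.361 mm uniform thickness, commissures at 60°,
free edge sagging toward the axis) is a *generic* tri-leaflet of plausible
surgical-valve proportions, not a certified reconstruction of any commercial
device; its role is to make the geometry pipeline runnable and testable
without measurements of a physical valve.

Coordinate convention: valve centreline = z, annulus plane z = 0, flow
toward +z. Geometric orifice area projects the joined three-leaflet free-edge
circuit along a chosen axis and applies the shoelace formula; a
self-intersecting projection warns but is not repaired, matching the simple
2-D projection definition of GOA. Input mm, output cm².

## Hemodynamic metrics

EOA is evaluated verbatim in its clinical mixed-unit form
Q_RMS[mL/s] / (51.6 √(ΔP̄[mmHg]/ρ_f[g/cm³])) → cm², keeping bit-level
compatibility with the Gorlin-type formula as used in practice. The
"positive differential pressure period" is the maximal contiguous dP > 0
interval containing the dP maximum — a rule that is robust to small diastolic
pressure-difference noise. MPG is a *sample mean* of 4v², not a time
integral, matching its discrete echocardiographic definition; TPG and VTI are
trapezoid time means/integrals.

Plane analysis samples a disc section with a midpoint polar quadrature
(default 64 radial × 64 angular nodes, ring-sector area weights summing
exactly to πR²) and trilinear interpolation of the grid velocities. Samples
interpolating into out-of-lumen (NaN) regions carry no flow and are excluded
from speed statistics; mean speed is area-weighted. Jet and mean velocities
use the speed magnitude rather than the normal component, following 4D-flow
jet-velocity reporting conventions. Maximum jet velocity is taken over all
frames at the plane unless a frame is specified.

## WSS metrics

All cycle integrals close periodically (the last→first frame wrap is
included); dropping the wrap term biases OSI on coarsely sampled series. OSI
is clamped to [0, 0.5] against floating-point overshoot and reported as
missing (NaN) on faces with identically zero shear, never as 0. RRT is
singular at full reversal; faces where (1 − 2·OSI)·TAWSS < 1e-6 Pa report the
sentinel 1e6 Pa⁻¹ with a flag instead of overflowing. Regional averages are
area-weighted means of the per-face metric values (average-of-pointwise, not
metric-of-average), skipping missing faces; area weighting was chosen over
vertex counting because it is mesh-refinement invariant.

## Synthetic data

The generators are closed-form — no ODE/PDE solves — so every target is known
exactly and the analysis can be tested closed-loop:

- *Inlet flow*: half-sine systolic lobe over a 0.35 fraction of a 1 s cycle,
  zero diastole, amplitude normalised through the package's own
  stroke-volume measurement so the measured SV equals the target to
  round-off (default 99.48 mL). The peak therefore matches the continuous
  closed form SV·π/(2·t_sys) only to quadrature accuracy (~1e-3 relative at
  256 samples); the normalisation target is the measured integral, which is
  the quantity the analysis consumes.
- *Pressure pair*: smooth LV/aortic traces whose systolic difference is a
  half-sine scaled so the measured TPG equals the target exactly; optional
  i.i.d. Gaussian noise.
- *WSS series*: per-face constant-magnitude vectors whose direction swings
  in a seeded plane as φ(t) = φ_max·sin(2πt/T). The discrete mean of cos φ
  is solved for φ_max (Brent, 1e-15 tolerance) so the discrete OSI hits its
  target to round-off; TAWSS is the magnitude outright. Recovery is 1e-6 or
  better at 256 frames.
- *Velocity volumes*: axial Poiseuille duct flow with exact analytic flow
  rate; two grid cells of explicit zero-velocity wall padding separate the
  lumen from the NaN out-of-lumen region so that near-wall interpolation
  sees the no-slip wall instead of a masked band.
- *Valve kinematics*: three 120° free-edge arcs opening from a collapsed
  (zero-area) state to a circular orifice of prescribed peak area and back,
  unimodal in time; the frame nearest peak systole is pinned to the exactly
  fully open state.

Default magnitudes (SV 99.48 mL, jet 2.20 m/s, peak GOA 2.28 cm²,
TPG 5.82 mmHg) are realistic for an adult with a well-functioning 25 mm
pericardial prosthesis and serve only as physiologic scales.

What the generators do **not** emulate: measurement noise structure of MRI
(velocity aliasing, partial-volume effects), turbulence, leaflet flutter,
asymmetric jets, or any coupling between the generated fields. Passing the
closed-loop suite therefore demonstrates that the *analysis* is correct on
data of known structure — it says nothing about solver fidelity on real
anatomy.

## File formats

Waveforms: `time_s,value` CSV. Velocity volumes: ASCII legacy-VTK
structured-points files with a `VECTORS velocity` array, one per frame, NaN
carried as a 9.9e30 sentinel, plus a frame-time CSV. WSS series: one
`face_index,tau_x,tau_y,tau_z` CSV per frame. Meshes: STL via `trimesh`;
designs as JSON; free-edge polylines as `x,y,z` CSV. The VTK reader/writer is
a minimal in-package implementation covering exactly this dialect.

## Problem sizes

Default discretisations — 256 samples per cycle, 64×64 disc quadrature,
40×40×8 velocity grids, 16×16 leaflet resolution, 100-point free-edge arcs —
were chosen as the coarsest sizes at which every closed-loop recovery meets
its stated tolerance with at least a factor-of-two margin; all are
constructor arguments and can be raised freely.

## Limitations

- The 3EWK estimation closure (proximal split, distal decay time) is a
  modelling choice, not an identified patient parameter.
- The default valve design is generic; no claim is made about any
  commercial device's geometry.
- Leaflet material symmetry is isotropic; pericardium is anisotropic.
- GOA uses an un-repaired projected polygon; strongly folded free edges at
  late closing may need self-intersection handling.
- The in-lumen mask for plane analysis must come with the data; no
  segmentation is performed.
- No closed-loop lumped-parameter network: inlet and outlets are open-loop.
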