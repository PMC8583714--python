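# Methods

This note documents the model behind `dosim`, the defaults it ships with,
and the reasoning behind the design choices that were genuinely open.

## Geometry and discretization

The osteotomized bone is modeled axisymmetrically in the (r, z) plane:
two fragments (cortical wall between r = 6 and 8 mm with marrow inside,
30 mm long each — the length is result-insensitive and configurable)
separated by the distraction gap. The gap region is rectangular: callus
occupies the annulus between the endosteal and periosteal radii only, with
no tissue inside the marrow bore and no external (periosteal) bulge. An
`external_callus`-style bulge is deliberately not modeled.

The mesh is a structured tensor grid of 4-node quadrilaterals: 0.25 mm
elements in the callus (so the 1 mm initial gap always carries at least
four element rows; the cortical wall shares the fine radial lines so the
cortex–callus interface conforms) and 0.5 mm in bone by default. Before
every distraction action the callus is rebuilt at the new gap height and
all per-element fields (tissue concentrations, perfusion, residual stress
state) are remapped by Gaussian-distance-weighted averaging of old element
centroids (kernel width σ = one callus element size, cutoff 3σ, weights
normalized so constant fields transfer exactly; a coinciding sample point
is copied verbatim, which makes the map the identity on an unchanged mesh).
The freshly distracted slab — new callus above the previous gap top — is
initialized to 100 % connective tissue with 0 % perfusion, consistent with
the initial conditions of the whole callus after latency.

## Viscoelastic finite elements

Small-strain bilinear axisymmetric quadrilaterals with 2×2 Gauss
integration; geometry update between events is absorbed by the remeshing
step, so no large-strain formulation is needed. The constitutive split is
isotropic with an elastic bulk response and a deviatorically relaxing
Prony series,

  s(t) = 2G [ g∞ e(t) + Σᵢ qᵢ(t) ],  qᵢ ← e^(−Δt/τᵢ) qᵢ + 2G gᵢ αᵢ Δe,
  αᵢ = (1 − e^(−Δt/τᵢ)) / (Δt/τᵢ),

the standard recursive update, exact for strain histories piecewise linear
in time. A flag applies the relaxation to the full tensor instead
(`relax_bulk`), which is the configuration used for the closed-form
relaxation oracle in the tests, where force/peak must equal g(t) exactly.
Distraction increments ramp over 1 s in 10 uniform sub-steps and hold for
12 h in 20 log-spaced sub-steps, resolving both published time constants
(≈11 s and ≈980 s). The non-decaying stress part plus the branch
overstresses are carried to the next event (element-level resolution so
they survive remeshing); during consolidation the branch stresses decay by
the elapsed day between load events.

The consolidation load (500 N, the axial walking load) is applied once per
day as a single quasi-static step through a rigid plate (all top-surface
nodes share one axial degree of freedom), with the external fixator as a
spring from the fixed base to that plate. The fixator law is linear by
default (a monotone piecewise-linear table is supported and solved by
secant iteration); its stiffness is calibrated in closed form — for a
linear spring and single-step solve the plate displacement obeys
q = −F/(k + k_t), so two probe solves determine k exactly — such that the
all-connective-tissue end-of-distraction construct yields IFM = 0.5 mm
under 500 N, the reference dynamic-fixation condition. With the default
library this gives k ≈ 983 N/mm.

The controller receives the *peak* (end-of-ramp) strain invariants of the
most recent event: the stimulus windows describe the distraction stretch,
which is largest before relaxation. Dilatational strain is the signed
trace (percent, tension positive); distortional strain is the octahedral
shear γ = (2/3)·√((e₁−e₂)² + (e₂−e₃)² + (e₃−e₁)²) in percent.

## Material library

Per-tissue elastic constants follow the standard fracture-healing
literature values: connective tissue 3 MPa (ν 0.30), cartilage 10 MPa
(0.45), woven bone 4 GPa (0.36), cortical bone 20 GPa (0.30); all
config-overridable. Woven bone at 4 GPa makes the fully ossified 15 mm
regenerate close to 0.02 mm under the 500 N load with the calibrated
fixator — the published healed-state IFM plateau. Element properties come
from the cube-root mixture rule E = (Σ cᵢEᵢ^(1/3))³ (strongly favoring the
stiff phase, so partial ossification stiffens quickly), linear mixing for
ν, and linear scaling of the Prony weights to zero as the mineralized
fraction reaches 100 %.

The daily relaxation-force law is implemented as three Maxwell branches
(time constants 3690 s, 469.3 s and a day-dependent 9.95·e^(0.09j) s) plus
an equilibrium term 1.22·e^(0.13j), each amplified by an exponential
day factor and proportional to the applied increment; this reading
reproduces both the published two-term Prony coefficients and the ≈6 %
residual-force fraction (F₀(0) = 18.47 N per mm of increment, equilibrium
fraction 1.22/18.47 = 6.6 % ≈ 6.23 %). It is isolated in one function.

`fit_prony` fits g(t) = 1 − Σ gᵢ(1 − e^(−t/τᵢ)) to a normalized curve by
nonlinear least squares with time constants optimized in log space. For
experimental-style curves whose hold is long enough that the slowest
physical mode has fully decayed (the 12 h hold versus τ_max = 3690 s), the
long-time fraction is *pinned to the observed end-of-hold plateau* rather
than extrapolated; this is the `pin_equilibrium` option, used by the
published-coefficient calibration. Unconstrained least squares (the
default) recovers exact Prony data to machine precision and is what the
round-trip tests exercise. The day-0 curve is fitted; fitting later days
is supported via the `day` argument. A separate utility calibrates an
instantaneous callus modulus from the t = 0 stiffness of the annular gap
(≈0.21 MPa for the 1 mm gap); the default library uses the literature
elastic constants instead, which the healed-state IFM endpoint validates.

## Fuzzy mechano-regulation

The published rule base this controller descends from is not printed in
full anywhere, so the default table is reconstructed from the quantitative
strain windows that are reported, as a config-serializable artifact
(trapezoidal memberships with 10 % shoulders around each breakpoint;
Mamdani min/max inference; centroid defuzzification over symmetric output
classes negative/zero/low/high = −1/0/+0.5/+1 times the per-process
maximum daily rate). Defaults: Δperfusion, Δcartilage, Δbone ≤ 10 %/day,
chosen so the gap ossifies on the experimental ~12-week timescale; one
regulation step per action (two per day, each advancing half a day) during
distraction and one per day during consolidation.

Tensile branch (distraction): angiogenesis and intramembranous
ossification require 0.01 < |ε| < 3.4 % and γ < 15 %, an advancing
perfusion/bone front in the neighborhood (vessels grow from vascularized
tissue, bone from the ossification front — the intact cortex seeds both),
and, for bone, locally high perfusion. Within the window the γ < 5 %
sub-band stimulates only at half rate: a fading stimulus (the end of a
constant low-rate course) regenerates slowly, which is what makes a late
high-rate switch profitable. γ between 15 and 20 % drives chondrogenesis.
Tensile exceedance of *either* bound (ε > 3.4 % or γ > 20 %) disrupts the
element — reset to unperfused connective tissue. The either-trigger is
deliberate: under the low rate the dilatational bound is exceeded until
the gap reaches ≈6 mm and under the high rate until ≈12 mm, reproducing
the reported disruptive ranges of the two rates; requiring both
exceedances simultaneously shrinks the disruptive ranges far below those
and collapses the protocol ordering.

Compressive branch (consolidation): the daily load squeezes rather than
tears, so disruption and the dilatational gate do not apply; angiogenesis
and ossification gate on the distortional stimulus instead, and elevated
to very high distortion drives chondrogenesis (fibrocartilage instead of
rupture), with cartilage calcifying into bone once vessels arrive and the
distortion calms below ≈20 %. This asymmetric treatment mirrors the
tension/compression distinction of the mechano-regulatory model family
this controller reconstructs, and it is what produces the observed
consolidation behavior: a strain-concentrating soft band in the closing
gap matures through the endochondral route instead of being destroyed
daily.

Neighborhood aggregates are Gaussian-kernel means over all other elements
within 3σ of the centroid (σ = one element size), excluding the element
itself; cortex participates with 100 % perfusion and 100 % bone, marrow
with 100 % perfusion.

State updates source new bone from connective tissue (intramembranous) or
from cartilage when calcification withdrew it, cartilage from connective
tissue; concentrations are clipped, the connective reservoir absorbs the
balance, and the four components are renormalized to sum to 100 % (checked
to 10⁻⁶ at every step of every run).

## Protocols and the design rule

Low rate L = 1 mm/day, high rate H = 2 mm/day, both as two equal actions
12 h apart; four latency days; every admissible label (`control`, `LxHy`,
`HxLy`) must transport exactly 15 mm or it is rejected. The gap length for
the effective-strain rule ε_eff = r/l on day d includes the 1 mm osteotomy
gap plus everything transported through day d−1. The favorable ε_eff
window reported by `protocol_strain_report` (0.08–0.25 /day) maps the
per-action octahedral-shear band 5–15 % through the free axial stretch of
the gap tissue at ν = 0.3. A "very low–low–high" grammar extension is not
implemented: no anchored rates exist for it.

## Simulation loop and outputs

Initialization (end of latency, day 4): callus 100 % connective, 0 %
perfusion; marrow and cortex fully perfused; cortex fully mineralized.
Per distraction action: remesh → transfer → FE increment-and-hold →
strain invariants → neighborhood aggregates → fuzzy rules → state and
material update. After the last action the fixator is calibrated, then
each consolidation day solves the 500 N case, records the IFM and runs one
regulation step. Bony bridging is the first consolidation day with
IFM < 0.05 mm; runs stop at day 120 or once bridged with the IFM flat
(|ΔIFM| < 10⁻³ mm for 7 consecutive days). Everything is deterministic
for a fixed configuration. Outputs: `ifm.csv`, `bone_area.csv` (bone area
is Σ c_bone/100 × element r–z area over the callus), `concentrations.csv`,
`result.json`, and legacy-ASCII VTK snapshots of the tissue fields at a
configurable cadence.

## Problem sizes used in the shipped analyses

The published-endpoint computations use the full 0.25 mm callus
discretization (the healed-construct IFM model has ≈2900 elements). The
protocol-ordering comparisons and the end-of-distraction field-pattern
check run on the 0.5 mm mesh with consolidation truncated shortly after
the bridging plateau (day 60), and the pipeline smoke tests on a 1 mm
mesh; the bridging-day ordering is stable between the 0.5 mm and finer
meshes, while absolute bridging days shift by a day or two with
resolution, as expected for a front-propagation problem sampled daily.

## Known limitations

- Two-dimensional axisymmetry: no periosteal callus bulge, no bending or
  torsion, no fixator pin geometry; the fixator is a single axial spring.
- The rule base is a reconstruction constrained by the published windows
  and qualitative healing narrative, not the unpublished original; absolute
  bridging days and bone areas should be read as model-relative quantities,
  while the protocol *ordering* is the robust output.
- Mixture, Prony-blending and compressive-branch choices are the simplest
  monotone rules consistent with the published behavior; all are
  config-exposed for sensitivity analysis.
- The daily consolidation load is a single quasi-static event; cyclic
  loading within a day is not resolved.
- Tissue transport is purely local (Gaussian neighborhoods); there is no
  cell migration, growth-factor or oxygen field.
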