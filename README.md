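# dosim — mechanobiological simulation of distraction osteogenesis

Distraction osteogenesis (DO) regenerates large bone defects by slowly
pulling apart an osteotomized bone so that new bone forms in the widening
gap. The healing outcome depends strongly on the distraction *rate*: too
fast tears the regenerate and its blood supply, too slow under-stimulates
it. `dosim` simulates this process for an axisymmetric long-bone transport
model (sheep metatarsus dimensions: endosteal ⌀ 12 mm, periosteal ⌀ 16 mm,
1 mm osteotomy gap, 15 mm transport) and lets you compare constant-rate and
**rate-varying** protocols — e.g. eleven low-rate days followed by two
high-rate days (`L11H2`) — by their time to bony bridging and bone
formation.

The package is aimed at computational biomechanics researchers studying
mechano-regulated bone regeneration and at anyone designing distraction
protocols in silico.

## Model

Three coupled components run in a daily loop over the latency → distraction
→ consolidation phases:

1. **Axisymmetric viscoelastic finite elements.** Bilinear 4-node
   quadrilaterals in the (r, z) plane with 2×2 Gauss integration. Each
   distraction action prescribes a displacement increment (1 s ramp, 12 h
   hold); the soft callus relaxes with a deviatoric Prony series
   g(t) = 1 − Σᵢ gᵢ(1 − e^(−t/τᵢ)), integrated by the recursive exponential
   update, with residual stress carried between events. The callus is
   remeshed before every action and all fields are remapped by normalized
   Gaussian-kernel averaging. During consolidation a 500 N axial load is
   applied once daily through a rigid plate, with the external fixator as a
   parallel spring calibrated so the all-connective-tissue construct yields
   an interfragmentary movement (IFM) of 0.5 mm.

2. **Daily relaxation law and Prony calibration.** The per-day traction
   force after an increment u follows the empirical law
   F_j(t) = u·(3.57e^(0.17j)e^(−t/3690) + 6.79e^(0.11j)e^(−t/469.3)
   + 6.89e^(0.08j)e^(−t/(9.95e^(0.09j))) + 1.22e^(0.13j)),
   with a long-time residual force of 6.23 % of the peak. A two-term Prony
   fit of the normalized day-0 curve (equilibrium pinned to the fully
   relaxed end-of-hold value) recovers the coefficients used for the callus:
   g₁ ≈ 0.41, τ₁ ≈ 11.8 s, g₂ ≈ 0.52, τ₂ ≈ 1069 s.

3. **Fuzzy mechano-regulation.** Each callus element is a mixture of
   connective tissue, cartilage, woven and cortical bone with a blood
   perfusion level. A Mamdani rule base maps seven state variables — the
   peak dilatational (ε) and octahedral distortional (γ) strains of the most
   recent event plus five biological variables (perfusion, cartilage, bone,
   and the Gaussian-kernel neighborhood perfusion and bone) — to daily
   changes of perfusion, cartilage and bone: angiogenesis, intramembranous
   and endochondral ossification, chondrogenesis, cartilage calcification
   and tissue disruption. The stimulatory window is 0.01 < ε < 3.4 % with
   γ < 15 %; tensile exceedance of either bound disrupts the tissue.
   Element stiffness follows the cube-root mixture rule
   E = (Σᵢ cᵢ Eᵢ^(1/3))³.

Protocol design is summarized by the effective strain **ε_eff = r / l**
(daily rate over current gap length): under a constant rate ε_eff decays as
the gap grows, which is why a late switch to a high rate keeps the stimulus
inside the favorable window.

## Worked example

Calibrate the Prony series of the day-0 relaxation curve:

```bash
$ dosim fit-prony
{
  "g": [0.41197237977870427, 0.5219729698112059],
  "tau_s": [11.759669842490245, 1068.9166808287785],
  "g_inf": 0.06605465041008984,
  "rms": 0.019024508331307415
}
```

The fast branch (g₁ = 0.412, τ₁ = 11.76 s) matches the published two-term
coefficients (0.396, 10.775 s) within a few percent, and the long-time
fraction g_∞ = 6.6 % reproduces the 6.23 % residual-force rule.

Run the constant low-rate control protocol on a coarse 0.5 mm mesh:

```python
from dosim import SimulationConfig, run

res = run(SimulationConfig(element_size=0.5, end_day=60))
print(res.bridging_day)        # 38.0   (day of first IFM < 0.05 mm)
print(res.fixator_stiffness)   # 982.6  (N/mm, calibrated)
print(res.ifm_series[-1])      # (51.0, 0.0219)  IFM plateau ~0.02 mm
print(res.bone_area_at(42.0))  # 30.0   (mm^2 regenerated bone at week 6)
```

The IFM starts at the 0.5 mm calibration level when consolidation begins
(day 19), decreases monotonically as the regenerate ossifies and plateaus
near 0.02 mm — the signature of a complete bony union. Comparing protocols:

```bash
dosim compare --protocols control,L11H2,H4L7 --element-size 0.5 --end-day 60
```

ranks the low-to-high protocol `L11H2` at least as fast as the control and
the high-to-low `H4L7` slower (bridging days 38 / 38 / 41 on this mesh),
with per-protocol bone areas at weeks 3, 6 and 9.

Equation-based protocol design, e.g. the rate that keeps ε_eff = 0.1/day at
a 10 mm gap:

```bash
$ dosim design --gap 10 --target-strain 0.1
{"gap_mm": 10.0, "target_strain_per_day": 0.1, "rate_mm_per_day": 1.0, ...}
```

Each `dosim run --outdir OUT` writes `ifm.csv`, `bone_area.csv`,
`concentrations.csv`, a `result.json` summary and legacy-ASCII VTK snapshots
of the tissue fields for ParaView.

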