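# Methods

This note records the scientific and numerical choices behind `latwin`:
what is modelled, which knobs matter, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## Cell model

The myocyte is the Courtemanche–Ramirez–Nattel (CRN) human atrial model
(21 state variables: Vm, 15 gates, 5 concentrations) extended with an
acetylcholine-activated potassium current I_KACh in a Kneller-style
formulation. The ACh level defaults to 0 µM, so the term is present but
inactive unless configured; the cohort runs below use 0.

Three multiplicative per-channel conductance layers compose in any order:

* **Chronic-AF remodeling** (default, replaceable via config):
  I_CaL × 0.3, I_to × 0.5, I_Kur × 0.5, I_K1 × 2.0 — the standard
  direction of chronic-AF electrical remodeling for this model family.
  With it, APD₉₀ at 500-ms pacing falls from ≈ 279 ms to ≈ 132 ms.
* **Fibrosis**: I_K1 × 0.5, I_CaL × 0.5, I_Na × 0.6 on fibrotic nodes.
* **Drug block**: factor (1 − θ) per channel from Hill's equation.

The shipped amiodarone table (IC50 in µM, nH = 1: I_Na 3.0, I_CaL 5.8,
I_Kr 1.0, I_to/I_Kur/I_Ks 20, I_K1 40) is *data, not algorithm*: it is a
literature-style multichannel profile chosen so that sodium-channel block
grows with dose and rapid-delayed-rectifier block dominates at
therapeutic doses. Any table with those qualitative features preserves
the package's directional results; the config file replaces it wholesale.

## Integration

Gates use Rush–Larsen exponential updates; Vm and concentrations use
forward Euler; reaction and diffusion are Lie-split with a shared step.
All voltage-dependent kinetics are pre-tabulated on a 0.05-mV grid per
time step (linear interpolation); Nernst potentials are refreshed every
10 steps (concentrations drift by < 10⁻³ mM per refresh interval, i.e.
< 10⁻³ mV of reversal-potential error). Defaults: dt = 0.02 ms single
cell, 0.05 ms tissue physics, 0.1 ms cohort runs (the declared reaction
stability bound; halving dt changes APD₉₀ by < 1 ms and activation times
by well under 1 ms). The diffusion CFL bound dt ≤ h²/(4·Dmax) is checked
at run time.

Equivalence against a naive reference integrator (plain Python loops,
closed-form rates each step, per-step Nernst, no tables) is enforced to
0.5 mV max deviation for a single-cell beat and a 1-D propagated cable
(tests use dt = 0.002–0.0025 ms so that method differences, which appear
as a phase shift of the steep upstroke, stay below that bound).

## Tissue operator

D = Dt·I + (Dl − Dt)·f fᵀ per node, with D{l,t} = scale · σ{l,t}/(χ·Cm),
χ = 1400 cm⁻¹ and Cm = 1 µF/cm² (so σ = 0.1264 S/m ↦ 0.090 mm²/ms).
Discretization on the uniform sheet is a conservative finite-volume
stencil: harmonic edge averaging for the diagonal-tensor fluxes, and the
cross term assembled as M + Mᵀ, where M conservatively discretizes
∂x(Dxy ∂yV) with arithmetic edge averaging — adding the transpose
supplies the adjoint term, making the operator symmetric with zero row
and column sums (no-flux boundaries and lesion decoupling fall out of
zeroed edge fluxes). Lesion nodes are decoupled and non-excitable.

Planar-wave conduction velocity is measured by pacing a ~1-mm-deep edge
band (capture then does not depend on the coupling strength) and
regressing activation time on distance over the central half of the
domain. CV ∝ √D holds within 5 % over a 4× diffusion range once the
wavefront spans several nodes (the test grid uses h = 0.1 mm).

Once all stimuli have passed and no activation has occurred for a
configurable quiet interval (default 1 s in protocol runs), the solver
finishes the window at rest — exact for this autonomous system, and it
makes terminated runs cost only their active span.

## Desk-scale AF: geometry and calibration

The study-scale left atrium (~4×10⁵ nodes, ~10 cm) is replaced by a
64 × 64 sheet. Two constraints pin the spacing at 0.4 mm (25.2-mm
domain): point-source (pacing-site) propagation in remodeled tissue
fails when transverse coupling σt/(χCm·h²) drops too low, which rules
out very fine-but-small domains at AF-compatible conduction velocities,
while reentry needs the domain to exceed the wavelength CV × APD.
At CV ≈ 0.15–0.25 m/s and remodeled APD ≈ 100 ms the wavelength is
15–25 mm, so the sheet sustains reentry anchored on the PVI-ring
obstacles and fibrotic patches (re-entrant waves, sometimes regular
enough to classify as AT rather than AF — both count as sustained).

Per-patient baseline calibration mirrors the clinical-twin procedure of
tailoring the diffusion coefficient until induced AF persists, in two
stages: (1) bisection of the global diffusion scale to a planar CV of
0.20 m/s (tolerance 15 %; the precise value only seeds stage 2); then
(2) actual ramp-pacing induction runs probing scale multipliers
(1.0, 1.4, 0.7), accepting the first scale whose induced rhythm is still
active at the end of the observation window. Patients with no sustaining
scale in the bracket are excluded and reported — the AF-maintenance
statistic is defined over calibrated patients, exactly as a baseline
tailored "to ensure persistence" implies. Which individual substrate
calibrates is sensitive to tiny parameter changes (the induced dynamics
are chaotic); the calibrated-fraction is therefore seed-dependent
(typically 40–70 %), while the maintenance fraction over calibrated
patients is structurally 100 %.

## Protocols

* Constant pacing: CL 500 ms at the earliest activation site (EAS; found
  from one paced beat, ties to the lowest node index), 20 conditioning
  beats before measurement.
* Ramp induction: CL 200→120 ms in 10-ms steps. The full protocol is
  8 beats per CL (Σ = 8 × 1440 ms = 11.52 s, enforced as an invariant);
  cohort runs use a compressed ramp of 2 beats per CL (2.88 s) so a 10-s
  observation window fits the desk budget. Stimuli are 2-ms pulses;
  cohort runs use a fixed 60 pA/pF (≈ 2× the diastolic threshold found
  by the automated strength search on these grids).
* Observation: 10 s in the reproduction script (32 s available by
  config); the test suite uses 6-s windows for the cohort test to keep
  the default run inside its time budget. Termination = no −40-mV
  upstroke crossing anywhere in the final 500 ms; AT = pooled
  cycle-length coefficient of variation < 0.1 with dominant CL > 120 ms;
  otherwise AF.

## Biomarkers

(DI, APD₉₀) pairs are read per node from the recorded Vm movie (2-ms
frames, linear interpolation of threshold crossings; activation = max
dV/dt, amplitude = peak − take-off, DI from 90 % repolarization of beat
k to activation of beat k+1). The restitution fit weights residuals by
the observed APD (measurement noise is closer to multiplicative than
additive), initialized at y₀ = min APD, A₁ = range, τ₁ = median DI, with
τ₁ ∈ [1, 1000] ms; Smax evaluates the closed-form slope at the smallest
observed DI (the slope is monotone decreasing in DI). Nodes with < 4
pairs, degenerate DI span, or failed fits are flagged, excluded from
regional means, and counted; > 50 % unfittable flags the summary
low-confidence. Both per-node restitution modes are available: all valid
ramp beats (default) or only the last three pairs.

DF uses mean removal, a Hann taper, 4× zero padding, and the maximal
bin in 1–20 Hz; the nominal 17–23-s window auto-shifts to the last 6 s
of a shorter observation, with the actual window recorded in output.

Regional aggregation uses a fixed 2 × 3 block template on the sheet
labelled with the six anatomical region names (septum, anterior wall,
appendage / left lateral isthmus, posterior wall, posterior-inferior
wall), standing in for anatomical segmentation so the aggregation logic
(mean, highest, lowest, Δregional) is fully exercised.

## Synthetic cohort

Each virtual patient is a seeded draw of: ≥ 500 uniformly scattered
EAM-like voltage points (background Gaussian, mean 0.8–1.1 mV, SD
0.35 mV, truncated at 0 — the fibrosis-active range), 3–5 low-voltage
patches (radius 3–5 mm, mean 0.1–0.3 mV) standing in for fibrotic
scar, an atlas-like twisting fiber field (30–90° twist), and a
two-vein-hole + 2-mm PVI-ring lesion template. Fibrosis always flows
through the voltage → probability → random-draw chain, so the full
substrate path is exercised. Fibrotic fractions land around 10–35 %.

What the generator does **not** emulate: real atrial geometry and wall
thickness, catheter-contact voltage artefacts, spatially correlated
mapping noise, atlas fiber fields, and the clinical LAT-synchronization
step. Passing cohort tests therefore demonstrates the pipeline's
mechanics and directional pharmacology on AF-capable synthetic
substrates, not clinical predictive performance.

Under the default desk-scale conditions the virtual drug terminates AF
in most calibrated patients at the high dose, so the Effective /
Ineffective split is usually one-sided on small cohorts; substrates
resistant at both therapeutic doses (Ineffective) appear only
occasionally. Larger domains and longer windows differentiate the
groups better; at desk scale the robust readouts are the baseline
maintenance fraction and the dose trend.

## Problem sizes used

Single-cell tests: 20 conditioning beats at dt = 0.02 ms. Tissue physics
tests: strips up to 100 × 8 (h = 0.1 mm) and sheets up to 64 × 64.
Cohort runs: 10 patients, 64 × 64, dt = 0.1 ms, 2-ms frame recording;
6-s observation in the test suite, 10-s in the reproduction script.

## Known limitations

* 2-D sheets only; no bi-atrial or 3-D shell geometry.
* Steady-state pore block only (no state/use-dependent drug kinetics,
  no active metabolites).
* Explicit time stepping bounds dt; no adaptive stepping.
* The printed Smax/DF magnitudes of the clinical cohort depend on
  patient anatomy and are not reproduced — only their directional
  behaviour under dose is.
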