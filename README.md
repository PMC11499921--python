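# latwin

Left-atrial digital-twin electrophysiology simulator for virtual
antiarrhythmic-drug testing.

`latwin` builds a per-patient model of drug-modulated atrial tissue —
fibrotic, fiber-anisotropic, with pulmonary-vein-isolation (PVI) lesions —
induces virtual atrial fibrillation (AF) by ramp pacing, classifies the
resulting rhythm (AF / atrial tachycardia / termination), and maps the two
wave-dynamics biomarkers used to stratify drug response: the maximal APD
restitution slope (Smax) and the dominant frequency (DF). A synthetic
virtual-patient generator emulates clinical electroanatomical-map (EAM)
inputs so the entire pipeline runs at desk scale with no external data.

## The model

* **Myocyte.** Courtemanche–Ramirez–Nattel (CRN) human atrial kinetics with
  an acetylcholine-gated potassium current (inactive by default):

  I_ion = I_Na + I_CaL + I_to + I_Kur + I_Kr + I_Ks + I_K1 + I_KACh
        + I_NaCa + I_NaK + I_b,Na + I_b,Ca + I_p,Ca

  Chronic-AF remodeling, fibrosis (I_K1 and I_CaL −50 %, I_Na −40 %), and
  drug block all act as multiplicative per-channel conductance factors.
* **Tissue.** Monodomain reaction–diffusion,
  ∂V/∂t = ∇·D∇V − (I_ion + I_stim)/C_m, on a 2-D sheet with a per-node
  anisotropic tensor D built from the fiber direction and the four-value
  conductivity table (0.1264 / 0.0546 S/m longitudinal, 0.0252 / 0.0068 S/m
  transverse for healthy / fibrotic tissue).
* **Substrate.** Sparse bipolar-voltage points are interpolated onto the
  node set by inverse-distance weighting (10-mm radius, power 2); each node
  is declared fibrotic when a uniform random draw falls below
  P_fibrosis(V) = clamp[(−40V³ + 155V² − 206V + 99.8)/100] on 0–1.74 mV.
* **Pharmacology.** Per-channel block via Hill's equation
  θ = [1 + (IC50/D)^nH]⁻¹ with amiodarone dose presets 1.6 µM (low),
  3.9 µM (high), 8.0 µM (toxic); conductances scale by (1 − θ).
* **Protocols and outcome.** Constant 500-ms pacing for APD₉₀ / dV/dt;
  ramp pacing (cycle length 200→120 ms in 10-ms steps, 8 beats per CL =
  11.52 s in the full protocol) for AF induction; termination means no
  activation in the final 500 ms of the observation window; the drug is
  *Effective* for a patient when AF terminates at ≥1 therapeutic dose.
* **Biomarkers.** Per-node restitution fits APD = y₀ + A₁(1 − e^(−DI/τ₁)),
  Smax = (A₁/τ₁)e^(−DI_min/τ₁); DF is the spectral peak (1–20 Hz, Hann,
  4× zero padding) over a 6-s window of sustained AF/AT; both are
  aggregated over the six-region atrial scheme (mean / highest / lowest /
  Δregional).

## Worked example

Per-channel amiodarone block at the high (3.9 µM) dose:

```bash
latwin blockade 3.9
```

    channel,theta
    INa,0.565320
    ICaL,0.402062
    ...
    IKr,0.795918

Steady-state single-cell dose response of a control (non-remodeled) cell
at 500-ms pacing:

```python
from latwin import dose_response_cell
from latwin.pharmacology import AMIODARONE

print(dose_response_cell(AMIODARONE, [0.0, 1.6, 3.9, 8.0], cl_ms=500.0))
```

    concentration_uM  apd90_ms  dvdtmax_Vps
                 0.0     279.0        200.0
                 1.6     319.5        137.8
                 3.9     320.2         86.6
                 8.0     312.0         56.4

(`latwin cell-sim` writes the same table for the chronic-AF-remodeled
cell used in tissue runs.) APD₉₀ lengthens at both therapeutic doses (class-III effect through I_Kr
block), sags slightly at the toxic dose (Ca/Na block catching up) while
remaining above baseline, and peak upstroke velocity falls strictly with
dose (use-independent I_Na block) — the expected amiodarone signature.

The full cohort pipeline (generate patients → calibrate diffusion for
sustained drug-free AF → virtual PVI → per-dose induction → verdicts →
biomarker maps):

```bash
latwin run-all -o out/           # writes manifest.csv, verdicts.csv,
                                 # cohort_summary.csv, biomarkers.csv
```

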