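# capfit

Lumped-parameter modelling of capillary microcirculation driven by the
ankle–brachial index (ABI), with particle-swarm system identification.

`capfit` is aimed at researchers in computational physiology and
biomedical engineering who want a non-invasive, circuit-analogue view of
skin-capillary hemodynamics — for example in the study of diabetic foot
ulcers, where capillary-level perfusion matters but direct capillary
measurements are impractical. From two bedside quantities (brachial and
ankle systolic pressure) the package derives pulsatile capillary flow
signals, fits a small electrical-analogue circuit to them, and analyses
the fitted system's dynamics.

## The model

The capillary is represented as a two-state Windkessel-type circuit: a
series resistance R₁ (proximal viscous loss) and inertance L (blood
inertia) feeding a parallel R₂–C pair (distal resistance and vessel
compliance), driven by an effort source u. With states x₁ (inductor
momentum) and x₂ (capacitor charge):

```
ẋ₁ = −(R₁/L)x₁ − (1/C)x₂ + u
ẋ₂ =  (1/L)x₁ − 1/(R₂C)x₂
```

The measured output is the capacitor effort x₂/C (distal pressure
analogue), giving the transfer function

```
G(s) = (1/LC) / (s² + (R₁/L + 1/R₂C)·s + (1 + R₁/R₂)/LC)
```

Around this core the package provides:

- **hemodynamics** — Poiseuille resistance R = 8ηl/(πr⁴) and flow
  Q = Δp/R, ABI computation and clinical strata, and the limb-pressure
  scaling rule that maps a patient's ankle systolic pressure onto
  capillary pressure and flow relative to a 120 mmHg baseline;
- **waveforms** — the systolic pulse Q(t) = Q₀·sin(2πt/Tₛ) during
  systole and 0 during diastole (72 BPM, Tₛ = 0.4·T_H by default), and
  the phase-shifted, ABI-scaled target signal;
- **fitting** — the OF = ISE + ITSE objective (integral of squared and
  time-weighted squared error) minimized by canonical global-best PSO
  with linearly decaying inertia (0.9 → 0.1), bound clamping, and a
  divergence guard;
- **stability** — Routh–Hurwitz tabulation cross-checked against pole
  locations, plus damping ratio ζ, natural frequency ωₙ, and the
  underdamped / critically damped / overdamped classification;
- **validation** — a known-parameter RLC bench (series L into parallel
  R‖C) for end-to-end recovery experiments, and a synthetic
  input/target generator for fitting tests.

## Worked example

The built-in three-patient cohort (ABI 0.6, 1.14 and 1.33):

```bash
$ capfit patient-table
patient,arterial_pressure_mmHg,capillary_pressure_mmHg,arterial_flow_m3_s,capillary_flow_m3_s,arterial_resistance_Pa_s_m3,capillary_resistance_Pa_s_m3
A,100.0,20.83,0.000442,1.95e-13,30200000.0,1.43e+16
B,160.0,33.33,0.000707,3.12e-13,30200000.0,1.43e+16
C,200.0,41.67,0.000883,3.9e-13,30200000.0,1.43e+16
```

Patient A's ankle pressure of 100 mmHg scales the 25 mmHg baseline
capillary pressure down to 20.83 mmHg and the capillary flow to
1.95×10⁻¹³ m³/s; the Poiseuille resistance of a 7 µm capillary is
1.43×10¹⁶ Pa·s/m³ for every patient — geometry, not pressure, sets it.

The reference fitted circuit (R₁ = 89.784, R₂ = 426.55, L = 27.506,
C = 0.00040675, in consistent abstract units):

```bash
$ capfit tf --params params.yaml
{
  "numerator_4sf": [89.38],
  "denominator_4sf": [1.0, 9.028, 108.2]
}
```

i.e. G(s) = 89.38/(s² + 9.028s + 108.2), a stable underdamped system
(ζ = 0.434, ωₙ = 10.40 rad/s) with conjugate poles at −4.5139 ± 9.371i:
capillary flow oscillates before settling after a pressure transient.

`capfit validate` runs the known-circuit bench: it synthesizes the
unit-step response of an RLC circuit with R = 1, L = 0.5, C = 0.25,
hands the input/output pair to the swarm, and reports per-seed parameter
estimates and the maximum step-response deviation between the true and
fitted systems.

Other subcommands: `synth-signal` (per-patient signal CSVs), `simulate`,
`fit`, `stability` (JSON report, optional gain sweep), `synth`
(synthetic fitting pairs), and `run` (the full per-patient pipeline with
a checksummed artifact manifest).

## Scope

The circuit layer is deliberately unit-agnostic (fitted R, L, C are in
consistent abstract units, not reconciled with the ~10¹⁶ Pa·s/m³
physical Poiseuille resistances). No wound-image processing, Doppler
signal processing, nonlinear vessel mechanics, or distributed (PDE)
hemodynamics — see `docs/methods.md` for the full method description
and its limitations.
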