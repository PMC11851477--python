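# Methods

## Model

The capillary is modelled as a linear time-invariant two-state circuit
analogue. A series resistance R₁ and inertance L feed a parallel R₂–C
pair; the driving term is an effort (pressure-analogue) source. In the
energy-based (bond-graph) derivation the natural states are the
inductor momentum and the capacitor charge, giving

    A = [[−R₁/L, −1/C], [1/L, −1/(R₂C)]],  B = [1, 0]ᵀ,  D = 0.

Two output conventions exist in the literature for this circuit. The
package's default measures the capacitor effort x₂/C (Cout = [0, 1/C]),
which is the physically meaningful distal-pressure analogue and the
convention whose transfer function has numerator 1/(LC); the
alternative that reads out the first state directly (Cout = [1, 0]) is
available via `assemble_state_space(..., output="first_state")` but has
no pressure interpretation. All derived quantities (transfer function,
DC gain, poles) follow from the chosen convention.

For positive parameters the model is unconditionally stable
(tr A < 0, det A > 0), so instability can only arise from candidate
vectors that violate positivity — which the fitting layer penalizes
rather than simulates.

The model layer is **unit-agnostic**: identified R₁, R₂, L, C live in
consistent abstract units. They are not reconciled with the physical
Poiseuille resistances (~10¹⁶ Pa·s/m³); the waveform amplitudes applied
to the circuit and the identified constants form a self-consistent
system on their own scale.

## Hemodynamic layer

Poiseuille's law gives the capillary resistance R = 8ηl/(πr⁴) with
r = diameter/2 (3.5 µm for the 7 µm reference capillary; a published
radius of 3 µm circulating in some tables is inconsistent with its own
diameter and does not reproduce the standard 1.43×10¹⁶ Pa·s/m³
resistance). The arterial (posterior tibial) resistance 3.02×10⁷ and
baseline flow 5.30×10⁻⁴ m³/s are literature constants that Poiseuille's
law cannot reproduce from the printed artery geometry — arteries are
not capillary-like laminar tubes — so they are treated as given
constants, never recomputed.

Patient profiles follow a linear limb-pressure scaling rule: with
s = ankle systolic / 120 mmHg, capillary pressure is 25·s mmHg, and
arterial and capillary flows scale by s from their baselines.
Linearity in the driving pressure at fixed resistance is exactly
Poiseuille's law; the rule reproduces all twelve published per-patient
values for the three-patient reference cohort at printed precision.
The mmHg→Pa factor is fixed at 133.322, which reproduces the published
ABI-scaled flows to 6 significant figures.

ABI strata: severe ≤ 0.4, moderate 0.41–0.7, normal 0.9–1.3,
Mönckeberg medial calcification ≥ 1.4, as conventionally printed with
inclusive boundaries. Values in the gaps (e.g. 1.33) are reported
`unclassified` rather than coerced into a neighbouring class.

## Waveforms

The input flow is a systolic sine pulse at 72 BPM: within each cardiac
period T_H = 60/72 s, Q(t) = Q₀ sin(2πt/Tₛ) for t ∈ (0, Tₛ) and 0 in
diastole, with Tₛ = (2/5)·T_H. The literal 2π argument implies a
negative second half-lobe during systole; because retrograde flow of
that magnitude is physiologically questionable, a `half_sine` variant
(single positive lobe, sin(πt/Tₛ)) is provided. The default remains
`full_sine`; none of the reference quantities depend on the choice.

The target (capillary-exit) signal is the same pulse delayed by 90° of
the systolic sine — a delay of Tₛ/4 — and rescaled so its peak equals
the patient's ABI-scaled capillary flow. Defaults: dt = T_H/1000,
three cardiac cycles per record (so the error-integral horizon ends at
the end of a diastole), both overridable.

## Simulation

`simulate_response` default (`method="exact"`) treats the sampled input
as piecewise linear between samples and propagates the state with the
exact first-order-hold discretization: the matrices e^(A·dt),
∫e^(As)ds·B and the ramp-weighted integral are obtained from one
augmented matrix exponential (Van Loan block construction), and the
resulting linear recursion is solved mode-by-mode with one-pole digital
filters after diagonalizing e^(A·dt). This is exact for the
interpolated input class, unconditionally stable, and fast enough to
sit inside the optimizer loop (≈1 ms per 2 500-sample record). A
defective propagation matrix (repeated eigenvalues) falls back to an
explicit loop.

`method="adaptive"` integrates the same interpolated input with an
adaptive explicit Runge–Kutta pair (rtol 1e-8, atol 1e-12, max step =
dt). The two routes agree to ~1e-6 on smooth inputs and to machine
precision on piecewise-constant ones; the test suite asserts this
dual-route agreement. Step and impulse responses use scipy's LTI
helpers over a horizon of eight time constants of the slowest mode.
Non-finite trajectories raise a divergence error carrying the blow-up
time.

## Objective and optimizer

The fitting objective is OF = ISE + ITSE with e(t) = target − simulated:
ISE = ∫e², ITSE = ∫t·e², both by the trapezoidal rule over the full
record. ISE emphasizes large early (transient) errors; ITSE penalizes
persistent late errors; the record spans an integer number of cardiac
cycles so the horizon T is the end of a diastole. Candidates that
violate parameter positivity or produce an unstable state matrix
receive a fixed penalty of 1e12 instead of a simulated error.

The optimizer is canonical global-best PSO:

| parameter | default | note |
|---|---|---|
| particles S | 20 | protocol default |
| iterations | 500 | protocol default |
| bounds | [1e-6, 450] per dim | protocol default (capillary fit) |
| inertia ω | 0.9 → 0.1, linear | decrement (ωf−ω₀)/MaxIter per iteration |
| cg, cs | 2.0 | canonical cognitive/social coefficients |
| v_init | uniform ±2·(x_max−x_min) | protocol default |
| v_max | 0.5·(x_max−x_min) | conventional half-range |
| r₁, r₂ | fresh uniform per particle-dimension | standard |

Out-of-bounds positions are clamped onto the box faces with the
velocity zeroed in the clamped dimensions (so particles do not pin
against the walls); velocities are clamped to ±v_max. A fixed seed
makes every run bit-reproducible.

**Identifiability.** The four circuit constants enter G(s) only through
three coefficients — 1/(LC), R₁/L + 1/(R₂C), (1 + R₁/R₂)/(LC) — so
(R₁, R₂, L, C) are identifiable only up to a one-parameter family.
Fits are therefore assessed in transfer-function (or response) space,
never by comparing raw parameter vectors.

**A caution on the search box.** In the [1e-6, 450]⁴ box prescribed for
the capillary fit, almost all of the volume corresponds to L·C products
so large that the system cannot respond within a few cardiac cycles:
the objective is flat there, and the equivalence family of any
fast-responding truth is a thin curve hugging the low-coordinate
region. Under these conditions the swarm reliably converges to
boundary attractors rather than the global valley; synthetic
self-recovery at this scale should not be expected to succeed at the
4-of-5-seeds level, and the acceptance suite documents exactly that.

## Validation bench

The bench circuit is an inductor L feeding a parallel R‖C pair driven
by a voltage source, output ix = v/R:

    A = [[−1/(RC), 1/C], [−1/L, 0]],  B = [0, 1/L]ᵀ,  Cout = [1/R, 0],

with characteristic polynomial s² + s/(RC) + 1/(LC) and DC gain 1/R (at
DC the inductor is a short and the capacitor open). The recovery
experiment excites the known circuit (default R = 1, L = 0.5, C = 0.25)
with a unit step, fits R, L, C per seed, and scores the maximum
deviation between true and fitted step responses relative to the true
final value.

Two bench design rules matter and are deliberate:

- **Search box [1e-6, 10]³** — a bench with known components of order
  one searches a region enclosing them with an order of magnitude of
  headroom; the capillary-problem box would turn the bench into a
  needle-in-a-haystack search that measures nothing about
  identification quality.
- **Record = 5× the 2% settling time** (4/min|Re pole|, i.e. 10 s for
  the default circuit, sampled at ~5 ms). A record that barely reaches
  settling cannot reject integrator-like impostors whose ramp crosses
  the target within the window; holding the steady state for several
  settling times lets ITSE separate them.

Even so, recovery is stochastic: across 20 seeds roughly four in five
runs recover the truth to machine precision and the rest stall on
wall-pinned local optima (a first-order lag matching the steady state,
or a near-integrator). Published per-run estimates of comparable
benches — e.g. (1.0187, 0.57453, 0.17955) and (1.0889, 0.42664,
0.22409) for this truth — sit well within the successful-run class and
are kept as reference magnitudes, not exact targets.

`synth_fit_pair` manufactures input/target pairs for the capillary
model from known parameters, optionally adding white Gaussian noise
whose standard deviation is a stated fraction of the clean target's
peak. It emulates the *structure* of clinical signal pairs (pulsatile
input, circuit-filtered target) but none of the physiological
variability of real microcirculation — beat-to-beat variation,
nonstationary vasomotor tone, measurement dropouts — so passing
recovery tests demonstrates correctness of the identification loop,
not clinical validity.

## Numerical choices

- Routh–Hurwitz zero pivots are replaced by ε = 1e-9·max|coefficient|;
  an all-zero row is replaced by the derivative of its auxiliary
  polynomial. The Routh verdict and the pole-location verdict are
  computed independently and must agree, else the report raises.
- Transfer-function numerators from the state-space conversion are
  stripped of leading coefficients below 1e-10 of the numerator scale,
  so strictly proper models stay strictly proper despite roundoff.
- Damping classification calls ζ = 1 "critically damped" within 1e-9
  relative; random-parameter draws essentially never hit it.
- Table rendering rounds pressures to 4 significant figures and flows
  and resistances to 3, matching how such tables are conventionally
  printed; full precision is kept internally everywhere.
- Reported pole coordinates inherit the precision of the five-figure
  input constants: the imaginary part of the reference pole pair is
  pinned only to ≈9.3712 by the printed parameters (quotations of
  9.3713 trace to unrounded internal values).

## Known limitations

- Single lumped capillary; no capillary network topology, no
  distributed (PDE) hemodynamics, no nonlinear vessel mechanics.
- The effort-source input is driven with a flow-shaped waveform
  without unit reconciliation, preserving the source formulation this
  model family uses; interpreting fitted constants in SI units is
  therefore not meaningful.
- The limb-pressure scaling rule is a linear reconstruction validated
  against a three-patient reference table, not a physiological model
  of pressure propagation.
- PSO success on the capillary-scale search box is landscape-limited
  (see the caution above); practical identification should either
  bound the search near the expected scale or fit in
  transfer-function coefficient space.
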