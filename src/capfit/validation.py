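"""Known-circuit validation bench and synthetic fixture generation.

Before trusting the optimizer on the capillary model, it is exercised on
a series RLC circuit whose parameters are known exactly: an inductor L
feeding a parallel R-C pair, driven by a voltage source vs, with the
resistor current ix = v/R as output.  With states (capacitor voltage v,
inductor current i):

    A = [[-1/(RC), 1/C], [-1/L, 0]],   B = [0, 1/L],   Cout = [1/R, 0],

giving G(s) = (1/(RLC)) / (s^2 + s/(RC) + 1/(LC)) and a DC gain of 1/R
(at DC the inductor is a short and the capacitor open, so the whole
source drops across R).  The recovery experiment drives this system with
a unit step, hands the input/output pair to the PSO, and measures how
far the fitted system's step response strays from the true one.

``synth_fit_pair`` plays the same role for the capillary model itself:
it manufactures an input/target pair from known circuit parameters
(optionally with additive white noise) so fitting tests have a ground
truth, standing in for clinical signals that cannot be shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import CircuitParams, StateSpaceModel, assemble_state_space, simulate_response
from .exceptions import InvalidInputError
from .fitting import PSOConfig, PSOResult, make_objective, pso_optimize
from .waveforms import SampledSignal, WaveformSpec, systolic_pulse


@dataclass(frozen=True)
class ValidationSystem:
    """Known RLC test circuit with its state-space realization."""

    r: float
    l: float
    c: float
    ss: StateSpaceModel


def build_validation_system(r: float, l: float, c: float) -> ValidationSystem:
    """Realize the validation circuit for positive R, L, C."""
    if not (r > 0 and l > 0 and c > 0):
        raise InvalidInputError("validation circuit parameters must be positive")
    a = np.array([[-1.0 / (r * c), 1.0 / c], [-1.0 / l, 0.0]])
    b = np.array([0.0, 1.0 / l])
    cout = np.array([1.0 / r, 0.0])
    return ValidationSystem(r=r, l=l, c=c, ss=StateSpaceModel(a=a, b=b, c=cout, d=0.0))


def _validation_builder(position: np.ndarray) -> StateSpaceModel:
    r, l, c = (float(v) for v in position)
    return build_validation_system(r, l, c).ss


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of the parameter-recovery experiment across seeds."""

    true_params: tuple[float, float, float]
    estimates: tuple[tuple[float, float, float], ...]
    relative_errors: tuple[tuple[float, float, float], ...]
    step_deviation: tuple[float, ...]
    objectives: tuple[float, ...]
    seeds: tuple[int, ...]


def step_input(horizon: float, n_points: int) -> SampledSignal:
    """Unit-step excitation sampled on [0, horizon]."""
    t = np.linspace(0.0, horizon, n_points)
    return SampledSignal(times=t, values=np.ones_like(t))


def recovery_experiment(
    truth: tuple[float, float, float] = (1.0, 0.5, 0.25),
    pso_config: PSOConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    horizon: float | None = None,
    n_points: int | None = None,
) -> RecoveryReport:
    """Fit the known circuit from its unit-step response, once per seed.

    The fitted quality metric is the maximum deviation between the true
    and fitted systems' step responses, normalized by the true final
    value (the DC gain 1/R); parameter-space relative errors are
    reported too, but the response is what the data actually constrain,
    so response deviation is the primary measure.

    The default search box is [1e-6, 10] per dimension: a bench with
    known components of order one searches a region enclosing them with
    an order of magnitude of headroom.  (The huge capillary-problem box
    would reduce the bench to a needle-in-a-haystack search that says
    nothing about identification quality.)

    The default record spans five times the true system's 2% settling
    time (4/min|Re(pole)|), sampled at ~5 ms.  A record that barely
    reaches settling cannot reject integrator-like impostors whose ramp
    happens to cross the target within the window; holding the steady
    state for several settling times lets the time-weighted error
    integral separate them.
    """
    if len(seeds) < 1:
        raise InvalidInputError("need at least one seed")
    r_true, l_true, c_true = truth
    true_system = build_validation_system(r_true, l_true, c_true)
    if horizon is None:
        rates = -np.linalg.eigvals(true_system.ss.a).real
        horizon = 5.0 * 4.0 / float(rates.min())
    if n_points is None:
        n_points = max(2, int(round(horizon / 0.005)) + 1)
    excitation = step_input(horizon, n_points)
    target = simulate_response(true_system.ss, excitation, method="exact")
    final_value = 1.0 / r_true

    base = pso_config if pso_config is not None else PSOConfig(n_dims=3, x_max=10.0)
    if base.n_dims != 3:
        raise InvalidInputError("the validation bench fits 3 parameters (R, L, C)")
    objective = make_objective(excitation, target, builder=_validation_builder)

    estimates, rel_errors, deviations, objectives = [], [], [], []
    for seed in seeds:
        config = PSOConfig(**{**base.__dict__, "rng_seed": int(seed)})
        result: PSOResult = pso_optimize(objective, config)
        r_hat, l_hat, c_hat = (float(v) for v in result.gbest_position)
        fitted = build_validation_system(r_hat, l_hat, c_hat)
        y_fit = simulate_response(fitted.ss, excitation, method="exact")
        deviation = float(np.max(np.abs(y_fit.values - target.values)) / abs(final_value))
        estimates.append((r_hat, l_hat, c_hat))
        rel_errors.append(
            tuple(abs(h - t) / abs(t) for h, t in zip((r_hat, l_hat, c_hat), truth))
        )
        deviations.append(deviation)
        objectives.append(result.gbest_value)
    return RecoveryReport(
        true_params=tuple(truth),
        estimates=tuple(estimates),
        relative_errors=tuple(rel_errors),
        step_deviation=tuple(deviations),
        objectives=tuple(objectives),
        seeds=tuple(int(s) for s in seeds),
    )


def synth_fit_pair(
    params: CircuitParams,
    spec: WaveformSpec,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[SampledSignal, SampledSignal]:
    """Input/target signal pair generated from known circuit parameters.

    The input is the systolic pulse of ``spec``; the target is the exact
    simulated response of the circuit, plus optional additive white
    Gaussian noise with standard deviation ``noise_sd`` expressed as a
    fraction of the clean target's peak magnitude.  Deterministic for a
    fixed ``seed``.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    input_signal = systolic_pulse(spec)
    target = simulate_response(assemble_state_space(params), input_signal, method="exact")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd * float(np.max(np.abs(target.values)))
        noisy = target.values + rng.normal(0.0, sigma, size=target.values.shape)
        target = SampledSignal(times=target.times, values=noisy)
    return input_signal, target
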