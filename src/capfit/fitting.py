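"""Error integrals, the fitting objective, and the particle swarm optimizer.

Parameter identification minimizes OF = ISE + ITSE, the sum of the
integral of squared error and the integral of time-weighted squared
error between the target signal and the simulated model output:

    ISE  = int_0^T e(t)^2 dt,     ITSE = int_0^T t e(t)^2 dt.

ISE penalizes large early errors, ITSE penalizes persistent late errors;
their sum balances transient and steady-state fit.  Both are evaluated
by the trapezoidal rule over the full record, which spans an integer
number of cardiac cycles so that T coincides with the end of a diastole.

The optimizer is the canonical global-best PSO: velocities are updated
with inertia, cognitive and social terms,

    v <- w v + cg r1 (pbest - x) + cs r2 (gbest - x),   x <- x + v,

with fresh uniform r1, r2 per particle and dimension, the inertia weight
decayed linearly from w0 to wf across iterations, velocities clamped to
+-v_max, and out-of-bounds positions clamped back into the box (the
velocity component is zeroed in clamped dimensions so particles do not
pin against the walls).  Candidate parameter vectors producing an
unstable state matrix, or a simulation that blows up, receive a fixed
large penalty instead of an error integral.

Identifiability caveat: the four circuit constants enter the
transfer function only through its three coefficients 1/(LC),
R1/L + 1/(R2 C) and (1 + R1/R2)/(LC), so (R1, R2, L, C) are identifiable
only up to a one-parameter family; fits are therefore compared in
transfer-function space, not parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .circuit import CircuitParams, assemble_state_space, simulate_response
from .exceptions import DivergenceError, InvalidInputError
from .waveforms import SampledSignal

#: Objective value assigned to diverging / unstable candidates.
DIVERGENCE_PENALTY = 1e12


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """ISE, ITSE and their sum for one candidate evaluation."""

    ise: float
    itse: float
    total: float
    diverged: bool = False

    @classmethod
    def penalty(cls) -> "ObjectiveBreakdown":
        return cls(ise=np.inf, itse=np.inf, total=DIVERGENCE_PENALTY, diverged=True)


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    Defaults mirror the fitting protocol this model family uses: 20 particles, 500 iterations,
    4 dimensions, position bounds [1e-6, 450], inertia decayed 0.9 -> 0.1,
    initial velocities uniform in +-2*(x_max - x_min).  The cognitive and
    social coefficients default to the canonical 2.0, and v_max to half
    the box width per dimension.
    """

    n_particles: int = 20
    max_iter: int = 500
    n_dims: int = 4
    x_min: float | Sequence[float] = 1e-6
    x_max: float | Sequence[float] = 450.0
    omega0: float = 0.9
    omegaf: float = 0.1
    cg: float = 2.0
    cs: float = 2.0
    v_init_scale: float = 2.0
    v_max: float | Sequence[float] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise InvalidInputError("need at least 2 particles")
        if self.max_iter < 1:
            raise InvalidInputError("need at least 1 iteration")
        if not 0.0 < self.omegaf <= self.omega0 < 2.0:
            raise InvalidInputError("inertia endpoints must satisfy 0 < omegaf <= omega0 < 2")
        if np.any(self.lower >= self.upper):
            raise InvalidInputError("x_min must be elementwise below x_max")

    @property
    def lower(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.x_min, dtype=float), (self.n_dims,)).copy()

    @property
    def upper(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.x_max, dtype=float), (self.n_dims,)).copy()

    @property
    def velocity_limit(self) -> np.ndarray:
        if self.v_max is not None:
            return np.broadcast_to(np.asarray(self.v_max, dtype=float), (self.n_dims,)).copy()
        return 0.5 * (self.upper - self.lower)


@dataclass
class PSOResult:
    """Best position found, per-particle archive, and convergence trace."""

    gbest_position: np.ndarray
    gbest_value: float
    pbest_positions: np.ndarray
    pbest_values: np.ndarray
    convergence_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    evaluations: int = 0


def error_integrals(reference: SampledSignal, simulated: SampledSignal) -> ObjectiveBreakdown:
    """Trapezoidal ISE and ITSE of e(t) = reference - simulated."""
    if reference.times.shape != simulated.times.shape or not np.allclose(
        reference.times, simulated.times, rtol=1e-9, atol=1e-12
    ):
        raise InvalidInputError("reference and simulated signals must share one time grid")
    t = reference.times
    e2 = (reference.values - simulated.values) ** 2
    ise = float(np.trapezoid(e2, t))
    itse = float(np.trapezoid(t * e2, t))
    return ObjectiveBreakdown(ise=ise, itse=itse, total=ise + itse)


def objective_function(
    position: np.ndarray,
    input_signal: SampledSignal,
    target: SampledSignal,
    *,
    builder: Callable[[np.ndarray], "object"] | None = None,
    stability_guard: bool = True,
) -> ObjectiveBreakdown:
    """Evaluate one candidate parameter vector against the target signal.

    ``position`` is mapped to circuit parameters in the order
    (R1, R2, L, C) unless a custom state-space ``builder`` is supplied
    (the validation bench passes a 3-parameter builder).  Unstable or
    diverging candidates receive the fixed penalty; no exception escapes.
    """
    try:
        if builder is None:
            ss = assemble_state_space(CircuitParams.from_array(position))
        else:
            ss = builder(np.asarray(position, dtype=float))
    except InvalidInputError:
        return ObjectiveBreakdown.penalty()
    if stability_guard and not ss.is_stable():
        return ObjectiveBreakdown.penalty()
    try:
        simulated = simulate_response(ss, input_signal, method="exact")
    except DivergenceError:
        return ObjectiveBreakdown.penalty()
    return error_integrals(target, simulated)


def make_objective(
    input_signal: SampledSignal,
    target: SampledSignal,
    *,
    builder: Callable[[np.ndarray], "object"] | None = None,
    stability_guard: bool = True,
) -> Callable[[np.ndarray], ObjectiveBreakdown]:
    """Bind input/target signals into a position -> breakdown callable."""

    def objective(position: np.ndarray) -> ObjectiveBreakdown:
        return objective_function(
            position, input_signal, target, builder=builder, stability_guard=stability_guard
        )

    return objective


def inertia_update(omega_k: float, config: PSOConfig) -> float:
    """One linear-decay step: w + (wf - w0)/MaxIter."""
    return omega_k + (config.omegaf - config.omega0) / config.max_iter


def pso_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    omega: float,
    config: PSOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One velocity/position update for the whole swarm.

    Velocities are clamped to +-v_max; positions leaving the box are
    clamped onto its faces with the corresponding velocity zeroed.
    """
    shape = positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    velocities = (
        omega * velocities
        + config.cg * r1 * (pbest - positions)
        + config.cs * r2 * (gbest[np.newaxis, :] - positions)
    )
    v_lim = config.velocity_limit
    velocities = np.clip(velocities, -v_lim, v_lim)
    positions = positions + velocities
    lower, upper = config.lower, config.upper
    clamped = (positions < lower) | (positions > upper)
    positions = np.clip(positions, lower, upper)
    velocities = np.where(clamped, 0.0, velocities)
    return positions, velocities


def _value_of(result: "ObjectiveBreakdown | float") -> float:
    return result.total if isinstance(result, ObjectiveBreakdown) else float(result)


def pso_optimize(
    objective: Callable[[np.ndarray], "ObjectiveBreakdown | float"],
    config: PSOConfig,
) -> PSOResult:
    """Run global-best PSO; deterministic for a fixed ``config.rng_seed``.

    The swarm is initialized uniformly inside the bounds with velocities
    uniform in +-v_init_scale*(x_max - x_min); every position (initial
    and updated) is evaluated, personal and global bests updated, then
    the swarm stepped and the inertia decayed, for ``max_iter``
    iterations.  The convergence trace (best objective after each
    evaluation sweep) is non-increasing by construction.
    """
    rng = np.random.default_rng(config.rng_seed)
    lower, upper = config.lower, config.upper
    span = upper - lower
    positions = rng.uniform(lower, upper, size=(config.n_particles, config.n_dims))
    velocities = rng.uniform(
        -config.v_init_scale * span, config.v_init_scale * span,
        size=(config.n_particles, config.n_dims),
    )

    values = np.array([_value_of(objective(p)) for p in positions])
    evaluations = config.n_particles
    pbest_positions = positions.copy()
    pbest_values = values.copy()
    best_idx = int(np.argmin(pbest_values))
    gbest_position = pbest_positions[best_idx].copy()
    gbest_value = float(pbest_values[best_idx])
    trace = [gbest_value]

    omega = config.omega0
    for _ in range(config.max_iter):
        positions, velocities = pso_step(
            positions, velocities, pbest_positions, gbest_position, omega, config, rng
        )
        values = np.array([_value_of(objective(p)) for p in positions])
        evaluations += config.n_particles
        improved = values < pbest_values
        pbest_positions[improved] = positions[improved]
        pbest_values[improved] = values[improved]
        best_idx = int(np.argmin(pbest_values))
        if pbest_values[best_idx] < gbest_value:
            gbest_value = float(pbest_values[best_idx])
            gbest_position = pbest_positions[best_idx].copy()
        trace.append(gbest_value)
        omega = inertia_update(omega, config)

    return PSOResult(
        gbest_position=gbest_position,
        gbest_value=gbest_value,
        pbest_positions=pbest_positions,
        pbest_values=pbest_values,
        convergence_trace=np.asarray(trace),
        evaluations=evaluations,
    )
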