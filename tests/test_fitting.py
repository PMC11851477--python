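"""Error integrals, objective guards, and the particle swarm optimizer."""

import numpy as np
import pytest

from capfit import (
    DIVERGENCE_PENALTY,
    CircuitParams,
    InvalidInputError,
    PSOConfig,
    SampledSignal,
    StateSpaceModel,
    error_integrals,
    inertia_update,
    make_objective,
    objective_function,
    pso_optimize,
    pso_step,
)
from capfit.validation import synth_fit_pair
from capfit.waveforms import WaveformSpec


def signal(times, values):
    return SampledSignal(times=np.asarray(times, float), values=np.asarray(values, float))


class TestErrorIntegrals:
    def test_zero_error(self):
        t = np.linspace(0, 1, 100)
        ref = signal(t, np.sin(t))
        out = error_integrals(ref, ref)
        assert out.ise == 0.0 and out.itse == 0.0 and out.total == 0.0

    def test_unit_error_on_unit_interval_squared(self):
        """e = 1 on [0, 2]: ISE = 2 and ITSE = int t dt = 2."""
        t = np.linspace(0, 2, 201)
        out = error_integrals(signal(t, np.ones_like(t)), signal(t, np.zeros_like(t)))
        assert out.ise == pytest.approx(2.0, rel=1e-12)
        assert out.itse == pytest.approx(2.0, rel=1e-12)
        assert out.total == out.ise + out.itse

    def test_sine_error_closed_forms(self):
        """e = sin t on [0, pi]: ISE = pi/2, ITSE = pi^2/4."""
        t = np.linspace(0, np.pi, 5001)
        out = error_integrals(signal(t, np.sin(t)), signal(t, np.zeros_like(t)))
        assert out.ise == pytest.approx(np.pi / 2.0, abs=1e-4)
        assert out.itse == pytest.approx(np.pi**2 / 4.0, abs=1e-3)

    def test_grid_mismatch_rejected(self):
        t1, t2 = np.linspace(0, 1, 50), np.linspace(0, 2, 50)
        with pytest.raises(InvalidInputError):
            error_integrals(signal(t1, t1), signal(t2, t2))


class TestObjective:
    def test_truth_parameters_give_zero(self, reference_params):
        inp, tgt = synth_fit_pair(reference_params, WaveformSpec(peak_flow=1.0))
        out = objective_function(reference_params.as_array(), inp, tgt)
        energy = float(np.trapezoid(tgt.values**2, tgt.times))
        assert out.total <= 1e-20 * energy
        assert not out.diverged

    def test_nonpositive_parameter_is_penalized(self, reference_params):
        inp, tgt = synth_fit_pair(reference_params, WaveformSpec(peak_flow=1.0, n_cycles=1))
        out = objective_function(np.array([-1.0, 1.0, 1.0, 1.0]), inp, tgt)
        assert out.diverged and out.total == DIVERGENCE_PENALTY

    def test_unstable_candidate_is_penalized(self, reference_params):
        """An anti-damped state matrix trips the stability guard."""
        inp, tgt = synth_fit_pair(reference_params, WaveformSpec(peak_flow=1.0, n_cycles=1))

        def antidamped_builder(position):
            r1, r2, l, c = position
            a = np.array([[r1 / l, -1.0 / c], [1.0 / l, 1.0 / (r2 * c)]])
            return StateSpaceModel(a=a, b=[1, 0], c=[0, 1 / c])

        out = objective_function(
            np.ones(4), inp, tgt, builder=antidamped_builder, stability_guard=True
        )
        assert out.diverged and out.total == DIVERGENCE_PENALTY
        assert np.all(np.linalg.eigvals(antidamped_builder(np.ones(4)).a).real > 0)


class TestInertiaUpdate:
    def test_single_step(self):
        config = PSOConfig(omega0=0.9, omegaf=0.1, max_iter=500)
        assert inertia_update(0.9, config) == pytest.approx(0.8984, abs=1e-12)

    def test_reaches_final_weight_after_max_iter_steps(self):
        config = PSOConfig(omega0=0.9, omegaf=0.1, max_iter=500)
        omega = config.omega0
        for _ in range(config.max_iter):
            omega = inertia_update(omega, config)
        assert omega == pytest.approx(config.omegaf, abs=1e-12)

    def test_equal_endpoints_are_constant(self):
        config = PSOConfig(omega0=0.5, omegaf=0.5, max_iter=100)
        assert inertia_update(0.5, config) == 0.5


class _HalfRng:
    """Stand-in RNG whose uniform draws are all exactly 0.5."""

    def uniform(self, size=None):
        return np.full(size, 0.5)


class TestPsoStep:
    def test_hand_computed_update(self):
        """x=1, v=1, pbest=2, gbest=3, w=0.5, cg=cs=2, r=0.5 -> v'=3.5, x'=4.5."""
        config = PSOConfig(n_dims=1, x_min=-100.0, x_max=100.0, cg=2.0, cs=2.0)
        positions = np.array([[1.0], [1.0]])
        velocities = np.array([[1.0], [1.0]])
        pbest = np.array([[2.0], [2.0]])
        gbest = np.array([3.0])
        new_pos, new_vel = pso_step(positions, velocities, pbest, gbest, 0.5, config, _HalfRng())
        assert new_vel[0, 0] == pytest.approx(3.5)
        assert new_pos[0, 0] == pytest.approx(4.5)

    def test_pure_inertia_preserves_velocity(self, rng):
        config = PSOConfig(n_dims=3, x_min=-50.0, x_max=50.0, cg=0.0, cs=0.0)
        positions = rng.uniform(-1, 1, size=(4, 3))
        velocities = rng.uniform(-1, 1, size=(4, 3))
        new_pos, new_vel = pso_step(
            positions, velocities, positions.copy(), np.zeros(3), 1.0, config, rng
        )
        assert np.allclose(new_vel, velocities)
        assert np.allclose(new_pos, positions + velocities)

    def test_converged_particle_is_a_fixed_point(self, rng):
        config = PSOConfig(n_dims=2, x_min=-5.0, x_max=5.0)
        point = np.array([[1.5, -0.5]])
        new_pos, new_vel = pso_step(
            point.copy(), np.zeros((1, 2)), point.copy(), point[0].copy(), 0.7, config, rng
        )
        assert np.array_equal(new_pos, point)
        assert np.array_equal(new_vel, np.zeros((1, 2)))

    def test_clamped_dimensions_zero_velocity(self):
        config = PSOConfig(n_dims=1, x_min=0.0, x_max=1.0, cg=0.0, cs=0.0, v_max=10.0)
        positions = np.array([[0.9]])
        velocities = np.array([[5.0]])
        new_pos, new_vel = pso_step(
            positions, velocities, positions.copy(), positions[0].copy(), 1.0, config, _HalfRng()
        )
        assert new_pos[0, 0] == 1.0
        assert new_vel[0, 0] == 0.0


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


class TestPsoOptimize:
    def test_sphere_minimum_found(self):
        config = PSOConfig(n_dims=4, x_min=-5.0, x_max=5.0, rng_seed=1)
        result = pso_optimize(sphere, config)
        assert result.gbest_value < 1e-4
        assert np.all(np.abs(result.gbest_position) < 5.0)

    def test_seed_determinism(self):
        config = PSOConfig(n_dims=4, x_min=-5.0, x_max=5.0, max_iter=60, rng_seed=7)
        a = pso_optimize(sphere, config)
        b = pso_optimize(sphere, config)
        assert np.array_equal(a.gbest_position, b.gbest_position)
        assert a.gbest_value == b.gbest_value
        assert np.array_equal(a.convergence_trace, b.convergence_trace)

    def test_trace_monotone_and_bounds_respected(self):
        config = PSOConfig(n_dims=4, x_min=-5.0, x_max=5.0, max_iter=80, rng_seed=3)
        result = pso_optimize(sphere, config)
        trace = result.convergence_trace
        assert np.all(np.diff(trace) <= 0)
        assert trace[-1] == result.gbest_value
        assert np.all(result.pbest_positions >= -5.0)
        assert np.all(result.pbest_positions <= 5.0)
        assert result.evaluations == config.n_particles * (config.max_iter + 1)

    def test_objective_breakdown_accepted(self, reference_params):
        """The optimizer consumes ObjectiveBreakdown-returning objectives."""
        inp, tgt = synth_fit_pair(
            reference_params, WaveformSpec(peak_flow=1.0, n_cycles=1)
        )
        config = PSOConfig(n_particles=6, max_iter=5, rng_seed=0)
        result = pso_optimize(make_objective(inp, tgt), config)
        assert np.isfinite(result.gbest_value)
        assert result.gbest_position.shape == (4,)

    def test_config_validation(self):
        with pytest.raises(InvalidInputError):
            PSOConfig(n_particles=1)
        with pytest.raises(InvalidInputError):
            PSOConfig(omega0=0.1, omegaf=0.9)
        with pytest.raises(InvalidInputError):
            PSOConfig(x_min=2.0, x_max=1.0)
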