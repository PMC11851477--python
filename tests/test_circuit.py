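"""State-space assembly, transfer functions, impedance, and simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capfit import (
    CircuitParams,
    DivergenceError,
    InvalidInputError,
    SampledSignal,
    StateSpaceModel,
    assemble_state_space,
    impulse_response,
    input_impedance,
    simulate_response,
    step_response,
    to_transfer_function,
)
from capfit.pipeline import round_sig

params_floats = st.floats(min_value=1e-2, max_value=1e2, allow_nan=False)


def tf_by_determinant_expansion(ss: StateSpaceModel) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: G(s) = C adj(sI - A) B / det(sI - A) for 2x2 A."""
    a, b, c = ss.a, ss.b, ss.c
    den = np.array([1.0, -(a[0, 0] + a[1, 1]), a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]])
    # adj(sI - A) = [[s - a11, a01], [a10, s - a00]]
    num_s = c[0] * b[0] + c[1] * b[1]
    num_0 = (
        -a[1, 1] * c[0] * b[0]
        + a[0, 1] * c[0] * b[1]
        + a[1, 0] * c[1] * b[0]
        - a[0, 0] * c[1] * b[1]
    )
    return np.array([num_s, num_0]), den


class TestAssembly:
    def test_reference_state_matrix_entries(self, reference_params):
        ss = assemble_state_space(reference_params)
        assert round_sig(ss.a[0, 0], 5) == -3.2642
        assert round_sig(ss.a[1, 1], 5) == -5.7637
        assert ss.a[0, 1] == -1.0 / reference_params.c
        assert ss.a[1, 0] == 1.0 / reference_params.l

    def test_unit_parameters(self):
        ss = assemble_state_space(CircuitParams(1, 1, 1, 1))
        assert np.array_equal(ss.a, [[-1.0, -1.0], [1.0, -1.0]])
        assert np.array_equal(ss.b, [1.0, 0.0])
        assert np.array_equal(ss.c, [0.0, 1.0])
        assert ss.d == 0.0

    def test_first_state_output_convention(self):
        ss = assemble_state_space(CircuitParams(1, 1, 1, 1), output="first_state")
        assert np.array_equal(ss.c, [1.0, 0.0])

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1), (1, 0, 1, 1), (1, 1, np.inf, 1)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            CircuitParams(*bad)


class TestTransferFunction:
    def test_unit_parameters_closed_form(self):
        tf = to_transfer_function(assemble_state_space(CircuitParams(1, 1, 1, 1)))
        assert np.allclose(tf.num, [1.0])
        assert np.allclose(tf.den, [1.0, 2.0, 2.0])

    def test_reference_coefficients_at_four_figures(self, reference_tf):
        assert round_sig(reference_tf.num[-1], 4) == 89.38
        assert round_sig(reference_tf.den[1], 4) == 9.028
        assert round_sig(reference_tf.den[2], 4) == 108.2

    @given(r1=params_floats, r2=params_floats, l=params_floats, c=params_floats)
    def test_matches_determinant_expansion_oracle(self, r1, r2, l, c):
        ss = assemble_state_space(CircuitParams(r1, r2, l, c))
        tf = to_transfer_function(ss)
        num_ref, den_ref = tf_by_determinant_expansion(ss)
        num_full = np.zeros(2)
        num_full[-tf.num.size :] = tf.num
        assert np.allclose(num_full, num_ref, rtol=1e-10, atol=1e-9 * np.max(np.abs(num_ref)))
        assert np.allclose(tf.den, den_ref, rtol=1e-10)

    @given(r1=params_floats, r2=params_floats, l=params_floats, c=params_floats)
    def test_closed_form_coefficients(self, r1, r2, l, c):
        """num = 1/(LC); a1 = R1/L + 1/(R2 C); a0 = (1 + R1/R2)/(LC)."""
        tf = to_transfer_function(assemble_state_space(CircuitParams(r1, r2, l, c)))
        assert tf.num[-1] == pytest.approx(1.0 / (l * c), rel=1e-10)
        assert tf.den[1] == pytest.approx(r1 / l + 1.0 / (r2 * c), rel=1e-10)
        assert tf.den[2] == pytest.approx((1.0 + r1 / r2) / (l * c), rel=1e-10)

    def test_dc_gain_ratio(self, reference_tf, reference_params):
        expected = 1.0 / (1.0 + reference_params.r1 / reference_params.r2)
        assert reference_tf.dc_gain() == pytest.approx(expected, rel=1e-12)


class TestImpedance:
    def test_dc_is_sum_of_resistances(self, reference_params):
        z = input_impedance(reference_params, 0.0)
        assert z == pytest.approx(516.334)
        assert z.imag == 0.0

    def test_inductor_dominates_at_high_frequency(self, reference_params):
        z6 = abs(input_impedance(reference_params, 1e6))
        z7 = abs(input_impedance(reference_params, 1e7))
        assert z7 / z6 == pytest.approx(10.0, rel=1e-3)

    def test_negative_frequency_rejected(self, reference_params):
        with pytest.raises(InvalidInputError):
            input_impedance(reference_params, -1.0)


def _grid(duration: float, n: int) -> np.ndarray:
    return np.linspace(0.0, duration, n)


class TestSimulation:
    def test_zero_input_zero_state_is_identically_zero(self, reference_params):
        ss = assemble_state_space(reference_params)
        t = _grid(2.0, 500)
        sig = SampledSignal(times=t, values=np.zeros_like(t))
        out = simulate_response(ss, sig)
        assert np.all(out.values == 0.0)

    def test_step_settles_to_dc_gain(self, reference_params, reference_tf):
        """Final-value theorem: unit step settles to 89.38/108.2 ~ 0.826."""
        ss = assemble_state_space(reference_params)
        t = _grid(4.0, 2000)
        out = simulate_response(ss, SampledSignal(times=t, values=np.ones_like(t)))
        assert out.values[-1] == pytest.approx(reference_tf.dc_gain(), abs=1e-4)
        assert round_sig(out.values[-1], 3) == 0.826

    def test_sinusoid_steady_amplitude_matches_frequency_response(self, reference_params):
        ss = assemble_state_space(reference_params)
        tf = to_transfer_function(ss)
        omega, amp = 5.0, 2.0
        t = _grid(12.0, 6000)
        out = simulate_response(ss, SampledSignal(times=t, values=amp * np.sin(omega * t)))
        steady = out.values[t > 10.0]
        assert np.max(np.abs(steady)) == pytest.approx(abs(tf(1j * omega)) * amp, rel=0.01)

    def test_exact_agrees_with_adaptive_integration(self, rng):
        """Dual-route check on random stable systems with a smooth input."""
        t = _grid(3.0, 1500)
        u = SampledSignal(times=t, values=np.sin(4.0 * t) + 0.3 * np.cos(9.0 * t))
        for _ in range(5):
            params = CircuitParams(*rng.uniform(0.2, 5.0, size=4))
            ss = assemble_state_space(params)
            y_exact = simulate_response(ss, u, method="exact")
            y_adapt = simulate_response(ss, u, method="adaptive")
            scale = np.max(np.abs(y_adapt.values))
            assert np.max(np.abs(y_exact.values - y_adapt.values)) < 1e-6 * max(scale, 1e-12)

    def test_divergence_reported_with_blow_up_time(self):
        unstable = StateSpaceModel(a=np.array([[50.0, 0.0], [0.0, 50.0]]), b=[1, 0], c=[0, 1])
        t = _grid(40.0, 4000)
        with pytest.raises(DivergenceError) as err:
            simulate_response(unstable, SampledSignal(times=t, values=np.ones_like(t)))
        assert 0.0 < err.value.blow_up_time <= 40.0


class TestCanonicalResponses:
    def test_underdamped_step_overshoots(self, reference_params, reference_tf):
        out = step_response(assemble_state_space(reference_params))
        assert np.max(out.values) > reference_tf.dc_gain() * 1.05
        assert out.values[-1] == pytest.approx(reference_tf.dc_gain(), rel=1e-3)

    def test_critically_damped_step_has_no_overshoot(self):
        # G(s) = 1/(s^2 + 2s + 1) in controllable canonical form
        ss = StateSpaceModel(a=np.array([[-2.0, -1.0], [1.0, 0.0]]), b=[1, 0], c=[0, 1])
        out = step_response(ss)
        assert np.max(out.values) <= 1.0 + 1e-9

    def test_impulse_area_equals_dc_gain(self, reference_params, reference_tf):
        out = impulse_response(assemble_state_space(reference_params))
        area = np.trapezoid(out.values, out.times)
        assert area == pytest.approx(reference_tf.dc_gain(), rel=5e-3)
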