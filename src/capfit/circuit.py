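"""Two-state lumped-parameter capillary circuit model.

The capillary is modelled as an electrical analogue: a series resistance
R1 (proximal viscous loss) and inertance L (blood inertia) feeding a
parallel R2-C pair (distal resistance and vessel compliance), driven by
an effort source.  With states x1 = inductor momentum p and
x2 = capacitor charge q the bond-graph derivation gives

    x1' = -(R1/L) x1 - (1/C) x2 + u
    x2' =  (1/L) x1 - 1/(R2 C) x2

The model output is the capacitor effort q/C (the distal pressure
analogue), which yields the transfer function

    G(s) = (1/(LC)) / (s^2 + (R1/L + 1/(R2 C)) s + (1 + R1/R2)/(LC)).

An alternative literal convention with Cout = [1, 0] (output = first
state) is available via ``output="first_state"`` but does not correspond
to a measurable pressure and is not the default.

The model layer is deliberately unit-agnostic: the identified R1, R2, L,
C live in consistent abstract units, not reconciled with the physical
Poiseuille resistances of :mod:`capfit.hemodynamics`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .exceptions import DivergenceError, InvalidInputError
from .waveforms import SampledSignal


@dataclass(frozen=True)
class CircuitParams:
    """The four identifiable circuit constants (all strictly positive)."""

    r1: float
    r2: float
    l: float
    c: float

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "l", "c"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidInputError(f"CircuitParams.{name} must be positive and finite, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.l, self.c], dtype=float)

    @classmethod
    def from_array(cls, position: np.ndarray) -> "CircuitParams":
        """Build from an optimizer position vector ordered (R1, R2, L, C)."""
        r1, r2, l, c = (float(v) for v in np.asarray(position, dtype=float))
        return cls(r1=r1, r2=r2, l=l, c=c)


@dataclass(frozen=True)
class StateSpaceModel:
    """Linear time-invariant realization x' = Ax + Bu, y = Cx + Du."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: float = 0.0

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.a, dtype=float))
        b = np.asarray(self.b, dtype=float).reshape(-1)
        c = np.asarray(self.c, dtype=float).reshape(-1)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        n = a.shape[0]
        if a.shape != (n, n) or b.shape != (n,) or c.shape != (n,):
            raise InvalidInputError("inconsistent state-space dimensions")

    @property
    def order(self) -> int:
        return self.a.shape[0]

    def is_stable(self) -> bool:
        """True iff every eigenvalue of A has a negative real part."""
        if self.order == 2:
            # Hurwitz conditions for 2x2: tr(A) < 0 and det(A) > 0.
            tr = self.a[0, 0] + self.a[1, 1]
            det = self.a[0, 0] * self.a[1, 1] - self.a[0, 1] * self.a[1, 0]
            return tr < 0.0 and det > 0.0
        return bool(np.all(np.linalg.eigvals(self.a).real < 0))


@dataclass(frozen=True)
class TransferFunction:
    """Rational transfer function with a monic denominator.

    ``num`` and ``den`` hold coefficients in descending powers of s;
    ``den[0]`` is 1 and ``len(num) < len(den)`` for the strictly proper
    circuit models built here (D = 0).
    """

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self) -> None:
        num = np.trim_zeros(np.asarray(self.num, dtype=float).reshape(-1), "f")
        den = np.asarray(self.den, dtype=float).reshape(-1)
        if den.size < 2:
            raise InvalidInputError("denominator must have degree >= 1")
        if den[0] == 0:
            raise InvalidInputError("denominator leading coefficient must be nonzero")
        if not np.isclose(den[0], 1.0):
            num = num / den[0]
            den = den / den[0]
        if num.size == 0:
            num = np.array([0.0])
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    def dc_gain(self) -> float:
        """G(0) = constant-numerator over constant-denominator ratio."""
        return float(self.num[-1] / self.den[-1])

    def __call__(self, s: complex) -> complex:
        return complex(np.polyval(self.num, s) / np.polyval(self.den, s))


def assemble_state_space(
    params: CircuitParams,
    output: Literal["capacitor_effort", "first_state"] = "capacitor_effort",
) -> StateSpaceModel:
    """Realize the capillary circuit as a 2-state model.

    With x = [inductor momentum, capacitor charge] and the effort source
    as input:  A = [[-R1/L, -1/C], [1/L, -1/(R2*C)]], B = [1, 0].
    ``output="capacitor_effort"`` (default) measures q/C, i.e.
    Cout = [0, 1/C]; ``"first_state"`` measures x1 directly (Cout = [1, 0]).
    """
    r1, r2, l, c = params.r1, params.r2, params.l, params.c
    a = np.array([[-r1 / l, -1.0 / c], [1.0 / l, -1.0 / (r2 * c)]])
    b = np.array([1.0, 0.0])
    if output == "capacitor_effort":
        cout = np.array([0.0, 1.0 / c])
    elif output == "first_state":
        cout = np.array([1.0, 0.0])
    else:
        raise InvalidInputError(f"unknown output convention {output!r}")
    return StateSpaceModel(a=a, b=b, c=cout, d=0.0)


def to_transfer_function(ss: StateSpaceModel) -> TransferFunction:
    """G(s) = Cout (sI - A)^-1 B + D with the denominator made monic."""
    num, den = sps.ss2tf(ss.a, ss.b.reshape(-1, 1), ss.c.reshape(1, -1), np.array([[ss.d]]))
    coeffs = num[0]
    # drop leading roundoff residue so strictly proper models stay strictly proper
    scale = np.max(np.abs(coeffs))
    if scale > 0:
        keep = np.abs(coeffs) > 1e-10 * scale
        coeffs = coeffs[np.argmax(keep) :] if np.any(keep) else coeffs[-1:]
    return TransferFunction(num=coeffs, den=den)


def input_impedance(params: CircuitParams, omega: float) -> complex:
    """Driving-point impedance R1 + j*w*L + R2/(1 + j*R2*w*C) at w rad/s."""
    if omega < 0:
        raise InvalidInputError("omega must be nonnegative")
    return (
        params.r1
        + 1j * omega * params.l
        + params.r2 / (1.0 + 1j * params.r2 * omega * params.c)
    )


def _check_finite(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(values)
    if np.any(bad):
        t_blow = float(times[np.argmax(bad)])
        raise DivergenceError(f"simulated trajectory became non-finite at t = {t_blow:g}", t_blow)
    return values


def simulate_response(
    ss: StateSpaceModel,
    input_signal: SampledSignal,
    x0: np.ndarray | None = None,
    method: Literal["exact", "adaptive"] = "exact",
) -> SampledSignal:
    """Simulate y(t) for a sampled input on the input's own grid.

    ``method="exact"`` (default) treats the input as piecewise linear
    between samples and propagates the state with the matrix-exponential
    first-order-hold discretization, which is exact for that input class
    and fast enough for use inside the optimizer loop.
    ``method="adaptive"`` integrates the same interpolated input with an
    adaptive explicit Runge-Kutta pair (rtol 1e-8, atol 1e-12); the two
    routes agree to solver tolerance and are cross-checked in the test
    suite.
    """
    t = input_signal.times
    u = input_signal.values
    dt = input_signal.dt
    n = ss.order
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).reshape(n)

    if method == "exact":
        with np.errstate(over="ignore", invalid="ignore"):
            y = _simulate_foh(ss, u, dt, x0)
        return SampledSignal(times=t.copy(), values=_check_finite(t, y))

    if method == "adaptive":
        from scipy.integrate import solve_ivp

        def rhs(tk: float, x: np.ndarray) -> np.ndarray:
            return ss.a @ x + ss.b * np.interp(tk, t, u)

        sol = solve_ivp(
            rhs, (t[0], t[-1]), x0, t_eval=t, rtol=1e-8, atol=1e-12, max_step=dt
        )
        if not sol.success:
            raise DivergenceError(f"adaptive integration failed: {sol.message}", float(sol.t[-1]))
        y = ss.c @ sol.y + ss.d * u
        return SampledSignal(times=t.copy(), values=_check_finite(t, y))

    raise InvalidInputError(f"unknown simulation method {method!r}")


def _foh_matrices(a: np.ndarray, b: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact first-order-hold propagation matrices via the Van Loan block trick.

    For a piecewise-linear input through the samples,
    x[k+1] = Ad x[k] + b1 u[k] + b2 u[k+1] with
    Ad = e^(A dt), b1 = (S1 - F13/dt) B, b2 = (F13/dt) B, where
    S1 = int_0^dt e^(As) ds and F13 = int_0^dt e^(As)(dt - s) ds come
    from one matrix exponential of the augmented block matrix.
    """
    from scipy.linalg import expm

    n = a.shape[0]
    m = np.zeros((3 * n, 3 * n))
    m[:n, :n] = a
    m[:n, n : 2 * n] = np.eye(n)
    m[n : 2 * n, 2 * n :] = np.eye(n)
    em = expm(m * dt)
    ad = em[:n, :n]
    s1 = em[:n, n : 2 * n]
    f13 = em[:n, 2 * n :]
    b2 = (f13 / dt) @ b
    b1 = s1 @ b - b2
    return ad, b1, b2


def _simulate_foh(ss: StateSpaceModel, u: np.ndarray, dt: float, x0: np.ndarray) -> np.ndarray:
    """Exact response to the piecewise-linear interpolant of the samples.

    The linear recursion is solved mode-by-mode with a one-pole digital
    filter after diagonalizing Ad, which keeps the whole simulation in
    vectorized compiled code; a defective (non-diagonalizable) Ad falls
    back to an explicit loop.
    """
    ad, b1, b2 = _foh_matrices(ss.a, ss.b, dt)
    w = b1[:, None] * u[:-1][None, :] + b2[:, None] * u[1:][None, :]

    lam, v = np.linalg.eig(ad)
    use_modal = np.linalg.cond(v) < 1e8
    n = ss.order
    nk = u.size
    if use_modal:
        vinv = np.linalg.inv(v)
        z0 = vinv @ x0.astype(complex)
        wz = vinv @ w
        x_modal = np.empty((n, nk), dtype=complex)
        x_modal[:, 0] = z0
        k = np.arange(1, nk)
        for i in range(n):
            conv = sps.lfilter([1.0], [1.0, -lam[i]], wz[i])
            x_modal[i, 1:] = lam[i] ** k * z0[i] + conv
        x = (v @ x_modal).real
    else:
        x = np.empty((n, nk))
        x[:, 0] = x0
        xk = x0.astype(float).copy()
        for j in range(nk - 1):
            xk = ad @ xk + w[:, j]
            x[:, j + 1] = xk
    return ss.c @ x + ss.d * u


def _response_horizon(ss: StateSpaceModel, n_time_constants: float = 8.0) -> float:
    """Horizon covering ``n_time_constants`` of the slowest stable mode."""
    eigs = np.linalg.eigvals(ss.a)
    rates = -eigs.real
    if np.any(rates <= 0):
        raise InvalidInputError("response horizon undefined for an unstable model")
    return float(n_time_constants / rates.min())


def step_response(
    ss: StateSpaceModel, horizon: float | None = None, n_points: int = 2000
) -> SampledSignal:
    """Unit step response over >= 8 time constants (settles to the DC gain)."""
    horizon = _response_horizon(ss) if horizon is None else horizon
    t = np.linspace(0.0, horizon, n_points)
    t_out, y = sps.step((ss.a, ss.b.reshape(-1, 1), ss.c.reshape(1, -1), ss.d), T=t)
    return SampledSignal(times=t_out, values=_check_finite(t_out, y))


def impulse_response(
    ss: StateSpaceModel, horizon: float | None = None, n_points: int = 2000
) -> SampledSignal:
    """Unit impulse response (its time integral equals the DC gain)."""
    horizon = _response_horizon(ss) if horizon is None else horizon
    t = np.linspace(0.0, horizon, n_points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_out, y = sps.impulse((ss.a, ss.b.reshape(-1, 1), ss.c.reshape(1, -1), ss.d), T=t)
    return SampledSignal(times=t_out, values=_check_finite(t_out, y))
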