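"""Routh-Hurwitz tabulation, pole extraction, and second-order characteristics.

Stability of the identified circuit is assessed two ways and
cross-checked: the classical Routh array built from the characteristic
polynomial (no root extraction), and the pole locations themselves.  For
the monic quadratic s^2 + a1 s + a0 the standard second-order quantities
are reported: natural frequency wn = sqrt(a0), damping ratio
zeta = a1/(2 wn), with zeta < 1 giving an underdamped (oscillatory)
transient and a complex-conjugate pole pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import TransferFunction
from .exceptions import InvalidInputError

#: Relative tolerance for calling zeta exactly 1 (critical damping).
_CRITICAL_RTOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    """Joint verdict of the Routh criterion and pole analysis."""

    poles: tuple[complex, ...]
    stable: bool
    routh_first_column: tuple[float, ...]
    sign_changes: int
    damping_ratio: float | None
    natural_frequency: float | None
    classification: str | None


def routh_hurwitz(den_coeffs) -> tuple[list[float], int, bool]:
    """Build the Routh array and count first-column sign changes.

    Parameters
    ----------
    den_coeffs : sequence of float
        Characteristic polynomial coefficients in descending powers;
        the leading coefficient must be nonzero.

    Returns
    -------
    (first_column, sign_changes, stable)
        ``sign_changes`` equals the number of open-right-half-plane
        roots (for polynomials without imaginary-axis roots); the system
        is declared stable iff it is zero.

    Notes
    -----
    A zero first-column pivot with a nonzero remainder of the row is
    replaced by a small epsilon of the same working scale; an all-zero
    row (symmetric root pattern) is replaced by the derivative of its
    auxiliary polynomial, per the standard procedure.
    """
    coeffs = np.asarray(den_coeffs, dtype=float).reshape(-1)
    coeffs = np.trim_zeros(coeffs, "f")
    degree = coeffs.size - 1
    if degree < 1:
        raise InvalidInputError("polynomial degree must be at least 1")
    eps = 1e-9 * np.max(np.abs(coeffs))

    width = (degree + 2) // 2
    table = np.zeros((degree + 1, width + 1))
    table[0, : (degree + 2) // 2] = coeffs[0::2]
    table[1, : (degree + 1) // 2] = coeffs[1::2]
    if degree == 1:
        table[1, 0] = coeffs[1]

    for i in range(2, degree + 1):
        if np.all(table[i - 1] == 0.0):
            # Auxiliary polynomial from the row above (even powers).
            aux_degree = degree - (i - 2)
            aux = table[i - 2, : width]
            deriv = np.array(
                [aux[j] * (aux_degree - 2 * j) for j in range((aux_degree // 2) + 1)],
                dtype=float,
            )
            table[i - 1, : deriv.size] = deriv
        pivot = table[i - 1, 0]
        if pivot == 0.0:
            pivot = eps
            table[i - 1, 0] = eps
        for j in range(width):
            table[i, j] = (
                pivot * table[i - 2, j + 1] - table[i - 2, 0] * table[i - 1, j + 1]
            ) / pivot

    first_column = [float(table[i, 0]) for i in range(degree + 1)]
    signs = np.sign([v if v != 0.0 else eps for v in first_column])
    sign_changes = int(np.sum(signs[:-1] != signs[1:]))
    return first_column, sign_changes, sign_changes == 0


def poles(tf: TransferFunction) -> list[complex]:
    """Denominator roots, sorted by real part then imaginary part."""
    roots = np.roots(tf.den)
    return sorted((complex(r) for r in roots), key=lambda z: (z.real, z.imag))


def second_order_characteristics(tf: TransferFunction) -> tuple[float, float, str]:
    """(zeta, wn, classification) for a monic quadratic denominator.

    Requires den = [1, a1, a0] with a0 > 0.  Classification is
    ``underdamped`` (zeta < 1), ``critically_damped`` (zeta = 1 within
    rounding) or ``overdamped`` (zeta > 1).
    """
    den = tf.den
    if den.size != 3:
        raise InvalidInputError("second-order characteristics require a quadratic denominator")
    a1, a0 = float(den[1]), float(den[2])
    if a0 <= 0:
        raise InvalidInputError("constant denominator coefficient must be positive")
    wn = float(np.sqrt(a0))
    zeta = a1 / (2.0 * wn)
    if abs(zeta - 1.0) <= _CRITICAL_RTOL:
        classification = "critically_damped"
    elif zeta < 1.0:
        classification = "underdamped"
    else:
        classification = "overdamped"
    return zeta, wn, classification


def stability_report(tf: TransferFunction) -> StabilityReport:
    """Full report: Routh verdict, poles, and (if quadratic) damping data.

    The Routh verdict and the pole-location verdict are computed
    independently and must agree; a mismatch raises, as it would signal
    a numerical defect rather than a property of the model.
    """
    first_column, sign_changes, routh_stable = routh_hurwitz(tf.den)
    pole_list = poles(tf)
    pole_stable = all(p.real < 0 for p in pole_list)
    if routh_stable != pole_stable:
        raise ArithmeticError(
            "Routh and pole-location verdicts disagree "
            f"(routh={routh_stable}, poles={pole_stable}); polynomial likely ill-conditioned"
        )
    zeta = wn = classification = None
    if tf.den.size == 3 and tf.den[2] > 0:
        zeta, wn, classification = second_order_characteristics(tf)
    return StabilityReport(
        poles=tuple(pole_list),
        stable=routh_stable,
        routh_first_column=tuple(first_column),
        sign_changes=sign_changes,
        damping_ratio=zeta,
        natural_frequency=wn,
        classification=classification,
    )
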