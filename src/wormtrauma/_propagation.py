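"""Quadrature error propagation primitives shared across modules.

Uncertainties on independent quantities combine as the square root of the
sum of squared first-order contributions (the standard "general formula"
delta_R = sqrt(sum_i (dR/dX_i * delta_X_i)^2)).
"""

from __future__ import annotations

import math

from .errors import DataError


def quotient_with_error(
    num: float, num_err: float, den: float, den_err: float
) -> tuple[float, float]:
    """Ratio ``num / den`` with its propagated uncertainty.

    Applies the quadrature rule to a quotient:
    ``delta = |R| * sqrt((num_err/num)^2 + (den_err/den)^2)``.

    Raises
    ------
    DataError
        If the denominator is not strictly positive (a fluorescence mean
        of zero or below cannot normalize anything).
    """
    if den <= 0:
        raise DataError(f"denominator mean must be > 0, got {den!r}")
    if num <= 0:
        raise DataError(f"numerator mean must be > 0, got {num!r}")
    value = num / den
    delta = value * math.sqrt((num_err / num) ** 2 + (den_err / den) ** 2)
    return value, delta


def quadrature(*errors: float) -> float:
    """Combine independent uncertainties in quadrature."""
    return math.sqrt(sum(e * e for e in errors))
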