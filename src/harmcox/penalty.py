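"""Harmonic penalty: a concave bridge between the L1 and L1/2 penalties.

The penalty family is indexed by a shrinkage parameter ``a`` in the open
interval (1, 2).  Writing ``c = (2 - a)/(a - 1)``, each coordinate
contributes

    P(b) = sqrt( (2 / (a (a - 1))) * b + c**2 ) - c,        b = |beta_j| >= 0.

As ``a -> 1`` the curve straightens into the absolute value (lasso penalty);
as ``a -> 2`` it bends into ``sqrt(b)`` (the L1/2 penalty).  Unlike a true
Lq penalty with q < 1, the slope at the origin is finite —
``P'(0) = 1 / (a (2 - a))`` — which is what makes direct path seeking
applicable: the gradient-to-penalty-slope ratio stays bounded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HarmonicPenalty", "penalty_value", "penalty_derivative"]


def _check_a(a: float) -> float:
    a = float(a)
    if not (1.0 < a < 2.0):
        raise ValueError(f"shrinkage parameter a must lie strictly in (1, 2), got {a}")
    return a


def penalty_value(b, a: float):
    """Harmonic penalty P(b) for coefficient magnitude(s) ``b >= 0``.

    Parameters
    ----------
    b : float or array-like
        Coefficient magnitude(s); must be nonnegative.
    a : float
        Shrinkage parameter in (1, 2).

    Returns
    -------
    float or ndarray
        Penalty value(s); 0 at b = 0, strictly increasing and concave in b.
    """
    a = _check_a(a)
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("coefficient magnitude b must be nonnegative")
    c = (2.0 - a) / (a - 1.0)
    x = (2.0 / (a * (a - 1.0))) * b
    # sqrt(x + c^2) - c == x / (sqrt(x + c^2) + c): the ratio form avoids
    # catastrophic cancellation when c is large (a near 1).
    out = x / (np.sqrt(x + c * c) + c)
    return out if out.ndim else float(out)


def penalty_derivative(b, a: float):
    """dP/db of the harmonic penalty; finite and strictly positive for b >= 0.

    Equals ``1 / (a (2 - a))`` at the origin and decays like ``b**-1/2``
    for large b (concavity), so large coefficients are penalized at a
    vanishing marginal rate while the origin still exerts lasso-like pull.
    """
    a = _check_a(a)
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("coefficient magnitude b must be nonnegative")
    c = (2.0 - a) / (a - 1.0)
    k = 2.0 / (a * (a - 1.0))
    out = (k / 2.0) / np.sqrt(k * b + c * c)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HarmonicPenalty:
    """The harmonic penalty family member with shrinkage parameter ``a``."""

    a: float

    def __post_init__(self):
        _check_a(self.a)

    def value(self, b):
        return penalty_value(b, self.a)

    def derivative(self, b):
        return penalty_derivative(b, self.a)
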