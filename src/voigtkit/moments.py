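"""Variance of the Voigt profile.

The full profile has no finite variance for any ``xi > 0``: the second
moment reduces to ``(1/2)(1 - coth(2 pi xi))(1 - 2 xi**2)
+ (xi/pi) * sum_{n>=0} (n**2 + 2)/(n**2 + 4 xi**2)`` whose series diverges
(terms tend to 1), a direct reflection of the Lorentzian ``1/v**2`` tail.
Finite closed forms exist only for the Gaussian-dominance approximations;
both reduce to the Gaussian value 1/2 as ``xi -> 0``.  Variances are in
reduced units (v); multiply by ``gauss_width**2`` for physical units
(:func:`variance_physical`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import special
from scipy.integrate import quad

from .core import QuadratureError, voigt_series

__all__ = [
    "VarianceResult",
    "variance_full",
    "variance_gauss_a",
    "variance_gauss_b",
    "variance_numeric_truncated",
    "variance_physical",
]

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class VarianceResult:
    """Variance value with finiteness flag and provenance tag.

    ``value`` is ``math.inf`` exactly when ``finite`` is False — divergence
    is a mathematical statement here, never a floating overflow.
    """

    value: float
    finite: bool
    method: str
    vmax: float | None = None

    def __post_init__(self) -> None:
        if self.finite != (self.value != math.inf):
            raise ValueError("finite flag inconsistent with value")
        if self.method == "numeric_truncated" and not (self.vmax and self.vmax > 0):
            raise ValueError("numeric_truncated requires vmax > 0")


def variance_full(xi: float) -> VarianceResult:
    """Variance of the full profile: 1/2 at xi = 0, divergent for xi > 0."""
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if xi == 0:
        return VarianceResult(0.5, True, "full")
    return VarianceResult(math.inf, False, "full")


def variance_gauss_a(xi: float) -> VarianceResult:
    """Closed-form variance of the general Gaussian-dominance approximation.

    ``(1/2)(1-2 xi**2) erfc(xi)
    + (1-exp(-xi**2))/(sqrt(pi) xi) * (0.6259 + 0.0814 xi**2)
    + exp(-xi**2)/pi * (1.5486 xi + 0.2605 xi**3 - 0.3136 xi**5
    + 0.0434 xi**7)``

    Continuous at xi = 0 (the middle factor ``(1-e^{-xi^2})/xi -> xi``);
    evaluated cancellation-free via ``expm1``.  Accurate only where the
    underlying near-maximum approximation is; rises again for xi > 3 as the
    profile turns Lorentzian.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if xi == 0:
        return VarianceResult(0.5, True, "eq11a")
    x2 = xi * xi
    val = (
        0.5 * (1.0 - 2.0 * x2) * special.erfc(xi)
        + (-math.expm1(-x2)) / (_SQRT_PI * xi) * (0.6259 + 0.0814 * x2)
        + math.exp(-x2) / math.pi
        * (1.5486 * xi + 0.2605 * xi * x2 - 0.3136 * xi * x2 * x2
           + 0.0434 * xi * x2 * x2 * x2)
    )
    return VarianceResult(val, True, "eq11a")


def variance_gauss_b(xi: float) -> VarianceResult:
    """Closed-form variance of the small-xi two-cosine approximation.

    ``(1/2)(1-2 xi**2) erfc(xi)
    + [1 - (1-2 xi**2) exp(-xi**2)] / (2 sqrt(pi) xi)``

    Meaningful only for ``xi << 1``; its large-xi decrease is an artifact
    of using the small-xi form outside its regime.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if xi == 0:
        return VarianceResult(0.5, True, "eq11b")
    x2 = xi * xi
    # 1 - (1-2x2) e^{-x2} = -expm1(-x2) + 2 x2 e^{-x2}, stable near 0
    num = -math.expm1(-x2) + 2.0 * x2 * math.exp(-x2)
    val = 0.5 * (1.0 - 2.0 * x2) * special.erfc(xi) + num / (2.0 * _SQRT_PI * xi)
    return VarianceResult(val, True, "eq11b")


def variance_numeric_truncated(xi: float, vmax: float) -> VarianceResult:
    """Second moment of the exact profile truncated to ``[-vmax, vmax]``.

    Monotone non-decreasing in ``vmax``; for xi > 0 it grows without bound,
    asymptotically like ``(2 xi / pi) * vmax`` from the Lorentzian tail.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if not vmax > 0:
        raise ValueError("vmax must be > 0")
    val, err = quad(lambda v: v * v * voigt_series(v, xi), 0.0, vmax,
                    epsabs=1e-12, epsrel=1e-10, limit=400)
    if err > max(1e-9, 1e-8 * abs(val)):
        raise QuadratureError(
            f"truncated-variance quadrature error {err:.2e} at xi={xi}, vmax={vmax}"
        )
    return VarianceResult(2.0 * val, True, "numeric_truncated", vmax=vmax)


def variance_physical(result: VarianceResult, gauss_width: float) -> float:
    """Convert a reduced-units variance to physical units (× width**2)."""
    if not gauss_width > 0:
        raise ValueError("gauss_width must be > 0")
    return result.value * gauss_width * gauss_width
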