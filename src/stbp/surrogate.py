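"""Surrogate derivatives for the spike nonlinearity.

The true derivative of the threshold activation g(u) = 1{u >= v_th} is a
Dirac impulse at the threshold, which carries no usable gradient.  Training
replaces dg/du with one of four unit-mass bump functions centred on v_th:

* ``rectangular``  h(u) = (1/a) * 1{|u - v_th| < a/2}
* ``polynomial``   h(u) = max(0, 1/(2a) - |u - v_th|/(4a^2))   (triangle,
                   peak 1/(2a), support |u - v_th| <= 2a)
* ``sigmoid``      h(u) = logistic'((u - v_th)/a) / a
* ``gaussian``     h(u) = N(u; v_th, a)                     (variance a)

``a`` controls the steepness (peak width): for every family, smaller a
means a narrower, taller bump.  Each family integrates to one for every
a > 0 and converges weakly to the Dirac impulse as a -> 0+, so all four
are consistent smoothings of the same ill-posed derivative.  (The triangle
is conventionally written with half-width 2/a; that convention inverts the
steepness direction relative to the other three families, so here its
half-width is 2a — the two forms coincide at the default a = 1 — and the
negative lobes outside the support are clipped to zero, as a derivative
approximation of a monotone step must be nonnegative.)

Each family also has a closed-form antiderivative (clipped ramp, piecewise
quadratic, logistic, normal CDF).  Substituting that antiderivative for the
hard threshold gives a fully differentiable "relaxed" network whose exact
gradient is the surrogate backward pass — the basis of the finite-difference
gradient oracle in :mod:`stbp.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import expit, ndtr

__all__ = [
    "FAMILIES",
    "SurrogateSpec",
    "surrogate_eval",
    "surrogate_integral",
    "dirac_limit_check",
    "smooth_activation",
]

FAMILIES = ("rectangular", "polynomial", "sigmoid", "gaussian")


@dataclass(frozen=True)
class SurrogateSpec:
    """Which bump family approximates dg/du, how steep, and where centred."""

    family: str = "rectangular"
    a: float = 1.0
    v_th: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown surrogate family {self.family!r}; choose from {FAMILIES}"
            )
        if self.a <= 0:
            raise ValueError(f"steepness a must be positive, got {self.a}")


def surrogate_eval(u: np.ndarray | float, spec: SurrogateSpec) -> np.ndarray:
    """Evaluate the surrogate density h(u).

    Symmetric about v_th with its maximum there.  The rectangular window
    includes its left edge and excludes its right edge so that exactly one
    convention holds at the (measure-zero) boundary.
    """
    d = np.asarray(u, dtype=float) - spec.v_th
    a = spec.a
    if spec.family == "rectangular":
        return np.where((d >= -a / 2) & (d < a / 2), 1.0 / a, 0.0)
    if spec.family == "polynomial":
        return np.maximum(0.0, 1 / (2 * a) - np.abs(d) / (4 * a * a))
    if spec.family == "sigmoid":
        s = expit(d / a)
        return s * (1.0 - s) / a
    # gaussian, variance a
    return np.exp(-d * d / (2 * a)) / np.sqrt(2 * np.pi * a)


def _support_halfwidth(spec: SurrogateSpec) -> float:
    """Half-width beyond which h is identically zero or below 1e-12."""
    a = spec.a
    if spec.family == "rectangular":
        return a / 2 + 1e-9
    if spec.family == "polynomial":
        return 2.0 * a + 1e-9
    if spec.family == "sigmoid":
        # h ~ exp(-|d|/a)/a; solve exp(-d/a)/a = 1e-12
        return a * (np.log(1e12) + abs(np.log(a))) + 1.0
    return np.sqrt(a) * np.sqrt(2 * np.log(1e12)) + 1.0


def surrogate_integral(spec: SurrogateSpec) -> float:
    """Numerically integrate h over its effective support.

    Adaptive quadrature (tolerance 1e-9) truncated where h < 1e-12; the
    deviation of the returned value from 1 measures the family's
    normalization error.
    """
    R = _support_halfwidth(spec)
    val, _ = integrate.quad(
        lambda x: float(surrogate_eval(x, spec)),
        spec.v_th - R,
        spec.v_th + R,
        points=[spec.v_th],
        limit=400,
        epsabs=1e-9,
        epsrel=1e-9,
    )
    return val


def dirac_limit_check(family: str, test_fn, a_sequence, v_th: float = 1.5) -> np.ndarray:
    """Smooth a test function against h_a for each a in ``a_sequence``.

    Returns the sequence of integrals  ∫ h_a(u) φ(u) du.  For a smooth,
    bounded φ these converge to φ(v_th) as a -> 0+, which is the weak-limit
    (Dirac) consistency of the surrogate construction.
    """
    out = []
    for a in a_sequence:
        spec = SurrogateSpec(family=family, a=float(a), v_th=v_th)
        R = _support_halfwidth(spec)
        val, _ = integrate.quad(
            lambda x: float(surrogate_eval(x, spec)) * test_fn(x),
            v_th - R,
            v_th + R,
            points=[v_th],
            limit=400,
            epsabs=1e-10,
            epsrel=1e-10,
        )
        out.append(val)
    return np.asarray(out)


def smooth_activation(u: np.ndarray | float, spec: SurrogateSpec) -> np.ndarray:
    """Antiderivative of h: the differentiable relaxation of the spike gate.

    Monotone from 0 to 1 with value 1/2 at the threshold; its derivative is
    exactly :func:`surrogate_eval`.
    """
    d = np.asarray(u, dtype=float) - spec.v_th
    a = spec.a
    if spec.family == "rectangular":
        return np.clip(d / a + 0.5, 0.0, 1.0)
    if spec.family == "polynomial":
        dc = np.clip(d, -2.0 * a, 2.0 * a)
        return np.where(
            dc <= 0,
            0.5 + dc / (2 * a) + dc * dc / (8 * a * a),
            0.5 + dc / (2 * a) - dc * dc / (8 * a * a),
        )
    if spec.family == "sigmoid":
        return expit(d / a)
    return ndtr(d / np.sqrt(a))
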