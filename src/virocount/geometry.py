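"""Virion surface-area and motor-density arithmetic.

Virions are modelled as tri-axial ellipsoids given by their full axis
lengths (nm). Surface area uses the Thomsen approximation

    S ≈ 4π · ((aᵖbᵖ + aᵖcᵖ + bᵖcᵖ) / 3)^(1/p),  p = 1.6075,

with a, b, c the semi-axes; it is exact for a sphere and within ~1% of the
true elliptic-integral area for moderate axis ratios. A quadrature fallback
is provided for verification. Motor surface density is reported as the
integer part (floor) of area per complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["EllipsoidDims", "ellipsoid_surface_area", "area_per_motor",
           "THOMSEN_P"]

THOMSEN_P = 1.6075


@dataclass(frozen=True)
class EllipsoidDims:
    """Full axis lengths of a tri-axial ellipsoid, nm."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValidationError("all ellipsoid axes must be positive")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return self.length / 2.0, self.width / 2.0, self.height / 2.0


def _quadrature_area(a: float, b: float, c: float) -> float:
    """Numerical surface integral over the parametrised ellipsoid."""
    from scipy import integrate

    def element(v, u):
        sv, cv = np.sin(v), np.cos(v)
        su, cu = np.sin(u), np.cos(u)
        return np.sqrt((b * c * cu * sv ** 2) ** 2
                       + (a * c * su * sv ** 2) ** 2
                       + (a * b * sv * cv) ** 2)

    val, _ = integrate.dblquad(element, 0.0, np.pi, 0.0, 2.0 * np.pi,
                               epsabs=1e-8, epsrel=1e-10)
    return float(val)


def ellipsoid_surface_area(dims: EllipsoidDims,
                           method: str = "thomsen",
                           p: float = THOMSEN_P) -> float:
    """Surface area (nm²) of the ellipsoid.

    ``method`` is ``"thomsen"`` (default) or ``"quadrature"`` (slow,
    verification-grade numerical integral).
    """
    a, b, c = dims.semi_axes
    if method == "quadrature":
        return _quadrature_area(a, b, c)
    if method != "thomsen":
        raise ValidationError(f"unknown method {method!r}")
    s = (( (a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    return float(4.0 * np.pi * s)


def area_per_motor(surface_area: float, n_complexes: int) -> int:
    """Surface area per motor complex, nm², floored to an integer.

    Floor (not round) is the reporting convention here; density strictly
    decreases as the motor count grows at fixed area.
    """
    if n_complexes < 1:
        raise ValidationError("n_complexes must be >= 1")
    if surface_area <= 0:
        raise ValidationError("surface_area must be positive")
    return int(np.floor(surface_area / n_complexes))
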