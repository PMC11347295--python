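"""Pointwise acoustic physics at tissue boundaries.

Reflection/transmission of a plane wave at an impedance discontinuity,
refraction geometry, frequency-dependent attenuation and the boundary
(surface) echo model.  All functions are pure and consumed by the path
tracer.

Conventions: impedances in kg/(m^2 s); attenuation in dB/(cm MHz);
intensities are dimensionless relative to the launched intensity.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "BoundaryInteraction",
    "reflection_coefficient",
    "refraction_cosine",
    "attenuate",
    "attenuation_factor",
    "surface_echo",
]

#: Grazing-incidence clamp for cos(theta)^gamma with gamma < 0, so boundary
#: echoes stay bounded.
COS_THETA_FLOOR = 1e-3


class BoundaryInteraction:
    """Resolved interaction of a ray with an impedance discontinuity.

    Carries the two impedances, the incidence/refraction cosines (or a
    total-internal-reflection flag) and the energy split R, T = 1 - R.
    """

    __slots__ = ("Z1", "Z2", "cos_theta1", "cos_theta2", "tir", "R", "T")

    def __init__(self, Z1: float, Z2: float, cos_theta1: float,
                 ratio: float | None = None):
        """``ratio`` is the refraction ratio (defaults to Z1/Z2 as printed
        in the reflection model; pass c1/c2 for the Snell convention)."""
        self.Z1 = float(Z1)
        self.Z2 = float(Z2)
        self.cos_theta1 = float(np.clip(abs(cos_theta1), 0.0, 1.0))
        if ratio is None:
            ratio = Z1 / Z2
        c2 = refraction_cosine_ratio(ratio, self.cos_theta1)
        self.tir = c2 is None
        self.cos_theta2 = 0.0 if self.tir else float(c2)
        self.R = reflection_coefficient(
            Z1, Z2, self.cos_theta1, None if self.tir else self.cos_theta2
        )
        self.T = 1.0 - self.R


def reflection_coefficient(
    Z1: float, Z2: float, cos_theta1: float, cos_theta2: float | None
) -> float:
    """Intensity reflection coefficient of a plane wave at a boundary.

    R = ((Z2 cos(theta2) - Z1 cos(theta1)) / (Z2 cos(theta2) + Z1 cos(theta1)))^2.
    ``cos_theta2 = None`` flags total internal reflection and returns 1.
    """
    if Z1 <= 0 or Z2 <= 0:
        raise ValueError("impedances must be positive")
    if cos_theta2 is None:
        return 1.0
    num = Z2 * cos_theta2 - Z1 * cos_theta1
    den = Z2 * cos_theta2 + Z1 * cos_theta1
    if den == 0.0:  # doubly grazing: all energy reflected
        return 1.0
    r = (num / den) ** 2
    return float(min(r, 1.0))


def refraction_cosine_ratio(ratio: float, cos_theta1: float) -> float | None:
    """cos(theta2) for a given refraction ratio; ``None`` flags TIR.

    cos(theta2) = sqrt(1 - ratio^2 (1 - cos^2(theta1))) when the radicand is
    non-negative.
    """
    radicand = 1.0 - ratio * ratio * (1.0 - cos_theta1 * cos_theta1)
    if radicand < 0.0:
        return None
    return math.sqrt(radicand)


def refraction_cosine(Z1: float, Z2: float, cos_theta1: float) -> float | None:
    """cos(theta2) using the impedance ratio Z1/Z2 (the model's printed
    convention); ``None`` flags total internal reflection."""
    if not 0.0 <= cos_theta1 <= 1.0:
        raise ValueError("cos_theta1 must lie in [0, 1]")
    return refraction_cosine_ratio(Z1 / Z2, cos_theta1)


def attenuation_factor(l_cm, f_mhz: float, alpha: float):
    """Multiplicative intensity factor 10^(-alpha f l / 10).

    Vectorized in ``l_cm``.  alpha in dB/(cm MHz), f in MHz, l in cm.
    """
    l_cm = np.asarray(l_cm, dtype=float)
    if np.any(l_cm < 0):
        raise ValueError("path length must be non-negative")
    if f_mhz <= 0:
        raise ValueError("frequency must be positive")
    if alpha < 0:
        raise ValueError("attenuation coefficient must be non-negative")
    return 10.0 ** (-alpha * f_mhz * l_cm / 10.0)


def attenuate(intensity, l_cm, f_mhz: float, alpha: float):
    """Attenuate an intensity over ``l_cm`` centimetres of tissue."""
    return intensity * attenuation_factor(l_cm, f_mhz, alpha)


def surface_echo(
    intensity: float,
    Z1: float,
    Z2: float,
    cos_theta: float,
    tau: float,
    gamma: float,
) -> float:
    """Echo intensity returned to the transducer from a boundary point.

    I_R = ((Z2 - Z1)/(Z2 + Z1))^2 * I * tau * cos(theta)^gamma.  For
    gamma < 0 the cosine is floored at COS_THETA_FLOOR so grazing incidence
    cannot emit unbounded echoes.
    """
    if Z1 <= 0 or Z2 <= 0:
        raise ValueError("impedances must be positive")
    c = float(np.clip(cos_theta, 0.0, 1.0))
    if gamma < 0:
        c = max(c, COS_THETA_FLOOR)
    elif c == 0.0:
        return 0.0 if gamma > 0 else intensity * ((Z2 - Z1) / (Z2 + Z1)) ** 2 * tau
    base = ((Z2 - Z1) / (Z2 + Z1)) ** 2
    return float(base * intensity * tau * c**gamma)
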