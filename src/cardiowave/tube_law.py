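"""Constitutive relations of the arterial wall.

The 1D blood-flow equations need a closure linking internal pressure to
cross-sectional area.  This module implements a Voigt-type visco-elastic
tube law

    P(x, t) = P_ext + K * (sqrt(A) - sqrt(A0)) / A0 + G * (1/(A0 sqrt(A))) * dA/dt

where the elastic coefficient K = (4/3) sqrt(pi) E h derives from the Young
modulus E and wall thickness h of a thin-walled elastic ring, and the viscous
coefficient G = (2/3) sqrt(pi) phi h from the wall viscosity phi.  All
quantities are SI (m, s, Pa, kg); unit conversion is confined to the I/O
layer.

The elastic part of the law defines the wave speed

    c(A) = sqrt(K sqrt(A) / (2 rho A0)),   c0 = c(A0) = sqrt(K / (2 rho sqrt(A0)))

and the Riemann invariants (characteristics) of the hyperbolic system,

    W_f = u + 4 (c(A) - c0),    W_b = u - 4 (c(A) - c0),

used throughout the boundary treatment.  The viscous term G * Psi is handled
by the solver as a source-term correction so the hyperbolic core stays
purely elastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WallProperties",
    "stiffness_coefficients",
    "pressure_from_area",
    "wave_speed",
    "reference_wave_speed",
    "characteristics",
    "invert_characteristics",
    "CollapsedLumenError",
    "InvalidGeometryError",
]

SQRT_PI = float(np.sqrt(np.pi))

#: default blood density, kg/m^3
RHO_BLOOD = 1060.0
#: default dynamic blood viscosity, Pa s
MU_BLOOD = 4.0e-3


class InvalidGeometryError(ValueError):
    """Raised for non-physical wall geometry (h <= 0, A0 <= 0, ...)."""


class CollapsedLumenError(ValueError):
    """Raised when a cross-sectional area is not strictly positive."""


def stiffness_coefficients(E: float, h: float, phi_w: float = 0.0) -> tuple[float, float]:
    """Elastic and viscous wall coefficients from material properties.

    Parameters
    ----------
    E : float
        Young modulus of the wall (Pa).
    h : float
        Wall thickness (m).
    phi_w : float
        Wall viscosity (Pa s).

    Returns
    -------
    (K, G) : tuple of float
        Elastic coefficient K = (4/3) sqrt(pi) E h (Pa m) and viscous
        coefficient G = (2/3) sqrt(pi) phi_w h (Pa s m).
    """
    if h <= 0.0:
        raise InvalidGeometryError(f"wall thickness must be positive, got h={h!r}")
    if E < 0.0 or phi_w < 0.0:
        raise InvalidGeometryError("E and phi_w must be non-negative")
    K = (4.0 / 3.0) * SQRT_PI * E * h
    G = (2.0 / 3.0) * SQRT_PI * phi_w * h
    return K, G


@dataclass
class WallProperties:
    """Wall-law parameters of one vessel element.

    Fields are arrays or scalars; arrays allow per-element (tapered)
    properties sampled piecewise constant along a vessel.
    """

    A0: np.ndarray | float          # reference cross-sectional area, m^2
    E: np.ndarray | float           # Young modulus, Pa
    h: np.ndarray | float           # wall thickness, m
    K: np.ndarray | float = field(default=None)   # elastic coefficient, Pa m
    phi_w: np.ndarray | float = 0.0  # wall viscosity, Pa s
    G: np.ndarray | float = field(default=None)   # viscous coefficient, Pa s m
    P_ext: float = 0.0              # external pressure, Pa
    rho: float = RHO_BLOOD          # blood density, kg/m^3

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.A0) <= 0.0):
            raise InvalidGeometryError("A0 must be positive")
        if np.any(np.asarray(self.h) <= 0.0):
            raise InvalidGeometryError("h must be positive")
        if np.any(np.asarray(self.E) < 0.0):
            raise InvalidGeometryError("E must be non-negative")
        if self.rho <= 0.0:
            raise InvalidGeometryError("rho must be positive")
        if self.K is None:
            self.K = (4.0 / 3.0) * SQRT_PI * np.asarray(self.E, dtype=float) * self.h
        if self.G is None:
            self.G = (2.0 / 3.0) * SQRT_PI * np.asarray(self.phi_w, dtype=float) * self.h


def pressure_from_area(A, dA_dt, wall: WallProperties):
    """Transmural pressure from the visco-elastic tube law (Pa)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise CollapsedLumenError("cross-sectional area must be positive")
    sqrtA = np.sqrt(A)
    elastic = wall.K * (sqrtA - np.sqrt(wall.A0)) / wall.A0
    viscous = wall.G * dA_dt / (wall.A0 * sqrtA)
    return wall.P_ext + elastic + viscous


def wave_speed(A, wall: WallProperties):
    """Elastic wave speed c(A) = sqrt(K sqrt(A) / (2 rho A0)) (m/s)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise CollapsedLumenError("cross-sectional area must be positive")
    if np.any(np.asarray(wall.K) <= 0.0):
        raise InvalidGeometryError("wave speed undefined for K <= 0")
    return np.sqrt(wall.K * np.sqrt(A) / (2.0 * wall.rho * wall.A0))


def reference_wave_speed(wall: WallProperties):
    """Wave speed at the reference area, c0 = sqrt(K / (2 rho sqrt(A0)))."""
    if np.any(np.asarray(wall.K) <= 0.0):
        raise InvalidGeometryError("wave speed undefined for K <= 0")
    return np.sqrt(wall.K / (2.0 * wall.rho * np.sqrt(wall.A0)))


def characteristics(A, u, wall: WallProperties):
    """Riemann invariants (W_f, W_b) = u +/- 4 (c(A) - c0)."""
    c = wave_speed(A, wall)
    c0 = reference_wave_speed(wall)
    u = np.asarray(u, dtype=float)
    return u + 4.0 * (c - c0), u - 4.0 * (c - c0)


def invert_characteristics(W_f, W_b, wall: WallProperties):
    """Recover (A, u) from the Riemann invariants.

    c = c0 + (W_f - W_b)/8 and A = (2 rho A0 c^2 / K)^2 invert the elastic
    wave-speed relation exactly.
    """
    W_f = np.asarray(W_f, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    c0 = reference_wave_speed(wall)
    c = c0 + (W_f - W_b) / 8.0
    if np.any(c <= 0.0):
        raise CollapsedLumenError(
            "characteristics imply non-positive wave speed (negative area)"
        )
    A = (2.0 * wall.rho * wall.A0 * c**2 / wall.K) ** 2
    u = 0.5 * (W_f + W_b)
    return A, u
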