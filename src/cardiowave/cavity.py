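"""Reduced-order cardiac cavity models.

The heart side of the heart–vessel coupling only has to expose a cavity
volume as a function of pressure and time, V_heart(p, t), together with its
pressure derivative.  Two interchangeable implementations are provided:

* :class:`ElastanceCavity` — the classic time-varying elastance surrogate,
  p = E(t) (V - V_rest), with the activation shape E(t) driven by the same
  phenomenological active-stress transient used in full electromechanics
  models,

      S_a(t, lambda) = S_peak phi(lambda) tanh^2(t_s/tau_c)
                       tanh^2((t_dur - t_s)/tau_r),   0 < t_s < t_dur,
      phi = tanh(ld (lambda - lambda_0)),
      tau_c = tau_c0 + ld_up (1 - phi),
      t_s = t - t_a - t_emd.

* :class:`SphereCavity` — a thick-walled incompressible sphere whose wall
  carries the transversely isotropic Guccione strain energy

      Psi = kappa/2 (log J)^2 + C_Guc/2 (exp(Q) - 1),
      Q = b_f (f0.E f0)^2 + b_t [(s0.E s0)^2 + (n0.E n0)^2 + 2 (s0.E n0)^2]
          + 2 b_fs [(f0.E s0)^2 + (f0.E n0)^2],

  (E the isochoric Green–Lagrange strain) plus the orthotropic active
  stress with full force along the fibre direction and 40% along the sheet
  direction.  Fibres are circumferential; cavity pressure follows from the
  radial equilibrium of the inflated shell, p = int 2 (sigma_t - sigma_r)/r dr,
  by Gauss quadrature, and V(p) by safeguarded root finding.  The two
  tangential Cauchy stresses of the anisotropic wall are averaged into a
  single effective hoop stress, the standard symmetrisation for spherical
  surrogates.

Also here: the divergence-theorem volume of a closed triangulated surface,
the formula by which a 3D electromechanics code would measure its cavity
volume.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

__all__ = [
    "ActiveStressParams",
    "GuccioneParams",
    "table1_guccione_params",
    "active_stress",
    "guccione_energy",
    "passive_stress",
    "active_stress_tensor",
    "CavityModel",
    "ElastanceCavity",
    "SphereCavity",
    "surface_volume",
    "InvalidDeformationError",
    "InvalidSurfaceError",
    "CavityStateError",
]


class InvalidDeformationError(ValueError):
    """Raised for a non-symmetric-positive-definite Cauchy–Green tensor."""


class InvalidSurfaceError(ValueError):
    """Raised when a surface mesh is open or inconsistently oriented."""


class CavityStateError(RuntimeError):
    """Raised when a cavity pressure/volume inversion leaves its bracket."""


# ---------------------------------------------------------------------------
# Active stress transient
# ---------------------------------------------------------------------------

@dataclass
class ActiveStressParams:
    """Parameters of the phenomenological active-stress transient (SI)."""

    S_peak: float = 60e3      # peak isometric tension, Pa
    t_dur: float = 0.575      # duration of the transient, s
    tau_c0: float = 0.105     # baseline contraction time constant, s
    tau_r: float = 0.090      # relaxation time constant, s
    ld: float = 35.0          # degree of length dependence
    ld_up: float = 0.100      # length dependence of the upstroke time, s
    lambda0: float = 0.7      # stretch floor below which no tension develops
    t_emd: float = 0.015      # electromechanical delay, s
    t_a: float = 0.0          # activation time, s (electrophysiology is a
                              # user parameter here, not a solved field)

    def __post_init__(self) -> None:
        if self.S_peak < 0.0:
            raise ValueError("S_peak must be non-negative")
        if self.t_dur <= 0.0 or self.tau_c0 <= 0.0 or self.tau_r <= 0.0:
            raise ValueError("t_dur, tau_c0, tau_r must be positive")


def active_stress(t: float, lam: float, p: ActiveStressParams) -> float:
    """Scalar active stress S_a(t, lambda) in Pa."""
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    t_s = t - p.t_a - p.t_emd
    if not 0.0 < t_s < p.t_dur:
        return 0.0
    phi = np.tanh(p.ld * (lam - p.lambda0))
    if phi <= 0.0:
        return 0.0
    tau_c = p.tau_c0 + p.ld_up * (1.0 - phi)
    return float(p.S_peak * phi
                 * np.tanh(t_s / tau_c) ** 2
                 * np.tanh((p.t_dur - t_s) / p.tau_r) ** 2)


# ---------------------------------------------------------------------------
# Guccione passive law
# ---------------------------------------------------------------------------

def _default_axes() -> np.ndarray:
    return np.eye(3)


@dataclass
class GuccioneParams:
    """Transversely isotropic Guccione material parameters (SI)."""

    C_guc: float = 800.0      # stress scaling, Pa
    b_f: float = 18.48        # fibre strain exponent weight
    b_t: float = 3.58         # transverse strain exponent weight
    b_fs: float = 1.627       # fibre-transverse shear exponent weight
    kappa: float = 650e3      # bulk modulus (incompressibility penalty), Pa
    axes: np.ndarray = field(default_factory=_default_axes)  # rows f0, s0, n0

    def __post_init__(self) -> None:
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3) or not np.allclose(
                self.axes @ self.axes.T, np.eye(3), atol=1e-10):
            raise ValueError("axes must be an orthonormal (f0, s0, n0) triad")

    @property
    def f0(self) -> np.ndarray:
        return self.axes[0]

    @property
    def s0(self) -> np.ndarray:
        return self.axes[1]

    @property
    def n0(self) -> np.ndarray:
        return self.axes[2]


def table1_guccione_params(**overrides) -> GuccioneParams:
    """Alternative parameter set mapped from an orthotropic tabulation.

    The orthotropic weights (b_ff=5, b_ss=6, b_nn=3, b_fs=10, b_fn=2,
    b_ns=2, scaling a=0.8 kPa) are collapsed onto the transversely
    isotropic law by b_f <- b_ff, b_t <- mean(b_ss, b_nn, b_ns),
    b_fs <- mean(b_fs, b_fn).  This is an approximation, shipped as an
    alternative config, not the default.
    """
    params = dict(C_guc=800.0, b_f=5.0, b_t=(6.0 + 3.0 + 2.0) / 3.0,
                  b_fs=(10.0 + 2.0) / 2.0)
    params.update(overrides)
    return GuccioneParams(**params)


def _check_spd(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape[-2:] != (3, 3):
        raise InvalidDeformationError("C must be (..., 3, 3)")
    if not np.allclose(C, np.swapaxes(C, -1, -2), atol=1e-10):
        raise InvalidDeformationError("C must be symmetric")
    if np.any(np.linalg.eigvalsh(C) <= 0.0):
        raise InvalidDeformationError("C must be positive definite")
    return C


def _exponent_Q(Ebar: np.ndarray, p: GuccioneParams):
    """Q and dQ/dEbar for batched symmetric strain tensors."""
    f, s, n = p.f0, p.s0, p.n0
    eff = np.einsum("i,...ij,j->...", f, Ebar, f)
    ess = np.einsum("i,...ij,j->...", s, Ebar, s)
    enn = np.einsum("i,...ij,j->...", n, Ebar, n)
    esn = np.einsum("i,...ij,j->...", s, Ebar, n)
    efs = np.einsum("i,...ij,j->...", f, Ebar, s)
    efn = np.einsum("i,...ij,j->...", f, Ebar, n)
    Q = (p.b_f * eff**2
         + p.b_t * (ess**2 + enn**2 + 2.0 * esn**2)
         + 2.0 * p.b_fs * (efs**2 + efn**2))

    def outer(a, b):
        return 0.5 * (np.multiply.outer(a, b) + np.multiply.outer(b, a))

    ff, ss, nn = outer(f, f), outer(s, s), outer(n, n)
    sn, fs, fn = outer(s, n), outer(f, s), outer(f, n)
    dQ = (2.0 * p.b_f * eff[..., None, None] * ff
          + 2.0 * p.b_t * (ess[..., None, None] * ss
                           + enn[..., None, None] * nn
                           + 2.0 * esn[..., None, None] * sn)
          + 4.0 * p.b_fs * (efs[..., None, None] * fs
                            + efn[..., None, None] * fn))
    return Q, dQ


def guccione_energy(C_tensor: np.ndarray, p: GuccioneParams):
    """Strain energy Psi(C) in Pa (batched over leading axes)."""
    C = _check_spd(C_tensor)
    J = np.sqrt(np.linalg.det(C))
    Cbar = J[..., None, None] ** (-2.0 / 3.0) * C
    Ebar = 0.5 * (Cbar - np.eye(3))
    Q, _ = _exponent_Q(Ebar, p)
    psi = 0.5 * p.kappa * np.log(J) ** 2 + 0.5 * p.C_guc * (np.exp(Q) - 1.0)
    return psi if psi.ndim else float(psi)


def passive_stress(C_tensor: np.ndarray, p: GuccioneParams) -> np.ndarray:
    """Second Piola–Kirchhoff passive stress S = 2 dPsi/dC (analytic)."""
    C = _check_spd(C_tensor)
    J = np.sqrt(np.linalg.det(C))
    Cinv = np.linalg.inv(C)
    Jm23 = J[..., None, None] ** (-2.0 / 3.0)
    Cbar = Jm23 * C
    Ebar = 0.5 * (Cbar - np.eye(3))
    Q, dQ = _exponent_Q(Ebar, p)
    # S_iso = C_guc e^Q J^(-2/3) [ D - (1/3)(D:C) C^-1 ] / ... with D = dQ/dEbar
    DC = np.einsum("...ij,...ij->...", dQ, C)
    S_iso = (0.5 * p.C_guc * np.exp(Q))[..., None, None] * Jm23 * (
        dQ - (DC / 3.0)[..., None, None] * Cinv)
    S_vol = (p.kappa * np.log(J))[..., None, None] * Cinv
    return S_vol + S_iso


def active_stress_tensor(S_a, C_tensor: np.ndarray, f0, s0) -> np.ndarray:
    """Orthotropic second Piola–Kirchhoff active stress.

    S_act = S_a (f0.C f0)^-1 f0 x f0 + 0.4 S_a (s0.C s0)^-1 s0 x s0.
    """
    C = _check_spd(C_tensor)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    cff = np.einsum("i,...ij,j->...", f0, C, f0)
    css = np.einsum("i,...ij,j->...", s0, C, s0)
    S_a = np.asarray(S_a, dtype=float)
    return ((S_a / cff)[..., None, None] * np.multiply.outer(f0, f0)
            + (0.4 * S_a / css)[..., None, None] * np.multiply.outer(s0, s0))


# ---------------------------------------------------------------------------
# Cavity models
# ---------------------------------------------------------------------------

class CavityModel(ABC):
    """Coupling contract: V(p, t) continuous and strictly increasing in p."""

    @abstractmethod
    def volume(self, p: float, t: float) -> float:
        """Cavity volume at pressure p and time t (m^3)."""

    @abstractmethod
    def pressure(self, V: float, t: float) -> float:
        """Cavity pressure at volume V and time t (Pa)."""

    def dvolume_dp(self, p: float, t: float, eps: float = 1.0) -> float:
        """dV/dp by central finite difference (m^3/Pa)."""
        return (self.volume(p + eps, t) - self.volume(p - eps, t)) / (2.0 * eps)


class ElastanceCavity(CavityModel):
    """Time-varying elastance chamber p = E(t) (V - V_rest).

    E(t) ramps from E_min to E_max following the normalised active-stress
    transient evaluated at unit stretch.
    """

    def __init__(self, V_rest: float = 10e-6, E_min: float = 1.2e7,
                 E_max: float = 2.7e8,
                 activation: ActiveStressParams | None = None):
        if not 0.0 < E_min <= E_max:
            raise ValueError("need 0 < E_min <= E_max")
        if V_rest < 0.0:
            raise ValueError("V_rest must be non-negative")
        self.V_rest = V_rest
        self.E_min = E_min
        self.E_max = E_max
        self.activation = activation or ActiveStressParams()
        ts = np.linspace(0.0, self.activation.t_dur, 2001)
        sa = np.array([active_stress(t + self.activation.t_a
                                     + self.activation.t_emd, 1.0,
                                     self.activation) for t in ts])
        self._peak = float(sa.max()) if sa.max() > 0.0 else 1.0

    def _shape(self, t: float) -> float:
        if self.activation.S_peak == 0.0:
            return 0.0
        return active_stress(t, 1.0, self.activation) / self._peak

    def elastance(self, t: float) -> float:
        return self.E_min + (self.E_max - self.E_min) * self._shape(t)

    def volume(self, p: float, t: float) -> float:
        return self.V_rest + p / self.elastance(t)

    def pressure(self, V: float, t: float) -> float:
        return self.elastance(t) * (V - self.V_rest)

    def dvolume_dp(self, p: float, t: float, eps: float = 1.0) -> float:
        return 1.0 / self.elastance(t)


class SphereCavity(CavityModel):
    """Thick-walled incompressible sphere with Guccione + active wall.

    The inflation map r^3 = R^3 + r_i^3 - R_i^3 is isochoric; the fibre
    stretch at radius r is the tangential stretch lambda = r/R.
    """

    def __init__(self, R_i: float = 0.025, R_o: float = 0.035,
                 guccione: GuccioneParams | None = None,
                 activation: ActiveStressParams | None = None,
                 n_quad: int = 8):
        if not 0.0 < R_i < R_o:
            raise ValueError("need 0 < R_i < R_o")
        self.R_i = R_i
        self.R_o = R_o
        self.guccione = guccione or GuccioneParams()
        self.activation = activation or ActiveStressParams()
        nodes, weights = leggauss(n_quad)
        # map [-1, 1] -> [R_i, R_o]
        self._R = 0.5 * (R_o - R_i) * nodes + 0.5 * (R_o + R_i)
        self._w = 0.5 * (R_o - R_i) * weights
        # circumferential fibre frame: f0 = theta, s0 = phi, n0 = radial
        self._axes = np.eye(3)
        self._V_last = self.reference_volume

    @property
    def reference_volume(self) -> float:
        """Stress-free cavity volume 4 pi R_i^3 / 3."""
        return 4.0 * np.pi * self.R_i**3 / 3.0

    def pressure(self, V: float, t: float) -> float:
        if V <= 0.0:
            raise CavityStateError("cavity volume must be positive")
        r_i3 = 3.0 * V / (4.0 * np.pi)
        shift = r_i3 - self.R_i**3
        R = self._R
        r = np.cbrt(R**3 + shift)
        lam = r / R
        # C in the (f0, s0, n0) frame: diag(lam^2, lam^2, lam^-4)
        nq = len(R)
        C = np.zeros((nq, 3, 3))
        C[:, 0, 0] = lam**2
        C[:, 1, 1] = lam**2
        C[:, 2, 2] = lam**-4
        S = passive_stress(C, self.guccione)
        S_a = np.array([active_stress(t, la, self.activation) for la in lam])
        S = S + active_stress_tensor(S_a, C, self._axes[0], self._axes[1])
        # Cauchy stresses (J = 1): sigma = F S F^T, F diagonal
        sigma_t = 0.5 * (lam**2 * S[:, 0, 0] + lam**2 * S[:, 1, 1])
        sigma_r = lam**-4 * S[:, 2, 2]
        # p = int_{r_i}^{r_o} 2 (sigma_t - sigma_r) / r dr, dr = (R/r)^2 dR
        integrand = 2.0 * (sigma_t - sigma_r) / r * (R / r) ** 2
        return float(np.sum(self._w * integrand))

    def volume(self, p: float, t: float, v_hint: float | None = None) -> float:
        """Invert p(V, t) for V near a continuation hint.

        At strong activation the sphere's p(V) relation develops a
        descending limb (the tanh length dependence saturates above
        lambda ~ 0.76 while the wall's geometric advantage shrinks on
        inflation), so the inverse is only locally unique.  The root
        nearest the hint (by default the previously returned volume) is
        selected, which tracks a continuous branch through a simulation.
        """
        V_ref = self.reference_volume
        hint = v_hint if v_hint is not None else self._V_last
        lo_lim, hi_lim = 0.02 * V_ref, 10.0 * V_ref
        # geometric scan outward from the hint; nearest sign change wins
        grid = hint * 1.22 ** np.arange(-18, 19)
        grid = grid[(grid > lo_lim) & (grid < hi_lim)]
        with np.errstate(over="ignore", invalid="ignore"):
            g = np.array([self.pressure(v, t) - p for v in grid])
        i_hint = int(np.argmin(np.abs(grid - hint)))
        ok = np.isfinite(g[:-1]) & np.isfinite(g[1:])
        sign_change = np.flatnonzero(ok & (np.sign(g[:-1]) * np.sign(g[1:]) <= 0.0))
        if len(sign_change) == 0:
            raise CavityStateError(
                f"no cavity volume in [{lo_lim:.2e}, {hi_lim:.2e}] m^3 "
                f"matches pressure {p:.1f} Pa")
        k = sign_change[np.argmin(np.abs(sign_change - i_hint))]
        V = float(brentq(lambda v: self.pressure(v, t) - p,
                         grid[k], grid[k + 1], xtol=1e-15, rtol=1e-14))
        self._V_last = V
        return V

    def dvolume_dp(self, p: float, t: float, eps: float = None) -> float:
        V = self.volume(p, t)
        dV = 1e-6 * max(V, self.reference_volume)
        dp_dV = (self.pressure(V + dV, t) - self.pressure(V - dV, t)) / (2.0 * dV)
        return 1.0 / dp_dV


# ---------------------------------------------------------------------------
# Divergence-theorem surface volume
# ---------------------------------------------------------------------------

def surface_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed, consistently oriented triangle mesh.

    V = (1/3) | sum_faces x_c . n dA |, evaluated exactly per triangle.
    Raises :class:`InvalidSurfaceError` if boundary edges exist (open
    surface) or an edge is not shared by exactly two faces.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise InvalidSurfaceError("faces must be (n, 3) vertex indices")
    edge_count: dict[tuple[int, int], int] = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    if any(c != 2 for c in edge_count.values()):
        raise InvalidSurfaceError("surface is open or non-manifold")
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    # (1/3) centroid . (normal * area) = (a+b+c) . ((b-a) x (c-a)) / 18
    contrib = np.einsum("ij,ij->i", a + b + c,
                        np.cross(b - a, c - a)) / 18.0
    return float(abs(contrib.sum()))
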