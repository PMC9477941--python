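"""Finite-volume discretisation of the 1D blood-flow equations.

The conservative system on one compliant vessel is

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx( alpha Q^2/A + B(A) ) = f/rho + taper sources + wall viscosity

with B(A) = K A^{3/2} / (3 rho A0) the pressure-flux potential of the
elastic tube law, friction f = -2 pi (zeta + 2) mu u for a power-law
velocity profile of exponent zeta (zeta = 9 gives the Coriolis coefficient
alpha = 1.1), and a Voigt-type visco-elastic wall term handled by operator
splitting as an implicit diffusion correction on Q.

Space: MUSCL reconstruction (minmod / MC / unlimited slopes) with an HLL
flux; tapered vessels carry per-element (A0, K) and the corresponding
non-conservative products appear as centred source terms.  Time: two-stage
explicit strong-stability-preserving Runge–Kutta under a CFL condition.
Boundary and interface elements (inlet, Windkessel terminals, junctions,
stenoses) are solved once per sub-step from the vessels' outgoing
characteristics and their fluxes are held fixed across the two stages,
which makes the discrete blood-volume bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tube_law import MU_BLOOD, WallProperties, reference_wave_speed, wave_speed
from .network_bc import (
    EndState,
    InflowBC,
    inflow_apply,
    inlet_flow_solve,
    junction_solve,
    stenosis_solve,
    windkessel_step,
)

__all__ = [
    "SchemeConfig",
    "VesselSegment",
    "ArterialNetwork",
    "StandaloneResult",
    "stable_dt",
    "advance",
    "run_standalone",
    "InstabilityError",
]


class InstabilityError(RuntimeError):
    """Raised when an explicit step produces a non-positive area."""


@dataclass
class SchemeConfig:
    """Spatial/temporal scheme parameters."""

    dt: float | None = None      # fixed sub-step, s (None -> CFL-chosen)
    cfl_number: float = 0.9
    order: int = 2               # 1 or 2 (MUSCL)
    limiter: str = "minmod"      # "minmod", "mc", or "none"

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.cfl_number <= 1.0:
            raise ValueError("cfl_number must lie in (0, 1]")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.limiter not in ("minmod", "mc", "none"):
            raise ValueError(f"unknown limiter {self.limiter!r}")


@dataclass
class VesselSegment:
    """Geometry, wall law, and discretised (A, Q) state of one 1D vessel."""

    id: str
    length: float                     # m
    n_elem: int
    wall: WallProperties              # array-valued fields, one per element
    zeta: float = 9.0                 # velocity-profile exponent
    alpha: float = None               # Coriolis coefficient; (zeta+2)/(zeta+1) if None
    mu: float = MU_BLOOD              # dynamic blood viscosity, Pa s
    A: np.ndarray = field(default=None)
    Q: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.length <= 0.0:
            raise ValueError("vessel length must be positive")
        if self.n_elem < 2:
            raise ValueError("vessel needs at least 2 elements")
        n = self.n_elem
        if self.alpha is None:
            self.alpha = (self.zeta + 2.0) / (self.zeta + 1.0)
        self.dx = self.length / n
        self.x = (np.arange(n) + 0.5) * self.dx
        # broadcast wall fields to per-element arrays
        for name in ("A0", "E", "h", "K", "phi_w", "G"):
            setattr(self.wall, name,
                    np.broadcast_to(np.asarray(getattr(self.wall, name), dtype=float),
                                    (n,)).copy())
        if self.A is None:
            self.A = self.wall.A0.copy()
        if self.Q is None:
            self.Q = np.zeros(n)
        self.A = np.asarray(self.A, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.A <= 0.0):
            raise InstabilityError(f"vessel {self.id}: non-positive initial area")
        # interface wall properties (n+1 interfaces incl. the two ends)
        self._A0_f = np.concatenate(([self.wall.A0[0]],
                                     0.5 * (self.wall.A0[:-1] + self.wall.A0[1:]),
                                     [self.wall.A0[-1]]))
        self._K_f = np.concatenate(([self.wall.K[0]],
                                    0.5 * (self.wall.K[:-1] + self.wall.K[1:]),
                                    [self.wall.K[-1]]))
        # taper-source gradients, centred
        self._dA0dx = np.gradient(self.wall.A0, self.dx)
        self._dKdx = np.gradient(self.wall.K, self.dx)
        self._tapered = (np.ptp(self.wall.A0) > 1e-14 * self.wall.A0[0]
                         or np.ptp(self.wall.K) > 1e-14 * abs(self.wall.K[0]))
        self._fric = 2.0 * np.pi * (self.zeta + 2.0) * self.mu
        self._c0 = reference_wave_speed(self.wall)
        self._has_viscous_wall = bool(np.any(self.wall.G > 0.0))

    # -- observables -------------------------------------------------------

    @property
    def volume(self) -> float:
        """Blood volume currently stored in the vessel (m^3)."""
        return float(np.sum(self.A) * self.dx)

    def pressure(self) -> np.ndarray:
        """Elastic pressure per element (Pa)."""
        w = self.wall
        return w.P_ext + w.K * (np.sqrt(self.A) - np.sqrt(w.A0)) / w.A0

    def end_state(self, side: str) -> EndState:
        """Interior state + wall data of one end ('left' or 'right')."""
        i = 0 if side == "left" else -1
        w = self.wall
        return EndState(
            A=float(self.A[i]), u=float(self.Q[i] / self.A[i]),
            A0=float(w.A0[i]), K=float(w.K[i]), c0=float(self._c0[i]),
            P_ext=float(w.P_ext), rho=float(w.rho),
        )


def stable_dt(segment: VesselSegment, cfl_number: float = 0.9) -> float:
    """CFL time-step bound dt = cfl * min( dx / (|u| + c) )."""
    c = wave_speed(segment.A, segment.wall)
    u = np.abs(segment.Q / segment.A)
    return float(cfl_number * np.min(segment.dx / (u + c)))


# ---------------------------------------------------------------------------
# Spatial operator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _slope(dl: float, dr: float, limiter: int) -> float:
    """Limited undivided slope: 0 minmod, 1 monotonised-central, 2 none."""
    if limiter == 2:
        return 0.5 * (dl + dr)
    if dl * dr <= 0.0:
        return 0.0
    if limiter == 0:
        if dl > 0.0:
            return min(dl, dr)
        return max(dl, dr)
    m = 0.5 * abs(dl + dr)
    m = min(m, 2.0 * abs(dl))
    m = min(m, 2.0 * abs(dr))
    return m if dl > 0.0 else -m


@njit(cache=True)
def _rhs_kernel(A, Q, A0, K, A0f, Kf, dA0dx, dKdx, rho, alpha, fric, dx,
                order, limiter, periodic, FbL1, FbL2, FbR1, FbR2,
                gA_l, gQ_l, gA_r, gQ_r, tapered, dAdt, dQdt):
    """Fused MUSCL-HLL right-hand side of the (A, Q) system.

    Non-periodic boundaries impose the interface fluxes (FbL*, FbR*) solved
    from boundary elements; the ghost values gA/gQ only feed the end-cell
    slopes.  A0f/Kf are the n+1 interface wall properties.
    """
    n = A.shape[0]
    sA = np.empty(n)
    sQ = np.empty(n)
    if order == 2:
        for i in range(n):
            if i == 0:
                aL = A[n - 1] if periodic else gA_l
                qL = Q[n - 1] if periodic else gQ_l
            else:
                aL = A[i - 1]
                qL = Q[i - 1]
            if i == n - 1:
                aR = A[0] if periodic else gA_r
                qR = Q[0] if periodic else gQ_r
            else:
                aR = A[i + 1]
                qR = Q[i + 1]
            sA[i] = _slope(A[i] - aL, aR - A[i], limiter)
            sQ[i] = _slope(Q[i] - qL, qR - Q[i], limiter)
    else:
        for i in range(n):
            sA[i] = 0.0
            sQ[i] = 0.0

    F1 = np.empty(n + 1)
    F2 = np.empty(n + 1)
    aa1 = alpha * (alpha - 1.0)
    for j in range(n + 1):
        if not periodic and j == 0:
            F1[0] = FbL1
            F2[0] = FbL2
            continue
        if not periodic and j == n:
            F1[n] = FbR1
            F2[n] = FbR2
            continue
        iL = j - 1 if j > 0 else n - 1
        iR = j if j < n else 0
        AL = A[iL] + 0.5 * sA[iL]
        QL = Q[iL] + 0.5 * sQ[iL]
        AR = A[iR] - 0.5 * sA[iR]
        QR = Q[iR] - 0.5 * sQ[iR]
        A0j = A0f[j]
        Kj = Kf[j]
        uL = QL / AL
        uR = QR / AR
        cL2 = Kj * np.sqrt(AL) / (2.0 * rho * A0j)
        cR2 = Kj * np.sqrt(AR) / (2.0 * rho * A0j)
        dL = np.sqrt(cL2 + aa1 * uL * uL)
        dR = np.sqrt(cR2 + aa1 * uR * uR)
        SL = min(alpha * uL - dL, alpha * uR - dR)
        SR = max(alpha * uL + dL, alpha * uR + dR)
        f1L = QL
        f2L = alpha * QL * uL + Kj * AL * np.sqrt(AL) / (3.0 * rho * A0j)
        f1R = QR
        f2R = alpha * QR * uR + Kj * AR * np.sqrt(AR) / (3.0 * rho * A0j)
        if SL >= 0.0:
            F1[j] = f1L
            F2[j] = f2L
        elif SR <= 0.0:
            F1[j] = f1R
            F2[j] = f2R
        else:
            inv = 1.0 / (SR - SL)
            F1[j] = (SR * f1L - SL * f1R + SL * SR * (AR - AL)) * inv
            F2[j] = (SR * f2L - SL * f2R + SL * SR * (QR - QL)) * inv

    inv_dx = 1.0 / dx
    for i in range(n):
        dAdt[i] = -(F1[i + 1] - F1[i]) * inv_dx
        dq = -(F2[i + 1] - F2[i]) * inv_dx
        dq -= fric * (Q[i] / A[i]) / rho
        if tapered:
            A32 = A[i] * np.sqrt(A[i])
            s_A0 = (2.0 * K[i] * A32 / (3.0 * rho * A0[i] * A0[i])
                    - K[i] * A[i] / (2.0 * rho * A0[i] * np.sqrt(A0[i])))
            s_K = (-2.0 * A32 / (3.0 * rho * A0[i])
                   + A[i] / (rho * np.sqrt(A0[i])))
            dq += s_A0 * dA0dx[i] + s_K * dKdx[i]
        dQdt[i] = dq


def _rhs(seg: VesselSegment, A: np.ndarray, Q: np.ndarray, cfg: SchemeConfig,
         left, right, t: float, forcing=None):
    """Semi-discrete RHS; ``left``/``right`` are boundary prescriptions.

    Boundary prescriptions: ("state", (A, Q)) imposes the flux of a solved
    boundary state; ("flux", (F1, F2)) imposes the interface flux directly;
    "periodic" wraps the domain.
    """
    rho = seg.wall.rho
    periodic = left == "periodic"
    limiter = {"minmod": 0, "mc": 1, "none": 2}[cfg.limiter]

    FbL1 = FbL2 = FbR1 = FbR2 = 0.0
    gA_l, gQ_l = A[0], Q[0]
    gA_r, gQ_r = A[-1], Q[-1]
    if periodic:
        A0f = np.empty(seg.n_elem + 1)
        Kf = np.empty(seg.n_elem + 1)
        A0f[1:-1] = 0.5 * (seg.wall.A0[:-1] + seg.wall.A0[1:])
        Kf[1:-1] = 0.5 * (seg.wall.K[:-1] + seg.wall.K[1:])
        A0f[0] = A0f[-1] = 0.5 * (seg.wall.A0[0] + seg.wall.A0[-1])
        Kf[0] = Kf[-1] = 0.5 * (seg.wall.K[0] + seg.wall.K[-1])
    else:
        A0f, Kf = seg._A0_f, seg._K_f
        for side, at_left in ((left, True), (right, False)):
            kind, val = side
            if kind == "state":
                Ab, Qb = val
                i_end = 0 if at_left else -1
                A0b, Kb = seg.wall.A0[i_end], seg.wall.K[i_end]
                f1 = Qb
                f2 = (seg.alpha * Qb**2 / Ab
                      + Kb * Ab**1.5 / (3.0 * rho * A0b))
                ghost = (Ab, Qb)
            else:  # "flux"
                f1, f2 = val
                ghost = None
            if at_left:
                FbL1, FbL2 = f1, f2
                if ghost is not None:
                    gA_l, gQ_l = ghost
            else:
                FbR1, FbR2 = f1, f2
                if ghost is not None:
                    gA_r, gQ_r = ghost

    dAdt = np.empty(seg.n_elem)
    dQdt = np.empty(seg.n_elem)
    _rhs_kernel(A, Q, seg.wall.A0, seg.wall.K, A0f, Kf,
                seg._dA0dx, seg._dKdx, rho, seg.alpha, seg._fric, seg.dx,
                cfg.order, limiter, periodic,
                FbL1, FbL2, FbR1, FbR2,
                gA_l, gQ_l, gA_r, gQ_r, seg._tapered, dAdt, dQdt)

    if forcing is not None:
        fA, fQ = forcing(seg.x, t)
        dAdt = dAdt + fA
        dQdt = dQdt + fQ
    return dAdt, dQdt


@njit(cache=True)
def _voigt_kernel(A, Q, G, A0, rho, dx, dt):
    """Implicit (backward Euler) step of the Voigt wall term,
    dQ/dt = (A/rho) d/dx(g dQ/dx), g = G/(A0 sqrt(A)), zero viscous flux
    through the vessel ends; Thomas algorithm on the tridiagonal system."""
    n = A.shape[0]
    gf = np.empty(n - 1)
    for i in range(n - 1):
        gi = G[i] / (A0[i] * np.sqrt(A[i]))
        gi1 = G[i + 1] / (A0[i + 1] * np.sqrt(A[i + 1]))
        gf[i] = 0.5 * (gi + gi1)
    inv = dt / (rho * dx * dx)
    diag = np.empty(n)
    upper = np.empty(n - 1)
    lower = np.empty(n - 1)
    for i in range(n):
        r = inv * A[i]
        d = 1.0
        if i < n - 1:
            d += r * gf[i]
            upper[i] = -r * gf[i]
        if i > 0:
            d += r * gf[i - 1]
            lower[i - 1] = -r * gf[i - 1]
        diag[i] = d
    # forward sweep
    cp = np.empty(n - 1)
    dp = np.empty(n)
    cp[0] = upper[0] / diag[0]
    dp[0] = Q[0] / diag[0]
    for i in range(1, n):
        m = diag[i] - lower[i - 1] * cp[i - 1]
        if i < n - 1:
            cp[i] = upper[i] / m
        dp[i] = (Q[i] - lower[i - 1] * dp[i - 1]) / m
    out = np.empty(n)
    out[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]
    return out


def _viscous_wall_correction(seg: VesselSegment, A: np.ndarray, Q: np.ndarray,
                             dt: float) -> np.ndarray:
    return _voigt_kernel(A, Q, seg.wall.G, seg.wall.A0, seg.wall.rho,
                         seg.dx, dt)


def advance(seg: VesselSegment, dt: float, left, right, cfg: SchemeConfig,
            t: float = 0.0, forcing=None) -> None:
    """One explicit SSP-RK2 step of a single vessel, in place.

    ``left``/``right`` boundary prescriptions are held fixed across the two
    stages (see module docstring).  Raises :class:`InstabilityError` with
    the offending element if an area turns non-positive.
    """
    A0s, Q0s = seg.A, seg.Q
    dA1, dQ1 = _rhs(seg, A0s, Q0s, cfg, left, right, t, forcing)
    A1 = A0s + dt * dA1
    Q1 = Q0s + dt * dQ1
    _check_positive(seg, A1)
    dA2, dQ2 = _rhs(seg, A1, Q1, cfg, left, right, t + dt, forcing)
    A2 = 0.5 * (A0s + A1 + dt * dA2)
    Q2 = 0.5 * (Q0s + Q1 + dt * dQ2)
    _check_positive(seg, A2)
    if seg._has_viscous_wall:
        Q2 = _viscous_wall_correction(seg, A2, Q2, dt)
    seg.A = A2
    seg.Q = Q2


def _check_positive(seg: VesselSegment, A: np.ndarray) -> None:
    m = A.min()
    if not (m > 0.0) or not np.isfinite(m):
        with np.errstate(invalid="ignore"):
            bad = int(np.argmin(np.where(np.isfinite(A), A, -np.inf)))
        raise InstabilityError(
            f"vessel {seg.id}: non-positive/non-finite area at element {bad} "
            f"(x = {seg.x[bad]:.4f} m)"
        )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class ArterialNetwork:
    """Directed tree of vessel segments with boundary/interface elements.

    ``stenoses`` couple an upstream vessel outlet to a downstream vessel
    inlet through a lumped pressure-jump element; ``terminals`` attach an
    RCR Windkessel to a leaf outlet.  The ``root`` vessel inlet is forced by
    ``inflow`` or, in coupled mode, by a flow prescribed per step.
    """

    def __init__(self, vessels, junctions=(), terminals=None, stenoses=(),
                 root=None, inflow: InflowBC | None = None,
                 scheme: SchemeConfig | None = None):
        if isinstance(vessels, dict):
            self.vessels = dict(vessels)
        else:
            self.vessels = {v.id: v for v in vessels}
        self.junctions = list(junctions)
        self.terminals = dict(terminals or {})
        self.stenoses = list(stenoses)   # (upstream_id, downstream_id, element)
        self.root = root if root is not None else next(iter(self.vessels))
        self.inflow = inflow
        self.scheme = scheme or SchemeConfig()
        self._validate()
        self.reset_tallies()
        self.last_inlet_state = None      # (A, Q) at the root inlet
        self.max_junction_defect = 0.0    # |sum Q| / max|Q| over all steps

    def _validate(self) -> None:
        if self.root not in self.vessels:
            raise ValueError(f"root vessel {self.root!r} not in network")
        child_ids = set()
        for j in self.junctions:
            if j.parent not in self.vessels:
                raise ValueError(f"junction parent {j.parent!r} unknown")
            for c in j.children:
                if c not in self.vessels:
                    raise ValueError(f"junction child {c!r} unknown")
                if c in child_ids:
                    raise ValueError(f"vessel {c!r} has two parents")
                child_ids.add(c)
        for up, dn, _ in self.stenoses:
            if dn in child_ids:
                raise ValueError(f"vessel {dn!r} has two parents")
            child_ids.add(dn)
        # every non-root vessel must be someone's child; every leaf terminal
        parents = {j.parent for j in self.junctions} | {s[0] for s in self.stenoses}
        for vid in self.vessels:
            if vid != self.root and vid not in child_ids:
                raise ValueError(f"vessel {vid!r} is unreachable from the root")
            if vid not in parents and vid not in self.terminals:
                raise ValueError(f"leaf vessel {vid!r} has no terminal")

    # -- state snapshots ---------------------------------------------------

    def get_state(self) -> dict:
        """Deep snapshot of all evolving state (restorable, side-effect free)."""
        return {
            "A": {k: v.A.copy() for k, v in self.vessels.items()},
            "Q": {k: v.Q.copy() for k, v in self.vessels.items()},
            "wk": {k: t.P_state for k, t in self.terminals.items()},
            "sten": [s[2].q_state for s in self.stenoses],
            "tallies": dict(self.tallies),
            "inlet_state": self.last_inlet_state,
        }

    def set_state(self, state: dict) -> None:
        for k, v in self.vessels.items():
            v.A = state["A"][k].copy()
            v.Q = state["Q"][k].copy()
        for k, t in self.terminals.items():
            t.P_state = state["wk"][k]
        for s, q in zip(self.stenoses, state["sten"]):
            s[2].q_state = q
        self.tallies = dict(state["tallies"])
        self.last_inlet_state = state["inlet_state"]

    # -- bookkeeping -------------------------------------------------------

    def reset_tallies(self) -> None:
        self.tallies = {"inlet": 0.0, "terminal_out": 0.0}
        self._cap_ref = {k: t.P_state for k, t in self.terminals.items()}
        self._vol_ref = self.total_vessel_volume()

    def total_vessel_volume(self) -> float:
        return sum(v.volume for v in self.vessels.values())

    def capacitor_volume_change(self) -> float:
        return sum(t.C * (t.P_state - self._cap_ref[k])
                   for k, t in self.terminals.items())

    def conservation_defect(self) -> float:
        """Net bookkeeping defect of the volume balance since the last reset (m^3)."""
        dV_vessels = self.total_vessel_volume() - self._vol_ref
        return (self.tallies["inlet"] - self.tallies["terminal_out"]
                - dV_vessels - self.capacitor_volume_change())

    # -- stepping ----------------------------------------------------------

    def stable_dt(self, cfl_number: float | None = None) -> float:
        cfl = cfl_number if cfl_number is not None else self.scheme.cfl_number
        return min(stable_dt(v, cfl) for v in self.vessels.values())

    def step(self, t: float, dt: float, inlet_q: float | None = None) -> None:
        """Advance the whole network by one sub-step of size dt."""
        bstates: dict[tuple[str, str], tuple] = {}

        # inlet
        root = self.vessels[self.root]
        end = root.end_state("left")
        if inlet_q is not None:
            bstates[(self.root, "left")] = ("state", inlet_flow_solve(inlet_q, end))
        elif self.inflow is not None:
            bstates[(self.root, "left")] = ("state", inflow_apply(self.inflow, end, t, dt))
        else:
            bstates[(self.root, "left")] = ("state", inlet_flow_solve(0.0, end))

        # terminals
        for vid, term in self.terminals.items():
            end = self.vessels[vid].end_state("right")
            A_b, Q_b = windkessel_step(term, end, dt, commit=True)
            bstates[(vid, "right")] = ("state", (A_b, Q_b))
            self.tallies["terminal_out"] += dt * (term.P_state - term.P_out) / term.R

        # junctions
        for j in self.junctions:
            p_end = self.vessels[j.parent].end_state("right")
            c_ends = [self.vessels[c].end_state("left") for c in j.children]
            p_state, c_states = junction_solve(p_end, c_ends, j.total_pressure)
            bstates[(j.parent, "right")] = ("state", p_state)
            q_sum = p_state[1]
            for c, cs in zip(j.children, c_states):
                bstates[(c, "left")] = ("state", cs)
                q_sum -= cs[1]
            q_max = max(abs(p_state[1]), max(abs(cs[1]) for cs in c_states), 1e-30)
            self.max_junction_defect = max(self.max_junction_defect,
                                           abs(q_sum) / q_max)

        # stenoses
        for up, dn, elem in self.stenoses:
            up_end = self.vessels[up].end_state("right")
            dn_end = self.vessels[dn].end_state("left")
            up_state, dn_state = stenosis_solve(
                elem, up_end, dn_end, dt,
                rho=up_end.rho, mu=self.vessels[up].mu, commit=True)
            bstates[(up, "right")] = ("state", up_state)
            bstates[(dn, "left")] = ("state", dn_state)

        self.last_inlet_state = bstates[(self.root, "left")][1]
        self.tallies["inlet"] += dt * self.last_inlet_state[1]

        for vid, seg in self.vessels.items():
            advance(seg, dt, bstates[(vid, "left")], bstates[(vid, "right")],
                    self.scheme, t=t)

    def advance_interval(self, t0: float, duration: float,
                         dt: float | None = None,
                         inlet_q: float | None = None) -> float:
        """Advance over [t0, t0+duration] in sub-steps; returns the end time."""
        if duration <= 0.0:
            return t0
        if dt is None:
            dt = min(self.stable_dt(), duration)
        n = max(1, int(np.ceil(duration / dt - 1e-12)))
        h = duration / n
        t = t0
        for _ in range(n):
            self.step(t, h, inlet_q=inlet_q)
            t += h
        return t

    # -- probes ------------------------------------------------------------

    def inlet_pressure(self) -> float:
        """Elastic pressure at the root inlet boundary (Pa)."""
        if self.last_inlet_state is None:
            seg = self.vessels[self.root]
            return float(seg.pressure()[0])
        end = self.vessels[self.root].end_state("left")
        return float(end.pressure(self.last_inlet_state[0]))

    def probe(self, vessel_id: str, frac: float) -> tuple[float, float]:
        """(pressure Pa, flow m^3/s) at a fractional position along a vessel."""
        seg = self.vessels[vessel_id]
        i = min(seg.n_elem - 1, max(0, int(frac * seg.n_elem)))
        return float(seg.pressure()[i]), float(seg.Q[i])


@dataclass
class StandaloneResult:
    """Diagnostics of a standalone (heartless) network run."""

    cycle_changes: list        # cycle-to-cycle relative L2 change of inlet pressure
    periodic: bool             # True once the change dropped below 1e-3
    period: float
    inlet_pressure: np.ndarray  # trace over the final cycle, Pa
    t: np.ndarray


def run_standalone(network: ArterialNetwork, inflow: InflowBC | None,
                   n_cycles: int, period: float,
                   periodicity_tol: float = 1e-3) -> StandaloneResult:
    """Cycle the arterial network alone under the inlet forcing.

    Advances ``n_cycles`` periods at the CFL-limited sub-step, reporting the
    cycle-to-cycle relative L2 change of the inlet pressure trace and a
    periodicity flag once that change falls below ``periodicity_tol``.
    """
    if inflow is not None:
        network.inflow = inflow
    changes: list[float] = []
    prev = None
    trace = np.array([])
    ts = np.array([])
    if n_cycles > 0:
        # fixed sub-step count so cycle traces are directly comparable;
        # margin on the initial CFL bound absorbs state-dependent changes
        dt = 0.8 * network.stable_dt()
        n = max(1, int(np.ceil(period / dt)))
        h = period / n
    for cyc in range(n_cycles):
        trace = np.empty(n)
        ts = np.empty(n)
        t = cyc * period
        for i in range(n):
            network.step(t, h)
            t += h
            trace[i] = network.inlet_pressure()
            ts[i] = t
        if prev is not None and prev.shape == trace.shape:
            denom = np.linalg.norm(prev)
            changes.append(float(np.linalg.norm(trace - prev) / max(denom, 1e-30)))
        prev = trace
    periodic = bool(changes) and changes[-1] < periodicity_tol
    return StandaloneResult(cycle_changes=changes, periodic=periodic,
                            period=period, inlet_pressure=trace, t=ts)
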