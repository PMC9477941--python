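"""Boundary and interface elements of an arterial network.

A 1D vessel exchanges information with its surroundings through the
characteristic that leaves the vessel at each end: at an outlet the forward
invariant W_f, at an inlet the backward invariant W_b.  Every element here
(inlet forcing, three-element Windkessel terminal, bifurcation/continuation
junction, lumped stenosis) closes the system by combining that outgoing
characteristic with its own algebraic or ODE model and returns a boundary
state (A, Q) from which the solver builds the interface flux.

The Windkessel terminal is the classic RCR model: characteristic impedance
Z in series with a parallel peripheral resistance R and compliance C,

    Q (1 + Z/R) + C Z dQ/dt = (P - P_out)/R + C dP_e/dt,

integrated implicitly (backward Euler) on the internal capacitor pressure
for unconditional stability at the coupling step.  P_e is identified with
the terminal pressure P.

Junctions enforce mass conservation and continuity of total pressure
P + rho u^2 / 2 (static-pressure matching available by flag) via a small
damped Newton solve on the (A, u) states of every connected end.

The stenosis is a Young–Tsai-type lumped element embedded as an internal
interface: the two vessel ends exchange a pressure jump

    dp = Kv mu/(A0 D0) q + Kt rho/(2 A0^2) (A0/A_s - 1)^2 q|q|
         + Ku rho L_s/A0 dq/dt

at equal through-flow q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .tube_law import CollapsedLumenError

__all__ = [
    "EndState",
    "WindkesselTerminal",
    "Junction",
    "StenosisElement",
    "InflowBC",
    "windkessel_step",
    "junction_solve",
    "stenosis_dp",
    "inflow_apply",
    "InvalidTerminalError",
    "JunctionFailureError",
]


class InvalidTerminalError(ValueError):
    """Raised for non-physical terminal parameters (R <= 0, ...)."""


class JunctionFailureError(RuntimeError):
    """Raised when the junction Newton solve does not converge."""


@dataclass
class EndState:
    """Scalar state and wall properties of one vessel end.

    ``A`` and ``u`` are the interior values adjacent to the boundary, used
    to evaluate the outgoing characteristic.  Wall quantities are the
    end-element values.
    """

    A: float          # interior area next to the boundary, m^2
    u: float          # interior velocity next to the boundary, m/s
    A0: float         # reference area, m^2
    K: float          # elastic wall coefficient, Pa m
    c0: float         # reference wave speed, m/s
    P_ext: float      # external pressure, Pa
    rho: float        # blood density, kg/m^3

    def c(self, A: float) -> float:
        return self.c0 * (A / self.A0) ** 0.25

    def pressure(self, A: float) -> float:
        return self.P_ext + self.K * (np.sqrt(A) - np.sqrt(self.A0)) / self.A0

    def w_forward(self) -> float:
        return self.u + 4.0 * (self.c(self.A) - self.c0)

    def w_backward(self) -> float:
        return self.u - 4.0 * (self.c(self.A) - self.c0)


# ---------------------------------------------------------------------------
# Windkessel terminal
# ---------------------------------------------------------------------------

@dataclass
class WindkesselTerminal:
    """Three-element (RCR) Windkessel terminal boundary element."""

    Z: float                 # characteristic impedance, Pa s/m^3
    R: float                 # peripheral resistance, Pa s/m^3
    C: float                 # peripheral compliance, m^3/Pa
    P_out: float = 0.0       # venous/outflow pressure, Pa
    P_state: float = None    # internal capacitor pressure, Pa

    def __post_init__(self) -> None:
        if self.R <= 0.0:
            raise InvalidTerminalError(f"peripheral resistance must be positive, got {self.R!r}")
        if self.Z < 0.0 or self.C < 0.0:
            raise InvalidTerminalError("Z and C must be non-negative")
        if self.P_state is None:
            self.P_state = self.P_out

    def capacitor_update(self, Q: float, dt: float) -> float:
        """Backward-Euler capacitor pressure after one step at inflow Q."""
        if self.C == 0.0:
            return self.P_out + self.R * Q
        a = dt / (self.R * self.C)
        return (self.P_state + (dt / self.C) * Q + a * self.P_out) / (1.0 + a)


def windkessel_step(term: WindkesselTerminal, end: EndState, dt: float,
                    commit: bool = True) -> tuple[float, float]:
    """Advance the RCR terminal one step coupled to the vessel outlet.

    Solves, for the boundary area A, the simultaneous system of the
    outgoing forward characteristic W_f (from the interior state) and the
    implicitly integrated lumped model

        P(A) = P_c^{n+1}(Q) + Z Q,   Q = A (W_f - 4 (c(A) - c0)).

    Returns the boundary state ``(A_bc, Q_bc)`` and, if ``commit``, stores
    the updated capacitor pressure.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    W_f = end.w_forward()
    if term.C > 0.0:
        a = dt / (term.R * term.C)
        denom = 1.0 + a
        # P_c^{n+1} = (P_state + (dt/C) Q + a P_out) / (1+a)
        p_base = (term.P_state + a * term.P_out) / denom
        q_coef = (dt / term.C) / denom
    else:
        p_base = term.P_out
        q_coef = term.R
    Z_eff = term.Z + q_coef

    A = end.A  # warm start from the interior value
    for _ in range(60):
        c = end.c(A)
        u = W_f - 4.0 * (c - end.c0)
        Q = A * u
        g = end.pressure(A) - p_base - Z_eff * Q
        dP_dA = end.K / (2.0 * end.A0 * np.sqrt(A))
        dQ_dA = u - c
        dg = dP_dA - Z_eff * dQ_dA
        step = g / dg
        A_new = A - step
        if A_new <= 0.0:
            A_new = 0.5 * A
        if abs(A_new - A) <= 1e-14 * end.A0:
            A = A_new
            break
        A = A_new
    else:
        raise JunctionFailureError("windkessel boundary solve did not converge")
    u = W_f - 4.0 * (end.c(A) - end.c0)
    Q = A * u
    if commit:
        term.P_state = term.capacitor_update(Q, dt)
    return float(A), float(Q)


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

@dataclass
class Junction:
    """Connectivity element joining a parent outlet to child inlets."""

    parent: str
    children: tuple[str, ...]
    total_pressure: bool = True   # False -> static-pressure matching

    def __post_init__(self) -> None:
        self.children = tuple(self.children)
        if len(self.children) < 1:
            raise ValueError("junction needs at least one child")
        ids = (self.parent, *self.children)
        if len(set(ids)) != len(ids):
            raise ValueError("junction vessel ids must be distinct")


@njit(cache=True)
def _junction_newton_kernel(A, u, A0, K, c0, rho, W_out, total_pressure,
                            has_jump, visc_c, turb_c, iner_c, q_prev,
                            max_iter):
    """Damped Newton on the junction matching system.

    Index 0 is the parent outlet, 1..nc the child inlets.  Unknowns
    z = [A_0, u_0, A_1, u_1, ...]; residuals: each vessel's outgoing
    characteristic (forward for the parent, backward for children), signed
    mass conservation, and (total-)pressure continuity parent -> child with
    an optional lumped pressure jump dp(q) applied to the first child.
    Returns (z, converged, scaled_residual, iterations).
    """
    m = A.shape[0]
    nc = m - 1
    n = 2 * m
    z = np.empty(n)
    for i in range(m):
        z[2 * i] = A[i]
        z[2 * i + 1] = u[i]

    u_scale = max(abs(u[0]), c0[0])
    if u_scale < 1.0:
        u_scale = 1.0
    p_scale = max(K[0] / np.sqrt(A0[0]), 1.0)
    q_scale = max(abs(A[0] * u[0]), A0[0] * u_scale)

    r = np.empty(n)
    Jm = np.empty((n, n))
    res = 1e300
    for it in range(max_iter):
        for a in range(n):
            for b in range(n):
                Jm[a, b] = 0.0
        A_p = z[0]
        u_p = z[1]
        q = A_p * u_p
        if has_jump:
            dp_jump = visc_c * q + turb_c * q * abs(q) + iner_c * (q - q_prev)
            ddp_dq = visc_c + 2.0 * turb_c * abs(q) + iner_c
        else:
            dp_jump = 0.0
            ddp_dq = 0.0

        c_p = c0[0] * (A_p / A0[0]) ** 0.25
        r[0] = u_p + 4.0 * (c_p - c0[0]) - W_out[0]
        Jm[0, 0] = c_p / A_p
        Jm[0, 1] = 1.0
        for i in range(nc):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            c_i = c0[1 + i] * (A_i / A0[1 + i]) ** 0.25
            r[1 + i] = u_i - 4.0 * (c_i - c0[1 + i]) - W_out[1 + i]
            Jm[1 + i, 2 + 2 * i] = -c_i / A_i
            Jm[1 + i, 3 + 2 * i] = 1.0

        k = 1 + nc
        r[k] = A_p * u_p
        Jm[k, 0] = u_p
        Jm[k, 1] = A_p
        for i in range(nc):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            r[k] -= A_i * u_i
            Jm[k, 2 + 2 * i] = -u_i
            Jm[k, 3 + 2 * i] = -A_i

        P_p = K[0] * (np.sqrt(A_p) - np.sqrt(A0[0])) / A0[0]
        dPp = K[0] / (2.0 * A0[0] * np.sqrt(A_p))
        for i in range(nc):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            row = k + 1 + i
            P_i = K[1 + i] * (np.sqrt(A_i) - np.sqrt(A0[1 + i])) / A0[1 + i]
            dPi = K[1 + i] / (2.0 * A0[1 + i] * np.sqrt(A_i))
            r[row] = P_p - P_i
            Jm[row, 0] = dPp
            Jm[row, 2 + 2 * i] = -dPi
            if total_pressure:
                r[row] += 0.5 * rho * u_p * abs(u_p) - 0.5 * rho * u_i * abs(u_i)
                Jm[row, 1] += rho * abs(u_p)
                Jm[row, 3 + 2 * i] -= rho * abs(u_i)
            if i == 0 and has_jump:
                r[row] -= dp_jump
                Jm[row, 0] -= ddp_dq * u_p
                Jm[row, 1] -= ddp_dq * A_p

        res = 0.0
        for a in range(1 + nc):
            res = max(res, abs(r[a]) / u_scale)
        res = max(res, abs(r[k]) / q_scale)
        for a in range(k + 1, n):
            res = max(res, abs(r[a]) / p_scale)
        if res < 1e-13:
            return z, True, res, it

        dz = np.linalg.solve(Jm, -r)
        lam = 1.0
        for i in range(m):
            Ai = z[2 * i]
            dAi = dz[2 * i]
            if Ai + lam * dAi <= 0.1 * Ai:
                lam = min(lam, -0.9 * Ai / dAi)
        for a in range(n):
            z[a] += lam * dz[a]
    return z, False, res, max_iter


def _solve_junction_system(parent: EndState, children: list[EndState],
                           total_pressure: bool,
                           jump_coeffs=None, max_iter: int = 20):
    """Pack the end states and run the jitted junction Newton."""
    ends = [parent] + list(children)
    m = len(ends)
    A = np.array([e.A for e in ends])
    u = np.array([e.u for e in ends])
    A0 = np.array([e.A0 for e in ends])
    K = np.array([e.K for e in ends])
    c0 = np.array([e.c0 for e in ends])
    W_out = np.empty(m)
    W_out[0] = parent.w_forward()
    for i, ch in enumerate(children):
        W_out[1 + i] = ch.w_backward()
    if jump_coeffs is None:
        has_jump, visc_c, turb_c, iner_c, q_prev = False, 0.0, 0.0, 0.0, 0.0
    else:
        has_jump = True
        visc_c, turb_c, iner_c, q_prev = jump_coeffs
    z, ok, res, _ = _junction_newton_kernel(
        A, u, A0, K, c0, parent.rho, W_out, total_pressure,
        has_jump, visc_c, turb_c, iner_c, q_prev, max_iter)
    if not ok:
        raise JunctionFailureError(
            f"junction Newton did not converge in {max_iter} iterations; "
            f"scaled residual {res:.3e}")
    return z


def junction_solve(parent: EndState, children: list[EndState],
                   total_pressure: bool = True):
    """Match a parent outlet to child inlets.

    Returns ``((A_p, Q_p), [(A_i, Q_i), ...])`` boundary states satisfying
    mass conservation and (total-)pressure continuity together with each
    vessel's outgoing characteristic.
    """
    for e in [parent] + list(children):
        if e.A <= 0.0:
            raise CollapsedLumenError("junction end has non-positive area")
    z = _solve_junction_system(parent, children, total_pressure)
    parent_state = (float(z[0]), float(z[0] * z[1]))
    child_states = [
        (float(z[2 + 2 * i]), float(z[2 + 2 * i] * z[3 + 2 * i]))
        for i in range(len(children))
    ]
    return parent_state, child_states


# ---------------------------------------------------------------------------
# Stenosis
# ---------------------------------------------------------------------------

@dataclass
class StenosisElement:
    """Lumped stenosis (Young–Tsai family) embedded as an internal interface.

    ``area_ratio`` is A_s/A0 of the narrowed lumen.  ``Kv`` defaults to the
    Poiseuille-profile factor 32 L_s/D0 when not given.
    """

    area_ratio: float          # A_s / A0, dimensionless
    L_s: float                 # stenosis length, m
    A0: float                  # reference area of the host vessel, m^2
    Kv: float = None           # viscous coefficient
    Kt: float = 1.52           # turbulent-loss coefficient
    Ku: float = 1.2            # inertial coefficient
    q_state: float = 0.0       # through-flow at the previous step, m^3/s

    def __post_init__(self) -> None:
        if not 0.0 < self.area_ratio < 1.0:
            raise ValueError(f"area ratio must lie in (0, 1), got {self.area_ratio!r}")
        if self.L_s <= 0.0 or self.A0 <= 0.0:
            raise ValueError("L_s and A0 must be positive")
        if self.Kv is None:
            D0 = 2.0 * np.sqrt(self.A0 / np.pi)
            self.Kv = 32.0 * self.L_s / D0

    @property
    def D0(self) -> float:
        return 2.0 * float(np.sqrt(self.A0 / np.pi))


def stenosis_dp(elem: StenosisElement, q: float, dq_dt: float,
                rho: float, mu: float) -> float:
    """Pressure drop across the stenosis at through-flow q (Pa)."""
    visc = elem.Kv * mu / (elem.A0 * elem.D0) * q
    turb = (elem.Kt * rho / (2.0 * elem.A0**2)) * (1.0 / elem.area_ratio - 1.0) ** 2 * q * abs(q)
    iner = elem.Ku * rho * elem.L_s / elem.A0 * dq_dt
    return visc + turb + iner


def stenosis_solve(elem: StenosisElement, upstream: EndState,
                   downstream: EndState, dt: float, rho: float, mu: float,
                   commit: bool = True):
    """Solve the internal stenosis interface for one step.

    The upstream outlet and downstream inlet exchange the lumped pressure
    jump at equal through-flow; dq/dt is discretised backward in time from
    the stored ``q_state``.
    """
    visc_c = elem.Kv * mu / (elem.A0 * elem.D0)
    turb_c = (elem.Kt * rho / (2.0 * elem.A0**2)) * (1.0 / elem.area_ratio - 1.0) ** 2
    iner_c = elem.Ku * rho * elem.L_s / elem.A0 / dt
    z = _solve_junction_system(
        upstream, [downstream], True,
        jump_coeffs=(visc_c, turb_c, iner_c, elem.q_state))
    q = float(z[0] * z[1])
    if commit:
        elem.q_state = q
    return (float(z[0]), q), (float(z[2]), float(z[2] * z[3]))


# ---------------------------------------------------------------------------
# Inlet forcing
# ---------------------------------------------------------------------------

@dataclass
class InflowBC:
    """Periodic inlet boundary forcing by a sampled flow or pressure table."""

    kind: str                   # "flow" or "pressure"
    t: np.ndarray               # sample times, s (covering one period)
    values: np.ndarray          # Q (m^3/s) or P (Pa)
    period: float               # s

    def __post_init__(self) -> None:
        if self.kind not in ("flow", "pressure"):
            raise ValueError(f"unknown inflow kind {self.kind!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError("waveform samples must be strictly increasing in t")
        # fast path for uniformly sampled tables starting at t = 0
        dts = np.diff(self.t)
        self._uniform = (abs(self.t[0]) < 1e-15 and len(dts) > 0
                         and np.allclose(dts, dts[0], rtol=1e-10))
        if self._uniform:
            self._dt_s = float(dts[0])
            # append the wrap-around sample for interpolation past the table end
            self._vals_ext = np.append(self.values, self.values[0])
            self._t_end = self.t[-1]

    def __call__(self, t: float) -> float:
        """Periodically wrapped linear interpolation of the waveform."""
        tau = t % self.period
        if self._uniform:
            if tau > self._t_end:
                # between the last sample and t = period (wraps to sample 0)
                w = (tau - self._t_end) / (self.period - self._t_end)
                return float((1.0 - w) * self.values[-1] + w * self.values[0])
            pos = tau / self._dt_s
            i = int(pos)
            w = pos - i
            return float((1.0 - w) * self._vals_ext[i] + w * self._vals_ext[i + 1])
        return float(np.interp(tau, self.t, self.values, period=self.period))


def inlet_flow_solve(Q_bc: float, end: EndState) -> tuple[float, float]:
    """Boundary state at an inlet with prescribed flow Q_bc.

    Combines Q = A u with the vessel's outgoing backward characteristic
    W_b = u - 4 (c(A) - c0).
    """
    W_b = end.w_backward()
    A = end.A
    for _ in range(60):
        c = end.c(A)
        g = Q_bc / A - 4.0 * (c - end.c0) - W_b
        dg = -Q_bc / A**2 - c / A
        A_new = A - g / dg
        if A_new <= 0.0:
            A_new = 0.5 * A
        if abs(A_new - A) <= 1e-14 * end.A0:
            A = A_new
            break
        A = A_new
    else:
        raise JunctionFailureError("inlet flow boundary solve did not converge")
    return float(A), float(Q_bc)


def inlet_pressure_solve(P_bc: float, end: EndState) -> tuple[float, float]:
    """Boundary state at an inlet with prescribed (elastic) pressure P_bc."""
    sqrtA = np.sqrt(end.A0) + (P_bc - end.P_ext) * end.A0 / end.K
    if sqrtA <= 0.0:
        raise CollapsedLumenError("prescribed pressure collapses the inlet")
    A = float(sqrtA**2)
    u = end.w_backward() + 4.0 * (end.c(A) - end.c0)
    return A, float(A * u)


def inflow_apply(bc: InflowBC, end: EndState, t: float, dt: float) -> tuple[float, float]:
    """Boundary state (A, Q) for the inlet forcing at time t."""
    if bc.kind == "flow":
        return inlet_flow_solve(bc(t), end)
    return inlet_pressure_solve(bc(t), end)
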