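"""Monolithic coupling of a cardiac cavity to the 1D arterial network.

At every coupling step the cavity pressure p is the extra unknown closing
the system: the volume the heart model assigns to the cavity must match the
volume the circulatory model predicts for that pressure,

    V_heart(p, t^{n+1}) - V_CS(p) = 0.

V_CS(p) is evaluated by actually running the valve + 1D network over the
coupling window [t^n, t^n + dt3D] (sub-stepped at dt1D) from a committed
snapshot with the trial cavity pressure held constant:

    V_CS(p) = V_cav^n - int q(p) dt.

The scalar residual is driven to zero by Newton iterations in which the
vascular compliance dV_CS/dp is approximated by a central finite difference
of trial runs — the reduced (Schur-complement) form of the saddle-point
block system.  During isovolumetric phases the vascular side degenerates
(dV_CS/dp = 0, V_CS = V0) and the Newton solve uses the cavity Jacobian
alone, keeping the volume constant while pressure adjusts to the evolving
active stress.

The aortic valve is a Bernoulli resistor with blood inertance,

    p_cav - p_root = B q |q| + L_in dq/dt,

stepped implicitly, acting as a diode: it opens when cavity pressure
exceeds root pressure (with a small hysteresis band against chatter) and
closes when the through-flow would reverse.  Filling is modelled by a
prescribed left-atrial pressure (preload) waveform; the cardiac cycle is
managed by a four-phase machine (filling, isovolumetric contraction,
ejection, isovolumetric relaxation).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cavity import CavityModel
from .solver1d import ArterialNetwork, InstabilityError

__all__ = [
    "ValveModel",
    "CouplingConfig",
    "CouplingState",
    "Afterload",
    "NetworkAfterload",
    "valve_flow",
    "vascular_volume",
    "coupling_compliance",
    "newton_coupled_step",
    "isovolumetric_step",
    "run_cardiac_cycle",
    "CouplingNonConvergence",
    "CycleError",
]

MMHG = 133.322  # Pa per mmHg


class CouplingNonConvergence(RuntimeError):
    """Raised when the coupled Newton solve exhausts k_max iterations."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class CycleError(RuntimeError):
    """Raised when the cardiac phase machine deadlocks."""


# ---------------------------------------------------------------------------
# Valve
# ---------------------------------------------------------------------------

@dataclass
class ValveModel:
    """Bernoulli resistor + inertance diode for the aortic valve."""

    B: float = 5.0e8          # Bernoulli resistance, Pa s^2/m^6
    L_in: float = 5.0e4       # blood inertance, Pa s^2/m^3
    open_threshold: float = 1.0   # hysteresis band against chatter, Pa
    is_open: bool = False
    q: float = 0.0            # through-flow, m^3/s

    def __post_init__(self) -> None:
        if self.B <= 0.0:
            raise ValueError("valve Bernoulli coefficient must be positive")
        if self.L_in < 0.0:
            raise ValueError("valve inertance must be non-negative")

    def update(self, p_cav: float, p_root: float, dt: float) -> float:
        """Implicit valve-flow step; returns the new through-flow q >= 0."""
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        dp = p_cav - p_root
        if not self.is_open:
            if dp > self.open_threshold:
                self.is_open = True
                self.q = 0.0
            else:
                self.q = 0.0
                return 0.0
        # solve L (q' - q)/dt + B q'^2 = dp for q' >= 0
        lam = self.L_in / dt
        rhs = dp + lam * self.q
        if rhs <= 0.0:
            self.is_open = False
            self.q = 0.0
            return 0.0
        if self.B == 0.0:
            q_new = rhs / max(lam, 1e-300)
        else:
            q_new = (-lam + np.sqrt(lam**2 + 4.0 * self.B * rhs)) / (2.0 * self.B)
        if q_new <= 0.0:
            self.is_open = False
            q_new = 0.0
        self.q = float(q_new)
        return self.q

    def state(self) -> tuple[bool, float]:
        return self.is_open, self.q

    def restore(self, state: tuple[bool, float]) -> None:
        self.is_open, self.q = state


def valve_flow(p_cav: float, p_root: float, valve: ValveModel, dt: float) -> float:
    """One implicit valve update (mutates the valve state)."""
    return valve.update(p_cav, p_root, dt)


# ---------------------------------------------------------------------------
# Configuration and per-step state
# ---------------------------------------------------------------------------

@dataclass
class CouplingConfig:
    """Parameters of the coupled Newton scheme and of the cardiac cycle."""

    k_max: int = 10                # maximal Newton steps per coupling step
    tol_abs: float = 1e-6          # residual tolerance, in units of V_scale
    V_scale: float = 1e-6          # volume scale of the residual (1e-6 m^3 = 1 mL)
    fd_eps: float = 10.0           # pressure perturbation for dV_CS/dp, Pa
    dt3D: float = 1e-3             # coupling (heart) step, s
    dt1D: float = 1e-4             # vascular sub-step, s
    period: float = 1.231          # cardiac cycle length, s
    p_preload: float = 10.0 * MMHG   # left-atrial filling pressure, Pa
    t_activation: float = 0.0      # activation time within the beat, s
    t_emd: float = 0.015           # electromechanical delay, s
    t_dur: float = 0.575           # active transient duration (phase fallback), s
    probes: tuple = ()             # ((vessel_id, frac), ...) sampled per step

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.tol_abs <= 0.0:
            raise ValueError("tol_abs must be positive")
        if self.dt1D > self.dt3D + 1e-15:
            raise ValueError("dt1D must not exceed dt3D")

    def preload(self, t: float) -> float:
        return self.p_preload


@dataclass
class CouplingState:
    """Cavity/coupling state after one coupling step."""

    phase: str                    # filling | isovol_contraction | ejection | isovol_relaxation
    p_cav: float                  # Pa
    V_cav: float                  # m^3
    V0: float = 0.0               # isovolumetric target volume, m^3
    newton_iters: int = 0
    residual: float = 0.0         # final volume defect, m^3
    q: float = 0.0                # valve through-flow, m^3/s


# ---------------------------------------------------------------------------
# Afterload abstraction (the vascular side of the saddle-point system)
# ---------------------------------------------------------------------------

class Afterload(ABC):
    """Vascular volume predictor V_CS(p) over one coupling window."""

    @abstractmethod
    def begin_step(self, t: float, V_cav: float) -> None:
        """Commit a snapshot at t^n from which all trials restart."""

    @abstractmethod
    def volume(self, p: float) -> float:
        """Trial V_CS(p) from the committed snapshot (side-effect free)."""

    @abstractmethod
    def commit(self, p: float) -> dict:
        """Advance the vascular state at the converged pressure."""

    def compliance(self, p: float, eps: float) -> float:
        """Central finite-difference dV_CS/dp from the same snapshot."""
        return (self.volume(p + eps) - self.volume(p - eps)) / (2.0 * eps)


class NetworkAfterload(Afterload):
    """The 1D network + aortic valve as the cavity's afterload."""

    def __init__(self, network: ArterialNetwork, valve: ValveModel,
                 dt3D: float, dt1D: float):
        self.network = network
        self.valve = valve
        self.dt3D = dt3D
        self.dt1D = dt1D
        self._snapshot = None
        self._valve_state = None
        self._t = 0.0
        self._V_cav = 0.0

    def begin_step(self, t: float, V_cav: float) -> None:
        self._t = t
        self._V_cav = V_cav
        self._snapshot = self.network.get_state()
        self._valve_state = self.valve.state()

    def _run(self, p: float) -> tuple[float, float]:
        """Sub-step the valve + network at constant cavity pressure p.

        Returns (integrated outflow, final q).  Leaves the network in the
        post-window state; callers restore or keep it.
        """
        n = max(1, round(self.dt3D / self.dt1D))
        h = self.dt3D / n
        t = self._t
        q_int = 0.0
        for _ in range(n):
            p_root = self.network.inlet_pressure()
            q = self.valve.update(p, p_root, h)
            self.network.step(t, h, inlet_q=q)
            q_int += q * h
            t += h
        return q_int, self.valve.q

    def volume(self, p: float) -> float:
        q_int, _ = self._run(p)
        self.network.set_state(self._snapshot)
        self.valve.restore(self._valve_state)
        return self._V_cav - q_int

    def commit(self, p: float) -> dict:
        q_int, q_end = self._run(p)
        return {"q_int": q_int, "q": q_end, "valve_open": self.valve.is_open,
                "p_root": self.network.inlet_pressure()}

    def advance_closed(self, t: float) -> dict:
        """Advance one coupling window with the valve shut (no trials)."""
        n = max(1, round(self.dt3D / self.dt1D))
        h = self.dt3D / n
        for i in range(n):
            self.network.step(t + i * h, h, inlet_q=0.0)
        return {"q_int": 0.0, "q": 0.0, "valve_open": False,
                "p_root": self.network.inlet_pressure()}


def vascular_volume(p_trial: float, afterload: Afterload) -> float:
    """V_CS(p_trial) from the afterload's committed snapshot."""
    return afterload.volume(p_trial)


def coupling_compliance(p: float, afterload: Afterload, fd_eps: float) -> float:
    """Finite-difference vascular compliance dV_CS/dp (m^3/Pa)."""
    if fd_eps <= 0.0:
        raise ValueError("fd_eps must be positive")
    return afterload.compliance(p, fd_eps)


# ---------------------------------------------------------------------------
# Newton solves
# ---------------------------------------------------------------------------

def newton_coupled_step(p0: float, t_new: float, cavity: CavityModel,
                        afterload: Afterload, cfg: CouplingConfig):
    """Solve V_heart(p, t^{n+1}) = V_CS(p) for the cavity pressure.

    Returns ``(p, V_CS, iters, residual)``; the afterload is *not* yet
    committed.  Raises :class:`CouplingNonConvergence` after k_max
    iterations, carrying the residual history.
    """
    p = p0
    tol = cfg.tol_abs * cfg.V_scale
    history = []
    V_cs = afterload.volume(p)
    for k in range(cfg.k_max + 1):
        r = cavity.volume(p, t_new) - V_cs
        history.append(abs(r))
        if abs(r) < tol:
            return p, V_cs, k, r
        if k == cfg.k_max:
            break
        dV_heart = cavity.dvolume_dp(p, t_new)
        dV_cs = afterload.compliance(p, cfg.fd_eps)
        jac = dV_heart - dV_cs
        if jac == 0.0:
            raise CouplingNonConvergence("singular coupling Jacobian", history)
        dp = -r / jac
        # damped update: retry on 1D instability of the trial
        for _ in range(6):
            try:
                V_cs_new = afterload.volume(p + dp)
                break
            except InstabilityError:
                dp *= 0.5
        else:
            raise CouplingNonConvergence(
                "trial runs unstable even after damping", history)
        p = p + dp
        V_cs = V_cs_new
    raise CouplingNonConvergence(
        f"coupled Newton: residual {history[-1]:.3e} m^3 above tolerance "
        f"{tol:.3e} m^3 after k_max = {cfg.k_max} updates", history)


def isovolumetric_step(p0: float, t_new: float, V0: float,
                       cavity: CavityModel, cfg: CouplingConfig):
    """Solve V_heart(p, t^{n+1}) = V0 (vascular side degenerate).

    Returns ``(p, iters, residual)``.
    """
    p = p0
    tol = cfg.tol_abs * cfg.V_scale
    history = []
    for k in range(cfg.k_max + 1):
        r = cavity.volume(p, t_new) - V0
        history.append(abs(r))
        if abs(r) < tol:
            return p, k, r
        if k == cfg.k_max:
            break
        p = p - r / cavity.dvolume_dp(p, t_new)
    raise CouplingNonConvergence(
        f"isovolumetric Newton: residual {history[-1]:.3e} m^3 after "
        f"k_max = {cfg.k_max} updates", history)


# ---------------------------------------------------------------------------
# Cardiac cycle driver
# ---------------------------------------------------------------------------

PHASES = ("filling", "isovol_contraction", "ejection", "isovol_relaxation")


def run_cardiac_cycle(cavity: CavityModel, network: ArterialNetwork,
                      cfg: CouplingConfig, n_beats: int = 1,
                      valve: ValveModel | None = None):
    """Run the coupled heart + network over ``n_beats`` cardiac cycles.

    The cavity sees beat-local time (the activation fires every period).
    Returns ``(traces, beats)``: a DataFrame of dense traces sampled at the
    coupling step (t, phase, p_cav, V_cav, p_root, q, newton_iters,
    residual, probe columns) and a DataFrame of beat-wise summaries (EDV,
    ESV, SV, ejection fraction, peak/min pressures, pulse pressures).
    """
    valve = valve or ValveModel()
    afterload = NetworkAfterload(network, valve, cfg.dt3D, cfg.dt1D)
    T = cfg.period
    max_steps = int(np.ceil(1.5 * (n_beats + 1) * T / cfg.dt3D))

    t = 0.0
    phase = "filling"
    p = cfg.preload(0.0)
    V = cavity.volume(p, 0.0)
    V0 = V
    beat = 0
    fired = False           # activation fired in the current beat
    phase_age = 0.0         # time since last transition (deadlock guard)

    rec = {k: [] for k in ("t", "phase", "p_cav", "V_cav", "p_root", "q",
                           "newton_iters", "residual", "beat")}
    probe_rec = {f"p_{vid}_{frac:g}": [] for vid, frac in cfg.probes}
    beat_rows = []
    cur = {"EDV": V, "ESV": np.nan, "q_int": 0.0,
           "p_cav_max": -np.inf, "p_root_max": -np.inf, "p_root_min": np.inf}

    def finish_beat():
        row = {"beat": beat, "EDV": cur["EDV"], "ESV": cur["ESV"],
               "SV": cur["EDV"] - cur["ESV"],
               "EF": (cur["EDV"] - cur["ESV"]) / cur["EDV"],
               "stroke_integral": cur["q_int"],
               "p_cav_max": cur["p_cav_max"],
               "p_root_max": cur["p_root_max"],
               "p_root_min": cur["p_root_min"],
               "pulse_pressure_root": cur["p_root_max"] - cur["p_root_min"]}
        beat_rows.append(row)

    for _ in range(max_steps):
        if beat >= n_beats:
            break
        tb = t - beat * T                     # beat-local time
        t_new = t + cfg.dt3D
        tb_new = tb + cfg.dt3D
        iters, res, q_step = 0, 0.0, 0.0

        if phase == "filling":
            info = afterload.advance_closed(t)
            p = cfg.preload(tb_new)
            V = cavity.volume(p, tb_new)
            if not fired and tb_new >= cfg.t_activation + cfg.t_emd:
                cur["EDV"] = V
                V0 = V
                phase = "isovol_contraction"
                fired = True
                phase_age = 0.0

        elif phase == "isovol_contraction":
            info = afterload.advance_closed(t)
            p, iters, res = isovolumetric_step(p, tb_new, V0, cavity, cfg)
            V = V0
            if p > info["p_root"] + valve.open_threshold:
                valve.is_open = True
                valve.q = 0.0
                phase = "ejection"
                phase_age = 0.0
            elif (tb_new - cfg.t_activation - cfg.t_emd >= cfg.t_dur
                  or p < cfg.preload(tb_new) - valve.open_threshold):
                phase = "filling"   # weak/no contraction: back to filling
                phase_age = 0.0

        elif phase == "ejection":
            afterload.begin_step(t, V)
            p, V_cs, iters, res = newton_coupled_step(p, tb_new, cavity,
                                                      afterload, cfg)
            info = afterload.commit(p)
            V = V_cs                # mass-consistent committed volume
            q_step = info["q"]
            cur["q_int"] += info["q_int"]
            if not info["valve_open"]:
                cur["ESV"] = V
                V0 = V
                phase = "isovol_relaxation"
                phase_age = 0.0

        else:  # isovol_relaxation
            info = afterload.advance_closed(t)
            p, iters, res = isovolumetric_step(p, tb_new, V0, cavity, cfg)
            V = V0
            if p <= cfg.preload(tb_new):
                phase = "filling"
                phase_age = 0.0

        t = t_new
        phase_age += cfg.dt3D
        if phase in ("ejection", "isovol_contraction") and phase_age > 1.5 * T:
            raise CycleError(f"phase machine stuck in {phase} for {phase_age:.3f} s")

        p_root = info["p_root"]
        cur["p_cav_max"] = max(cur["p_cav_max"], p)
        cur["p_root_max"] = max(cur["p_root_max"], p_root)
        cur["p_root_min"] = min(cur["p_root_min"], p_root)

        rec["t"].append(t)
        rec["phase"].append(phase)
        rec["p_cav"].append(p)
        rec["V_cav"].append(V)
        rec["p_root"].append(p_root)
        rec["q"].append(q_step)
        rec["newton_iters"].append(iters)
        rec["residual"].append(res)
        rec["beat"].append(beat)
        for (vid, frac), key in zip(cfg.probes, probe_rec):
            probe_rec[key].append(network.probe(vid, frac)[0])

        # roll the beat over only once back in filling, so a late-running
        # ejection keeps its beat-local clock (and its decaying transient)
        if phase == "filling" and t >= (beat + 1) * T - 1e-9:
            finish_beat()
            beat += 1
            fired = False
            cur = {"EDV": V, "ESV": np.nan, "q_int": 0.0,
                   "p_cav_max": -np.inf, "p_root_max": -np.inf,
                   "p_root_min": np.inf}

    traces = pd.DataFrame({**rec, **probe_rec})
    beats = pd.DataFrame(beat_rows)
    return traces, beats
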