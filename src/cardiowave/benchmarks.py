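"""Verification oracles and the standard coupled studies.

Everything here recomputes a physical or numerical quantity from scratch by
running the solver and compares it against an independent closed form
(linear wave theory, lumped-model analytics, manufactured solutions) or
reports study observables (pressure-volume loop indices, pulse-pressure
amplification).  These functions back the ``cardiowave verify`` command and
the reproduction studies.
"""

from __future__ import annotations

import numpy as np

from .cavity import ActiveStressParams, ElastanceCavity
from .coupling import CouplingConfig, ValveModel, run_cardiac_cycle
from .fixtures import (
    make_bifurcating_tree,
    make_single_vessel,
    make_stenotic_vessel,
)
from .io import build_network
from .network_bc import InflowBC, Junction, WindkesselTerminal
from .solver1d import (
    ArterialNetwork,
    SchemeConfig,
    VesselSegment,
    advance,
    run_standalone,
    stable_dt,
)
from .tube_law import (
    RHO_BLOOD,
    WallProperties,
    reference_wave_speed,
    stiffness_coefficients,
    wave_speed,
)

__all__ = [
    "measure_pulse_speed",
    "windkessel_steady_check",
    "windkessel_decay_tau",
    "junction_conservation",
    "convergence_order",
    "reflection_coefficient",
    "coupled_run",
    "dt_robustness_study",
    "stiffening_study",
    "tree_study",
    "scale_activation",
]


# ---------------------------------------------------------------------------
# Wave-speed transit oracle
# ---------------------------------------------------------------------------

def measure_pulse_speed(E: float = 0.25e6, radius: float = 0.010,
                        h: float = 1.5e-3, amplitude: float = 1e-3,
                        length: float = 1.0, dx: float = 2e-3) -> dict:
    """Transit speed of a small forward pulse vs the analytic c0.

    A low-amplitude Gaussian area pulse with the forward-wave velocity
    relation u = 4 (c - c0) is tracked through a long uniform frictionless
    vessel; the fitted peak speed is compared with
    c0 = sqrt(K / (2 rho sqrt(A0))).
    """
    A0 = np.pi * radius**2
    wall = WallProperties(A0=A0, E=E, h=h, phi_w=0.0)
    seg = VesselSegment(id="pulse", length=length,
                        n_elem=int(round(length / dx)), wall=wall, mu=0.0)
    c0 = float(reference_wave_speed(seg.wall)[0])
    x0, width = 0.25 * length, 0.05
    g = np.exp(-((seg.x - x0) ** 2) / (2.0 * width**2))
    seg.A = seg.wall.A0 * (1.0 + amplitude * g)
    c = wave_speed(seg.A, seg.wall)
    u = 4.0 * (c - reference_wave_speed(seg.wall))
    seg.Q = seg.A * u

    cfg = SchemeConfig(cfl_number=0.5, order=2, limiter="none")
    rest = ("state", (float(seg.wall.A0[0]), 0.0))
    t, times, xs = 0.0, [], []
    while t < 0.9 * (0.7 * length - x0) / c0:
        dt = stable_dt(seg, 0.5)
        advance(seg, dt, rest, rest, cfg, t=t)
        t += dt
        i = int(np.argmax(seg.A))
        if 1 <= i <= seg.n_elem - 2:
            d2 = seg.A[i - 1] - 2.0 * seg.A[i] + seg.A[i + 1]
            xp = seg.x[i] + 0.5 * seg.dx * (seg.A[i - 1] - seg.A[i + 1]) / d2
            if 0.35 * length < xp < 0.70 * length:
                times.append(t)
                xs.append(xp)
    speed = float(np.polyfit(times, xs, 1)[0])
    return {"c_measured": speed, "c0": c0,
            "rel_err": abs(speed - c0) / c0}


# ---------------------------------------------------------------------------
# Windkessel analytics
# ---------------------------------------------------------------------------

def windkessel_steady_check(Q_bar: float = 1.0e-4, Z: float = 1.6e7,
                            R: float = 1.6e8, C: float = 2.0e-10,
                            P_out: float = 1333.2,
                            duration: float = 5.0) -> dict:
    """Terminal pressure under constant inflow vs P_out + Q (R + Z).

    A frictionless vessel is driven with a constant inflow until the RCR
    terminal settles; the boundary pressure must reach the purely resistive
    steady state.
    """
    A0 = np.pi * 0.010**2
    wall = WallProperties(A0=A0, E=0.25e6, h=1.5e-3, phi_w=0.0)
    seg = VesselSegment(id="wk", length=0.1, n_elem=20, wall=wall, mu=0.0)
    term = WindkesselTerminal(Z=Z, R=R, C=C, P_out=P_out)
    inflow = InflowBC(kind="flow", t=np.array([0.0, 1.0]),
                      values=np.array([Q_bar, Q_bar]), period=2.0)
    net = ArterialNetwork({seg.id: seg}, terminals={seg.id: term},
                          root=seg.id, inflow=inflow,
                          scheme=SchemeConfig(cfl_number=0.8, limiter="none"))
    net.advance_interval(0.0, duration)
    P_end = float(seg.pressure()[-1])
    P_theory = P_out + Q_bar * (R + Z)
    return {"P_measured": P_end, "P_theory": P_theory,
            "rel_err": abs(P_end - P_theory) / P_theory}


def windkessel_decay_tau(R: float = 1.6e8, C: float = 1.0e-8,
                         P_out: float = 0.0, P0: float = 10000.0,
                         dt: float = 1e-4, n_tau: float = 2.0) -> dict:
    """Fitted capacitor decay time constant at Q = 0 vs the analytic R C."""
    term = WindkesselTerminal(Z=1e7, R=R, C=C, P_out=P_out, P_state=P0)
    tau = R * C
    n = int(n_tau * tau / dt)
    ps = np.empty(n)
    for i in range(n):
        term.P_state = term.capacitor_update(0.0, dt)
        ps[i] = term.P_state
    t = dt * np.arange(1, n + 1)
    slope = np.polyfit(t, np.log(ps - P_out), 1)[0]
    tau_fit = -1.0 / slope
    return {"tau_fit": float(tau_fit), "tau": tau,
            "rel_err": abs(tau_fit - tau) / tau}


# ---------------------------------------------------------------------------
# Junction conservation
# ---------------------------------------------------------------------------

def junction_conservation(generations: int = 2, cycles: int = 2,
                          dx: float = 5e-3) -> float:
    """Max junction mass defect |sum Q| / max |Q| over a standalone tree run."""
    net_dict = make_bifurcating_tree(generations=generations, dx=dx)
    net = build_network(net_dict)
    period = net.inflow.period
    run_standalone(net, None, cycles, period)
    return net.max_junction_defect


# ---------------------------------------------------------------------------
# Manufactured-solution convergence
# ---------------------------------------------------------------------------

def _manufactured(E: float = 0.25e6, radius: float = 0.010,
                  amp: float = 0.05, u_b: float = 0.5, length: float = 1.0):
    """Smooth periodic exact solution and its forcing for the 1D system."""
    A0 = np.pi * radius**2
    K, _ = stiffness_coefficients(E, 1.5e-3)
    rho = RHO_BLOOD
    c0 = np.sqrt(K / (2.0 * rho * np.sqrt(A0)))
    k = 2.0 * np.pi / length
    om = k * c0
    alpha = 11.0 / 10.0

    def exact(x, t):
        th = k * x - om * t
        return A0 * (1.0 + amp * np.sin(th)), A0 * u_b * np.cos(th)

    def forcing(x, t):
        th = k * x - om * t
        A = A0 * (1.0 + amp * np.sin(th))
        Q = A0 * u_b * np.cos(th)
        A_x = A0 * amp * k * np.cos(th)
        A_t = -A0 * amp * om * np.cos(th)
        Q_x = -A0 * u_b * k * np.sin(th)
        Q_t = A0 * u_b * om * np.sin(th)
        sA = A_t + Q_x
        conv_x = alpha * (2.0 * Q * Q_x * A - Q**2 * A_x) / A**2
        B_x = K * np.sqrt(A) / (2.0 * rho * A0) * A_x
        sQ = Q_t + conv_x + B_x
        return sA, sQ

    return A0, K, exact, forcing


def convergence_order(resolutions=(160, 320, 640), t_final: float = 0.05) -> dict:
    """Observed L2 order of accuracy on the manufactured periodic solution."""
    A0, K, exact, forcing = _manufactured()
    errors = []
    for n in resolutions:
        wall = WallProperties(A0=A0, E=0.25e6, h=1.5e-3, phi_w=0.0)
        seg = VesselSegment(id="mms", length=1.0, n_elem=n, wall=wall, mu=0.0)
        seg.A, seg.Q = exact(seg.x, 0.0)
        cfg = SchemeConfig(cfl_number=0.4, order=2, limiter="none")
        t = 0.0
        while t < t_final - 1e-13:
            dt = min(stable_dt(seg, 0.4), t_final - t)
            advance(seg, dt, "periodic", "periodic", cfg, t=t, forcing=forcing)
            t += dt
        A_ex, _ = exact(seg.x, t_final)
        errors.append(float(np.sqrt(np.mean((seg.A - A_ex) ** 2)) / A0))
    slopes = [np.log(errors[i] / errors[i + 1]) / np.log(2.0)
              for i in range(len(errors) - 1)]
    return {"errors": errors, "slopes": slopes,
            "order": float(np.mean(slopes))}


# ---------------------------------------------------------------------------
# Linear reflection at a stiffness discontinuity
# ---------------------------------------------------------------------------

def reflection_coefficient(E1: float = 0.25e6, E2: float = 1.0e6,
                           radius: float = 0.010, length: float = 1.5,
                           dx: float = 2.5e-3) -> dict:
    """Measured vs theoretical pressure reflection at an abrupt stiffness change.

    Linear theory: R = (Y1 - Y2) / (Y1 + Y2) with admittance Y = A0/(rho c0).
    A narrow Gaussian flow pulse is launched into vessel 1; incident and
    reflected pressure amplitudes are read at a probe upstream of the
    junction in disjoint time windows.
    """
    A0 = np.pi * radius**2
    walls = {}
    vessels = {}
    for vid, E in (("v1", E1), ("v2", E2)):
        wall = WallProperties(A0=A0, E=E, h=1.5e-3, phi_w=0.0)
        vessels[vid] = VesselSegment(id=vid, length=length,
                                     n_elem=int(round(length / dx)),
                                     wall=wall, mu=0.0)
        walls[vid] = wall
    c01 = float(reference_wave_speed(walls["v1"])[0])
    c02 = float(reference_wave_speed(walls["v2"])[0])
    Y1, Y2 = A0 / (RHO_BLOOD * c01), A0 / (RHO_BLOOD * c02)
    R_theory = (Y1 - Y2) / (Y1 + Y2)

    t0, s = 0.05, 0.010
    tt = np.linspace(0.0, 10.0, 4001)
    qq = 2e-6 * np.exp(-((tt - t0) ** 2) / (2.0 * s**2))
    inflow = InflowBC(kind="flow", t=tt, values=qq, period=20.0)
    term = WindkesselTerminal(Z=RHO_BLOOD * c02 / A0, R=1e9, C=1e-10, P_out=0.0)
    net = ArterialNetwork(vessels, junctions=[Junction("v1", ("v2",))],
                          terminals={"v2": term}, root="v1", inflow=inflow,
                          scheme=SchemeConfig(cfl_number=0.5, limiter="none"))

    probe_frac = 0.75
    x_probe = probe_frac * length
    t_inc = t0 + x_probe / c01
    t_ref = t0 + (2.0 * length - x_probe) / c01
    t_end = 0.5 * (t_ref + t0 + (2.0 * length - x_probe) / c01 + 0.3)
    t, dt = 0.0, 0.5 * stable_dt(vessels["v1"], 1.0)
    ts, ps = [], []
    while t < t_ref + 4.0 * s:
        net.step(t, dt)
        t += dt
        ts.append(t)
        ps.append(net.probe("v1", probe_frac)[0])
    ts = np.asarray(ts)
    ps = np.asarray(ps)
    win_inc = (ts > t_inc - 4 * s) & (ts < t_inc + 4 * s)
    win_ref = (ts > t_ref - 4 * s) & (ts < t_ref + 4 * s)
    amp_inc = float(np.max(np.abs(ps[win_inc])))
    amp_ref = float(np.max(np.abs(ps[win_ref])))
    R_measured = amp_ref / amp_inc * np.sign(R_theory)
    return {"R_measured": R_measured, "R_theory": R_theory,
            "rel_err": abs(R_measured - R_theory) / abs(R_theory)}


# ---------------------------------------------------------------------------
# Coupled studies
# ---------------------------------------------------------------------------

def scale_activation(act: ActiveStressParams, factor: float) -> ActiveStressParams:
    """Rescale all time constants of the active transient by ``factor``."""
    return ActiveStressParams(S_peak=act.S_peak, t_dur=act.t_dur * factor,
                              tau_c0=act.tau_c0 * factor,
                              tau_r=act.tau_r * factor, ld=act.ld,
                              ld_up=act.ld_up * factor, lambda0=act.lambda0,
                              t_emd=act.t_emd, t_a=act.t_a)


def coupled_run(net_dict: dict, dt3D: float = 1e-3, dt1D: float = 1e-4,
                beats: int = 3, init_cycles: int = 20,
                cavity=None, cfg: CouplingConfig | None = None,
                probes=()):
    """Initialise the network standalone, then run coupled heart beats.

    Returns ``(traces, beat_summaries, network)``.
    """
    net = build_network(net_dict)
    period = net.inflow.period
    run_standalone(net, None, init_cycles, period)
    if cfg is None:
        act = ActiveStressParams()
        if abs(period - 1.231) > 1e-9:
            act = scale_activation(act, period / 1.231)
        cfg = CouplingConfig(dt3D=dt3D, dt1D=dt1D, period=period,
                             t_emd=act.t_emd, t_dur=act.t_dur, probes=tuple(probes))
        if cavity is None:
            cavity = ElastanceCavity(activation=act)
    elif cavity is None:
        cavity = ElastanceCavity()
    net.reset_tallies()
    net.max_junction_defect = 0.0
    traces, beats_df = run_cardiac_cycle(cavity, net, cfg, n_beats=beats,
                                         valve=ValveModel())
    return traces, beats_df, net


def dt_robustness_study(beats: int = 3, dx: float = 12.5e-3,
                        init_cycles: int = 20) -> dict:
    """Coupled single-vessel runs over a grid of (dt3D, dt1D) pairs.

    The 200 mm vessel benchmark; the mesh is coarse enough that the largest
    sub-step respects the CFL bound.  Returns the cavity-pressure traces
    keyed by (dt3D, dt1D), interpolated onto a common time grid.
    """
    pairs = [(1e-3, 5e-4), (1e-3, 1e-4), (1e-3, 5e-5), (5e-4, 1e-4)]
    out = {}
    for dt3D, dt1D in pairs:
        net_dict = make_single_vessel(length=0.200, dx=dx)
        traces, _, _ = coupled_run(net_dict, dt3D=dt3D, dt1D=dt1D,
                                   beats=beats, init_cycles=init_cycles)
        out[(dt3D, dt1D)] = traces
    # common comparison grid: the coarsest coupling step
    t_grid = out[(1e-3, 1e-4)]["t"].to_numpy()
    traces_p = {}
    for key, tr in out.items():
        traces_p[key] = np.interp(t_grid, tr["t"], tr["p_cav"])
    return {"t": t_grid, "p_cav": traces_p, "raw": out}


def pairwise_linf(traces: dict) -> float:
    """Max pairwise relative L-infinity difference between traces."""
    keys = list(traces)
    worst = 0.0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = traces[keys[i]], traces[keys[j]]
            worst = max(worst, float(np.max(np.abs(a - b)) / np.max(np.abs(a))))
    return worst


def stiffening_study(E_values=(0.25e6, 0.50e6, 0.75e6), stenosis: bool = False,
                     beats: int = 3, dt1D: float = 1e-4,
                     init_cycles: int = 20, dx: float = 2.5e-3) -> dict:
    """PV-loop response of the 126 mm segment to aortic stiffening.

    With ``stenosis=True`` the vessel carries the 30% lumped narrowing at
    mid-length (run at a finer sub-step for stability of the sharper
    waveforms).
    """
    rows = {}
    for E in E_values:
        if stenosis:
            net_dict = make_stenotic_vessel(length=0.126, E=E, dx=dx)
        else:
            net_dict = make_single_vessel(length=0.126, E=E, dx=dx)
        traces, beats_df, net = coupled_run(net_dict, dt1D=dt1D, beats=beats,
                                            init_cycles=init_cycles)
        last = beats_df.iloc[-1]
        sv = last["EDV"] - last["ESV"]
        rows[E] = {
            "EDV": last["EDV"], "ESV": last["ESV"], "SV": sv,
            "EF": sv / last["EDV"],
            "p_cav_max": last["p_cav_max"], "p_root_max": last["p_root_max"],
            "pulse_pressure_root": last["pulse_pressure_root"],
            "max_newton_iters": int(traces["newton_iters"].max()),
            "max_residual": float(traces["residual"].abs().max()),
            "conservation_defect": net.conservation_defect(),
        }
    return rows


def tree_study(generations: int = 3, beats: int = 3, dt1D: float = 1e-4,
               init_cycles: int = 20, dx: float = 5e-3) -> dict:
    """Pulse-pressure amplification root -> periphery, young vs aged."""
    out = {}
    distal = "v0" + "L" * generations
    for profile in ("young", "aged"):
        net_dict = make_bifurcating_tree(generations=generations,
                                         age_profile=profile, dx=dx)
        probes = (("v0", 0.05), (distal, 0.9))
        traces, beats_df, net = coupled_run(net_dict, dt1D=dt1D, beats=beats,
                                            init_cycles=init_cycles,
                                            probes=probes)
        last_beat = traces["beat"].max()
        sel = traces[traces["beat"] == last_beat]
        pp_root = float(sel["p_v0_0.05"].max() - sel["p_v0_0.05"].min())
        key_d = f"p_{distal}_0.9"
        pp_dist = float(sel[key_d].max() - sel[key_d].min())
        out[profile] = {
            "pp_root": pp_root, "pp_distal": pp_dist,
            "amplification": pp_dist / pp_root,
            "max_junction_defect": net.max_junction_defect,
            "SV": float(beats_df.iloc[-1]["SV"]),
        }
    return out
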