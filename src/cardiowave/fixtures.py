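"""Generated study networks and analytic inflow waveforms.

Every experiment runs on a network generated here; there are no external
datasets.  Fixtures are returned as plain dictionaries in the network-file
schema of :mod:`cardiowave.io` (human-readable YAML with unit-suffixed
keys), so each can be written to disk, reloaded, and built into an
:class:`~cardiowave.solver1d.ArterialNetwork`.

Defaults emulate a human upper thoracic aorta: lumen radius 10 mm, wall
thickness 1.5 mm, baseline Young modulus 0.25 MPa (stiffened variants 0.50
and 0.75 MPa), blood density 1060 kg/m^3, dynamic viscosity 4 mPa s, wall
viscosity 1 kPa s.  Terminal RCR values are not standardised anywhere, so
documented physiological defaults are used: the characteristic impedance Z
matched to the attached vessel (rho c0 / A0), a total arterial resistance
of 1.8e8 Pa s/m^3 referenced to a venous pressure of 10 mmHg, and a
compliance of 1e-8 m^3/Pa (time constant R C ~ 1.6 s).
"""

from __future__ import annotations

import numpy as np

from .tube_law import MU_BLOOD, RHO_BLOOD, stiffness_coefficients

__all__ = [
    "make_single_vessel",
    "make_stenotic_vessel",
    "make_bifurcating_tree",
    "make_inflow_waveform",
    "DEFAULT_RADIUS",
    "DEFAULT_WALL_THICKNESS",
]

DEFAULT_RADIUS = 0.010          # m
DEFAULT_WALL_THICKNESS = 1.5e-3  # m
DEFAULT_PHI_W = 1.0e3           # wall viscosity, Pa s
DEFAULT_R_TOTAL = 1.8e8         # Z + R of a single-vessel terminal, Pa s/m^3
DEFAULT_C_WK = 1.0e-8           # terminal compliance, m^3/Pa
DEFAULT_P_OUT = 1333.2          # 10 mmHg venous reference, Pa
DEFAULT_DX = 2.5e-3             # element size, m


def _c0(E: float, h: float, radius: float, rho: float = RHO_BLOOD) -> float:
    A0 = np.pi * radius**2
    K, _ = stiffness_coefficients(E, h)
    return float(np.sqrt(K / (2.0 * rho * np.sqrt(A0))))


def _vessel_row(vid: str, length: float, E: float, radius_in: float,
                radius_out: float | None = None, h: float = DEFAULT_WALL_THICKNESS,
                phi_w: float = DEFAULT_PHI_W, dx: float = DEFAULT_DX) -> dict:
    if length <= 0.0:
        raise ValueError("vessel length must be positive")
    if E <= 0.0:
        raise ValueError("Young modulus must be positive")
    return {
        "id": vid,
        "length_m": float(length),
        "n_elem": max(2, int(round(length / dx))),
        "inlet_radius_m": float(radius_in),
        "outlet_radius_m": float(radius_out if radius_out is not None else radius_in),
        "E_Pa": float(E),
        "h_m": float(h),
        "phi_w_Pa_s": float(phi_w),
    }


def _terminal_row(vid: str, E: float, h: float, radius: float,
                  R_total: float = DEFAULT_R_TOTAL, C: float = DEFAULT_C_WK,
                  P_out: float = DEFAULT_P_OUT) -> dict:
    A0 = np.pi * radius**2
    Z = RHO_BLOOD * _c0(E, h, radius) / A0
    return {
        "vessel": vid,
        "Z_Pa_s_m3": float(Z),
        "R_Pa_s_m3": float(R_total - Z),
        "C_m3_Pa": float(C),
        "P_out_Pa": float(P_out),
    }


def make_inflow_waveform(period: float = 1.231, peak_flow: float = 4.0e-4,
                         systole_fraction: float = 0.30,
                         n_samples: int = 200) -> dict:
    """Analytic inflow: smooth squared-sine systolic pulse, zero diastole.

    Q(t) = peak_flow * sin^2(pi t / T_sys) for 0 <= t < T_sys, else 0, with
    T_sys = systole_fraction * period.  The stroke volume is exactly
    peak_flow * T_sys / 2 (the mean of sin^2 is 1/2), and the uniformly
    sampled table integrates to it exactly when systole_fraction *
    n_samples is an integer.  Default period 1.231 s matches a ~49 bpm
    baseline cycle; the bifurcating-tree case uses 0.800 s.
    """
    if period <= 0.0:
        raise ValueError("period must be positive")
    if not 0.0 < systole_fraction < 1.0:
        raise ValueError("systole_fraction must lie in (0, 1)")
    t_sys = systole_fraction * period
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    q = np.where(t < t_sys, peak_flow * np.sin(np.pi * t / t_sys) ** 2, 0.0)
    return {
        "kind": "flow",
        "period_s": float(period),
        "t_s": [float(v) for v in t],
        "values": [float(v) for v in q],
        "stroke_volume_m3": float(peak_flow * t_sys / 2.0),
        "peak_flow_m3_s": float(peak_flow),
    }


def make_single_vessel(length: float = 0.126, E: float = 0.25e6,
                       radius: float = DEFAULT_RADIUS,
                       h: float = DEFAULT_WALL_THICKNESS,
                       phi_w: float = DEFAULT_PHI_W,
                       dx: float = DEFAULT_DX,
                       period: float = 1.231,
                       peak_flow: float = 4.0e-4) -> dict:
    """Uniform aortic segment with an RCR terminal.

    ``length=0.200`` gives the time-step robustness benchmark geometry;
    ``length=0.126`` with ``E=0.25e6`` the baseline stiffening case.
    """
    vessel = _vessel_row("aorta", length, E, radius, radius, h, phi_w, dx)
    return {
        "blood": {"rho_kg_m3": RHO_BLOOD, "mu_Pa_s": MU_BLOOD},
        "vessels": [vessel],
        "junctions": [],
        "terminals": [_terminal_row("aorta", E, h, radius)],
        "stenoses": [],
        "inlet": {"vessel": "aorta",
                  "waveform": make_inflow_waveform(period, peak_flow)},
    }


def make_stenotic_vessel(length: float = 0.126, area_ratio: float = 0.70,
                         position_frac: float = 0.5, L_s: float = 0.01,
                         E: float = 0.25e6, **kwargs) -> dict:
    """Aortic segment with a lumped stenosis (default: 30% area reduction
    halfway along a 126 mm vessel) — the coarctation fixture."""
    if not 0.0 < area_ratio < 1.0:
        raise ValueError("area ratio must lie in (0, 1)")
    if not 0.0 < position_frac < 1.0:
        raise ValueError("stenosis position fraction must lie in (0, 1)")
    net = make_single_vessel(length=length, E=E, **kwargs)
    net["stenoses"] = [{
        "vessel": "aorta",
        "position_frac": float(position_frac),
        "area_ratio": float(area_ratio),
        "L_s_m": float(L_s),
        "Kt": 1.52,
        "Ku": 1.2,
    }]
    return net


#: multiplicative scalings applied by the aged profile
AGED_E_FACTOR = 2.0
AGED_R_FACTOR = 1.3


def make_bifurcating_tree(generations: int = 3, age_profile: str = "young",
                          root_radius: float = DEFAULT_RADIUS,
                          root_length: float = 0.10,
                          E_root: float = 0.25e6,
                          period: float = 0.800,
                          peak_flow: float = 4.0e-4,
                          dx: float = DEFAULT_DX) -> dict:
    """Symmetric bifurcating surrogate of a large systemic-artery network.

    Each generation halves into two daughters with radii scaled by
    2^(-1/2.3) (Murray-type, mildly area-increasing), lengths by 0.7, and
    stiffness increasing towards the periphery.  Every vessel tapers
    linearly to 95% of its inlet radius.  The aged profile scales all
    Young moduli by 2.0 and all terminal resistances by 1.3.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    if age_profile not in ("young", "aged"):
        raise ValueError(f"unknown age profile {age_profile!r}")
    e_scale = AGED_E_FACTOR if age_profile == "aged" else 1.0
    r_scale = AGED_R_FACTOR if age_profile == "aged" else 1.0

    vessels, junctions, terminals = [], [], []
    radius_ratio = 2.0 ** (-1.0 / 2.3)
    n_leaves = 2 ** generations
    R_leaf_total = DEFAULT_R_TOTAL * r_scale * n_leaves
    C_leaf = DEFAULT_C_WK / n_leaves

    def add(vid: str, gen: int, radius: float, length: float):
        E = E_root * e_scale * (1.0 + 0.3 * gen)
        vessels.append(_vessel_row(vid, length, E, radius, 0.95 * radius,
                                   dx=dx))
        if gen < generations:
            r_d = radius * radius_ratio
            l_d = length * 0.7
            children = (f"{vid}L", f"{vid}R")
            junctions.append({"parent": vid, "children": list(children)})
            for c in children:
                add(c, gen + 1, r_d, l_d)
        else:
            terminals.append(_terminal_row(vid, E, DEFAULT_WALL_THICKNESS,
                                           radius, R_total=R_leaf_total,
                                           C=C_leaf))

    add("v0", 0, root_radius, root_length)
    return {
        "blood": {"rho_kg_m3": RHO_BLOOD, "mu_Pa_s": MU_BLOOD},
        "vessels": vessels,
        "junctions": junctions,
        "terminals": terminals,
        "stenoses": [],
        "inlet": {"vessel": "v0",
                  "waveform": make_inflow_waveform(period, peak_flow)},
    }
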