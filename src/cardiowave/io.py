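"""File formats and model construction.

Networks and run configurations are human-readable YAML with explicit unit
suffixes in the keys; waveforms may be embedded in the network file or
referenced as two-column delimited text.  Writing is canonical (sorted
keys, fixed float formatting via YAML), so write -> read -> write is
byte-identical.  All quantities are SI; any mmHg/mL presentation happens
only in reporting code.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cavity import ActiveStressParams, ElastanceCavity, GuccioneParams, SphereCavity
from .coupling import CouplingConfig, ValveModel
from .fixtures import (
    make_bifurcating_tree,
    make_single_vessel,
    make_stenotic_vessel,
)
from .network_bc import InflowBC, Junction, StenosisElement, WindkesselTerminal
from .solver1d import ArterialNetwork, SchemeConfig, VesselSegment
from .tube_law import WallProperties

__all__ = [
    "write_network",
    "read_network",
    "validate_network",
    "build_network",
    "write_waveform",
    "read_waveform",
    "read_off_surface",
    "RunConfig",
    "read_config",
    "make_fixture",
    "NetworkFileError",
]

FIXTURES = {
    "single-vessel": make_single_vessel,
    "stability-vessel": lambda **kw: make_single_vessel(length=0.200, **kw),
    "stenotic-vessel": make_stenotic_vessel,
    "bifurcating-tree": make_bifurcating_tree,
}


class NetworkFileError(ValueError):
    """Raised for malformed network or configuration files."""


# ---------------------------------------------------------------------------
# Network files
# ---------------------------------------------------------------------------

_VESSEL_KEYS = {"id", "length_m", "n_elem", "inlet_radius_m", "outlet_radius_m",
                "E_Pa", "h_m", "phi_w_Pa_s"}
_TERMINAL_KEYS = {"vessel", "Z_Pa_s_m3", "R_Pa_s_m3", "C_m3_Pa", "P_out_Pa"}
_STENOSIS_KEYS = {"vessel", "position_frac", "area_ratio", "L_s_m", "Kv", "Kt", "Ku"}


def validate_network(net: dict, base_dir: str = ".") -> None:
    """Check the schema and the tree invariants of a network description."""
    for section in ("blood", "vessels", "terminals", "inlet"):
        if section not in net:
            raise NetworkFileError(f"missing section {section!r}")
    ids = [v["id"] for v in net["vessels"]]
    if len(set(ids)) != len(ids):
        raise NetworkFileError("duplicate vessel ids")
    known = set(ids)
    for v in net["vessels"]:
        missing = _VESSEL_KEYS - set(v)
        if missing:
            raise NetworkFileError(f"vessel {v.get('id')!r} missing {sorted(missing)}")
        if v["length_m"] <= 0 or v["n_elem"] < 2:
            raise NetworkFileError(f"vessel {v['id']!r}: bad geometry")
        if v["E_Pa"] <= 0 or v["h_m"] <= 0:
            raise NetworkFileError(f"vessel {v['id']!r}: bad wall properties")
    child_ids: set[str] = set()
    for j in net.get("junctions", []):
        if j["parent"] not in known:
            raise NetworkFileError(f"junction parent {j['parent']!r} unknown")
        for c in j["children"]:
            if c not in known:
                raise NetworkFileError(f"junction child {c!r} unknown")
            if c in child_ids:
                raise NetworkFileError(f"vessel {c!r} has two parents")
            child_ids.add(c)
    for t in net["terminals"]:
        missing = _TERMINAL_KEYS - set(t)
        if missing:
            raise NetworkFileError(f"terminal {t.get('vessel')!r} missing {sorted(missing)}")
        if t["vessel"] not in known:
            raise NetworkFileError(f"terminal vessel {t['vessel']!r} unknown")
        if t["R_Pa_s_m3"] <= 0:
            raise NetworkFileError(f"terminal {t['vessel']!r}: R must be positive")
    for s in net.get("stenoses", []):
        extra = set(s) - _STENOSIS_KEYS
        if extra:
            raise NetworkFileError(f"stenosis on {s.get('vessel')!r}: unknown keys {sorted(extra)}")
        if s["vessel"] not in known:
            raise NetworkFileError(f"stenosis vessel {s['vessel']!r} unknown")
        if not 0.0 < s["area_ratio"] < 1.0:
            raise NetworkFileError("stenosis area ratio must lie in (0, 1)")
        if not 0.0 < s["position_frac"] < 1.0:
            raise NetworkFileError("stenosis position fraction must lie in (0, 1)")
    inlet = net["inlet"]
    if inlet["vessel"] not in known:
        raise NetworkFileError(f"inlet vessel {inlet['vessel']!r} unknown")
    if "waveform" not in inlet and "waveform_file" not in inlet:
        raise NetworkFileError("inlet needs 'waveform' or 'waveform_file'")
    if "waveform_file" in inlet:
        path = os.path.join(base_dir, inlet["waveform_file"])
        if not os.path.exists(path):
            raise NetworkFileError(f"waveform file {path!r} does not exist")
    # every leaf (non-parent) vessel must carry exactly one terminal
    parents = {j["parent"] for j in net.get("junctions", [])}
    term_ids = [t["vessel"] for t in net["terminals"]]
    if len(set(term_ids)) != len(term_ids):
        raise NetworkFileError("duplicate terminals")
    for vid in known:
        if vid not in parents and vid not in term_ids:
            raise NetworkFileError(f"leaf vessel {vid!r} has no terminal")


def write_network(net: dict, path: str) -> None:
    """Write a network description in canonical YAML form."""
    validate_network(net, base_dir=os.path.dirname(path) or ".")
    with open(path, "w") as fh:
        yaml.safe_dump(net, fh, sort_keys=True, default_flow_style=False)


def read_network(path: str) -> dict:
    with open(path) as fh:
        net = yaml.safe_load(fh)
    if not isinstance(net, dict):
        raise NetworkFileError(f"{path!r} does not contain a network mapping")
    validate_network(net, base_dir=os.path.dirname(path) or ".")
    return net


def write_waveform(wave: dict, path: str) -> None:
    """Waveform table as two-column delimited text (t_s, value)."""
    df = pd.DataFrame({"t_s": wave["t_s"], "value": wave["values"]})
    with open(path, "w") as fh:
        fh.write(f"# kind={wave['kind']} period_s={wave['period_s']}\n")
        df.to_csv(fh, index=False)


def read_off_surface(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read an ASCII OFF triangle mesh (for divergence-theorem volumes).

    Returns ``(vertices, faces)`` suitable for
    :func:`cardiowave.cavity.surface_volume`.
    """
    with open(path) as fh:
        tokens = [t for line in fh
                  for t in [line.split("#", 1)[0].strip()] if t]
    if not tokens or tokens[0].split()[0] != "OFF":
        raise NetworkFileError(f"{path!r} is not an OFF surface file")
    flat = " ".join(tokens).split()
    idx = 1
    nv, nf = int(flat[idx]), int(flat[idx + 1])
    idx += 3  # skip edge count
    verts = np.array(flat[idx:idx + 3 * nv], dtype=float).reshape(nv, 3)
    idx += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(flat[idx])
        if k != 3:
            raise NetworkFileError("only triangle faces are supported")
        faces.append([int(flat[idx + 1]), int(flat[idx + 2]), int(flat[idx + 3])])
        idx += 1 + k
    return verts, np.array(faces, dtype=int)


def read_waveform(path: str) -> dict:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh)
    return {"kind": meta["kind"], "period_s": float(meta["period_s"]),
            "t_s": df["t_s"].tolist(), "values": df["value"].tolist()}


# ---------------------------------------------------------------------------
# Building the in-memory model
# ---------------------------------------------------------------------------

def _build_vessel(row: dict, blood: dict, suffix: str = "",
                  x_range: tuple[float, float] = (0.0, 1.0),
                  n_elem: int | None = None) -> VesselSegment:
    n = n_elem if n_elem is not None else int(row["n_elem"])
    length = row["length_m"] * (x_range[1] - x_range[0])
    # linear radius taper sampled at element centroids
    s = x_range[0] + (np.arange(n) + 0.5) / n * (x_range[1] - x_range[0])
    radius = row["inlet_radius_m"] + (row["outlet_radius_m"] - row["inlet_radius_m"]) * s
    wall = WallProperties(A0=np.pi * radius**2, E=row["E_Pa"], h=row["h_m"],
                          phi_w=row["phi_w_Pa_s"], rho=blood["rho_kg_m3"])
    return VesselSegment(id=row["id"] + suffix, length=length, n_elem=n,
                         wall=wall, mu=blood["mu_Pa_s"])


def build_network(net: dict, scheme: SchemeConfig | None = None,
                  base_dir: str = ".") -> ArterialNetwork:
    """Construct an :class:`ArterialNetwork` from a network description.

    A vessel carrying a stenosis row is split at the stenosis position into
    two sub-segments joined by the lumped element; junction/terminal
    references to the host id are rewired to the appropriate half.
    """
    validate_network(net, base_dir=base_dir)
    blood = net["blood"]
    sten_by_vessel = {s["vessel"]: s for s in net.get("stenoses", [])}
    vessels: dict[str, VesselSegment] = {}
    stenoses = []
    inlet_map: dict[str, str] = {}    # original id -> id of the inlet-side piece
    outlet_map: dict[str, str] = {}

    for row in net["vessels"]:
        vid = row["id"]
        if vid in sten_by_vessel:
            s = sten_by_vessel[vid]
            frac = s["position_frac"]
            n = int(row["n_elem"])
            n_a = max(2, int(round(frac * n)))
            n_b = max(2, n - n_a)
            va = _build_vessel(row, blood, ":a", (0.0, frac), n_a)
            vb = _build_vessel(row, blood, ":b", (frac, 1.0), n_b)
            vessels[va.id] = va
            vessels[vb.id] = vb
            r_here = row["inlet_radius_m"] + (row["outlet_radius_m"]
                                              - row["inlet_radius_m"]) * frac
            elem = StenosisElement(area_ratio=s["area_ratio"], L_s=s["L_s_m"],
                                   A0=np.pi * r_here**2,
                                   Kv=s.get("Kv"), Kt=s.get("Kt", 1.52),
                                   Ku=s.get("Ku", 1.2))
            stenoses.append((va.id, vb.id, elem))
            inlet_map[vid], outlet_map[vid] = va.id, vb.id
        else:
            v = _build_vessel(row, blood)
            vessels[vid] = v
            inlet_map[vid] = outlet_map[vid] = vid

    junctions = [Junction(parent=outlet_map[j["parent"]],
                          children=tuple(inlet_map[c] for c in j["children"]))
                 for j in net.get("junctions", [])]
    terminals = {outlet_map[t["vessel"]]: WindkesselTerminal(
        Z=t["Z_Pa_s_m3"], R=t["R_Pa_s_m3"], C=t["C_m3_Pa"], P_out=t["P_out_Pa"])
        for t in net["terminals"]}

    inlet = net["inlet"]
    wave = (inlet["waveform"] if "waveform" in inlet
            else read_waveform(os.path.join(base_dir, inlet["waveform_file"])))
    inflow = InflowBC(kind=wave["kind"], t=np.asarray(wave["t_s"]),
                      values=np.asarray(wave["values"]),
                      period=wave["period_s"])
    return ArterialNetwork(vessels=vessels, junctions=junctions,
                           terminals=terminals, stenoses=stenoses,
                           root=inlet_map[inlet["vessel"]], inflow=inflow,
                           scheme=scheme)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "network_file", "beats", "init_cycles", "seed", "output_dir",
    "scheme", "coupling", "cavity", "valve", "probes",
}
_SCHEME_KEYS = {"dt1D_s", "cfl", "order", "limiter"}
_COUPLING_KEYS = {"k_max", "tol_abs", "V_scale_m3", "fd_eps_Pa", "dt3D_s",
                  "period_s", "p_preload_Pa", "t_activation_s", "t_emd_s",
                  "t_dur_s"}
_CAVITY_KEYS = {"model", "V_rest_m3", "E_min_Pa_m3", "E_max_Pa_m3",
                "R_i_m", "R_o_m", "guccione", "activation", "n_quad"}
_VALVE_KEYS = {"B_Pa_s2_m6", "L_Pa_s2_m3"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one coupled simulation."""

    network_file: str
    beats: int = 3
    init_cycles: int = 20
    seed: int = 0
    output_dir: str = "output"
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    cavity_kind: str = "elastance"
    cavity_params: dict = field(default_factory=dict)
    valve: ValveModel = field(default_factory=ValveModel)
    probes: tuple = ()

    def make_cavity(self):
        p = dict(self.cavity_params)
        act = ActiveStressParams(**p.pop("activation", {}))
        if self.cavity_kind == "elastance":
            return ElastanceCavity(V_rest=p.get("V_rest_m3", 10e-6),
                                   E_min=p.get("E_min_Pa_m3", 1.2e7),
                                   E_max=p.get("E_max_Pa_m3", 2.7e8),
                                   activation=act)
        if self.cavity_kind == "sphere":
            guc = GuccioneParams(**p.pop("guccione", {}))
            return SphereCavity(R_i=p.get("R_i_m", 0.025),
                                R_o=p.get("R_o_m", 0.035),
                                guccione=guc, activation=act,
                                n_quad=p.get("n_quad", 8))
        raise NetworkFileError(f"unknown cavity model {self.cavity_kind!r}")


def _check_keys(section: dict, allowed: set, what: str) -> None:
    extra = set(section) - allowed
    if extra:
        raise NetworkFileError(f"unknown keys in {what}: {sorted(extra)}")


def read_config(path: str) -> RunConfig:
    """Parse and validate a run-configuration YAML file.

    Unknown keys are rejected outright so silent typos cannot change a
    simulation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _CONFIG_KEYS, "config")
    if "network_file" not in raw:
        raise NetworkFileError("config must name a network_file")

    sch = raw.get("scheme", {})
    _check_keys(sch, _SCHEME_KEYS, "scheme")
    scheme = SchemeConfig(dt=sch.get("dt1D_s"), cfl_number=sch.get("cfl", 0.9),
                          order=sch.get("order", 2),
                          limiter=sch.get("limiter", "minmod"))

    cp = raw.get("coupling", {})
    _check_keys(cp, _COUPLING_KEYS, "coupling")
    coupling = CouplingConfig(
        k_max=cp.get("k_max", 10), tol_abs=cp.get("tol_abs", 1e-6),
        V_scale=cp.get("V_scale_m3", 1e-6), fd_eps=cp.get("fd_eps_Pa", 10.0),
        dt3D=cp.get("dt3D_s", 1e-3),
        dt1D=sch.get("dt1D_s", 1e-4) or 1e-4,
        period=cp.get("period_s", 1.231),
        p_preload=cp.get("p_preload_Pa", 1333.2),
        t_activation=cp.get("t_activation_s", 0.0),
        t_emd=cp.get("t_emd_s", 0.015), t_dur=cp.get("t_dur_s", 0.575),
        probes=tuple(tuple(p) for p in raw.get("probes", [])))

    cav = dict(raw.get("cavity", {}))
    _check_keys(cav, _CAVITY_KEYS, "cavity")
    kind = cav.pop("model", "elastance")

    vv = raw.get("valve", {})
    _check_keys(vv, _VALVE_KEYS, "valve")
    valve = ValveModel(B=vv.get("B_Pa_s2_m6", 2.0e9),
                       L_in=vv.get("L_Pa_s2_m3", 6.0e4))

    return RunConfig(network_file=raw["network_file"],
                     beats=raw.get("beats", 3),
                     init_cycles=raw.get("init_cycles", 20),
                     seed=raw.get("seed", 0),
                     output_dir=raw.get("output_dir", "output"),
                     scheme=scheme, coupling=coupling,
                     cavity_kind=kind, cavity_params=cav, valve=valve,
                     probes=coupling.probes)


def make_fixture(name: str, **kwargs) -> dict:
    """Generate a named fixture network (see :data:`FIXTURES`)."""
    if name not in FIXTURES:
        raise NetworkFileError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return FIXTURES[name](**kwargs)
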