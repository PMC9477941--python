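"""Fixture generators, network files, run configuration, and the CLI."""

import os

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from cardiowave import cli, io
from cardiowave.fixtures import (
    make_bifurcating_tree,
    make_inflow_waveform,
    make_single_vessel,
    make_stenotic_vessel,
)


class TestWaveform:
    def test_default_period_is_baseline_cycle_time(self):
        assert make_inflow_waveform()["period_s"] == 1.231

    def test_table_integral_matches_documented_stroke_volume(self):
        w = make_inflow_waveform()
        dt = w["period_s"] / len(w["t_s"])
        integral = dt * sum(w["values"])
        assert integral == pytest.approx(w["stroke_volume_m3"], rel=1e-10)

    def test_peak_of_table_equals_peak_flow(self):
        w = make_inflow_waveform(peak_flow=3.3e-4)
        assert max(w["values"]) == pytest.approx(3.3e-4, rel=1e-12)

    def test_tree_cycle_period(self):
        w = make_inflow_waveform(period=0.8)
        assert w["period_s"] == 0.8


class TestFixtures:
    def test_stability_fixture_geometry(self):
        net = make_single_vessel(length=0.200)
        assert net["vessels"][0]["length_m"] == 0.200

    def test_baseline_fixture_geometry(self):
        net = make_single_vessel(length=0.126, E=0.25e6)
        v = net["vessels"][0]
        assert v["length_m"] == 0.126 and v["E_Pa"] == 0.25e6

    def test_zero_modulus_rejected(self):
        with pytest.raises(ValueError):
            make_single_vessel(E=0.0)

    def test_stenosis_defaults_are_thirty_percent_midway(self):
        net = make_stenotic_vessel()
        s = net["stenoses"][0]
        assert s["area_ratio"] == 0.70 and s["position_frac"] == 0.5

    def test_stenosis_position_bounds(self):
        with pytest.raises(ValueError):
            make_stenotic_vessel(position_frac=1.5)

    def test_near_unity_ratio_degenerates_to_plain_vessel(self):
        """area ratio -> 1: the lumped element's loss terms vanish and the
        simulation matches the unstenosed vessel."""
        from cardiowave.solver1d import run_standalone
        nets = {}
        for name, d in (("plain", make_single_vessel(length=0.126, dx=12.5e-3)),
                        ("sten", make_stenotic_vessel(length=0.126,
                                                      area_ratio=0.9999,
                                                      dx=12.5e-3))):
            net = io.build_network(d)
            run_standalone(net, None, 2, net.inflow.period)
            nets[name] = net.inlet_pressure()
        assert nets["sten"] == pytest.approx(nets["plain"], rel=1e-3)

    @pytest.mark.parametrize("generations", [1, 2, 3, 4, 5])
    def test_tree_valid_across_generations(self, generations):
        net = make_bifurcating_tree(generations=generations)
        io.validate_network(net)
        assert len(net["vessels"]) == 2 ** (generations + 1) - 1
        assert len(net["terminals"]) == 2 ** generations

    def test_minimal_tree_is_three_vessels(self):
        net = make_bifurcating_tree(generations=1)
        assert len(net["vessels"]) == 3
        assert len(net["junctions"]) == 1


class TestNetworkFiles:
    def test_round_trip_is_byte_identical(self, tmp_path):
        net = make_bifurcating_tree(generations=2)
        p1 = tmp_path / "net1.yaml"
        p2 = tmp_path / "net2.yaml"
        io.write_network(net, str(p1))
        io.write_network(io.read_network(str(p1)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_leaf_without_terminal_rejected(self):
        net = make_single_vessel()
        net["terminals"] = []
        with pytest.raises(io.NetworkFileError, match="terminal"):
            io.validate_network(net)

    def test_duplicate_parent_rejected(self):
        net = make_bifurcating_tree(generations=2)
        net["junctions"].append({"parent": "v0", "children": ["v0LL"]})
        with pytest.raises(io.NetworkFileError, match="two parents"):
            io.validate_network(net)

    def test_missing_waveform_file_rejected(self, tmp_path):
        net = make_single_vessel()
        del net["inlet"]["waveform"]
        net["inlet"]["waveform_file"] = "nope.csv"
        with pytest.raises(io.NetworkFileError, match="does not exist"):
            io.validate_network(net, base_dir=str(tmp_path))

    def test_waveform_file_round_trip(self, tmp_path):
        w = make_inflow_waveform()
        path = tmp_path / "wave.csv"
        io.write_waveform(w, str(path))
        back = io.read_waveform(str(path))
        assert back["period_s"] == w["period_s"]
        np.testing.assert_allclose(back["values"], w["values"])

    def test_off_surface_reader_feeds_volume(self, tmp_path):
        """A tetrahedron in OFF format round-trips into the exact
        divergence-theorem volume (1/6 for the unit corner tet)."""
        off = ("OFF\n4 4 6\n"
               "0 0 0\n1 0 0\n0 1 0\n0 0 1\n"
               "3 0 2 1\n3 0 1 3\n3 0 3 2\n3 1 2 3\n")
        path = tmp_path / "tet.off"
        path.write_text(off)
        from cardiowave.cavity import surface_volume
        v, f = io.read_off_surface(str(path))
        assert surface_volume(v, f) == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_stenotic_vessel_is_split_on_build(self):
        net = io.build_network(make_stenotic_vessel())
        assert set(net.vessels) == {"aorta:a", "aorta:b"}
        assert len(net.stenoses) == 1
        assert net.root == "aorta:a"


class TestRunConfig:
    def write_cfg(self, tmp_path, extra=""):
        io.write_network(make_single_vessel(dx=12.5e-3),
                         str(tmp_path / "net.yaml"))
        cfg = f"""
network_file: net.yaml
beats: 0
init_cycles: 1
scheme:
  dt1D_s: 5.0e-4
{extra}"""
        path = tmp_path / "run.yaml"
        path.write_text(cfg)
        return str(path)

    def test_parse_defaults(self, tmp_path):
        cfg = io.read_config(self.write_cfg(tmp_path))
        assert cfg.beats == 0
        assert cfg.coupling.k_max == 10
        assert cfg.coupling.tol_abs == 1e-6
        assert cfg.cavity_kind == "elastance"

    def test_unknown_keys_rejected(self, tmp_path):
        with pytest.raises(io.NetworkFileError, match="unknown keys"):
            io.read_config(self.write_cfg(tmp_path, extra="typo_key: 3\n"))

    def test_cavity_models_constructible(self, tmp_path):
        cfg = io.read_config(self.write_cfg(tmp_path))
        from cardiowave.cavity import ElastanceCavity, SphereCavity
        assert isinstance(cfg.make_cavity(), ElastanceCavity)
        cfg.cavity_kind = "sphere"
        assert isinstance(cfg.make_cavity(), SphereCavity)


class TestCli:
    def test_make_fixture_writes_valid_network(self, tmp_path):
        out = str(tmp_path / "net.yaml")
        res = CliRunner().invoke(cli.main,
                                 ["make-fixture", "single-vessel", "-o", out])
        assert res.exit_code == 0, res.output
        io.read_network(out)

    def test_unknown_fixture_is_bad_input(self, tmp_path):
        res = CliRunner().invoke(cli.main, ["make-fixture", "warp-drive"])
        assert res.exit_code == 2

    def test_run_initialisation_only(self, tmp_path):
        io.write_network(make_single_vessel(dx=12.5e-3),
                         str(tmp_path / "net.yaml"))
        (tmp_path / "run.yaml").write_text(
            "network_file: net.yaml\nbeats: 0\ninit_cycles: 2\n"
            f"output_dir: {tmp_path / 'out'}\n")
        res = CliRunner().invoke(cli.main, ["run", str(tmp_path / "run.yaml")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "standalone_inlet_pressure.csv").exists()

    def test_coupled_run_is_deterministic(self, tmp_path):
        """Identical config twice: bit-identical trace files."""
        io.write_network(make_single_vessel(dx=12.5e-3),
                         str(tmp_path / "net.yaml"))
        outputs = []
        for tag in ("a", "b"):
            out = tmp_path / f"out_{tag}"
            (tmp_path / f"run_{tag}.yaml").write_text(
                "network_file: net.yaml\nbeats: 1\ninit_cycles: 2\n"
                "scheme: {dt1D_s: 5.0e-4}\n"
                f"output_dir: {out}\n")
            res = CliRunner().invoke(cli.main,
                                     ["run", str(tmp_path / f"run_{tag}.yaml")])
            assert res.exit_code == 0, res.output
            outputs.append((out / "traces.csv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_missing_config_is_bad_input(self):
        res = CliRunner().invoke(cli.main, ["run", "/nonexistent.yaml"])
        assert res.exit_code == 2
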