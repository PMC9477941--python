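"""Heart-vessel coupling: valve diode, vascular volume trials, compliance,
the reduced Newton solve, isovolumetric phases, and full cardiac cycles."""

import numpy as np
import pytest

from cardiowave import benchmarks
from cardiowave.cavity import ActiveStressParams, ElastanceCavity
from cardiowave.coupling import (
    Afterload,
    CouplingConfig,
    NetworkAfterload,
    ValveModel,
    coupling_compliance,
    isovolumetric_step,
    newton_coupled_step,
    run_cardiac_cycle,
    valve_flow,
    vascular_volume,
)
from cardiowave.io import build_network
from cardiowave.solver1d import run_standalone

MMHG = 133.322


class TestValve:
    def test_closed_diode_blocks_reverse_gradient(self):
        v = ValveModel()
        assert valve_flow(5000.0, 9000.0, v, 1e-4) == 0.0
        assert not v.is_open

    def test_algebraic_bernoulli_limit(self):
        """L = 0: q = sqrt(dp / B) immediately."""
        v = ValveModel(B=2e9, L_in=0.0)
        q = valve_flow(11000.0, 10000.0, v, 1e-4)
        assert q == pytest.approx(np.sqrt(1000.0 / 2e9), rel=1e-12)

    def test_flow_decays_continuously_to_closure(self):
        """Ramping the gradient across zero: q falls smoothly to 0 and the
        valve shuts without oscillation."""
        v = ValveModel()
        dt = 1e-3
        valve_flow(12000.0, 10000.0, v, dt)
        qs = [v.q]
        for dp in np.linspace(1500.0, -3000.0, 40):
            qs.append(valve_flow(10000.0 + dp, 10000.0, v, dt))
        qs = np.array(qs)
        assert qs[-1] == 0.0 and not v.is_open
        assert np.all(qs >= 0.0)
        # once closed it stays closed within the step
        assert valve_flow(9000.0, 10000.0, v, dt) == 0.0


class LinearAfterload(Afterload):
    """Test double: V_CS = a - b p, exactly linear in the trial pressure."""

    def __init__(self, a, b):
        self.a, self.b = a, b

    def begin_step(self, t, V_cav):
        pass

    def volume(self, p):
        return self.a - self.b * p

    def commit(self, p):
        return {}


class TestNewtonOnLinearSurrogate:
    def test_compliance_exact_on_linear_afterload(self):
        aft = LinearAfterload(a=1.5e-4, b=2e-12)
        assert coupling_compliance(5000.0, aft, fd_eps=10.0) == pytest.approx(
            -2e-12, rel=1e-9)

    def test_affine_problem_converges_in_one_update(self):
        """Elastance cavity (linear V(p)) + linear afterload: Newton is
        exact after a single update."""
        cav = ElastanceCavity()
        aft = LinearAfterload(a=1.5e-4, b=2e-12)
        cfg = CouplingConfig()
        p, V, iters, res = newton_coupled_step(4000.0, 5.0, cav, aft, cfg)
        assert iters == 1
        assert abs(res) < cfg.tol_abs * cfg.V_scale
        assert cav.volume(p, 5.0) == pytest.approx(aft.volume(p), abs=1e-15)


@pytest.fixture(scope="module")
def primed_afterload():
    """A small initialised network + open valve ready for trial runs."""
    net = build_network(benchmarks.make_single_vessel(length=0.126, dx=5e-3))
    run_standalone(net, None, 5, net.inflow.period)
    valve = ValveModel()
    valve.is_open = True
    valve.q = 1e-4
    aft = NetworkAfterload(net, valve, dt3D=1e-3, dt1D=1e-4)
    p_root = net.inlet_pressure()
    aft.begin_step(0.0, 120e-6)
    return aft, p_root


class TestVascularVolume:
    def test_trials_are_bit_identical(self, primed_afterload):
        aft, p_root = primed_afterload
        v1 = vascular_volume(p_root + 2000.0, aft)
        v2 = vascular_volume(p_root + 2000.0, aft)
        assert v1 == v2

    def test_higher_pressure_ejects_more(self, primed_afterload):
        aft, p_root = primed_afterload
        v_lo = aft.volume(p_root + 1000.0)
        v_hi = aft.volume(p_root + 4000.0)
        assert v_hi < v_lo

    def test_closed_valve_keeps_volume(self, primed_afterload):
        aft, p_root = primed_afterload
        was = aft.valve.state()
        aft.valve.restore((False, 0.0))
        try:
            assert aft.volume(p_root - 5000.0) == 120e-6
        finally:
            aft.valve.restore(was)

    def test_compliance_richardson_stable(self, primed_afterload):
        """dV_CS/dp estimates at eps and eps/2 agree within 1%."""
        aft, p_root = primed_afterload
        p = p_root + 2000.0
        d1 = aft.compliance(p, 20.0)
        d2 = aft.compliance(p, 10.0)
        assert d1 == pytest.approx(d2, rel=0.01)


class TestIsovolumetric:
    def test_stationary_without_activation(self):
        cav = ElastanceCavity(activation=ActiveStressParams(S_peak=0.0))
        V0 = cav.volume(2000.0, 0.1)
        p, iters, res = isovolumetric_step(2000.0, 0.2, V0,
                                           cav, CouplingConfig())
        assert p == pytest.approx(2000.0, abs=1e-9)

    def test_pressure_rises_with_active_stress(self):
        cav = ElastanceCavity()
        cfg = CouplingConfig()
        V0 = cav.volume(1333.0, 0.0)
        t, p = 0.05, 1333.0
        ps = []
        while t < 0.20:
            p, _, _ = isovolumetric_step(p, t, V0, cav, cfg)
            ps.append(p)
            t += cfg.dt3D
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] > 3 * ps[0]

    def test_volume_constraint_enforced(self, baseline_run):
        """During isovolumetric phases the committed volume never drifts."""
        tr = baseline_run["traces"]
        for phase in ("isovol_contraction", "isovol_relaxation"):
            seg = tr[tr["phase"] == phase]
            for beat, grp in seg.groupby("beat"):
                V = grp["V_cav"].to_numpy()
                if len(V) > 1:
                    assert np.max(np.abs(V - V[0])) / V[0] < 1e-6


class TestCardiacCycle:
    def test_zero_active_stress_never_ejects(self):
        """No contraction: the cavity stays on the passive filling curve."""
        act = ActiveStressParams(S_peak=0.0)
        cav = ElastanceCavity(activation=act)
        net = build_network(benchmarks.make_single_vessel(length=0.126,
                                                          dx=12.5e-3))
        run_standalone(net, None, 3, net.inflow.period)
        cfg = CouplingConfig(dt1D=5e-4, period=1.231)
        traces, beats = run_cardiac_cycle(cav, net, cfg, n_beats=1)
        assert "ejection" not in set(traces["phase"])
        expected = cav.volume(cfg.p_preload, 5.0)
        sel = traces[traces["phase"] == "filling"]
        np.testing.assert_allclose(sel["V_cav"], expected, rtol=1e-9)

    def test_pv_loop_closes(self, baseline_run):
        """After three beats the loop is periodic: EDV changes < 1%."""
        beats = baseline_run["beats"]
        assert abs(beats["EDV"].iloc[-1] - beats["EDV"].iloc[-2]) \
            / beats["EDV"].iloc[-1] < 0.01
        assert abs(beats["SV"].iloc[-1] - beats["SV"].iloc[-2]) \
            / beats["SV"].iloc[-1] < 0.05

    def test_stroke_volume_equals_ejected_charge(self, baseline_run):
        """EDV - ESV must equal the integral of valve flow over ejection."""
        beats = baseline_run["beats"]
        for _, row in beats.iterrows():
            assert row["SV"] == pytest.approx(row["stroke_integral"],
                                              rel=1e-6)

    def test_physiological_baseline_indices(self, baseline_run):
        beats = baseline_run["beats"]
        last = beats.iloc[-1]
        assert 100e-6 < last["EDV"] < 150e-6
        assert 0.4 < last["EF"] < 0.7
        assert 100 < last["p_root_max"] / MMHG < 140
        assert 50 < last["p_root_min"] / MMHG < 90

    def test_phase_sequence_is_physiological(self, baseline_run):
        """Within each full beat the machine visits filling -> IVC ->
        ejection -> IVR in order."""
        tr = baseline_run["traces"]
        order = {"filling": 0, "isovol_contraction": 1, "ejection": 2,
                 "isovol_relaxation": 3}
        for beat, grp in tr.groupby("beat"):
            codes = [order[p] for p in grp["phase"]]
            # strip the leading filling tail, then codes must be sorted
            # until the final return to filling
            seq = []
            for c in codes:
                if not seq or c != seq[-1]:
                    seq.append(c)
            assert seq in ([0, 1, 2, 3, 0], [1, 2, 3, 0], [0, 1, 2, 3]), seq
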