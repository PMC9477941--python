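"""Cardiac cavity models: active transient, Guccione law, sphere and
elastance cavities, divergence-theorem surface volume."""

import numpy as np
import pytest
import sympy as sp
import trimesh

from cardiowave.cavity import (
    ActiveStressParams,
    CavityStateError,
    ElastanceCavity,
    GuccioneParams,
    InvalidDeformationError,
    InvalidSurfaceError,
    SphereCavity,
    active_stress,
    active_stress_tensor,
    guccione_energy,
    passive_stress,
    surface_volume,
    table1_guccione_params,
)


class TestActiveStress:
    def test_silent_before_onset_and_at_end(self):
        p = ActiveStressParams()
        assert active_stress(p.t_a + p.t_emd, 1.0, p) == 0.0         # t_s = 0
        assert active_stress(p.t_a + p.t_emd - 0.1, 1.0, p) == 0.0   # t_s < 0
        assert active_stress(p.t_a + p.t_emd + p.t_dur, 1.0, p) == 0.0

    def test_mid_transient_peak_value(self):
        """Direct evaluation of the transient at t_s = t_dur/2, lambda = 1:
        phi = tanh(35*0.3), tau_c = 105 ms + 100 ms (1 - phi),
        S_a = 60 kPa phi tanh^2(t_s/tau_c) tanh^2((t_dur - t_s)/tau_r)."""
        p = ActiveStressParams()
        t_s = 0.5 * p.t_dur
        phi = np.tanh(35.0 * (1.0 - 0.7))
        tau_c = 0.105 + 0.100 * (1.0 - phi)
        expected = (60e3 * phi * np.tanh(t_s / tau_c) ** 2
                    * np.tanh((p.t_dur - t_s) / 0.090) ** 2)
        got = active_stress(p.t_a + p.t_emd + t_s, 1.0, p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(58.6e3, rel=1e-3)

    def test_stretch_floor_switches_tension_off(self):
        p = ActiveStressParams()
        assert active_stress(0.3, 0.65, p) == 0.0

    def test_length_dependence_monotone(self):
        p = ActiveStressParams()
        s = [active_stress(0.3, lam, p) for lam in (0.8, 0.9, 1.0, 1.1)]
        assert all(a < b for a, b in zip(s, s[1:]))


def random_spd(rng, scale=0.15):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    return F.T @ F


class TestGuccione:
    def test_reference_state_has_zero_energy(self):
        assert guccione_energy(np.eye(3), GuccioneParams()) == 0.0

    def test_pure_dilation_is_volumetric_only(self):
        p = GuccioneParams()
        for J in (0.9, 1.1, 1.3):
            C = J ** (2.0 / 3.0) * np.eye(3)
            assert guccione_energy(C, p) == pytest.approx(
                0.5 * p.kappa * np.log(J) ** 2, rel=1e-12)

    def test_isochoric_fiber_stretch_against_symbolic_oracle(self):
        """Computer-algebra evaluation of the energy at an isochoric
        uniaxial fibre stretch lambda = 1.1 with the text defaults."""
        lam_v = 1.1
        lam, bf, bt, bfs, Cg = sp.symbols("lam b_f b_t b_fs C_g", positive=True)
        # C = diag(lam^2, 1/lam, 1/lam): J = 1, Ebar = (C - I)/2
        e_f = (lam**2 - 1) / 2
        e_t = (1 / lam - 1) / 2
        Q = bf * e_f**2 + bt * (e_t**2 + e_t**2)
        psi = Cg / 2 * (sp.exp(Q) - 1)
        expected = float(psi.subs({lam: lam_v, bf: sp.Rational(1848, 100),
                                   bt: sp.Rational(358, 100),
                                   bfs: sp.Rational(1627, 1000),
                                   Cg: 800}).evalf(30))
        C = np.diag([lam_v**2, 1.0 / lam_v, 1.0 / lam_v])
        assert guccione_energy(C, GuccioneParams()) == pytest.approx(
            expected, rel=1e-10)

    def test_frame_indifference(self, rng):
        """Rotating C together with the material axes leaves Psi unchanged."""
        p0 = GuccioneParams()
        C = random_spd(rng)
        psi0 = guccione_energy(C, p0)
        for _ in range(10):
            M = rng.standard_normal((3, 3))
            R, _ = np.linalg.qr(M)
            p_rot = GuccioneParams(axes=(R @ p0.axes.T).T)
            C_rot = R @ C @ R.T
            assert guccione_energy(C_rot, p_rot) == pytest.approx(
                psi0, rel=1e-10)

    def test_passive_stress_matches_energy_gradient(self, rng):
        """S_pas = 2 dPsi/dC: analytic implementation vs central FD."""
        p = GuccioneParams()
        for _ in range(5):
            C = random_spd(rng)
            S = passive_stress(C, p)
            h = 1e-7
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += 0.5 * h
                    dC[j, i] += 0.5 * h
                    # central difference of Psi along the symmetric direction
                    # (e_ij + e_ji)/2 equals S_ij = 2 dPsi/dC_ij directly
                    num = (guccione_energy(C + dC, p)
                           - guccione_energy(C - dC, p)) / h
                    assert num == pytest.approx(
                        S[i, j], rel=2e-6, abs=1e-4 * abs(S).max())

    def test_orthotropic_table_mapping(self):
        p = table1_guccione_params()
        assert p.b_f == 5.0
        assert p.b_t == pytest.approx(11.0 / 3.0)
        assert p.b_fs == 6.0

    def test_non_spd_rejected(self):
        with pytest.raises(InvalidDeformationError):
            guccione_energy(np.diag([1.0, -0.5, 1.0]), GuccioneParams())


class TestActiveStressTensor:
    def test_zero_scalar_gives_zero_tensor(self):
        S = active_stress_tensor(0.0, np.eye(3), [1, 0, 0], [0, 1, 0])
        np.testing.assert_array_equal(S, 0.0)

    def test_identity_metric_eigenstructure(self):
        S = active_stress_tensor(1e4, np.eye(3), [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(np.diag(S), [1e4, 0.4e4, 0.0])

    def test_normalisation_identity(self, rng):
        """trace(S_act C) = 1.4 S_a for any SPD metric."""
        for _ in range(5):
            C = random_spd(rng)
            S = active_stress_tensor(2.5e4, C, [1, 0, 0], [0, 1, 0])
            assert np.trace(S @ C) == pytest.approx(1.4 * 2.5e4, rel=1e-12)


class TestSphereCavity:
    def test_reference_volume_is_stress_free(self):
        cav = SphereCavity()
        assert cav.pressure(cav.reference_volume, t=5.0) == pytest.approx(
            0.0, abs=1e-8)

    def test_passive_curve_is_monotone(self):
        cav = SphereCavity()
        V = cav.reference_volume * np.linspace(0.7, 2.2, 12)
        p = [cav.pressure(v, t=5.0) for v in V]
        assert all(a < b for a, b in zip(p, p[1:]))

    def test_active_pressure_exceeds_passive(self):
        cav = SphereCavity()
        V = 1.3 * cav.reference_volume
        t_sys = cav.activation.t_a + cav.activation.t_emd + 0.25
        assert cav.pressure(V, t_sys) > cav.pressure(V, 5.0)

    def test_volume_inverts_pressure(self):
        """Continuation inversion recovers the volume on its local branch."""
        cav = SphereCavity()
        for frac, t in ((1.2, 5.0), (1.5, 5.0), (1.1, 0.3)):
            V = frac * cav.reference_volume
            p = cav.pressure(V, t)
            assert cav.volume(p, t, v_hint=0.9 * V) == pytest.approx(V, rel=1e-9)

    def test_full_activation_has_descending_limb(self):
        """Known limitation: with the saturating tanh length dependence,
        the fully activated sphere's p(V) is locally decreasing (the
        inverse is branch-local, cf. the continuation hint)."""
        cav = SphereCavity()
        Vr = cav.reference_volume
        t_sys = 0.3
        p1 = cav.pressure(1.0 * Vr, t_sys)
        p2 = cav.pressure(1.4 * Vr, t_sys)
        assert p2 < p1

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(CavityStateError):
            SphereCavity().pressure(-1e-6, t=5.0)

    def test_physiological_operating_point(self):
        """~120 mL at a ~10 mmHg preload for the default geometry."""
        cav = SphereCavity()
        V = cav.volume(1333.0, t=5.0)
        assert 80e-6 < V < 160e-6


class TestElastanceCavity:
    def test_linear_pressure_volume_relation(self):
        cav = ElastanceCavity()
        p = 2000.0
        V = cav.volume(p, t=5.0)
        assert cav.pressure(V, t=5.0) == pytest.approx(p, rel=1e-12)
        assert cav.dvolume_dp(p, t=5.0) == pytest.approx(1.0 / cav.E_min)

    def test_contract_monotone_in_pressure(self):
        """V(p) strictly increasing: elastance at any phase, sphere on its
        passive branch (the coupled solver's operating regime)."""
        cases = [(ElastanceCavity(), 0.25), (ElastanceCavity(), 5.0),
                 (SphereCavity(), 5.0)]
        for cav, t in cases:
            ps = np.linspace(500.0, 8000.0, 6)
            Vs = [cav.volume(p, t) for p in ps]
            assert all(a < b for a, b in zip(Vs, Vs[1:]))

    def test_elastance_rises_during_systole(self):
        cav = ElastanceCavity()
        assert cav.elastance(0.3) > 5 * cav.E_min
        assert cav.elastance(5.0) == cav.E_min


class TestSurfaceVolume:
    def cube(self):
        m = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        return m.vertices, m.faces

    def test_unit_cube_is_exact(self):
        v, f = self.cube()
        assert surface_volume(v, f) == pytest.approx(1.0, rel=1e-14)

    def test_refined_icosphere_converges_to_ball_volume(self):
        m = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        V = surface_volume(m.vertices, m.faces)
        assert V == pytest.approx(4.0 * np.pi / 3.0, rel=5e-3)
        # cross-check against the mesh library's own volume
        assert V == pytest.approx(m.volume, rel=1e-12)

    def test_translation_invariance(self):
        v, f = self.cube()
        assert surface_volume(v + np.array([3.1, -2.2, 0.7]), f) == (
            pytest.approx(surface_volume(v, f), rel=1e-12))

    def test_open_surface_rejected(self):
        v, f = self.cube()
        with pytest.raises(InvalidSurfaceError):
            surface_volume(v, f[:-1])
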