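import numpy as np
import pytest
from dataclasses import replace

from cerebrofsi.wall_mechanics import (MembraneState, WallMaterial,
                                       membrane_wall_update,
                                       sphere_equilibrium, sphere_limit_point,
                                       sphere_pressure, strain_energy,
                                       tube_equilibrium,
                                       uniaxial_nominal_stress)


class TestConstitutive:
    def test_energy_zero_at_identity(self, wall_material):
        assert strain_energy(3.0, 1.0, wall_material) == 0.0

    def test_energy_uniaxial_hand_value(self, wall_material):
        lam = 1.1
        I1 = lam ** 2 + 2.0 / lam
        assert strain_energy(I1, 1.0, wall_material) == \
            pytest.approx(4.678e3, rel=1e-3)

    def test_incompressible_requires_unit_volume_ratio(self, wall_material):
        with pytest.raises(ValueError):
            strain_energy(3.5, 1.01, wall_material)

    def test_compressible_volumetric_term(self):
        mat = WallMaterial(D1=1e-6)
        base = strain_energy(3.0, 1.0, mat)
        assert strain_energy(3.0, 1.001, mat) - base == \
            pytest.approx(1e-6 / 1e-6, rel=1e-6)   # (J-1)^2 / D1

    def test_uniaxial_stress_values(self, wall_material):
        assert uniaxial_nominal_stress(1.0, wall_material) == 0.0
        assert uniaxial_nominal_stress(1.1, wall_material) == \
            pytest.approx(332e3 * (1.1 - 1.1 ** -2), rel=1e-12)  # ~90.8 kPa

    def test_uniaxial_slope_is_small_strain_modulus(self, wall_material):
        # d sigma / d lambda at identity = 6 C1 (incompressible Young's mod)
        h = 1e-7
        slope = (uniaxial_nominal_stress(1 + h, wall_material)
                 - uniaxial_nominal_stress(1 - h, wall_material)) / (2 * h)
        assert slope == pytest.approx(6 * wall_material.C1, rel=1e-6)

    def test_stress_is_energy_derivative_along_uniaxial_path(self,
                                                            wall_material):
        lam = 1.17
        h = 1e-6

        def W(l):
            return strain_energy(l ** 2 + 2.0 / l, 1.0, wall_material)

        fd = (W(lam + h) - W(lam - h)) / (2 * h)
        assert uniaxial_nominal_stress(lam, wall_material) == \
            pytest.approx(fd, rel=1e-6)


class TestTubeEquilibrium:
    def test_zero_pressure_identity(self, wall_material):
        st = tube_equilibrium(0.0, 1.6e-3, 125e-6, wall_material)
        assert st.stretch == 1.0 and st.displacement == 0.0

    def test_reference_inflation(self, wall_material):
        st = tube_equilibrium(2e3, 1.6e-3, 125e-6, wall_material)
        assert st.stretch == pytest.approx(1.0203, abs=2e-4)
        assert st.displacement == pytest.approx(3.3e-5, rel=0.03)

    def test_balance_residual(self, wall_material):
        st = tube_equilibrium(2e3, 1.6e-3, 125e-6, wall_material)
        mu = wall_material.shear_modulus
        lhs = mu * (st.stretch ** 2 - st.stretch ** -2)
        rhs = 2e3 * st.stretch ** 2 * 1.6e-3 / 125e-6
        assert abs(lhs - rhs) / abs(rhs) < 1e-10

    def test_monotone_in_pressure(self, wall_material):
        P = np.linspace(0, 20e3, 40)
        lams = [tube_equilibrium(p, 1.6e-3, 125e-6, wall_material).stretch
                for p in P]
        assert np.all(np.diff(lams) > 0)

    def test_instability_detected(self, wall_material):
        P_lim = wall_material.shear_modulus * 125e-6 / 1.6e-3
        with pytest.raises(ValueError, match="stability"):
            tube_equilibrium(P_lim * 1.01, 1.6e-3, 125e-6, wall_material)

    def test_state_invariants(self, wall_material):
        st = tube_equilibrium(5e3, 1.6e-3, 125e-6, wall_material)
        assert isinstance(st, MembraneState)
        assert st.thickness == pytest.approx(125e-6 / st.stretch)
        assert st.displacement == pytest.approx((st.stretch - 1) * 1.6e-3)


class TestSphereEquilibrium:
    def test_limit_point_location(self, wall_material):
        lam_star, p_max = sphere_limit_point(2.5e-3, 27e-6, wall_material)
        assert lam_star == pytest.approx(7 ** (1 / 6), rel=1e-12)
        # independent scalar evaluation of P(7^(1/6)) for the sac parameters
        mu = wall_material.shear_modulus
        expect = 2 * mu * (27e-6 / 2.5e-3) * (lam_star ** -1 - lam_star ** -7)
        assert p_max == pytest.approx(expect, rel=1e-12)
        assert p_max == pytest.approx(4.44e3, rel=0.01)

    def test_zero_pressure(self, wall_material):
        assert sphere_equilibrium(0.0, 2.5e-3, 27e-6,
                                  wall_material).stretch == 1.0

    def test_ascending_branch_root(self, wall_material):
        st = sphere_equilibrium(2e3, 2.5e-3, 27e-6, wall_material)
        assert 1.0 < st.stretch < 7 ** (1 / 6)
        assert sphere_pressure(st.stretch, 2.5e-3, 27e-6, wall_material) == \
            pytest.approx(2e3, rel=1e-10)

    def test_beyond_limit_point_raises(self, wall_material):
        with pytest.raises(ValueError, match="limit point"):
            sphere_equilibrium(5e3, 2.5e-3, 27e-6, wall_material)


class TestMembraneWallUpdate:
    def _arc(self, R0, span=2.2, n=241):
        th = np.linspace(-span, span, n)
        pts = R0 * np.stack([np.cos(th), np.sin(th)], axis=1)
        return pts, pts / R0

    def test_zero_traction_zero_displacement(self, wall_material):
        pts, nrm = self._arc(1.6e-3)
        w = membrane_wall_update(pts, nrm, np.zeros(len(pts)), wall_material,
                                 thickness=np.full(len(pts), 125e-6))
        assert np.all(w == 0.0)

    def test_cylinder_arc_matches_tube_closed_form(self, wall_material):
        R0, t0, P = 1.6e-3, 125e-6, 2e3       # lambda ~ 1.02 < 1.05
        pts, nrm = self._arc(R0)
        w = membrane_wall_update(pts, nrm, np.full(len(pts), P),
                                 wall_material,
                                 thickness=np.full(len(pts), t0))
        exact = tube_equilibrium(P, R0, t0, wall_material).displacement
        assert w[len(pts) // 2] == pytest.approx(exact, rel=0.02)

    def test_flat_wall_matches_dense_reference(self, wall_material):
        L, t0, q = 10e-3, 125e-6, 500.0
        results = {}
        for n in (81, 481):
            x = np.linspace(0, L, n)
            pts = np.stack([x, np.zeros_like(x)], axis=1)
            nrm = np.tile([0.0, 1.0], (n, 1))
            w = membrane_wall_update(pts, nrm, np.full(n, q), wall_material,
                                     thickness=np.full(n, t0))
            results[n] = w[n // 2]
        assert results[81] == pytest.approx(results[481], rel=0.01)

    def test_stiffness_scaling_at_small_load(self, wall_material):
        # doubling C1 halves the deflection to first order (curved wall,
        # where the response is material-stiffness dominated)
        pts, nrm = self._arc(1.6e-3)
        t = np.full(len(pts), 125e-6)
        q = np.full(len(pts), 50.0)
        w1 = membrane_wall_update(pts, nrm, q, wall_material, thickness=t)
        w2 = membrane_wall_update(pts, nrm, q,
                                  replace(wall_material, C1=2 * 166e3),
                                  thickness=t)
        mid = len(pts) // 2
        assert w2[mid] == pytest.approx(w1[mid] / 2, rel=0.02)

    def test_anchors_are_clamped(self, wall_material):
        pts, nrm = self._arc(1.6e-3)
        w = membrane_wall_update(pts, nrm, np.full(len(pts), 1e3),
                                 wall_material,
                                 thickness=np.full(len(pts), 125e-6))
        assert w[0] == 0.0 and w[-1] == 0.0

    def test_requires_anchors(self, wall_material):
        pts, nrm = self._arc(1.6e-3)
        with pytest.raises(ValueError):
            membrane_wall_update(pts, nrm, np.zeros(len(pts)), wall_material,
                                 anchors=[])

    def test_rigid_material_limit_on_curved_wall(self, wall_material):
        pts, nrm = self._arc(1.6e-3)
        w = membrane_wall_update(pts, nrm, np.full(len(pts), 2e3),
                                 replace(wall_material, C1=1e12),
                                 thickness=np.full(len(pts), 125e-6))
        assert np.abs(w).max() < 1e-9
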