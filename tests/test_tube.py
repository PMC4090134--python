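"""Analytic tube solutions: hyperelastic inflation, Lame, diagnostics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from wallstress import (
    LinearMaterial,
    TubeGeometry,
    effective_stress,
    equilibrium_integral,
    find_unloaded_tube,
    get_material,
    linear_tube_displacement,
    solve_linear_tube,
    solve_nonlinear_tube,
)
from conftest import P_SYS


class TestNonlinearTube:
    def test_benchmark_deformed_radii(self, imaged_tube, rv):
        """Inflating the 14.8/16.1 mm tube treated as unloaded (the
        conventional-model solve) expands the lumen to about 16.3 mm."""
        deformed, _ = solve_nonlinear_tube(imaged_tube, rv, P_SYS)
        assert deformed.a == pytest.approx(16.27, rel=0.01)
        # area preservation is exact for the incompressible solve
        assert deformed.b**2 - deformed.a**2 == pytest.approx(
            16.1**2 - 14.8**2, rel=1e-10
        )

    def test_unloaded_identity(self, imaged_tube, rv):
        deformed, prof = solve_nonlinear_tube(imaged_tube, rv, 0.0)
        assert (deformed.a, deformed.b) == (14.8, 16.1)
        assert not prof.sigma_eff.any()

    @pytest.mark.parametrize("name", ["RV", "P1", "P2"])
    def test_global_force_balance(self, imaged_tube, name):
        _, prof = solve_nonlinear_tube(imaged_tube, get_material(name), P_SYS)
        integral, pa = equilibrium_integral(prof)
        assert integral == pytest.approx(pa, rel=1e-4)

    def test_traction_boundary_conditions(self, imaged_tube, rv):
        _, prof = solve_nonlinear_tube(imaged_tube, rv, P_SYS)
        assert abs(prof.sigma_rr[0] + P_SYS) < 1e-8 * P_SYS
        assert abs(prof.sigma_rr[-1]) < 1e-8 * P_SYS

    @pytest.mark.parametrize("name", ["RV", "P1", "P2"])
    def test_monotone_inflation(self, name):
        mat = get_material(name)
        geom = TubeGeometry(14.8, 16.1)
        radii = [
            solve_nonlinear_tube(geom, mat, p)[0].a
            for p in (0.004, 0.008, 0.016, 0.027)
        ]
        assert np.all(np.diff(radii) > 0)

    def test_conventional_overexpands_reference(self, imaged_tube, rv):
        """Seeding the conventional model with the reference deformed
        configuration inflates it beyond the imaged geometry."""
        unloaded = find_unloaded_tube((14.8, 16.1), rv, P_SYS)
        ref, _ = solve_nonlinear_tube(unloaded, rv, P_SYS)
        conv, _ = solve_nonlinear_tube(TubeGeometry(ref.a, ref.b), rv, P_SYS)
        assert conv.a > ref.a

    def test_unloaded_geometry_roundtrip(self, rv):
        unloaded = find_unloaded_tube((14.8, 16.1), rv, P_SYS)
        deformed, _ = solve_nonlinear_tube(unloaded, rv, P_SYS)
        assert deformed.a == pytest.approx(14.8, abs=1e-8)
        assert deformed.b == pytest.approx(16.1, abs=1e-8)

    def test_rejects_negative_pressure(self, imaged_tube, rv):
        with pytest.raises(ValueError):
            solve_nonlinear_tube(imaged_tube, rv, -0.01)


class TestLinearTube:
    def test_equilibrium_integral_equals_pa(self, imaged_tube):
        prof = solve_linear_tube(imaged_tube, P_SYS)
        integral, pa = equilibrium_integral(prof)
        assert pa == pytest.approx(0.016 * 14.8)
        assert integral == pytest.approx(0.2368, abs=2e-4)

    def test_zero_pressure(self, imaged_tube):
        prof = solve_linear_tube(imaged_tube, 0.0)
        assert not prof.sigma_eff.any()

    def test_stresses_independent_of_modulus(self, imaged_tube):
        """The Lame stress formulas contain no E; displacement does."""
        p1 = solve_linear_tube(imaged_tube, P_SYS)
        p2 = solve_linear_tube(imaged_tube, P_SYS)
        np.testing.assert_array_equal(p1.sigma_tt, p2.sigma_tt)
        _, u1 = linear_tube_displacement(imaged_tube, LinearMaterial(E=1.0), P_SYS)
        _, u2 = linear_tube_displacement(imaged_tube, LinearMaterial(E=2.0), P_SYS)
        np.testing.assert_allclose(u1, 2.0 * u2, rtol=1e-14)

    def test_displacement_negligible_at_high_modulus(self, imaged_tube):
        _, u = linear_tube_displacement(
            imaged_tube, LinearMaterial(E=8.4e9, nu=0.4999), P_SYS
        )
        assert np.abs(u).max() < 1.3e-9

    def test_zero_pressure_displacement(self, imaged_tube):
        _, u = linear_tube_displacement(imaged_tube, LinearMaterial(E=1.0), 0.0)
        assert not u.any()

    def test_matches_equilibrium_ode_shooting(self, imaged_tube):
        """Independent oracle: solve the radial displacement ODE
        u'' + u'/r - u/r^2 = 0 by shooting on the two traction conditions
        and rebuild sigma_tt from the plane-strain constitutive law."""
        a, b = imaged_tube.A, imaged_tube.B
        E, nu = 10.0, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))

        def srr(r, u, du):
            return (lam + 2 * mu) * du + lam * u / r

        def stt(r, u, du):
            return (lam + 2 * mu) * u / r + lam * du

        def shoot(du0):
            sol = solve_ivp(
                lambda r, y: [y[1], -y[1] / r + y[0] / r**2],
                (a, b), [1.0 * u0_scale, du0], rtol=1e-12, atol=1e-14,
                dense_output=True,
            )
            return sol

        # linear problem: superpose two solutions to satisfy both BCs
        u0_scale = 1.0
        sols = []
        for du0 in (0.0, 1.0):
            sols.append(shoot(du0))
        import numpy.linalg as la

        # c1*sol0 + c2*sol1 with srr(a) = -p, srr(b) = 0
        rows = []
        for r_eval in (a, b):
            rows.append(
                [srr(r_eval, *s.sol(r_eval)) for s in sols]
            )
        c = la.solve(np.array(rows), np.array([-P_SYS, 0.0]))
        prof = solve_linear_tube(imaged_tube, P_SYS, nu=nu)
        for r_eval in np.linspace(a, b, 7):
            u = sum(ci * s.sol(r_eval)[0] for ci, s in zip(c, sols))
            du = sum(ci * s.sol(r_eval)[1] for ci, s in zip(c, sols))
            expected = stt(r_eval, u, du)
            got = np.interp(r_eval, prof.r_nodes, prof.sigma_tt)
            assert got == pytest.approx(expected, rel=1e-7)


class TestThinWallLimit:
    def test_mean_hoop_stress_approaches_membrane_value(self, rv):
        geom = TubeGeometry(100.0, 100.5)  # h/a = 0.005
        p = 1e-4
        lam_prof = solve_linear_tube(geom, p)
        membrane = p * geom.A / geom.thickness
        assert lam_prof.sigma_tt.mean() == pytest.approx(membrane, rel=0.02)
        deformed, prof = solve_nonlinear_tube(geom, rv, p)
        membrane_def = p * deformed.a / deformed.thickness
        assert prof.sigma_tt.mean() == pytest.approx(membrane_def, rel=0.02)


class TestEffectiveStress:
    def test_hydrostatic_state_is_zero(self):
        assert effective_stress(0.3, 0.3, 0.3) == 0.0

    def test_uniaxial(self):
        assert effective_stress(0.0, 0.19, 0.0) == pytest.approx(0.19)

    def test_triaxial_matches_direct_formula(self):
        s = (-0.008, 0.19, 0.09)
        expected = np.sqrt(
            0.5 * ((s[0] - s[1]) ** 2 + (s[1] - s[2]) ** 2 + (s[2] - s[0]) ** 2)
        )
        assert effective_stress(*s) == pytest.approx(expected, rel=1e-14)

    def test_shear_contribution(self):
        assert effective_stress(0, 0, 0, tau_rt=0.1) == pytest.approx(
            np.sqrt(3) * 0.1
        )


class TestEquilibriumIntegral:
    def test_conventional_integral_larger_than_reference(self, imaged_tube, rv):
        _, conv = solve_nonlinear_tube(imaged_tube, rv, P_SYS)
        lin = solve_linear_tube(imaged_tube, P_SYS)
        assert equilibrium_integral(conv)[0] > equilibrium_integral(lin)[0]

    def test_too_few_nodes(self, imaged_tube):
        prof = solve_linear_tube(imaged_tube, P_SYS)
        prof.r_nodes = prof.r_nodes[:1]
        with pytest.raises(ValueError):
            equilibrium_integral(prof)

    def test_csv_export(self, imaged_tube, tmp_path):
        import pandas as pd

        prof = solve_linear_tube(imaged_tube, P_SYS)
        path = tmp_path / "prof.csv"
        prof.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "r_mm", "r_norm", "sigma_rr", "sigma_tt", "sigma_zz", "sigma_eff"
        ]
        np.testing.assert_allclose(back.sigma_tt.values, prof.sigma_tt)
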