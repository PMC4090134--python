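"""Stress-difference metrics and the analytic sweep engine."""

import numpy as np
import pytest

from wallstress import (
    SweepSpec,
    TubeGeometry,
    compare_profiles,
    find_unloaded_tube,
    get_material,
    integrated_diff,
    percent_diff,
    run_sweep,
    solve_linear_tube,
    solve_nonlinear_tube,
)
from wallstress.compare import mpr_pair
from conftest import P_SYS


class TestPercentDiff:
    def test_identical_fields(self):
        f = np.array([1.0, 2.0, 3.0])
        assert not percent_diff(f, f).any()

    def test_uniform_scaling(self):
        f = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(percent_diff(1.1 * f, f), 10.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            percent_diff(np.ones(3), np.ones(4))

    def test_reference_zeros_masked(self):
        with pytest.warns(UserWarning, match="masked"):
            out = percent_diff(np.ones(3), np.array([1.0, 0.0, 2.0]))
        assert out.mask.tolist() == [False, True, False]

    def test_matches_spot_evaluation_on_tube_profiles(self, imaged_tube, rv):
        """Pointwise formula re-evaluated by hand at three radii."""
        lin = solve_linear_tube(imaged_tube, P_SYS)
        unloaded = find_unloaded_tube((14.8, 16.1), rv, P_SYS)
        _, ref = solve_nonlinear_tube(unloaded, rv, P_SYS)
        pct = percent_diff(lin.sigma_eff, ref.sigma_eff)
        for idx in (0, 100, 200):
            by_hand = 100.0 * (lin.sigma_eff[idx] - ref.sigma_eff[idx]) / ref.sigma_eff[idx]
            assert pct[idx] == pytest.approx(by_hand, rel=1e-12)


class TestIntegratedDiff:
    def test_identical_profiles(self):
        grid = np.linspace(0, 1, 11)
        assert integrated_diff((grid, grid + 1), (grid, grid + 1)) == 0.0

    def test_piecewise_constant_closed_form(self):
        grid = np.linspace(0, 1, 11)
        two, one = np.full(11, 2.0), np.ones(11)
        assert integrated_diff((grid, two), (grid, one)) == pytest.approx(100.0)

    def test_signed_integrand_option(self):
        grid = np.linspace(0, 1, 101)
        ref = np.ones(101)
        test = 1.0 + np.sin(2 * np.pi * grid)  # symmetric over/under-shoot
        assert integrated_diff((grid, test), (grid, ref), signed=True) == pytest.approx(
            0.0, abs=1e-10
        )
        assert integrated_diff((grid, test), (grid, ref)) > 10.0

    def test_resampling_warns(self):
        g1, g2 = np.linspace(0, 1, 11), np.linspace(0, 1, 21)
        with pytest.warns(UserWarning, match="resampling"):
            integrated_diff((g1, np.ones(11)), (g2, np.ones(21)))

    def test_scale_invariance(self, imaged_tube, rv):
        lin = solve_linear_tube(imaged_tube, P_SYS)
        _, conv = solve_nonlinear_tube(imaged_tube, rv, P_SYS)
        grid = lin.normalized_thickness
        d1 = integrated_diff(conv, lin)
        d2 = integrated_diff((grid, 3.7 * np.interp(grid, conv.normalized_thickness,
                                                    conv.sigma_eff)),
                             (grid, 3.7 * lin.sigma_eff))
        assert d1 == pytest.approx(d2, rel=1e-9)


@pytest.fixture(scope="module")
def small_spec():
    return SweepSpec(
        alpha_ref=np.array([0.1, 0.174, 0.35]),
        beta_ref=np.array([1.0, 1.881]),
        geometries=[(16.1, 1.3)],
    )


@pytest.fixture(scope="module")
def table(small_spec):
    return run_sweep(small_spec)


class TestSweep:
    def test_deterministic(self, small_spec, table):
        again = run_sweep(small_spec)
        import pandas.testing as pdt

        pdt.assert_frame_equal(table, again)

    def test_linear_beats_conventional_in_majority(self, table):
        piv = table.pivot_table(index=["alpha_ref", "beta_ref"], columns="model",
                                values="integrated_pct")
        frac = (piv["linear"].abs() <= piv["conventional"].abs()).mean()
        assert frac > 0.5

    def test_differences_decrease_with_alpha(self, table):
        sub = table[(table.beta_ref == 1.881)]
        for model in ("linear", "conventional"):
            vals = sub[sub.model == model].sort_values("alpha_ref").integrated_pct
            assert vals.abs().is_monotonic_decreasing

    def test_pressure_raises_conventional_error_only(self):
        """Raising systolic to hypertensive pressure grows the conventional
        model's error; the linear stress field stays exact in equilibrium
        (its integral metric changes only through the reference)."""
        geom = (16.1, 1.3)
        cells = {}
        for p in (0.016, 0.027):
            spec = SweepSpec(alpha_ref=np.array([0.174]),
                             beta_ref=np.array([1.881]),
                             geometries=[geom], pressure=p)
            t = run_sweep(spec)
            cells[p] = t.set_index("model").integrated_pct
        assert cells[0.027]["conventional"] > cells[0.016]["conventional"]

    def test_diameter_increases_conventional_gap(self):
        """Larger aneurysm diameter at fixed thickness widens the gap
        between the conventional and linear models."""
        out = {}
        for B in (16.1, 25.0):
            spec = SweepSpec(alpha_ref=np.array([0.174]),
                             beta_ref=np.array([1.881]), geometries=[(B, 1.3)])
            t = run_sweep(spec).set_index("model")
            out[B] = (t.loc["conventional", "integrated_pct"]
                      - t.loc["linear", "integrated_pct"])
        assert out[25.0] > out[16.1]

    def test_failed_cell_recorded(self):
        spec = SweepSpec(alpha_ref=np.array([0.0]), beta_ref=np.array([0.0]),
                         geometries=[(16.1, 1.3)])
        t = run_sweep(spec)
        assert t.integrated_pct.isna().all()
        assert (t.error != "").all()


class TestComparisonOnBenchmarkTube:
    def test_linear_closer_than_conventional(self, imaged_tube, rv):
        unloaded = find_unloaded_tube((14.8, 16.1), rv, P_SYS)
        _, ref = solve_nonlinear_tube(unloaded, rv, P_SYS)
        lin = solve_linear_tube(imaged_tube, P_SYS)
        _, conv = solve_nonlinear_tube(imaged_tube, rv, P_SYS)
        c_lin = compare_profiles(lin, ref)
        c_conv = compare_profiles(conv, ref)
        assert c_lin.integrated_pct < c_conv.integrated_pct
        assert abs(c_lin.max_eff_pct) < abs(c_conv.max_eff_pct)


class TestMprPairs:
    @pytest.mark.parametrize("mpr", [4.0, 6.7, 10.25])
    def test_alpha_over_D1_realizes_ratio(self, mpr):
        wall, ilt = mpr_pair(mpr)
        assert wall.alpha / ilt.D1 == pytest.approx(mpr, rel=0.005)

    def test_unknown_ratio(self):
        with pytest.raises(KeyError):
            mpr_pair(5.5)
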