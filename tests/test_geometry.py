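"""Geometry generators and mesh I/O."""

import numpy as np
import pytest

from wallstress import (
    ThicknessModulation,
    TubeGeometry,
    make_aaa_mesh,
    make_aaa_profile,
    make_patient_like_profile,
    make_ring_mesh,
    make_tube_mesh,
)
from wallstress.fem import read_inp, read_vtk, write_vtk
from wallstress.fem._core import ElementData


class TestTubeMesh:
    def test_element_count_and_jacobians(self):
        mesh = make_tube_mesh(TubeGeometry(14.8, 16.1), 6, 20)
        assert mesh.n_elements == 120
        assert (mesh.jacobians() > 0).all()

    def test_cross_section_area_matches_annulus(self):
        geom = TubeGeometry(14.8, 16.1)
        mesh = make_tube_mesh(geom, 6, 20, length=10.0)
        data = ElementData(mesh, "axisymmetric")
        # weight = r dr dz per radian; 2 pi / L recovers the annulus area
        area = 2.0 * np.pi * data.weight.sum() / 10.0
        assert area == pytest.approx(np.pi * (geom.B**2 - geom.A**2), rel=1e-8)

    def test_boundary_nodes_exact(self):
        geom = TubeGeometry(14.8, 16.1)
        mesh = make_tube_mesh(geom, 3, 4)
        assert (mesh.nodes[mesh.edge_sets["lumen"].ravel(), 0] == geom.A).all()
        assert (mesh.nodes[mesh.edge_sets["outer"].ravel(), 0] == geom.B).all()

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            make_tube_mesh(TubeGeometry(14.8, 16.1), 0, 4)

    def test_longitudinal_thickness_modulation(self):
        mod = ThicknessModulation("longitudinal", amplitude=0.4, wavelength=20.0)
        mesh = make_tube_mesh(TubeGeometry(14.8, 16.1), 3, 10, length=20.0,
                              thickness_mod=mod)
        outer_r = mesh.nodes[mesh.edge_sets["outer"].ravel(), 0]
        assert outer_r.max() == pytest.approx(16.5, abs=1e-9)
        assert outer_r.min() == pytest.approx(15.7, abs=1e-9)

    def test_excessive_modulation_rejected(self):
        mod = ThicknessModulation("longitudinal", amplitude=2.0, wavelength=20.0)
        with pytest.raises(ValueError, match="thickness"):
            make_tube_mesh(TubeGeometry(14.8, 16.1), 3, 10, length=20.0,
                           thickness_mod=mod)


class TestRingMesh:
    def test_circumferential_modulation(self):
        mod = ThicknessModulation("circumferential", amplitude=0.5)
        mesh = make_ring_mesh(TubeGeometry(14.8, 16.1), 3, 24, thickness_mod=mod)
        assert (mesh.jacobians() > 0).all()
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        assert r.max() == pytest.approx(16.6, abs=1e-9)

    def test_odd_circumferential_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_ring_mesh(TubeGeometry(14.8, 16.1), 3, 7)


class TestAAAProfile:
    def test_printed_dimensions(self):
        prof = make_aaa_profile()
        Z = np.linspace(0, prof.height, 1301)
        outer = prof.outer_radius_of_Z(Z)
        assert prof.height == 130.0
        assert outer.max() == pytest.approx(25.0)  # 50 mm max diameter
        assert Z[np.argmax(outer)] == pytest.approx(65.0, abs=0.1)
        assert prof.wall_thickness == 1.5

    def test_profile_is_smooth_c1(self):
        prof = make_aaa_profile()
        Z = np.linspace(0.0, 130.0, 26001)
        d = np.diff(prof.outer_radius_of_Z(Z)) / np.diff(Z)
        # derivative has no jumps at the bulge boundaries
        assert np.abs(np.diff(d)).max() < 1e-3

    def test_lumen_below_inner_wall(self):
        prof = make_aaa_profile()
        Z = np.linspace(0, 130, 401)
        assert (prof.lumen_radius_of_Z(Z) <= prof.inner_radius_of_Z(Z) + 1e-12).all()


class TestAAAMesh:
    def test_wall_only_dimensions(self):
        mesh = make_aaa_mesh(make_aaa_profile(), n_thickness=3, n_axial=26)
        assert mesh.nodes[:, 0].max() == pytest.approx(25.0)
        assert (mesh.jacobians() > 0).all()
        # uniform wall: outer minus inner radius = 1.5 on every node column
        z_vals = np.unique(mesh.nodes[:, 1])
        for z in z_vals[:: len(z_vals) // 7]:
            r = mesh.nodes[np.isclose(mesh.nodes[:, 1], z), 0]
            assert r.max() - r.min() == pytest.approx(1.5, abs=1e-9)

    def test_thrombus_region_conforming(self):
        mesh = make_aaa_mesh(make_aaa_profile(), with_thrombus=True,
                             n_thickness=2, n_axial=26, n_thrombus=4)
        assert set(np.unique(mesh.region_id)) == {0, 1}
        wall_nodes = set(np.unique(mesh.elements[mesh.region_id == 0]).tolist())
        thr_nodes = set(np.unique(mesh.elements[mesh.region_id == 1]).tolist())
        shared = wall_nodes & thr_nodes
        assert shared  # interface is node-matched
        # shared nodes lie on the inner wall surface
        prof = make_aaa_profile()
        for nid in list(shared)[:20]:
            r, z = mesh.nodes[nid]
            assert r == pytest.approx(float(prof.inner_radius_of_Z(z)), abs=1e-9)

    def test_thrombus_impossible_raises(self):
        prof = make_aaa_profile()
        prof.lumen_radius_of_Z = prof.inner_radius_of_Z  # lumen fills the sac
        with pytest.raises(ValueError, match="thrombus"):
            make_aaa_mesh(prof, with_thrombus=True)


class TestPatientLikeProfile:
    def test_deterministic_in_seed(self):
        Z = np.linspace(0, 130, 400)
        r1 = make_patient_like_profile(seed=7).outer_radius_of_Z(Z)
        r2 = make_patient_like_profile(seed=7).outer_radius_of_Z(Z)
        r3 = make_patient_like_profile(seed=8).outer_radius_of_Z(Z)
        np.testing.assert_array_equal(r1, r2)
        assert not np.array_equal(r1, r3)

    def test_zero_amplitude_is_straight_tube(self):
        prof = make_patient_like_profile(seed=3, amplitude_range=(0.0, 0.0))
        Z = np.linspace(0, 130, 50)
        np.testing.assert_allclose(prof.outer_radius_of_Z(Z), 20.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_meshes_without_inverted_elements(self, seed):
        prof = make_patient_like_profile(seed=seed)
        mesh = make_aaa_mesh(prof, n_thickness=2, n_axial=30)
        assert (mesh.jacobians() > 0).all()


class TestMeshIO:
    def test_vtk_roundtrip(self, tmp_path):
        mesh = make_aaa_mesh(make_aaa_profile(), with_thrombus=True,
                             n_thickness=2, n_axial=20, n_thrombus=3)
        path = tmp_path / "m.vtk"
        eff = np.linspace(0.0, 1.0, mesh.n_nodes)
        write_vtk(mesh, path, point_data={"sigma_eff": eff,
                                          "u": np.zeros((mesh.n_nodes, 2))})
        back, pdata, _ = read_vtk(path)
        np.testing.assert_allclose(back.nodes, mesh.nodes)
        np.testing.assert_array_equal(back.elements, mesh.elements)
        np.testing.assert_array_equal(back.region_id, mesh.region_id)
        np.testing.assert_allclose(pdata["sigma_eff"], eff)

    def test_inp_reader(self, tmp_path):
        text = """** minimal file
*NODE
1, 0.0, 0.0
2, 1.0, 0.0
3, 1.0, 1.0
4, 0.0, 1.0
5, 0.5, 0.0
6, 1.0, 0.5
7, 0.5, 1.0
8, 0.0, 0.5
9, 0.5, 0.5
*ELEMENT, TYPE=CAX9
1, 1, 2, 3, 4, 5, 6, 7, 8, 9
*NSET, NSET=ends
1, 2
"""
        path = tmp_path / "m.inp"
        path.write_text(text)
        mesh = read_inp(path)
        assert mesh.n_nodes == 9
        assert mesh.n_elements == 1
        assert (mesh.jacobians() > 0).all()
        np.testing.assert_array_equal(mesh.node_sets["ends"], [0, 1])
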