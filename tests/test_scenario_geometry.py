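import numpy as np
import pytest
from dataclasses import replace

import cerebrofsi.scenario_geometry as sg
from cerebrofsi.scenario_geometry import (Branch, Scenario, ScenarioSpec,
                                          StenosisSpec, WallSide,
                                          build_annulus_channel,
                                          build_channel, build_scenario,
                                          default_spec, refine,
                                          stenosis_profile, target_points)


@pytest.fixture(scope="module")
def meshes():
    return {s: build_scenario(default_spec(s))
            for s in ("intact", "icas", "aca")}


class TestStenosisProfile:
    def setup_method(self):
        self.sten = StenosisSpec(Branch.PARENT, center_offset=4.8e-3,
                                 length=1.6e-3, degree=0.5)

    def test_peak_inset_at_center(self):
        w = 3.2e-3
        assert stenosis_profile(4.8e-3, self.sten, w) == \
            pytest.approx(0.5 * w / 2)

    def test_vanishes_with_zero_slope_at_ends(self):
        w = 3.2e-3
        edge = 4.8e-3 + 0.8e-3
        assert stenosis_profile(edge, self.sten, w) == pytest.approx(0.0,
                                                                     abs=1e-15)
        h = 1e-7
        slope = (stenosis_profile(edge, self.sten, w)
                 - stenosis_profile(edge - h, self.sten, w)) / h
        assert abs(slope) < 1e-3 * 0.5 * w / 2 / 1.6e-3

    def test_bump_integral_closed_form(self):
        w = 3.2e-3
        s = np.linspace(3.8e-3, 5.8e-3, 20001)
        integral = np.trapezoid(stenosis_profile(s, self.sten, w), s)
        assert integral == pytest.approx(0.5 * w * 1.6e-3 / 4, rel=1e-6)


class TestBuildScenario:
    def test_mesh_invariants(self, meshes):
        for mesh in meshes.values():
            mesh.validate()
            assert np.all(mesh.triangle_areas() > 0)
            # every boundary edge has exactly one tag; tags partition
            tags = set(mesh.edge_tags)
            assert tags == {"INLET", "OUTLET_1", "OUTLET_2", "WALL"}

    def test_inlet_outlet_widths_match_spec(self, meshes):
        for mesh in meshes.values():
            assert mesh.edge_lengths(mesh.edges_of("INLET")).sum() == \
                pytest.approx(3.2e-3, rel=1e-9)
            for tag in ("OUTLET_1", "OUTLET_2"):
                assert mesh.edge_lengths(mesh.edges_of(tag)).sum() == \
                    pytest.approx(2.0e-3, rel=1e-9)

    def test_parent_width_intact(self, meshes):
        mesh = meshes["intact"]
        wall = mesh.points[mesh.wall_nodes]
        parent = wall[(wall[:, 0] > -10e-3) & (wall[:, 0] < -4e-3)]
        assert parent[:, 1].max() == pytest.approx(1.6e-3, rel=1e-9)
        assert parent[:, 1].min() == pytest.approx(-1.6e-3, rel=1e-9)

    def test_stenosis_throat_widths(self, meshes):
        mesh = meshes["icas"]
        fr = sg._geometry_frame(mesh.spec)
        wall = mesh.points[mesh.wall_nodes]
        # parent throat at 4.8 mm upstream of the junction: (1-0.5)*3.2 mm
        xc = fr["J"][0] - 4.8e-3
        near = wall[np.abs(wall[:, 0] - xc) < 1.01e-4]
        throat = near[near[:, 1] > 0][:, 1].min() - \
            near[near[:, 1] < 0][:, 1].max()
        assert throat == pytest.approx(1.6e-3, rel=0.01)
        # daughter-1 throat at 3 mm downstream: (1-0.5)*2.0 mm
        u1, J = fr["u1"], fr["J"]
        t_hat = np.array([-u1[1], u1[0]])
        s = (wall - J) @ u1
        t = (wall - J) @ t_hat
        near = np.abs(s - 3.0e-3) < 1.01e-4
        upper = near & (wall[:, 1] > 0.2e-3)
        throat_d = t[upper].max() - t[upper].min()
        assert throat_d == pytest.approx(1.0e-3, rel=0.015)

    def test_zero_degree_stenosis_reproduces_intact_nodes(self):
        sten = tuple(replace(s, degree=0.0) for s in sg._default_stenoses())
        icas0 = build_scenario(ScenarioSpec(scenario=Scenario.ICAS,
                                            stenoses=sten))
        intact = build_scenario(default_spec("intact"))
        assert np.array_equal(icas0.points, intact.points)
        assert np.array_equal(icas0.triangles, intact.triangles)

    def test_mirror_symmetry_of_boundary(self, meshes):
        for mesh in meshes.values():
            ids = np.unique(mesh.boundary_edges)
            bp = mesh.points[ids]
            from scipy.spatial import cKDTree
            d, _ = cKDTree(bp).query(bp * np.array([1.0, -1.0]))
            assert d.max() < 1e-12

    def test_determinism_byte_identical(self):
        a = build_scenario(default_spec("aca"))
        b = build_scenario(default_spec("aca"))
        assert a.content_hash() == b.content_hash()

    def test_wall_thickness_map(self, meshes):
        aca = meshes["aca"]
        wall_t = np.asarray([t for t, tag in
                             zip(aca.edge_thickness, aca.edge_tags)
                             if tag == "WALL"])
        assert wall_t.min() == pytest.approx(27e-6, rel=1e-6)
        assert wall_t.max() == pytest.approx(125e-6, rel=1e-6)
        # intermediate blend values exist across the neck band
        assert np.any((wall_t > 30e-6) & (wall_t < 120e-6))
        intact_t = meshes["intact"].edge_thickness
        assert np.allclose(
            intact_t[meshes["intact"].edge_tags == "WALL"], 125e-6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=Scenario.ICAS)         # needs stenoses
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=Scenario.INTACT,
                         stenoses=sg._default_stenoses())
        with pytest.raises(ValueError):
            StenosisSpec(degree=1.0)
        with pytest.raises(ValueError):
            build_scenario(replace(
                default_spec("icas"),
                stenoses=(StenosisSpec(Branch.PARENT, 11.9e-3),)))


class TestTargetPoints:
    def test_apex_target_for_intact_and_icas(self, meshes):
        for name in ("intact", "icas"):
            tp = meshes[name].target_points
            assert set(tp) == {"bifurcation_apex"}
            apex = meshes[name].points[tp["bifurcation_apex"]]
            assert np.linalg.norm(apex) < meshes[name].spec.mesh_size

    def test_sac_vertex_target(self, meshes):
        aca = meshes["aca"]
        tp = aca.target_points
        assert set(tp) == {"sac_vertex"}
        fr = sg._geometry_frame(aca.spec)
        vertex = aca.points[tp["sac_vertex"]]
        assert np.linalg.norm(vertex - fr["sac_vertex"]) < \
            aca.spec.mesh_size
        # vertex sits roughly neck offset + 2 sac radii beyond the apex
        assert vertex[0] == pytest.approx(
            fr["A1"][0] + 2 * aca.spec.sac_radius, abs=3 * 2.5e-3 * 0.1)

    def test_snap_stability_under_refinement(self, meshes):
        coarse = meshes["intact"]
        fine = refine(coarse, 2.0)
        pc = coarse.points[coarse.target_points["bifurcation_apex"]]
        pf = fine.points[target_points(fine)["bifurcation_apex"]]
        assert np.linalg.norm(pc - pf) < coarse.spec.mesh_size

    def test_wrong_scenario_rejected(self, meshes):
        with pytest.raises((KeyError, ValueError)):
            _ = meshes["intact"].target_points["sac_vertex"]


class TestRefine:
    def test_identity_factor(self, meshes):
        same = refine(meshes["intact"], 1.0)
        assert len(same.points) == len(meshes["intact"].points)

    def test_refinement_grows_triangle_count(self, meshes):
        fine = refine(meshes["intact"], 2.0)
        assert len(fine.triangles) >= 3 * len(meshes["intact"].triangles)

    def test_boundary_stays_close(self, meshes):
        coarse = meshes["intact"]
        fine = refine(coarse, 2.0)
        from scipy.spatial import cKDTree
        tree = cKDTree(coarse.points[np.unique(coarse.boundary_edges)])
        d, _ = tree.query(fine.points[np.unique(fine.boundary_edges)])
        assert d.max() < coarse.spec.mesh_size

    def test_invalid_factor(self, meshes):
        with pytest.raises(ValueError):
            refine(meshes["intact"], 0.0)


class TestStructuredChannels:
    def test_channel_tags_and_dimensions(self, channel_mesh):
        assert channel_mesh.edge_lengths(
            channel_mesh.edges_of("INLET")).sum() == pytest.approx(3.2e-3)
        assert set(channel_mesh.edge_tags) == {"INLET", "OUTLET_1", "WALL"}
        assert len(channel_mesh.wall_chains()) == 2

    def test_annulus_channel_valid(self):
        mesh = build_annulus_channel()
        mesh.validate()
        assert set(mesh.edge_tags) == {"INLET", "OUTLET_1", "WALL"}
        radii = np.linalg.norm(mesh.points, axis=1)
        assert radii.min() == pytest.approx(6e-3 - 1.6e-3, rel=1e-9)
        assert radii.max() == pytest.approx(6e-3 + 1.6e-3, rel=1e-9)

    def test_vtk_round_trip_header(self, channel_mesh):
        text = channel_mesh.to_vtk()
        assert text.startswith("# vtk DataFile Version 3.0")
        assert f"POINTS {len(channel_mesh.points)} double" in text
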