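"""Circle clipping, sphere wrapping, closest-point projection, organ fixture."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from auxforge.geometry import BeamNetwork, TriSurface
from auxforge.planar import PlanarDesign, gen_planar_auxetic
from auxforge.wrap import (SurfaceProjector, WrapConfig, _closest_on_tris,
                           clip_to_circle, closest_point_on_surface,
                           gen_synthetic_organ, project_network_to_surface,
                           wrap_onto_organ, wrap_to_sphere)


@pytest.fixture(scope="module")
def sheet():
    net = gen_planar_auxetic(PlanarDesign(kind="reentrant", n1=6, n2=3,
                                          t=0.3, width=16, height=16))
    return net.translated(-net.vertices.mean(axis=0))


class TestClip:
    def test_large_radius_is_identity(self, sheet):
        out = clip_to_circle(sheet, np.zeros(3), radius=100.0)
        assert out.n_vertices == sheet.n_vertices
        assert out.n_beams == sheet.n_beams

    def test_retained_vertices_inside(self, sheet):
        out = clip_to_circle(sheet, np.zeros(3), radius=5.0)
        rho = np.linalg.norm(out.vertices - 0, axis=1)
        assert np.all(rho <= 5.0 + 1e-9)

    def test_trimmed_endpoint_exactly_on_circle(self):
        net = BeamNetwork([[-3, 0.5, 0], [3, 0.5, 0]], [[0, 1]], 0.2)
        out = clip_to_circle(net, np.zeros(3), radius=1.0)
        rho = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(rho - 1.0).max() < 1e-12

    def test_empty_result_errors(self, sheet):
        far = sheet.translated([100, 0, 0])
        with pytest.raises(ValueError, match="empty"):
            clip_to_circle(far, np.zeros(3), radius=1.0)


class TestSphereWrap:
    def test_center_maps_to_pole(self):
        net = BeamNetwork([[0, 0, 0], [1, 0, 0]], [[0, 1]], 0.1)
        out = wrap_to_sphere(net, R=10.0)
        d, _ = cKDTree(out.vertices).query([0, 0, 10.0])
        assert d < 1e-9

    def test_quarter_and_half_wrap(self):
        R = 4.0
        net = BeamNetwork([[0, 0, 0], [np.pi * R / 2, 0, 0],
                           [np.pi * R, 0, 0]],
                          [[0, 1], [1, 2]], 0.1)
        out = wrap_to_sphere(net, R)
        tree = cKDTree(out.vertices)
        d_eq, _ = tree.query([R, 0, 0])        # equator point
        d_anti, _ = tree.query([0, 0, -R])     # antipode
        assert d_eq < 1e-9 and d_anti < 1e-9

    def test_radial_geodesics_preserved(self, sheet):
        R = 12.0
        clipped = clip_to_circle(sheet, np.zeros(3), radius=7.0)
        out = wrap_to_sphere(clipped, R)
        rho = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(rho - R).max() < 1e-9
        # geodesic distance from pole equals planar radial distance: spot
        # check the original corner vertices by azimuth + geodesic
        psi = np.arccos(np.clip(out.vertices[:, 2] / R, -1, 1))
        geo = R * psi
        phi = np.arctan2(out.vertices[:, 1], out.vertices[:, 0])
        planar = np.stack([geo * np.cos(phi), geo * np.sin(phi),
                           np.zeros_like(geo)], axis=-1)
        dist, _ = cKDTree(planar).query(clipped.vertices)
        assert dist.max() < 1e-9

    def test_overwrap_errors(self):
        net = BeamNetwork([[0, 0, 0], [20, 0, 0]], [[0, 1]], 0.1)
        with pytest.raises(ValueError, match="antipode"):
            wrap_to_sphere(net, R=2.0)


class TestClosestPoint:
    def test_surface_vertex_distance_zero(self, organ):
        q, d, _ = closest_point_on_surface(organ.vertices[17], organ)
        assert d < 1e-12

    def test_centroid_normal_offset(self):
        tri = TriSurface([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0, 1, 2]])
        cen = tri.triangles()[0].mean(axis=0)
        p = cen + 0.7 * tri.face_normals()[0]
        q, d, f = closest_point_on_surface(p, tri)
        assert np.allclose(q, cen, atol=1e-12)
        assert d == pytest.approx(0.7)

    def test_accelerated_matches_brute_force(self, organ, rng):
        pts = rng.uniform(-14, 14, (500, 3))
        proj = SurfaceProjector(organ)
        q, d, f = proj.query(pts)
        tri = organ.triangles()
        for i in range(0, 500, 7):      # exhaustive check on a stride
            _, d2 = _closest_on_tris(pts[i], tri)
            assert abs(np.sqrt(d2.min()) - d[i]) < 1e-9
        # and the full set against the distance minima in bulk
        worst = 0.0
        for i in range(500):
            _, d2 = _closest_on_tris(pts[i], tri)
            worst = max(worst, abs(np.sqrt(d2.min()) - d[i]))
        assert worst < 1e-9


class TestProjection:
    def test_identity_on_own_sphere(self, sheet):
        R = 12.0
        clipped = clip_to_circle(sheet, np.zeros(3), radius=7.0)
        curved = wrap_to_sphere(clipped, R)
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=4, radius=R)
        sphere = TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces))
        out = project_network_to_surface(curved, sphere)
        disp = np.linalg.norm(out.vertices - curved.vertices, axis=1)
        # sphere is faceted: displacement bounded by the sagitta
        edge = np.linalg.norm(np.diff(sphere.triangles(), axis=1),
                              axis=2).max()
        assert disp.max() < edge ** 2 / (4 * R)

    def test_external_point_projects_radially(self):
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        sphere = TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces))
        q, d, _ = closest_point_on_surface(np.array([2.0, 0, 0]), sphere)
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=5e-3)
        assert d == pytest.approx(1.0, abs=5e-3)

    def test_projection_lands_on_surface_and_is_idempotent(self, organ,
                                                           sheet):
        cfg = WrapConfig(clip_radius=7.0, sphere_radius=10.0)
        wrapped = wrap_onto_organ(sheet, organ, cfg, subdiv=2)
        _, d, _ = SurfaceProjector(organ).query(wrapped.vertices)
        assert d.max() < 1e-6
        again = project_network_to_surface(
            wrapped, organ,
            face_mask=organ.face_normals()[:, 2] < 0)
        move = np.linalg.norm(again.vertices - wrapped.vertices, axis=1)
        assert move.max() < 1e-9

    def test_connectivity_unchanged(self, organ, sheet):
        cfg = WrapConfig(clip_radius=6.0, sphere_radius=10.0)
        clipped = clip_to_circle(sheet, np.zeros(3), cfg.clip_radius)
        curved = wrap_to_sphere(clipped, cfg.sphere_radius)
        out = project_network_to_surface(curved, organ)
        assert np.array_equal(out.beams, curved.beams)
        assert out.n_components() == curved.n_components()


class TestSyntheticOrgan:
    def test_watertight_and_genus_zero(self, organ):
        assert organ.is_watertight()
        assert organ.euler_characteristic() == 2

    def test_face_budget(self, organ):
        assert 4000 <= organ.n_faces <= 6500

    def test_deterministic_per_seed(self):
        a = gen_synthetic_organ(seed=9)
        b = gen_synthetic_organ(seed=9)
        assert np.array_equal(a.vertices, b.vertices)
        c = gen_synthetic_organ(seed=10)
        assert not np.array_equal(a.vertices, c.vertices)
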