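"""Geometric substrate: capsule SDFs, voxelization, CSG, marching cubes, STL."""

import numpy as np
import pytest

from auxforge.geometry import (BeamNetwork, STLParseError, TriSurface,
                               VoxelGrid, boolean_op, box_sdf, extract_surface,
                               grid_from_bounds, read_stl, sample_sdf,
                               sdf_capsule, sphere_sdf, voxelize_network,
                               write_stl)


class TestCapsuleSDF:
    def test_center_of_end_sphere(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 2.0, 3.0])
        assert sdf_capsule(a, a, b, 0.7) == pytest.approx(-0.7)

    def test_point_on_surface(self):
        a, b = np.zeros(3), np.array([2.0, 0.0, 0.0])
        p = np.array([1.0, 0.5, 0.0])      # perpendicular at distance r
        assert sdf_capsule(p, a, b, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_matches_point_segment_oracle(self, rng):
        a = np.array([0.3, -1.0, 0.5])
        b = np.array([2.0, 1.5, -0.7])
        r = 0.4
        p = rng.uniform(-2, 3, (1000, 3))
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
        oracle = np.linalg.norm(p - (a + t[:, None] * ab), axis=1) - r
        assert np.abs(sdf_capsule(p, a, b, r) - oracle).max() < 1e-12

    def test_zero_length_degenerates_to_sphere(self):
        a = np.array([1.0, 1.0, 1.0])
        p = np.array([1.0, 1.0, 3.0])
        assert sdf_capsule(p, a, a, 0.5) == pytest.approx(1.5)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sdf_capsule(np.zeros(3), np.zeros(3), np.ones(3), 0.0)


class TestVoxelize:
    def test_capsule_volume_matches_analytic(self, single_beam):
        g = voxelize_network(single_beam, spacing=0.1)  # <= t/8
        L, t = 5.0, 0.8
        v_true = np.pi * t ** 2 / 4 * L + np.pi * t ** 3 / 6
        assert g.solid_volume() == pytest.approx(v_true, rel=0.10)

    def test_empty_network_errors(self):
        net = BeamNetwork(np.zeros((1, 3)), np.zeros((0, 2), int),
                          np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            voxelize_network(net, spacing=0.1)

    def test_disjoint_beams_two_components(self):
        net = BeamNetwork([[0, 0, 0], [2, 0, 0], [0, 0, 5], [2, 0, 5]],
                          [[0, 1], [2, 3]], 0.5)
        g = voxelize_network(net, spacing=0.1)
        assert g.n_solid_components() == 2

    def test_under_resolution_warns(self, single_beam):
        with pytest.warns(UserWarning, match="under-resolved"):
            voxelize_network(single_beam, spacing=0.5)

    def test_translation_equivariance(self, single_beam):
        g0 = voxelize_network(single_beam, spacing=0.11)
        g1 = voxelize_network(single_beam.translated([1.7, -0.9, 2.3]),
                              spacing=0.11)
        assert np.array_equal(g0.indicator(), g1.indicator())

    def test_surface_vertices_near_true_capsule(self, single_beam):
        g = voxelize_network(single_beam, spacing=0.1)
        surf = extract_surface(g)
        d = sdf_capsule(surf.vertices, single_beam.vertices[0],
                        single_beam.vertices[1], 0.4)
        assert np.abs(d).max() <= g.spacing


class TestBooleanOps:
    @pytest.fixture()
    def sphere_grid(self):
        g = grid_from_bounds([-2.5] * 3, [2.5] * 3, 5.0 / 64)
        return sample_sdf(g, sphere_sdf([0, 0, 0], 1.5))

    def test_self_subtraction_empties(self, sphere_grid):
        out = boolean_op(sphere_grid, sphere_grid, "subtract")
        assert not out.indicator().any()

    def test_union_with_empty_is_identity(self, sphere_grid):
        empty = grid_from_bounds([-2.5] * 3, [2.5] * 3, 5.0 / 64)
        out = boolean_op(sphere_grid, empty, "union")
        assert np.array_equal(out.values, sphere_grid.values)

    def test_box_minus_sphere_volume(self):
        g = grid_from_bounds([-2.5] * 3, [2.5] * 3, 4.0 / 64)  # box/64
        box = sample_sdf(g, box_sdf([-2, -2, -2], [2, 2, 2]))
        sph = sample_sdf(g, sphere_sdf([0, 0, 0], 1.2))
        out = boolean_op(box, sph, "subtract")
        v_true = 4.0 ** 3 - 4 / 3 * np.pi * 1.2 ** 3
        assert out.solid_volume() == pytest.approx(v_true, rel=0.05)

    def test_union_below_inputs_pointwise(self, sphere_grid):
        other = sample_sdf(grid_from_bounds([-2.5] * 3, [2.5] * 3, 5.0 / 64),
                           sphere_sdf([0.8, 0, 0], 1.0))
        u = boolean_op(sphere_grid, other, "union")
        assert np.all(u.values <= sphere_grid.values + 1e-15)
        assert np.all(u.values <= other.values + 1e-15)

    def test_mismatched_grids_error(self, sphere_grid):
        other = grid_from_bounds([-2.5] * 3, [2.5] * 3, 0.1)
        with pytest.raises(ValueError, match="mismatched"):
            boolean_op(sphere_grid, other, "union")

    def test_unknown_op_error(self, sphere_grid):
        with pytest.raises(ValueError, match="unknown boolean op"):
            boolean_op(sphere_grid, sphere_grid, "xor")


class TestExtractSurface:
    def test_sphere_area(self):
        R = 2.0
        g = sample_sdf(grid_from_bounds([-2.4] * 3, [2.4] * 3, R / 32),
                       sphere_sdf([0, 0, 0], R))
        s = extract_surface(g)
        assert s.area() == pytest.approx(4 * np.pi * R ** 2, rel=0.03)
        assert s.is_watertight()

    def test_all_positive_gives_empty_with_warning(self):
        g = grid_from_bounds([0, 0, 0], [1, 1, 1], 0.1)
        with pytest.warns(UserWarning, match="iso level"):
            s = extract_surface(g)
        assert s.n_faces == 0

    def test_cube_euler_characteristic(self):
        g = sample_sdf(grid_from_bounds([-2] * 3, [2] * 3, 0.08),
                       box_sdf([-1.2] * 3, [1.2] * 3))
        s = extract_surface(g)
        assert s.is_watertight()
        assert s.euler_characteristic() == 2


def _unit_cube_surface():
    import trimesh
    box = trimesh.creation.box(extents=(1, 1, 1))
    return TriSurface(np.asarray(box.vertices), np.asarray(box.faces))


class TestSTL:
    def test_cube_roundtrip_binary(self, tmp_path):
        s = _unit_cube_surface()
        p = tmp_path / "cube.stl"
        write_stl(s, p, mode="binary")
        back = read_stl(p)
        assert back.n_faces == 12
        tri0 = np.sort(s.triangles().astype(np.float32).reshape(-1, 9), axis=0)
        tri1 = np.sort(back.triangles().astype(np.float32).reshape(-1, 9),
                       axis=0)
        assert np.array_equal(tri0, tri1)

    def test_ascii_binary_identical_soup(self, tmp_path):
        s = _unit_cube_surface()
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        write_stl(s, pa, mode="ascii")
        write_stl(s, pb, mode="binary")
        ta = np.sort(read_stl(pa).triangles().reshape(-1, 9), axis=0)
        tb = np.sort(read_stl(pb).triangles().reshape(-1, 9), axis=0)
        assert np.array_equal(ta, tb)

    def test_trimesh_reads_our_binary(self, tmp_path):
        import trimesh
        s = _unit_cube_surface()
        p = tmp_path / "cube.stl"
        write_stl(s, p, mode="binary")
        m = trimesh.load(str(p), file_type="stl")
        assert len(m.faces) == 12

    def test_empty_file_parse_error(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_bytes(b"")
        with pytest.raises(STLParseError, match="byte 0"):
            read_stl(p)

    def test_truncated_binary_names_offset(self, tmp_path):
        s = _unit_cube_surface()
        p = tmp_path / "cube.stl"
        write_stl(s, p, mode="binary")
        data = p.read_bytes()
        p.write_bytes(data[:200])
        with pytest.raises(STLParseError, match="byte 200"):
            read_stl(p)

    def test_count_mismatch_detected(self, tmp_path):
        import struct
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\0" * 80 + struct.pack("<I", 10) + b"\0" * 50)
        with pytest.raises(STLParseError, match="10 triangles"):
            read_stl(p)


class TestVoxelGridContainer:
    def test_npz_roundtrip(self, tmp_path):
        g = sample_sdf(grid_from_bounds([0, 0, 0], [1, 1, 1], 0.1),
                       sphere_sdf([0.5] * 3, 0.3))
        p = tmp_path / "grid.npz"
        g.save(p)
        back = VoxelGrid.load(p)
        assert back.spacing == g.spacing
        assert np.array_equal(back.values, g.values)
        assert np.array_equal(back.origin, g.origin)


class TestBeamNetworkInvariants:
    def test_duplicate_beams_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BeamNetwork([[0, 0, 0], [1, 0, 0]], [[0, 1], [1, 0]], 0.1)

    def test_degenerate_beam_rejected(self):
        with pytest.raises(ValueError, match="a == b"):
            BeamNetwork([[0, 0, 0], [1, 0, 0]], [[0, 0]], 0.1)

    def test_subdivision_preserves_length_and_connectivity(self, single_beam):
        fine = single_beam.subdivided(7)
        assert fine.n_beams == 7
        assert fine.n_components() == 1
        A, B = fine.segment_endpoints()
        assert np.linalg.norm(B - A, axis=1).sum() == pytest.approx(5.0)


class TestSDFProperties:
    """Seeded property checks over random capsules."""

    def test_capsule_sdf_symmetry_and_triangle_bound(self):
        from hypothesis import given, settings, strategies as st

        coord = st.floats(-5, 5, allow_nan=False)
        point = st.tuples(coord, coord, coord).map(np.array)

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(a=point, b=point, p=point, r=st.floats(0.05, 2.0))
        def check(a, b, p, r):
            d = float(sdf_capsule(p, a, b, r))
            # swapping the endpoints leaves the field unchanged
            assert float(sdf_capsule(p, b, a, r)) == pytest.approx(d,
                                                                   abs=1e-12)
            # 1-Lipschitz: moving the query point by delta changes the
            # distance by at most |delta|
            delta = np.array([0.3, -0.2, 0.1])
            d2 = float(sdf_capsule(p + delta, a, b, r))
            assert abs(d2 - d) <= np.linalg.norm(delta) + 1e-12

        check()
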