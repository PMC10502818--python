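"""Channel trees, alveoli, icosahedral vessel nets and construct assembly."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from auxforge.geometry import extract_surface, sphere_sdf, union_of_spheres_sdf
from auxforge.perfusable import (AlveolusDesign, ChannelDesign,
                                 VesselNetDesign, assemble_perfusable_construct,
                                 gen_alveolus, gen_channel_tree,
                                 gen_icosa_network, hollow_shape,
                                 void_connected, wrap_network_to_offset_surface)


class TestChannelTree:
    def test_degenerate_single_straight_channel(self):
        net = gen_channel_tree(ChannelDesign(n_copies=1, amplitude=0.0, D=0.0))
        assert np.abs(net.vertices[:, :2]).max() < 1e-12
        assert net.n_components() == 1

    def test_sevenfold_rotational_symmetry(self):
        net = gen_channel_tree(ChannelDesign(n_copies=7))
        ang = 2 * np.pi / 7
        Rm = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        d, _ = cKDTree(net.vertices).query(net.vertices @ Rm.T)
        assert d.max() < 1e-9

    def test_inlet_outlet_path_count(self):
        # unit-capacity max flow between the inlet and outlet junctions
        # equals the number of parallel channel branches
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import maximum_flow

        c = ChannelDesign(n_copies=7)
        net = gen_channel_tree(c)
        assert net.n_components() == 1
        L = 0.8 * c.block[2] / 2
        tree = cKDTree(net.vertices)
        _, src = tree.query([0, 0, L])
        _, snk = tree.query([0, 0, -L])
        i, j = net.beams[:, 0], net.beams[:, 1]
        cap = coo_matrix((np.ones(net.n_beams, dtype=np.int32), (i, j)),
                         shape=(net.n_vertices,) * 2)
        cap = (cap + cap.T).tocsr()
        flow = maximum_flow(cap, int(src), int(snk)).flow_value
        assert flow == c.n_copies

    def test_thickness_tapers_from_inlet(self):
        c = ChannelDesign(d=1.5, t=0.5)
        net = gen_channel_tree(c)
        assert net.thickness.max() <= c.d + 1e-12
        assert net.thickness.min() >= c.t - 1e-12


class TestAlveolus:
    def test_single_bud_is_one_sphere(self):
        grid, centers, radii = gen_alveolus(
            AlveolusDesign(n_buds=1, Rp=2.0, r=1.0), spacing=0.1)
        assert len(centers) == 1 and np.allclose(centers[0], 0)
        v = grid.solid_volume()
        assert v == pytest.approx(4 / 3 * np.pi, rel=0.05)

    def test_centers_bound_by_periphery(self):
        _, centers, _ = gen_alveolus(AlveolusDesign(n_buds=12, o=0.5),
                                     spacing=0.2)
        assert np.linalg.norm(centers, axis=1).max() <= 3.0 + 1e-9

    def test_union_volume_bounded_by_sum(self):
        grid, centers, radii = gen_alveolus(AlveolusDesign(), spacing=0.1)
        v_sum = (4 / 3 * np.pi * radii ** 3).sum()
        assert grid.solid_volume() <= v_sum * 1.02    # voxel tolerance

    def test_overlapping_buds_strictly_smaller_than_sum(self):
        a = AlveolusDesign(Rp=1.5, r=1.2, o=0.3, n_buds=6)
        grid, centers, radii = gen_alveolus(a, spacing=0.08)
        v_sum = (4 / 3 * np.pi * radii ** 3).sum()
        assert grid.solid_volume() < 0.9 * v_sum

    def test_unplaceable_spacing_reports_achieved_count(self):
        with pytest.raises(ValueError, match="achieved"):
            gen_alveolus(AlveolusDesign(n_buds=40, o=2.5), spacing=0.3)

    def test_random_mode_deterministic(self):
        a = AlveolusDesign(placement="random", seed=5, n_buds=6, o=0.6)
        _, c1, _ = gen_alveolus(a, spacing=0.3)
        _, c2, _ = gen_alveolus(a, spacing=0.3)
        assert np.array_equal(c1, c2)


class TestHollow:
    def test_sphere_shell_thickness(self):
        from auxforge.geometry import grid_from_bounds, sample_sdf

        R, s = 2.0, 0.7
        g = sample_sdf(grid_from_bounds([-2.4] * 3, [2.4] * 3, 0.06),
                       sphere_sdf([0, 0, 0], R))
        shell = hollow_shape(g, s)
        # shell spans radii [s*R, R]
        cx, cy, cz = shell.centers()
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        rr = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)[shell.indicator()]
        assert rr.min() == pytest.approx(s * R, abs=2 * shell.spacing)
        assert rr.max() == pytest.approx(R, abs=2 * shell.spacing)

    def test_invalid_scale_rejected(self):
        from auxforge.geometry import grid_from_bounds, sample_sdf

        g = sample_sdf(grid_from_bounds([-2] * 3, [2] * 3, 0.1),
                       sphere_sdf([0, 0, 0], 1.0))
        for s in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                hollow_shape(g, s)

    def test_shell_surface_watertight(self):
        from auxforge.geometry import grid_from_bounds, sample_sdf

        g = sample_sdf(grid_from_bounds([-2.4] * 3, [2.4] * 3, 0.08),
                       sphere_sdf([0, 0, 0], 2.0))
        shell = hollow_shape(g, 0.6)
        surf = extract_surface(shell)
        assert surf.is_watertight()
        # two closed components (outer + inner sphere): Euler characteristic 4
        assert surf.euler_characteristic() == 4


class TestIcosaNetwork:
    @pytest.mark.parametrize("level,n_beams", [(0, 60), (1, 240), (2, 960)])
    def test_beam_counts_per_level(self, level, n_beams):
        net = gen_icosa_network(VesselNetDesign(level=level, n_interp=2))
        assert net.n_beams == n_beams          # 3 beams per face, faces x4
        assert net.n_components() == 1

    def test_degree_pattern_before_interpolation(self):
        net = gen_icosa_network(VesselNetDesign(level=1, n_interp=2))
        deg = net.degrees()
        assert set(deg) == {2, 3}
        assert (deg == 3).sum() == 80          # one per face (centroids)
        assert (deg == 2).sum() == 120         # one per edge (midpoints)

    def test_interpolation_gives_ten_sub_beams(self):
        net = gen_icosa_network(VesselNetDesign(level=1, n_interp=11))
        assert net.n_beams == 240 * 10

    def test_points_on_circumscribed_sphere(self):
        v = VesselNetDesign(level=1, radius=4.0)
        net = gen_icosa_network(v)
        r = np.linalg.norm(net.vertices, axis=1)
        assert np.abs(r - v.radius).max() < 1e-9

    def test_thickness_gradient_ends_thicker_than_middle(self):
        v = VesselNetDesign(level=1, base_thickness=0.4, mid_thickness=0.2)
        net = gen_icosa_network(v)
        x = np.abs(net.vertices[net.beams].mean(axis=1)[:, 0])
        outer = net.thickness[x > 0.8 * x.max()].mean()
        inner = net.thickness[x < 0.2 * x.max()].mean()
        assert outer > inner


class TestOffsetWrap:
    def test_identity_on_circumsphere_with_zero_gap(self):
        v = VesselNetDesign(level=1, radius=4.0)
        net = gen_icosa_network(v)
        out = wrap_network_to_offset_surface(net, [[0, 0, 0]], [4.0], gap=0.0)
        assert np.abs(out.vertices - net.vertices).max() < 1e-9

    def test_gap_is_respected(self):
        v = VesselNetDesign(level=1, radius=4.0)
        net = gen_icosa_network(v)
        a = AlveolusDesign(Rp=2.4, r=1.0, o=0.7, n_buds=9)
        _, centers, radii = gen_alveolus(a, spacing=0.2)
        out = wrap_network_to_offset_surface(net, centers, radii, gap=0.25)
        sdf = union_of_spheres_sdf(centers, radii)
        assert np.abs(sdf(out.vertices) - 0.25).max() < 1e-6

    def test_connectivity_unchanged(self):
        net = gen_icosa_network(VesselNetDesign(level=0))
        out = wrap_network_to_offset_surface(net, [[0, 0, 0.3]], [1.5],
                                             gap=0.1)
        assert np.array_equal(out.beams, net.beams)
        assert out.n_components() == net.n_components()


class TestAssembly:
    def test_channel_construct_is_perfusable(self):
        c = ChannelDesign()
        net = gen_channel_tree(c)
        grid = assemble_perfusable_construct(
            net, cavity_sdf=sphere_sdf([0, 0, 0], c.sphere_radius),
            outer="box", outer_dims=c.block, spacing=0.15, n_ports=0)
        bz = c.block[2]
        assert void_connected(grid, [0, 0, bz / 2 - 0.2],
                              [0, 0, -bz / 2 + 0.2])

    def test_no_channels_leaves_single_cavity(self):
        from scipy import ndimage

        grid = assemble_perfusable_construct(
            None, cavity_sdf=sphere_sdf([0, 0, 0], 1.5),
            outer="box", outer_dims=(6, 6, 6), spacing=0.15)
        lab, n = ndimage.label(~grid.indicator())
        assert n == 2                      # exterior + the cavity

    def test_cavity_accommodates_prefabricated_sphere(self):
        # voxel set of a sphere of the cavity's radius is contained in the
        # carved cavity (prefab integration)
        from auxforge.geometry import sample_sdf

        R_cav = 1.5
        grid = assemble_perfusable_construct(
            None, cavity_sdf=sphere_sdf([0, 0, 0], R_cav),
            outer="box", outer_dims=(6, 6, 6), spacing=0.15)
        sph = sample_sdf(grid.like(grid.values), sphere_sdf([0, 0, 0], R_cav))
        assert not (sph.indicator() & grid.indicator()).any()

    def test_ports_require_branch_points(self):
        from auxforge.geometry import BeamNetwork

        line = BeamNetwork([[0, 0, -3], [0, 0, 3]], [[0, 1]], 0.5)
        with pytest.raises(ValueError, match="branch"):
            assemble_perfusable_construct(line, outer="box",
                                          outer_dims=(4, 4, 8), spacing=0.2)

    def test_subtraction_monotone(self):
        from auxforge.geometry import sample_sdf, grid_from_bounds, box_sdf

        c = ChannelDesign()
        net = gen_channel_tree(c)
        full = assemble_perfusable_construct(net, outer="box",
                                             outer_dims=c.block, spacing=0.2,
                                             n_ports=0)
        outer_only = assemble_perfusable_construct(
            None, outer="box", outer_dims=c.block, spacing=0.2)
        assert not (full.indicator() & ~outer_only.indicator()).any()

    def test_vessel_ports_reach_branch_points(self):
        # vessel thickness comfortably above the voxel size so the carved
        # capillary voids stay connected on the grid
        v = VesselNetDesign(level=1, radius=3.0, base_thickness=0.8,
                            mid_thickness=0.5)
        net = gen_icosa_network(v)
        grid = assemble_perfusable_construct(
            net, cavity_sdf=sphere_sdf([0, 0, 0], 2.0), outer="cylinder",
            outer_dims=(4.5, 10.0), spacing=0.12, n_ports=2)
        # the embedded vessel void is reachable from outside only through
        # the port shafts cut into the top face; probe an actual vessel
        # vertex (points between beams are solid)
        corner = grid.origin + 0.5 * grid.spacing
        probe = net.vertices[int(np.argmax(net.vertices[:, 0]))]
        assert void_connected(grid, corner, probe)
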