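"""Perfusable construct design: channel trees, budding alveoli and
icosahedral capillary networks, plus boolean assembly into printable solids.

The building blocks mirror a lung-tissue chip: a hollow construct is carved
from an outer solid by subtracting a vessel/channel network, a central
cavity (sphere or alveolar pocket) and inlet/outlet port cylinders, leaving
one connected void from inlet to outlet (perfusability, checked by flood
fill).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (BeamNetwork, VoxelGrid, _min_capsule_sdf_into, boolean_op,
                       box_sdf, cylinder_sdf, grid_from_bounds, sample_sdf,
                       sphere_sdf, union_of_spheres_sdf)

__all__ = ["ChannelDesign", "AlveolusDesign", "VesselNetDesign",
           "gen_channel_tree", "gen_alveolus", "hollow_shape",
           "gen_icosa_network", "wrap_network_to_offset_surface",
           "assemble_perfusable_construct", "void_connected"]


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class ChannelDesign:
    """Hyperbolic-sine channel tree around a central cavity.

    ``d`` inlet channel diameter (mm), ``t`` individual channel thickness
    (mm), ``D`` diameter of the channel offset circle at the centre (mm),
    ``n_copies`` rotational copies about the axis, ``amplitude`` the sinh
    amplitude (mm, 0 = straight), ``block`` outer cuboid dims (mm),
    ``sphere_radius``/``sphere_offset`` the central cavity sphere and its
    clearance from the channels.
    """

    d: float = 1.2
    t: float = 0.6
    D: float = 4.0
    n_copies: int = 7
    amplitude: float = 0.5
    block: tuple = (8.0, 8.0, 12.0)
    sphere_radius: float = 1.5
    sphere_offset: float = 0.5

    def __post_init__(self):
        if self.d <= 0 or self.t <= 0:
            raise ValueError("channel diameters must be positive")
        if self.D < 0 or self.amplitude < 0:
            raise ValueError("D and amplitude must be >= 0")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class AlveolusDesign:
    """Budding alveolus: a parent sphere divided into mini-spheres.

    Mini-sphere centres sit inside the parent (radius ``Rp``) at mutual
    spacing >= ``o``; each is scaled up to radius ``r``.  ``placement`` is
    ``"fibonacci"`` (deterministic spherical Fibonacci shell) or
    ``"random"`` (seeded rejection sampling).
    """

    Rp: float = 3.0
    r: float = 1.2
    o: float = 0.8
    n_buds: int = 9
    wall: float = 0.3
    seed: int = 0
    placement: str = "fibonacci"

    def __post_init__(self):
        if not (0 < self.r < self.Rp):
            raise ValueError("need 0 < r < Rp")
        if self.n_buds < 1:
            raise ValueError("n_buds must be >= 1")
        if self.wall <= 0:
            raise ValueError("wall must be positive")
        if self.o < 0:
            raise ValueError("offset o must be >= 0")
        if self.placement not in ("fibonacci", "random"):
            raise ValueError("placement must be 'fibonacci' or 'random'")


@dataclass
class VesselNetDesign:
    """Icosahedral capillary network parameters.

    ``level`` is the subdivision density D (faces x4 per level), thickness
    is linearly graded from ``base_thickness`` at the left/right ends of the
    inlet-outlet axis to ``mid_thickness`` at the equator, the top cap is
    spread by ``top_enlarge`` to open an inlet window, every beam is
    interpolated into ``n_interp`` equidistant points (n_interp - 1
    sub-beams) and wrapped onto the circumscribed sphere of ``radius``;
    ``gap`` (mm) is the clearance kept between vessels and alveolus.
    """

    level: int = 1
    base_thickness: float = 0.4
    mid_thickness: float = 0.2
    top_enlarge: float = 2.0
    n_interp: int = 11
    gap: float = 0.25
    radius: float = 4.0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("level must be >= 0")
        if self.base_thickness <= 0 or self.mid_thickness <= 0:
            raise ValueError("thicknesses must be positive")
        if self.n_interp < 2:
            raise ValueError("n_interp must be >= 2")
        if self.gap < 0 or self.radius <= 0:
            raise ValueError("gap >= 0 and radius > 0 required")


# ---------------------------------------------------------------------------
# channel tree
# ---------------------------------------------------------------------------

def gen_channel_tree(c: ChannelDesign, n_samples: int = 24) -> BeamNetwork:
    """One sinh-profile channel, rotated into ``n_copies`` copies about the
    z axis, mirrored through the midplane with the channel offset circle of
    diameter ``D`` at the centre, the two halves joined by straight
    channels; thickness tapers from ``d`` at the inlet to ``t``.

    With zero amplitude the radial profile degenerates to a straight taper
    (and with D = 0 to a single axial channel).
    """
    bz = c.block[2]
    top = bz / 2 + c.t          # stubs pierce the block faces
    L = 0.8 * bz / 2            # inlet/outlet junctions
    zeta = 0.15 * bz / 2        # straight mid-section half-length

    u = np.linspace(0.0, 1.0, n_samples)
    if c.amplitude > 1e-12 and c.D > 0:
        k = math.asinh(c.D / (2 * c.amplitude))
        rho = c.amplitude * np.sinh(k * u)
    else:
        rho = (c.D / 2) * u
    z_half = L - u * (L - zeta)
    thick_half = c.d + u * (c.t - c.d)

    nets = []
    for m in range(c.n_copies):
        phi = 2 * np.pi * m / c.n_copies
        cphi, sphi = math.cos(phi), math.sin(phi)
        for sign in (1.0, -1.0):        # top half and mirrored bottom half
            pts = np.column_stack([rho * cphi, rho * sphi, sign * z_half])
            beams = np.column_stack([np.arange(n_samples - 1),
                                     np.arange(1, n_samples)])
            th = 0.5 * (thick_half[:-1] + thick_half[1:])
            nets.append(BeamNetwork(pts, beams, th))
        # straight connector through the midplane at radius D/2
        pa = np.array([[c.D / 2 * cphi, c.D / 2 * sphi, zeta],
                       [c.D / 2 * cphi, c.D / 2 * sphi, -zeta]])
        nets.append(BeamNetwork(pa, [[0, 1]], c.t))
    # inlet / outlet stubs out through the top and bottom faces
    stub = np.array([[0.0, 0.0, L], [0.0, 0.0, top]])
    nets.append(BeamNetwork(stub, [[0, 1]], c.d))
    nets.append(BeamNetwork(stub * [1, 1, -1], [[0, 1]], c.d))
    from .geometry import concat_networks
    return concat_networks(nets, merge_tol=1e-9)


# ---------------------------------------------------------------------------
# alveolus
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = np.pi * (1 + math.sqrt(5.0)) * i
    s = np.sqrt(1 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def gen_alveolus(a: AlveolusDesign, spacing: float | None = None,
                 padding: float | None = None):
    """Budding alveolus solid.

    Returns ``(grid, centers, radii)``: an SDF voxel grid of the union of
    mini-spheres plus the centre list.  Centres are bound by the parent
    periphery (|c| <= Rp) and mutually spaced >= o; placement is the seeded
    rejection sampler or the deterministic Fibonacci shell.  Raises with the
    achieved count when n_buds cannot be placed at spacing o.
    """
    if a.n_buds == 1:
        centers = np.zeros((1, 3))
    elif a.placement == "fibonacci":
        shell = max(a.Rp - a.r / 2, 0.0)
        centers = shell * _fibonacci_directions(a.n_buds)
        dmin = np.inf
        for i in range(a.n_buds):
            d = np.linalg.norm(centers[i + 1:] - centers[i], axis=1)
            if len(d):
                dmin = min(dmin, d.min())
        if dmin < a.o:
            n_ok = _max_fibonacci_count(shell, a.o, a.n_buds)
            raise ValueError(
                f"cannot place {a.n_buds} mini-spheres at spacing {a.o} on "
                f"the Fibonacci shell (min spacing {dmin:.3g}); "
                f"achieved count {n_ok}")
    else:
        rng = np.random.default_rng(a.seed)
        centers_list: list[np.ndarray] = []
        tries = 0
        while len(centers_list) < a.n_buds:
            c = rng.uniform(-a.Rp, a.Rp, 3)
            tries += 1
            if np.linalg.norm(c) > a.Rp:
                continue
            if all(np.linalg.norm(c - e) >= a.o for e in centers_list):
                centers_list.append(c)
                tries = 0
            elif tries > 20000:
                raise ValueError(
                    f"cannot place {a.n_buds} mini-spheres at spacing "
                    f"{a.o}; achieved count {len(centers_list)}")
        centers = np.array(centers_list)
    radii = np.full(len(centers), a.r)
    if spacing is None:
        spacing = a.r / 6
    if padding is None:
        padding = 2 * spacing
    lo = centers.min(axis=0) - a.r - padding
    hi = centers.max(axis=0) + a.r + padding
    grid = grid_from_bounds(lo, hi, spacing)
    grid = sample_sdf(grid, union_of_spheres_sdf(centers, radii))
    return grid, centers, radii


def _max_fibonacci_count(shell: float, o: float, n_max: int) -> int:
    for n in range(n_max, 0, -1):
        c = shell * _fibonacci_directions(n)
        if n == 1:
            return 1
        dmin = min(np.linalg.norm(c[i] - c[j])
                   for i in range(n) for j in range(i + 1, n))
        if dmin >= o:
            return n
    return 0


def hollow_shape(solid: VoxelGrid, scale: float) -> VoxelGrid:
    """Hollow a solid by subtracting a concentric scaled-down copy.

    The copy is scaled about the solid's centroid; for a true SDF the scaled
    field is ``scale * f(center + (p - center)/scale)``, resampled on the
    same grid (linear interpolation).  ``scale`` must lie in (0, 1).
    """
    if not (0 < scale < 1):
        raise ValueError("scale must lie strictly between 0 and 1")
    ind = solid.indicator()
    if not ind.any():
        raise ValueError("solid grid has no interior voxels")
    idx = np.argwhere(ind)
    center_idx = idx.mean(axis=0)
    # index-space scaling about the centroid (isotropic grid: identical to mm)
    grids = np.meshgrid(*[np.arange(n) for n in solid.shape], indexing="ij")
    coords = [center_idx[i] + (grids[i] - center_idx[i]) / scale
              for i in range(3)]
    far = float(solid.values.max())
    inner = scale * ndimage.map_coordinates(solid.values, coords, order=1,
                                            mode="constant", cval=far)
    out = solid.like(np.maximum(solid.values, -inner))
    if not out.indicator().any():
        raise ValueError("hollowing removed the entire solid")
    return out


# ---------------------------------------------------------------------------
# icosahedral vessel network
# ---------------------------------------------------------------------------

def _icosahedron_vertex_up() -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron (circumradius 1) rotated so a vertex points +z."""
    import trimesh

    ico = trimesh.creation.icosahedron()
    v = np.asarray(ico.vertices, float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)[0]
    top = v[np.argmax(v[:, 2])]
    axis_z = top / np.linalg.norm(top)
    # rotate axis_z onto +z
    z = np.array([0.0, 0.0, 1.0])
    c = float(axis_z @ z)
    if c < 1 - 1e-12:
        ax = np.cross(axis_z, z)
        s = np.linalg.norm(ax)
        ax = ax / s
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                      [-ax[1], ax[0], 0]])
        Rm = np.eye(3) + s * K + (1 - c) * (K @ K)
        v = v @ Rm.T
    return v, np.asarray(ico.faces, dtype=np.intp)


def _subdivide_faces(verts: np.ndarray, faces: np.ndarray):
    """One level of 4-way midpoint subdivision (no spherical projection)."""
    edge_mid: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def mid(i, j):
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            verts.append((np.asarray(verts[i]) + np.asarray(verts[j])) / 2)
            edge_mid[key] = len(verts) - 1
        return edge_mid[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    return np.array(verts), np.array(new_faces, dtype=np.intp)


def gen_icosa_network(v: VesselNetDesign) -> BeamNetwork:
    """Capillary network from a subdivided icosahedron.

    Every face is split 4-way ``level`` times; each triangle's geometric
    centre is joined to its three edge midpoints (3 beams per face, so 60
    beams at level 0 and 240 at level 1).  Thickness is graded linearly from
    the axis ends to the equator, every beam is interpolated into
    ``n_interp`` equidistant points, and all points are projected radially
    onto the circumscribed sphere; finally the cap around the apex vertex is
    spread over the sphere by ``top_enlarge`` (polar angles inside the cap
    scaled by the factor, blending smoothly to identity) to open the inlet
    window.  A straight pre-projection scaling of the cap by exactly 2 would
    collapse cap centroids onto their neighbours (a midpoint-subdivision
    identity), so the opening is cut on the sphere instead.
    """
    verts, faces = _icosahedron_vertex_up()
    apex = int(np.argmax(verts[:, 2]))
    for _ in range(v.level):
        verts, faces = _subdivide_faces(verts, faces)

    # centroid + edge-midpoint graph
    mid_index: dict[tuple[int, int], int] = {}
    net_verts: list[np.ndarray] = []
    beams: list[tuple[int, int]] = []
    apex_touched: list[int] = []

    def midpoint_id(i, j):
        key = (min(i, j), max(i, j))
        if key not in mid_index:
            net_verts.append((verts[i] + verts[j]) / 2)
            mid_index[key] = len(net_verts) - 1
        return mid_index[key]

    for f in faces:
        edges = [(f[0], f[1]), (f[1], f[2]), (f[2], f[0])]
        mids = [midpoint_id(*e) for e in edges]
        net_verts.append(verts[f].mean(axis=0))
        cen_id = len(net_verts) - 1
        for m in mids:
            beams.append((cen_id, m))
        if apex in f:
            # the opening is cut by moving the cap's inner ring (apex-face
            # centroids and apex-edge midpoints); boundary midpoints shared
            # with non-apex faces stay put
            apex_touched.append(cen_id)
            apex_touched += [m for m, e in zip(mids, edges) if apex in e]
    net_verts = np.array(net_verts)

    # thickness gradient along the inlet-outlet (x) axis
    beams_arr = np.array(beams)
    xm = np.abs(net_verts[beams_arr].mean(axis=1)[:, 0])
    xmax = max(xm.max(), 1e-12)
    thick = v.mid_thickness + (v.base_thickness - v.mid_thickness) * xm / xmax
    net = BeamNetwork(net_verts * v.radius, beams_arr, thick)

    # cap angular radius before subdivision (inner ring of the apex cap)
    cap = np.array(sorted(set(apex_touched)))
    dirs = net_verts[cap] / np.linalg.norm(net_verts[cap], axis=1,
                                           keepdims=True)
    psi_cap = float(np.arccos(np.clip(dirs[:, 2], -1, 1)).max())

    # equidistant interpolation, then wrap onto the circumscribed sphere
    fine = net.subdivided(v.n_interp - 1)

    def to_sphere(p):
        n = np.linalg.norm(p, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return v.radius * p / n

    on_sphere = fine.transformed(to_sphere)
    opened = on_sphere.transformed(
        lambda p: _spread_cap(p, v.radius, v.top_enlarge, psi_cap))
    return opened.merged(1e-9)


def _spread_cap(p: np.ndarray, radius: float, factor: float,
                psi_cap: float) -> np.ndarray:
    """Open the inlet window: scale polar angles within the apex cap by
    ``factor``, blending linearly back to identity outside (monotone map,
    so no two beams ever collapse onto each other)."""
    if factor == 1.0:
        return p
    psi = np.arccos(np.clip(p[:, 2] / radius, -1, 1))
    psi_end = min(0.45 * np.pi, 2.2 * factor * psi_cap)
    psi_end = max(psi_end, 1.05 * factor * psi_cap)
    # piecewise-linear monotone map: [0, cap] scaled by the factor, then
    # [cap, end] compressed onto [factor*cap, end], identity beyond
    slope = (psi_end - factor * psi_cap) / max(psi_end - psi_cap, 1e-12)
    new_psi = np.where(
        psi <= psi_cap, factor * psi,
        np.where(psi >= psi_end, psi,
                 factor * psi_cap + (psi - psi_cap) * slope))
    phi = np.arctan2(p[:, 1], p[:, 0])
    s = np.sin(new_psi)
    return np.stack([radius * s * np.cos(phi), radius * s * np.sin(phi),
                     radius * np.cos(new_psi)], axis=-1)


def wrap_network_to_offset_surface(net: BeamNetwork, centers, radii,
                                   gap: float, n_iter: int = 60,
                                   tol: float = 1e-9) -> BeamNetwork:
    """Project every network point onto the union-of-spheres surface dilated
    by ``gap`` (closest point on the offset surface).

    Uses damped gradient marching on the exact union SDF; for a single
    sphere this reduces to radial projection, and with gap = 0 onto the very
    sphere the net already lies on it is the identity.  Connectivity is
    unchanged.
    """
    sdf = union_of_spheres_sdf(centers, radii)
    centers = np.atleast_2d(np.asarray(centers, float))
    radii = np.broadcast_to(np.asarray(radii, float), (len(centers),))
    p = net.vertices.copy()
    for _ in range(n_iter):
        d = np.linalg.norm(p[:, None, :] - centers, axis=-1) - radii
        best = d.argmin(axis=1)
        f = d[np.arange(len(p)), best] - gap
        if np.max(np.abs(f)) < tol:
            break
        g = p - centers[best]
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        gn[gn == 0] = 1.0
        p = p - 0.8 * f[:, None] * (g / gn)
    return BeamNetwork(p, net.beams.copy(), net.thickness.copy(),
                       None if net.labels is None else list(net.labels))


# ---------------------------------------------------------------------------
# assembly and perfusability
# ---------------------------------------------------------------------------

def assemble_perfusable_construct(net: BeamNetwork | None,
                                  cavity_sdf=None,
                                  outer: str = "box",
                                  outer_dims=(8.0, 8.0, 12.0),
                                  spacing: float = 0.15,
                                  port_radius: float | None = None,
                                  n_ports: int = 2) -> VoxelGrid:
    """Carve channels, a cavity and inlet/outlet ports out of an outer solid.

    ``outer`` is ``"box"`` (dims = (x, y, z) mm, centred at the origin) or
    ``"cylinder"`` (dims = (radius, height)).  ``cavity_sdf`` is an SDF
    callable (e.g. a sphere or union of alveolar spheres) or ``None``.
    Port cylinders are sunk from the top face to the branch points (vertices
    of degree >= 3) nearest to ``n_ports`` antipodal top positions; an error
    is raised if the network has no branch point to intersect.  Subtraction
    never creates solid where none existed.
    """
    if outer == "box":
        dims = np.asarray(outer_dims, float)
        lo, hi = -dims / 2, dims / 2
        outer_fn = box_sdf(lo, hi)
    elif outer == "cylinder":
        rad, height = float(outer_dims[0]), float(outer_dims[1])
        lo = np.array([-rad, -rad, -height / 2])
        hi = np.array([rad, rad, height / 2])
        outer_fn = cylinder_sdf([0, 0, 0], rad, height / 2)
    else:
        raise ValueError("outer must be 'box' or 'cylinder'")
    grid = sample_sdf(grid_from_bounds(lo - spacing, hi + spacing, spacing),
                      outer_fn)

    if net is not None:
        chan = grid.like(np.full(grid.shape, float(np.linalg.norm(hi - lo))))
        _min_capsule_sdf_into(chan, net)
        grid = boolean_op(grid, chan, "subtract")

        if n_ports > 0:
            deg = net.degrees()
            branch = np.nonzero(deg >= 3)[0]
            if len(branch) == 0:
                raise ValueError("no branching point for port placement")
            bp = net.vertices[branch]
            top_z = hi[2]
            r_port = (net.thickness.max() / 2 if port_radius is None
                      else port_radius)
            for k in range(n_ports):
                phi = 2 * np.pi * k / max(n_ports, 1)
                target = np.array([0.6 * hi[0] * np.cos(phi),
                                   0.6 * hi[1] * np.sin(phi), top_z])
                i = int(np.argmin(np.linalg.norm(bp - target, axis=1)))
                p = bp[i]
                half = (top_z + spacing - p[2]) / 2 + r_port / 2
                port_fn = cylinder_sdf([p[0], p[1], top_z + spacing - half],
                                       r_port, half)
                grid = boolean_op(grid, sample_sdf(grid.like(grid.values),
                                                   port_fn), "subtract")
    if cavity_sdf is not None:
        grid = boolean_op(grid, sample_sdf(grid.like(grid.values),
                                           cavity_sdf), "subtract")
    return grid


def void_connected(grid: VoxelGrid, p_a, p_b) -> bool:
    """Are two points inside the same 6-connected void component?"""
    lab, _ = ndimage.label(~grid.indicator(),
                           structure=ndimage.generate_binary_structure(3, 1))

    def voxel_of(p):
        i = np.floor((np.asarray(p, float) - grid.origin) / grid.spacing)
        i = np.clip(i, 0, np.array(grid.shape) - 1).astype(int)
        return tuple(i)

    la, lb = lab[voxel_of(p_a)], lab[voxel_of(p_b)]
    return bool(la != 0 and la == lb)
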