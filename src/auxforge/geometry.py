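"""Shared geometric substrate for lattice design.

Beam networks, capsule signed-distance fields, voxelization, boolean CSG,
iso-surface extraction and STL I/O.  All lengths are millimetres; voxel grids
are isotropic.  The signed-distance convention is negative = inside, stated
here once and asserted throughout the test suite.

Points are plain ``(3,)`` float arrays (or ``(N, 3)`` batches); a
:class:`BeamNetwork` stores vertices together with thickness-attributed
edges and is the universal representation for auxetic lattices and vessel
networks alike.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BeamNetwork",
    "VoxelGrid",
    "TriSurface",
    "sdf_capsule",
    "voxelize_network",
    "boolean_op",
    "extract_surface",
    "read_stl",
    "write_stl",
    "grid_from_bounds",
    "sample_sdf",
    "sphere_sdf",
    "box_sdf",
    "cylinder_sdf",
    "union_of_spheres_sdf",
]


# ---------------------------------------------------------------------------
# beam networks
# ---------------------------------------------------------------------------

@dataclass
class BeamNetwork:
    """A lattice of straight beams.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.
    beams : (M, 2) int array
        Vertex index pairs.  Pairs are unordered; duplicates (in either
        orientation) are invalid.
    thickness : (M,) float array
        Solid diameter of each beam in mm (beams are rendered as capsules of
        radius ``thickness / 2``).
    labels : list of str, optional
        Per-beam tags (e.g. ``"vertical"``/``"horizontal"``).
    """

    vertices: np.ndarray
    beams: np.ndarray
    thickness: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.beams = np.asarray(self.beams, dtype=np.intp).reshape(-1, 2)
        self.thickness = np.broadcast_to(
            np.asarray(self.thickness, dtype=float), (len(self.beams),)
        ).copy()
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if len(self.beams):
            if self.beams.min() < 0 or self.beams.max() >= len(self.vertices):
                raise ValueError("beam index out of range")
            if np.any(self.beams[:, 0] == self.beams[:, 1]):
                raise ValueError("degenerate beam (a == b)")
            key = np.sort(self.beams, axis=1)
            uniq = np.unique(key, axis=0)
            if len(uniq) != len(key):
                raise ValueError("duplicate beams (unordered pair uniqueness)")
            if np.any(self.thickness <= 0):
                raise ValueError("beam thickness must be positive")

    # -- basic queries ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box of the centre-lines (ignores thickness)."""
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def segment_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices[self.beams[:, 0]], self.vertices[self.beams[:, 1]]

    def n_components(self) -> int:
        """Number of connected components of the beam graph."""
        if self.n_vertices == 0:
            return 0
        m = coo_matrix(
            (np.ones(self.n_beams), (self.beams[:, 0], self.beams[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        n, _ = connected_components(m, directed=False)
        return n

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        np.add.at(deg, self.beams[:, 0], 1)
        np.add.at(deg, self.beams[:, 1], 1)
        return deg

    # -- transforms ---------------------------------------------------------
    def translated(self, offset) -> "BeamNetwork":
        return BeamNetwork(self.vertices + np.asarray(offset, float),
                           self.beams.copy(), self.thickness.copy(),
                           None if self.labels is None else list(self.labels))

    def transformed(self, fn) -> "BeamNetwork":
        """Apply ``fn`` (mapping (N,3) -> (N,3)) to the vertices."""
        return BeamNetwork(fn(self.vertices), self.beams.copy(),
                           self.thickness.copy(),
                           None if self.labels is None else list(self.labels))

    def subdivided(self, n_per_beam) -> "BeamNetwork":
        """Split every beam into straight sub-beams.

        ``n_per_beam`` is an int (same count for every beam) or an (M,) array
        of per-beam counts.  Interior points are equidistant along each beam;
        thickness (and label) is inherited by the sub-beams.
        """
        n_per_beam = np.broadcast_to(np.asarray(n_per_beam, dtype=int),
                                     (self.n_beams,))
        if np.any(n_per_beam < 1):
            raise ValueError("subdivision count must be >= 1")
        verts = [self.vertices]
        beams, thick, labels = [], [], []
        next_idx = self.n_vertices
        for k, (a, b) in enumerate(self.beams):
            n = n_per_beam[k]
            chain = [a]
            if n > 1:
                ts = np.arange(1, n) / n
                pts = (1 - ts[:, None]) * self.vertices[a] + ts[:, None] * self.vertices[b]
                verts.append(pts)
                chain += list(range(next_idx, next_idx + n - 1))
                next_idx += n - 1
            chain.append(b)
            for i in range(n):
                beams.append((chain[i], chain[i + 1]))
                thick.append(self.thickness[k])
                if self.labels is not None:
                    labels.append(self.labels[k])
        return BeamNetwork(np.vstack(verts), np.array(beams), np.array(thick),
                           labels if self.labels is not None else None)

    def merged(self, tol: float = 1e-9) -> "BeamNetwork":
        """Merge vertices closer than ``tol`` and drop duplicate/degenerate beams."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.vertices)
        parent = np.arange(self.n_vertices)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in tree.query_pairs(tol, output_type="ndarray"):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        roots = np.array([find(i) for i in range(self.n_vertices)])
        first, inv = np.unique(roots, return_inverse=True)
        verts = self.vertices[first]
        beams = inv[self.beams]
        keep = beams[:, 0] != beams[:, 1]
        beams, thick = beams[keep], self.thickness[keep]
        labels = ([l for l, k in zip(self.labels, keep) if k]
                  if self.labels is not None else None)
        key = np.sort(beams, axis=1)
        _, uniq = np.unique(key, axis=0, return_index=True)
        uniq = np.sort(uniq)
        return BeamNetwork(verts, beams[uniq], thick[uniq],
                           [labels[i] for i in uniq] if labels is not None else None)


def concat_networks(nets: list[BeamNetwork], merge_tol: float | None = 1e-9) -> BeamNetwork:
    """Concatenate networks, optionally fusing coincident vertices."""
    verts = np.vstack([n.vertices for n in nets])
    offs = np.cumsum([0] + [n.n_vertices for n in nets])[:-1]
    beams = np.vstack([n.beams + o for n, o in zip(nets, offs)])
    thick = np.concatenate([n.thickness for n in nets])
    labels = None
    if all(n.labels is not None for n in nets):
        labels = sum((list(n.labels) for n in nets), [])
    net = BeamNetwork(verts, beams, thick, labels)
    return net.merged(merge_tol) if merge_tol is not None else net


# ---------------------------------------------------------------------------
# signed distance fields
# ---------------------------------------------------------------------------

def sdf_capsule(p, a, b, r: float) -> np.ndarray:
    """Exact signed distance from point(s) ``p`` to the capsule around
    segment ``ab`` inflated by radius ``r`` (negative inside).

    A zero-length segment (``a == b``) degenerates to a sphere of radius
    ``r`` — allowed by design so that generator corner cases need no special
    handling.
    """
    if r <= 0:
        raise ValueError("capsule radius must be positive")
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    pa = p - a
    if denom == 0.0:
        d = np.linalg.norm(pa, axis=-1)
        return d - r
    t = np.clip((pa @ ab) / denom, 0.0, 1.0)
    closest = a + np.multiply.outer(t, ab)
    d = np.linalg.norm(p - closest, axis=-1)
    return d - r


@dataclass
class VoxelGrid:
    """Regular, axis-aligned, isotropic scalar grid.

    ``values`` holds either a signed distance (mm, negative inside) or an
    indicator; the sample point of voxel ``(i, j, k)`` is its centre at
    ``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinate vectors."""
        return tuple(self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing
                     for i in range(3))

    def indicator(self) -> np.ndarray:
        """Boolean inside/outside view (SDF < 0)."""
        return self.values < 0.0

    def solid_volume(self) -> float:
        return float(self.indicator().sum()) * self.spacing ** 3

    def n_solid_components(self, connectivity: int = 1) -> int:
        structure = ndimage.generate_binary_structure(3, connectivity)
        _, n = ndimage.label(self.indicator(), structure=structure)
        return n

    def like(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.spacing, values)

    def copy(self) -> "VoxelGrid":
        return self.like(self.values.copy())

    # -- persistence (documented NPZ container) -----------------------------
    def save(self, path) -> None:
        np.savez_compressed(path, origin=self.origin,
                            spacing=np.float64(self.spacing), values=self.values)

    @staticmethod
    def load(path) -> "VoxelGrid":
        with np.load(path) as z:
            return VoxelGrid(z["origin"], float(z["spacing"]), z["values"])


def grid_from_bounds(lo, hi, spacing: float) -> VoxelGrid:
    """Empty (all +far) grid covering ``[lo, hi]`` at the given spacing."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    far = float(np.linalg.norm(hi - lo)) + spacing
    return VoxelGrid(lo, spacing, np.full(tuple(shape), far))


def sample_sdf(grid: VoxelGrid, fn) -> VoxelGrid:
    """Evaluate ``fn((N,3) points) -> (N,) sdf`` at all voxel centres."""
    cx, cy, cz = grid.centers()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    return grid.like(np.asarray(fn(pts), float).reshape(grid.shape))


def sphere_sdf(center, radius: float):
    center = np.asarray(center, float)

    def fn(p):
        return np.linalg.norm(np.asarray(p, float) - center, axis=-1) - radius

    return fn


def box_sdf(lo, hi):
    """Exact SDF of the axis-aligned box ``[lo, hi]``."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    c = (lo + hi) / 2
    h = (hi - lo) / 2

    def fn(p):
        q = np.abs(np.asarray(p, float) - c) - h
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(q.max(axis=-1), 0.0)
        return outside + inside

    return fn


def cylinder_sdf(center, radius: float, half_height: float, axis: int = 2):
    """Exact SDF of a finite solid cylinder aligned with a coordinate axis."""
    center = np.asarray(center, float)
    other = [i for i in range(3) if i != axis]

    def fn(p):
        p = np.asarray(p, float) - center
        dr = np.linalg.norm(p[..., other], axis=-1) - radius
        dz = np.abs(p[..., axis]) - half_height
        q = np.stack([dr, dz], axis=-1)
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(np.maximum(dr, dz), 0.0)
        return outside + inside

    return fn


def union_of_spheres_sdf(centers, radii):
    centers = np.atleast_2d(np.asarray(centers, float))
    radii = np.broadcast_to(np.asarray(radii, float), (len(centers),))

    def fn(p):
        p = np.asarray(p, float)
        d = np.linalg.norm(p[..., None, :] - centers, axis=-1) - radii
        return d.min(axis=-1)

    return fn


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def default_spacing(net: BeamNetwork) -> float:
    """Default resolution heuristic: min beam thickness / 6."""
    return float(net.thickness.min()) / 6.0


def voxelize_network(net: BeamNetwork, spacing: float | None = None,
                     padding: float | None = None) -> VoxelGrid:
    """Render a beam network as a voxel SDF grid (union of capsules).

    The grid covers the network bounding box inflated by the largest capsule
    radius plus ``padding`` (default: 2 voxels).  Values are the exact union
    SDF within a band of ``radius + 4 * spacing`` around each beam and a
    positive upper bound of the true distance elsewhere, so the inside
    indicator (SDF < 0) and the extracted iso-surface are exact.

    A spacing larger than half the thinnest beam triggers an under-resolution
    warning.  Zero-length beams render as spheres (documented degenerate
    rule; see :func:`sdf_capsule`).
    """
    if net.n_beams == 0:
        raise ValueError("cannot voxelize an empty network")
    if spacing is None:
        spacing = default_spacing(net)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > net.thickness.min() / 2:
        warnings.warn("voxel spacing exceeds min(thickness)/2: beams are "
                      "under-resolved", stacklevel=2)
    if padding is None:
        padding = 2 * spacing
    rmax = net.thickness.max() / 2
    lo, hi = net.bounds()
    grid = grid_from_bounds(lo - rmax - padding, hi + rmax + padding, spacing)
    _min_capsule_sdf_into(grid, net)
    return grid


def _min_capsule_sdf_into(grid: VoxelGrid, net: BeamNetwork) -> None:
    """In-place min-combine the capsule SDF of every beam into the grid.

    Each beam only touches voxels inside its padded bounding window, which
    keeps voxelization linear in beam count rather than beams x voxels.
    """
    cx, cy, cz = grid.centers()
    centers = (cx, cy, cz)
    A, B = net.segment_endpoints()
    radii = net.thickness / 2
    band = 4 * grid.spacing
    for a, b, r in zip(A, B, radii):
        lo = np.minimum(a, b) - r - band
        hi = np.maximum(a, b) + r + band
        sl = []
        for ax in range(3):
            i0 = int(np.searchsorted(centers[ax], lo[ax]))
            i1 = int(np.searchsorted(centers[ax], hi[ax]))
            if i0 >= i1:
                sl = None
                break
            sl.append(slice(i0, i1))
        if sl is None:
            continue
        X, Y, Z = np.meshgrid(cx[sl[0]], cy[sl[1]], cz[sl[2]], indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = sdf_capsule(pts, a, b, r)
        sub = grid.values[sl[0], sl[1], sl[2]]
        np.minimum(sub, d, out=sub)


# ---------------------------------------------------------------------------
# boolean CSG
# ---------------------------------------------------------------------------

def boolean_op(ga: VoxelGrid, gb: VoxelGrid, op: str) -> VoxelGrid:
    """SDF boolean: union = min(A, B); subtract = max(A, -B);
    intersect = max(A, B).  Grids must share origin, spacing and shape."""
    if ga.shape != gb.shape or abs(ga.spacing - gb.spacing) > 1e-12 \
            or not np.allclose(ga.origin, gb.origin, atol=1e-12):
        raise ValueError("mismatched grids (origin/spacing/shape must agree)")
    if op == "union":
        v = np.minimum(ga.values, gb.values)
    elif op == "subtract":
        v = np.maximum(ga.values, -gb.values)
    elif op == "intersect":
        v = np.maximum(ga.values, gb.values)
    else:
        raise ValueError(f"unknown boolean op {op!r} (union|subtract|intersect)")
    return ga.like(v)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Indexed triangle mesh (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.intp).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(M, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        ln = np.linalg.norm(n, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        return n / ln

    def area(self) -> float:
        t = self.triangles()
        return float(np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum() / 2)

    def euler_characteristic(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        n_verts = len(np.unique(self.faces))
        return n_verts - n_edges + self.n_faces

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def drop_degenerate_faces(self, tol: float = 0.0) -> "TriSurface":
        t = self.triangles()
        areas = np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]),
                               axis=1) / 2
        return TriSurface(self.vertices, self.faces[areas > tol])

    def as_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)


def extract_surface(grid: VoxelGrid, iso: float = 0.0) -> TriSurface:
    """Marching-cubes iso-surface of an SDF grid.

    Returns a watertight mesh for closed solids whose surface stays away from
    the grid border.  An iso level outside the value range yields an empty
    surface with a warning.
    """
    from skimage import measure

    v = grid.values
    if not (v.min() < iso < v.max()):
        warnings.warn("iso level outside grid value range: empty surface",
                      stacklevel=2)
        return TriSurface(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    verts, faces, _, _ = measure.marching_cubes(v, level=iso)
    # marching_cubes works in index space; voxel (i,j,k) samples its centre
    verts = grid.origin + (verts + 0.5) * grid.spacing
    return TriSurface(verts, faces).drop_degenerate_faces()


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

class STLParseError(ValueError):
    pass


def write_stl(surface: TriSurface, path, mode: str = "binary") -> None:
    """Write an STL file.  ``mode`` is ``"binary"`` or ``"ascii"``.

    Coordinates are emitted as float32 in both modes (ASCII uses 9
    significant digits, which round-trips float32 exactly), so the two modes
    produce identical triangle soups.
    """
    tri = surface.triangles().astype(np.float32)
    nrm = surface.face_normals().astype(np.float32)
    if mode == "binary":
        with open(path, "wb") as f:
            f.write(b"auxforge binary STL".ljust(80, b" "))
            f.write(struct.pack("<I", len(tri)))
            rec = np.zeros(len(tri), dtype=np.dtype([
                ("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
            rec["normal"] = nrm
            rec["v"] = tri
            f.write(rec.tobytes())
    elif mode == "ascii":
        with open(path, "w") as f:
            f.write("solid auxforge\n")
            for n, t in zip(nrm, tri):
                f.write("  facet normal %.9g %.9g %.9g\n" % tuple(n))
                f.write("    outer loop\n")
                for vtx in t:
                    f.write("      vertex %.9g %.9g %.9g\n" % tuple(vtx))
                f.write("    endloop\n  endfacet\n")
            f.write("endsolid auxforge\n")
    else:
        raise ValueError("mode must be 'binary' or 'ascii'")


def read_stl(path) -> TriSurface:
    """Read a binary or ASCII STL file into a triangle soup surface.

    Malformed files (truncated records, triangle-count mismatch) raise
    :class:`STLParseError` naming the byte offset of the problem.
    """
    with open(path, "rb") as f:
        data = f.read()
    if len(data) == 0:
        raise STLParseError("empty STL file (0 bytes; header expected at byte 0)")
    head = data[:512]
    if data[:5] == b"solid" and (b"facet" in head or b"endsolid" in head):
        return _read_stl_ascii(data)
    return _read_stl_binary(data)


def _read_stl_binary(data: bytes) -> TriSurface:
    if len(data) < 84:
        raise STLParseError(
            f"truncated binary STL: {len(data)} bytes, header+count need 84 "
            f"(missing data from byte {len(data)})")
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        raise STLParseError(
            f"binary STL declares {count} triangles ({expected} bytes) but "
            f"file ends at byte {len(data)}")
    rec = np.frombuffer(data, dtype=np.dtype([
        ("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]),
        count=count, offset=84)
    tri = rec["v"].astype(float).reshape(-1, 3)
    faces = np.arange(len(tri)).reshape(-1, 3)
    return TriSurface(tri, faces)


def _read_stl_ascii(data: bytes) -> TriSurface:
    verts = []
    offset = 0
    for line in data.split(b"\n"):
        stripped = line.strip()
        if stripped.startswith(b"vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise STLParseError(
                    f"malformed ASCII STL vertex line at byte {offset}")
            try:
                verts.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise STLParseError(
                    f"unparsable coordinate at byte {offset}: {exc}") from exc
        offset += len(line) + 1
    if len(verts) == 0 or len(verts) % 3 != 0:
        raise STLParseError(
            f"ASCII STL holds {len(verts)} vertices (not a multiple of 3); "
            f"file length {len(data)} bytes")
    verts = np.array(verts)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return TriSurface(verts, faces)
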