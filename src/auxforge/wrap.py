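"""Organ-specific mesh wrapping.

A planar auxetic sheet is intersected with a circle, wrapped onto a sphere,
and finally projected onto an arbitrary closed target surface (e.g. a heart
model read from STL) by smallest distance.  The sphere wrap is the
azimuthal-equidistant map: a planar point at polar coordinates (rho, phi)
lands at polar angle psi = rho / R and azimuth phi, so radial geodesic
distances from the pole equal the planar radial distances and mesh cells
stay nearly undistorted.

Closest-point queries run through a KD-tree candidate filter whose result is
contractually identical to exhaustive search over all triangles (the filter
is conservative: any triangle that could beat the current best is examined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import BeamNetwork, TriSurface

__all__ = ["WrapConfig", "clip_to_circle", "wrap_to_sphere",
           "closest_point_on_surface", "SurfaceProjector",
           "project_network_to_surface", "wrap_onto_organ",
           "gen_synthetic_organ"]


@dataclass
class WrapConfig:
    """Wrap pipeline parameters.

    ``clip_radius`` (mm) bounds the circular sheet, ``sphere_radius`` (mm)
    the intermediate sphere (clip_radius <= pi * sphere_radius / 2 keeps the
    wrap on a single hemisphere), ``intersection_depth`` (mm) how far the
    organ is sunk into the curved sheet before projection (``None`` = 5% of
    the organ bounding-box height), and ``density_index`` the dimensionless
    mesh density d of the source auxetic sheet.
    """

    clip_radius: float = 8.0
    sphere_radius: float = 10.0
    intersection_depth: float | None = None
    density_index: int = 8

    def __post_init__(self):
        if self.clip_radius <= 0 or self.sphere_radius <= 0:
            raise ValueError("radii must be positive")
        if self.clip_radius > np.pi * self.sphere_radius / 2 + 1e-12:
            raise ValueError("clip_radius > pi*R/2: sheet exceeds one hemisphere")
        if self.intersection_depth is not None and self.intersection_depth < 0:
            raise ValueError("intersection_depth must be >= 0")


# ---------------------------------------------------------------------------
# circle clip
# ---------------------------------------------------------------------------

def clip_to_circle(net: BeamNetwork, center, radius: float) -> BeamNetwork:
    """Intersect a planar network with a circle.

    Vertices outside the circle are dropped; beams crossing the boundary are
    trimmed at the exact segment-circle intersection, inserting new boundary
    vertices.  Errors out if nothing remains.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, float).reshape(3)
    A, B = net.segment_endpoints()
    pieces, thick = [], []
    for k in range(net.n_beams):
        a, b = A[k], B[k]
        d = b - a
        f = a - center
        aa = float(d @ d)
        # |f + t d|^2 = r^2
        if aa == 0:
            continue
        bb = 2 * float(f @ d)
        cc = float(f @ f) - radius ** 2
        disc = bb * bb - 4 * aa * cc
        if disc < 0:          # entirely outside (never intersects the disk)
            if cc > 0:
                continue
            t0, t1 = 0.0, 1.0
        else:
            s = np.sqrt(disc)
            t0 = max(0.0, (-bb - s) / (2 * aa))
            t1 = min(1.0, (-bb + s) / (2 * aa))
            if t1 <= t0:
                continue
        p0 = a + t0 * d
        p1 = a + t1 * d
        pieces.append((p0, p1))
        thick.append(net.thickness[k])
    if not pieces:
        raise ValueError("clip circle too small: empty result")
    verts = np.array([p for seg in pieces for p in seg])
    beams = np.arange(len(verts)).reshape(-1, 2)
    return BeamNetwork(verts, beams, np.array(thick)).merged(1e-9)


# ---------------------------------------------------------------------------
# sphere wrap
# ---------------------------------------------------------------------------

def _subdivision_counts(net: BeamNetwork, R: float,
                        max_arc: float = np.radians(5.0)) -> np.ndarray:
    A, B = net.segment_endpoints()
    L = np.linalg.norm(B - A, axis=1)
    return np.maximum(1, np.ceil(L / (R * max_arc)).astype(int))


def wrap_to_sphere(net: BeamNetwork, R: float) -> BeamNetwork:
    """Azimuthal-equidistant wrap of a circular planar sheet onto a sphere.

    The sheet must be centred at the origin in the z = 0 plane; its centre
    maps to the pole (0, 0, R), and a planar radial distance rho maps to the
    geodesic distance rho from the pole (psi = rho / R).  Beams are
    subdivided before mapping so they follow the sphere.  rho > pi * R
    (over-wrap past the antipode) is an error.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    rho = np.hypot(net.vertices[:, 0], net.vertices[:, 1])
    if rho.max() > np.pi * R * (1 + 1e-12):
        raise ValueError("sheet radius exceeds pi*R: cannot wrap past antipode")
    fine = net.subdivided(_subdivision_counts(net, R))

    def to_sphere(p):
        rho = np.hypot(p[:, 0], p[:, 1])
        phi = np.arctan2(p[:, 1], p[:, 0])
        psi = rho / R
        return np.stack([R * np.sin(psi) * np.cos(phi),
                         R * np.sin(psi) * np.sin(phi),
                         R * np.cos(psi)], axis=-1)

    return fine.transformed(to_sphere).merged(1e-9)


# ---------------------------------------------------------------------------
# closest point on a triangle surface
# ---------------------------------------------------------------------------

def _closest_on_tris(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest points of one query point on many triangles.

    Vectorized barycentric region test (Ericson, Real-Time Collision
    Detection).  Returns (points (M,3), squared distances (M,)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    q = a.copy()                                   # region A
    done = (d1 <= 0) & (d2 <= 0)
    m = ~done & (d3 >= 0) & (d4 <= d3)             # region B
    q[m] = b[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    q[m] = a[m] + v[m, None] * ab[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)             # region C
    q[m] = c[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    q[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)   # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    q[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    m = ~done                                       # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    q[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    d2q = np.einsum("ij,ij->i", p - q, p - q)
    return q, d2q


class SurfaceProjector:
    """Accelerated closest-point lookup on a triangle surface.

    Builds a KD-tree over triangle centroids; for each query the distance to
    a handful of nearby triangles gives an upper bound, and every triangle
    whose centroid could possibly beat that bound is then checked exactly,
    so results match brute force to machine precision.
    """

    def __init__(self, surf: TriSurface, face_mask=None):
        if surf.n_faces == 0:
            raise ValueError("empty surface")
        faces = np.arange(surf.n_faces) if face_mask is None \
            else np.nonzero(np.asarray(face_mask, bool))[0]
        if len(faces) == 0:
            raise ValueError("face mask excludes every face")
        self.face_ids = faces
        self.tri = surf.triangles()[faces]
        self.centroids = self.tri.mean(axis=1)
        self.r_tri = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.r_max = float(self.r_tri.max())
        self.tree = cKDTree(self.centroids)

    def query(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface points: returns (q (N,3), dist (N,), face (N,))."""
        points = np.atleast_2d(np.asarray(points, float))
        k = min(8, len(self.tri))
        _, seed_idx = self.tree.query(points, k=k)
        seed_idx = np.atleast_2d(seed_idx)
        qs = np.empty_like(points)
        ds = np.empty(len(points))
        fs = np.empty(len(points), dtype=np.intp)
        for n, p in enumerate(points):
            cand = seed_idx[n]
            q, d2 = _closest_on_tris(p, self.tri[cand])
            best = int(np.argmin(d2))
            d_up = np.sqrt(d2[best])
            # conservative sweep: triangles with |p - centroid| <= d_up + r_max
            more = self.tree.query_ball_point(p, d_up + self.r_max + 1e-12)
            more = np.setdiff1d(np.asarray(more, dtype=np.intp), cand)
            qq, dd2 = q[best], d2[best]
            ff = cand[best]
            if len(more):
                q2, d22 = _closest_on_tris(p, self.tri[more])
                b2 = int(np.argmin(d22))
                if d22[b2] < dd2:
                    qq, dd2, ff = q2[b2], d22[b2], more[b2]
            qs[n], ds[n], fs[n] = qq, np.sqrt(dd2), self.face_ids[ff]
        return qs, ds, fs


def closest_point_on_surface(p, surf: TriSurface):
    """Globally closest surface point to ``p``: (q, distance, face index)."""
    q, d, f = SurfaceProjector(surf).query(np.asarray(p, float).reshape(1, 3))
    return q[0], float(d[0]), int(f[0])


def project_network_to_surface(net: BeamNetwork, surf: TriSurface,
                               subdiv: int = 1,
                               face_mask=None) -> BeamNetwork:
    """Replace every vertex (and beam subdivision point) by its closest point
    on the surface; connectivity is untouched.  ``face_mask`` optionally
    restricts the projection to a face subset (e.g. the organ's bottom)."""
    fine = net.subdivided(subdiv) if subdiv > 1 else net
    proj = SurfaceProjector(surf, face_mask)
    q, _, _ = proj.query(fine.vertices)
    return BeamNetwork(q, fine.beams.copy(), fine.thickness.copy(),
                       None if fine.labels is None else list(fine.labels))


def wrap_onto_organ(net: BeamNetwork, organ: TriSurface, cfg: WrapConfig,
                    subdiv: int = 2, bottom_only: bool = True) -> BeamNetwork:
    """Full pipeline: clip the planar sheet to a circle, wrap it onto a
    sphere, sink the organ slightly into the resulting bowl, and project
    every sheet point onto the (by default, bottom) organ surface."""
    lo, hi = organ.vertices.min(axis=0), organ.vertices.max(axis=0)
    cxy = (lo + hi) / 2
    depth = (0.05 * (hi[2] - lo[2]) if cfg.intersection_depth is None
             else cfg.intersection_depth)
    center = net.vertices.mean(axis=0)
    clipped = clip_to_circle(net.translated(-center), np.zeros(3),
                             cfg.clip_radius)
    curved = wrap_to_sphere(clipped, cfg.sphere_radius)
    # flip the cap into a bowl opening upward and slide it under the organ
    bowl = curved.transformed(lambda p: p * np.array([1.0, 1.0, -1.0]))
    bowl_top = bowl.vertices[:, 2].max()     # rim; apex at -R
    bowl = bowl.translated([cxy[0], cxy[1],
                            lo[2] + depth - (bowl.vertices[:, 2].min())])
    mask = organ.face_normals()[:, 2] < 0 if bottom_only else None
    return project_network_to_surface(bowl, organ, subdiv=subdiv,
                                      face_mask=mask)


# ---------------------------------------------------------------------------
# synthetic organ fixture
# ---------------------------------------------------------------------------

def gen_synthetic_organ(seed: int = 0, size: float = 10.0,
                        subdivisions: int = 4) -> TriSurface:
    """Deterministic watertight heart-like blob (synthetic stand-in for a
    repository organ model).

    A subdivided icosphere (4 levels = 5120 faces) is radially deformed into
    a two-lobed, apex-tapered, smooth star-shaped body; a small seeded
    low-frequency perturbation individualizes the shape without breaking
    closedness.  ``size`` is the nominal radius in mm; the apex points down
    (-z).
    """
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    d = np.asarray(ico.vertices, float)
    dz = d[:, 2]
    phi = np.arctan2(d[:, 1], d[:, 0])
    # two lobes on top, tapered apex below
    r = 1.0 + 0.22 * np.clip(dz, 0, None) ** 2 * (1 + 0.35 * np.cos(2 * phi))
    r *= 1.0 - 0.18 * np.clip(-dz, 0, None) ** 3
    rng = np.random.default_rng(seed)
    for _ in range(4):
        k = rng.normal(size=3)
        amp = rng.normal(scale=0.015)
        r *= 1.0 + amp * np.sin(d @ k)
    verts = size * r[:, None] * d
    # taper: narrow the apex laterally and stretch it downward
    low = np.clip(-verts[:, 2] / size, 0, None)
    verts[:, 0] *= 1 - 0.35 * low
    verts[:, 1] *= 1 - 0.35 * low
    verts[:, 2] -= 0.25 * size * low ** 2
    return TriSurface(verts, np.asarray(ico.faces, dtype=np.intp))
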