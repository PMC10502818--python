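"""Finite-cell (fictitious-domain) linear elasticity on voxel grids.

The lattice geometry is embedded in a regular grid: no body-fitted meshing.
Each cell is a bilinear quad (2-D plane stress) or trilinear hex (3-D) whose
stiffness is integrated over ``quadrature_depth`` sub-voxels per edge, with
the material indicator alpha = 1 inside the solid and ``alpha_void`` << 1 in
the fictitious void.  Cells with no solid sub-voxel at all are dropped from
the system (their stiffness would be pure void), which keeps the linear
systems small and well-conditioned; cut cells keep their void-weighted
sub-voxel contributions, so results remain alpha-insensitive.

Stretch screening: an axial stretch prescribes a displacement on the top
boundary nodes of the solid with the bottom on rollers (normal displacement
fixed, tangential free) or fully fixed; the Poisson's ratio follows the
-dW/dL convention, nu = -(lateral strain)/(axial strain), with the lateral
strain measured from the mean lateral displacement of the 5% extreme
boundary-node bands on each side (normalised by the distance between the
band centroids, which is exact for affine fields).  Radial stretch of
cylinders prescribes an outward radial end-ring displacement proportional to
radius, and nu_radial = -(axial strain)/(radial strain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .geometry import BeamNetwork, sdf_capsule

__all__ = ["ElasticProblem", "StretchBC", "MechResult", "SweepResult",
           "solve_elasticity", "solve_cantilever", "poisson_ratio",
           "sweep_poisson", "problem_from_planar", "problem_from_network_3d",
           "default_sweep_spacing"]

GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# problem containers
# ---------------------------------------------------------------------------

@dataclass
class ElasticProblem:
    """Voxel-embedded elasticity problem.

    ``fine_solid`` is the solid indicator sampled at sub-voxel resolution:
    shape ``(nx*q, ny*q)`` in 2-D or ``(nx*q, ny*q, nz*q)`` in 3-D for a
    cell grid of shape ``(nx, ny[, nz])`` and quadrature depth ``q``.
    ``E`` (kPa) and ``nu_mat`` describe the base material (near-
    incompressible hydrogel by default), ``alpha_void`` the fictitious
    void stiffness factor.
    """

    fine_solid: np.ndarray
    origin: np.ndarray
    spacing: float
    E: float = 50.0
    nu_mat: float = 0.45
    alpha_void: float = 1e-6
    quadrature_depth: int = 2
    mode: str = "plane_stress_2d"

    def __post_init__(self):
        self.fine_solid = np.asarray(self.fine_solid, bool)
        self.origin = np.asarray(self.origin, float)
        dim = 2 if self.mode == "plane_stress_2d" else 3
        if self.mode not in ("plane_stress_2d", "solid_3d"):
            raise ValueError("mode must be 'plane_stress_2d' or 'solid_3d'")
        if self.fine_solid.ndim != dim:
            raise ValueError("fine_solid dimensionality does not match mode")
        if not (0 < self.nu_mat < 0.5):
            raise ValueError("nu_mat must lie in (0, 0.5)")
        if not (0 < self.alpha_void < 1):
            raise ValueError("alpha_void must lie in (0, 1)")
        if self.E <= 0 or self.spacing <= 0:
            raise ValueError("E and spacing must be positive")
        q = self.quadrature_depth
        if any(s % q for s in self.fine_solid.shape):
            raise ValueError("fine_solid shape must be a multiple of "
                             "quadrature_depth")
        if not self.fine_solid.any():
            raise ValueError("empty geometry: no solid sub-voxel")

    @property
    def dim(self) -> int:
        return 2 if self.mode == "plane_stress_2d" else 3

    @property
    def cells(self) -> tuple[int, ...]:
        q = self.quadrature_depth
        return tuple(s // q for s in self.fine_solid.shape)


@dataclass
class StretchBC:
    """Stretch boundary condition.

    ``direction``: 'axial' (prescribed displacement on the solid's top
    boundary, axis = y in 2-D / z in 3-D) or 'radial' (outward end-ring
    displacement, 3-D cylinders).  ``strain`` is the small applied strain;
    ``constraint`` picks 'roller_bottom' (free lateral expansion) or
    'fixed_bottom'.
    """

    direction: str = "axial"
    strain: float = 0.01
    constraint: str = "roller_bottom"

    def __post_init__(self):
        if self.direction not in ("axial", "radial"):
            raise ValueError("direction must be 'axial' or 'radial'")
        if self.strain == 0:
            raise ValueError("applied strain must be nonzero")
        if self.constraint not in ("roller_bottom", "fixed_bottom"):
            raise ValueError("constraint must be 'roller_bottom' or "
                             "'fixed_bottom'")


@dataclass
class MechResult:
    """Solved stretch problem: nodal displacements plus the strain summary."""

    node_coords: np.ndarray
    displacement: np.ndarray
    eps_axial: float
    eps_lateral: float
    nu: float
    reactions: dict = field(default_factory=dict)
    residual: float = 0.0


@dataclass
class SweepResult:
    """Design sweep table: one row per design with its computed nu."""

    table: pd.DataFrame

    @property
    def nu_min(self) -> float:
        return float(self.table["nu"].min())

    @property
    def nu_max(self) -> float:
        return float(self.table["nu"].max())

    def summary(self) -> dict:
        ok = self.table["nu"].notna()
        return {"n_designs": int(len(self.table)), "n_failed": int((~ok).sum()),
                "nu_min": self.nu_min, "nu_max": self.nu_max}


# ---------------------------------------------------------------------------
# sub-voxel element stiffness
# ---------------------------------------------------------------------------

def _material_matrix(E: float, nu: float, mode: str) -> np.ndarray:
    if mode == "plane_stress_2d":
        f = E / (1 - nu ** 2)
        return f * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = mu * np.eye(3)
    return C


def _shape_gradients(xi: np.ndarray, dim: int) -> np.ndarray:
    """d N_a / d xi_k for the 4-node quad / 8-node hex at one point."""
    if dim == 2:
        corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
    else:
        corners = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                           float)
    n = len(corners)
    grads = np.empty((n, dim))
    for a in range(n):
        for k in range(dim):
            val = corners[a, k]
            for j in range(dim):
                if j != k:
                    val *= (1 + corners[a, j] * xi[j])
            grads[a, k] = val / 2 ** dim
    return grads


def _b_matrix(grad_x: np.ndarray, dim: int) -> np.ndarray:
    """Strain-displacement matrix from shape-function x-gradients."""
    n = len(grad_x)
    if dim == 2:
        B = np.zeros((3, 2 * n))
        B[0, 0::2] = grad_x[:, 0]
        B[1, 1::2] = grad_x[:, 1]
        B[2, 0::2] = grad_x[:, 1]
        B[2, 1::2] = grad_x[:, 0]
        return B
    B = np.zeros((6, 3 * n))
    B[0, 0::3] = grad_x[:, 0]
    B[1, 1::3] = grad_x[:, 1]
    B[2, 2::3] = grad_x[:, 2]
    B[3, 0::3] = grad_x[:, 1]   # gamma_xy
    B[3, 1::3] = grad_x[:, 0]
    B[4, 1::3] = grad_x[:, 2]   # gamma_yz
    B[4, 2::3] = grad_x[:, 1]
    B[5, 0::3] = grad_x[:, 2]   # gamma_xz
    B[5, 2::3] = grad_x[:, 0]
    return B


def _subcell_stiffness(E: float, nu: float, h: float, q: int,
                       mode: str) -> np.ndarray:
    """Partial element stiffness per sub-voxel: (q^dim, ndof, ndof).

    Sub-voxel s (C-order over local (sx[, sy], sz) = fine-grid offsets) is
    integrated with 2-point Gauss per direction; summing over s with
    alpha = 1 recovers the standard fully integrated element.
    """
    dim = 2 if mode == "plane_stress_2d" else 3
    C = _material_matrix(E, nu, mode)
    n_nodes = 4 if dim == 2 else 8
    ndof = dim * n_nodes
    out = np.zeros((q ** dim, ndof, ndof))
    delta = 1.0 / q
    jac = (h / 2) ** dim
    subs = np.ndindex(*([q] * dim))
    for s_flat, s in enumerate(subs):
        centers = np.array([-1 + (2 * s[k] + 1) * delta for k in range(dim)])
        K = np.zeros((ndof, ndof))
        for gp in np.ndindex(*([2] * dim)):
            xi = centers + delta * GAUSS_1D[list(gp)]
            grad_xi = _shape_gradients(xi, dim)
            grad_x = grad_xi * (2.0 / h)
            B = _b_matrix(grad_x, dim)
            w = delta ** dim * jac
            K += w * (B.T @ C @ B)
        out[s_flat] = K
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Assembled:
    """Assembled stiffness on the active node set."""

    def __init__(self, p: ElasticProblem):
        dim = p.dim
        q = p.quadrature_depth
        cells = p.cells
        fine = p.fine_solid

        # per-element alpha vector over sub-voxels (C-order = np.ndindex)
        if dim == 2:
            a = fine.reshape(cells[0], q, cells[1], q)
            alpha = a.transpose(0, 2, 1, 3).reshape(cells[0] * cells[1], q * q)
        else:
            a = fine.reshape(cells[0], q, cells[1], q, cells[2], q)
            alpha = a.transpose(0, 2, 4, 1, 3, 5).reshape(
                np.prod(cells), q ** 3)
        active = alpha.any(axis=1)
        self.elem_ids = np.nonzero(active)[0]
        alpha = np.where(alpha[active], 1.0, p.alpha_void)

        Ks = _subcell_stiffness(p.E, p.nu_mat, p.spacing, q, p.mode)
        nodes_shape = tuple(c + 1 for c in cells)

        if dim == 2:
            ii, jj = np.unravel_index(self.elem_ids, cells)
            n00 = ii * nodes_shape[1] + jj
            conn = np.stack([n00, n00 + nodes_shape[1],
                             n00 + nodes_shape[1] + 1, n00 + 1], axis=1)
        else:
            ii, jj, kk = np.unravel_index(self.elem_ids, cells)
            sy, sz = nodes_shape[1] * nodes_shape[2], nodes_shape[2]

            def nid(di, dj, dk):
                return (ii + di) * sy + (jj + dj) * sz + (kk + dk)
            conn = np.stack([nid(0, 0, 0), nid(1, 0, 0), nid(1, 1, 0),
                             nid(0, 1, 0), nid(0, 0, 1), nid(1, 0, 1),
                             nid(1, 1, 1), nid(0, 1, 1)], axis=1)

        # restrict to active nodes
        used, conn_local = np.unique(conn, return_inverse=True)
        conn_local = conn_local.reshape(conn.shape)
        self.n_nodes = len(used)
        grid_idx = np.array(np.unravel_index(used, nodes_shape)).T
        self.coords = p.origin + grid_idx * p.spacing

        ndof_e = Ks.shape[1]
        dofs = (conn_local[:, :, None] * dim
                + np.arange(dim)[None, None, :]).reshape(len(conn_local), ndof_e)
        rows = np.repeat(dofs, ndof_e, axis=1).ravel()
        cols = np.tile(dofs, (1, ndof_e)).ravel()
        vals = np.einsum("es,sab->eab", alpha, Ks).ravel()
        n = self.n_nodes * dim
        self.K = sparse.coo_matrix((vals, (rows, cols)),
                                   shape=(n, n)).tocsr()
        self.dim = dim

    def solve(self, fixed: np.ndarray, u_fixed: np.ndarray,
              f_ext: np.ndarray | None = None,
              rtol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
        """Solve with Dirichlet data; returns (u (n,dim), reactions flat)."""
        n = self.K.shape[0]
        u = np.zeros(n)
        u[fixed] = u_fixed
        free = np.setdiff1d(np.arange(n), fixed)
        rhs = np.zeros(n) if f_ext is None else f_ext.copy()
        b = rhs[free] - self.K[free][:, fixed] @ u[fixed]
        Kff = self.K[free][:, free].tocsc()
        with warnings.catch_warnings():
            warnings.simplefilter("error", sparse.linalg.MatrixRankWarning)
            try:
                uf = spsolve(Kff, b)
            except sparse.linalg.MatrixRankWarning as exc:
                raise RuntimeError(
                    "singular stiffness matrix: the solid region does not "
                    "connect the loaded boundaries") from exc
        if not np.all(np.isfinite(uf)):
            raise RuntimeError("singular stiffness matrix: disconnected "
                               "load path")
        u[free] = uf
        scale = max(np.linalg.norm(b), 1e-30)
        res = np.linalg.norm(Kff @ uf - b) / scale
        if res > rtol * 100:
            raise RuntimeError(f"solver did not converge: relative residual "
                               f"{res:.2e}")
        reactions = self.K @ u - rhs
        return u.reshape(-1, self.dim), reactions


# ---------------------------------------------------------------------------
# rasterization of beam networks
# ---------------------------------------------------------------------------

def default_sweep_spacing(t: float) -> float:
    """Screening resolution heuristic: half the element thickness, clamped
    to [0.05, 0.3] mm (sub-voxel quadrature recovers the cut fraction)."""
    return float(np.clip(t / 2, 0.05, 0.3))


def _segment_distance_2d(px, py, a, b):
    d = b - a
    denom = float(d @ d)
    if denom == 0:
        return np.hypot(px - a[0], py - a[1])
    t = ((px - a[0]) * d[0] + (py - a[1]) * d[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def problem_from_planar(net: BeamNetwork, spacing: float | None = None,
                        E: float = 50.0, nu_mat: float = 0.45,
                        alpha_void: float = 1e-6, q: int = 2) -> ElasticProblem:
    """Rasterize a planar (z = 0) beam network into a plane-stress problem.

    The solid indicator is sampled at the sub-voxel centres of a cell grid
    covering the inflated bounding box of the network.
    """
    if spacing is None:
        spacing = default_sweep_spacing(float(net.thickness.min()))
    r = net.thickness / 2
    lo = net.vertices[:, :2].min(axis=0) - r.max()
    hi = net.vertices[:, :2].max(axis=0) + r.max()
    cells = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    hf = spacing / q
    fx = lo[0] + (np.arange(cells[0] * q) + 0.5) * hf
    fy = lo[1] + (np.arange(cells[1] * q) + 0.5) * hf
    solid = np.zeros((len(fx), len(fy)), dtype=bool)
    A, B = net.segment_endpoints()
    for k in range(net.n_beams):
        a2, b2 = A[k, :2], B[k, :2]
        rr = r[k]
        wlo = np.minimum(a2, b2) - rr - hf
        whi = np.maximum(a2, b2) + rr + hf
        i0, i1 = np.searchsorted(fx, (wlo[0], whi[0]))
        j0, j1 = np.searchsorted(fy, (wlo[1], whi[1]))
        if i0 >= i1 or j0 >= j1:
            continue
        PX, PY = np.meshgrid(fx[i0:i1], fy[j0:j1], indexing="ij")
        d = _segment_distance_2d(PX, PY, a2, b2)
        solid[i0:i1, j0:j1] |= d <= rr
    return ElasticProblem(solid, lo, spacing, E=E, nu_mat=nu_mat,
                          alpha_void=alpha_void, quadrature_depth=q,
                          mode="plane_stress_2d")


def problem_from_network_3d(net: BeamNetwork, spacing: float | None = None,
                            E: float = 50.0, nu_mat: float = 0.45,
                            alpha_void: float = 1e-6,
                            q: int = 2) -> ElasticProblem:
    """Rasterize a 3-D beam network into a solid (trilinear hex) problem."""
    if spacing is None:
        spacing = default_sweep_spacing(float(net.thickness.min()))
    r = net.thickness / 2
    lo = net.vertices.min(axis=0) - r.max()
    hi = net.vertices.max(axis=0) + r.max()
    cells = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    hf = spacing / q
    axes = [lo[i] + (np.arange(cells[i] * q) + 0.5) * hf for i in range(3)]
    solid = np.zeros(tuple(len(a) for a in axes), dtype=bool)
    A, B = net.segment_endpoints()
    for k in range(net.n_beams):
        a, b, rr = A[k], B[k], r[k]
        wlo = np.minimum(a, b) - rr - hf
        whi = np.maximum(a, b) + rr + hf
        sl = []
        for ax in range(3):
            i0, i1 = np.searchsorted(axes[ax], (wlo[ax], whi[ax]))
            if i0 >= i1:
                sl = None
                break
            sl.append(slice(i0, i1))
        if sl is None:
            continue
        X, Y, Z = np.meshgrid(axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]],
                              indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = sdf_capsule(pts, a, b, rr)
        solid[sl[0], sl[1], sl[2]] |= d <= 0
    return ElasticProblem(solid, lo, spacing, E=E, nu_mat=nu_mat,
                          alpha_void=alpha_void, quadrature_depth=q,
                          mode="solid_3d")


def problem_from_indicator(solid, origin, spacing, **kw) -> ElasticProblem:
    """Problem from a pre-computed fine solid indicator array."""
    return ElasticProblem(np.asarray(solid, bool), np.asarray(origin, float),
                          spacing, **kw)


# ---------------------------------------------------------------------------
# boundary conditions + solve
# ---------------------------------------------------------------------------

def _band(coords_1d: np.ndarray, side: str, width: float) -> np.ndarray:
    if side == "min":
        return coords_1d <= coords_1d.min() + width
    return coords_1d >= coords_1d.max() - width


def solve_elasticity(p: ElasticProblem, bc: StretchBC) -> MechResult:
    """Solve the embedded stretch problem and extract the Poisson's ratio."""
    asm = _Assembled(p)
    dim = asm.dim
    coords = asm.coords
    hw = 0.51 * p.spacing
    ax = 1 if dim == 2 else 2           # stretch axis: y in 2-D, z in 3-D

    if bc.direction == "axial":
        return _solve_axial(p, bc, asm, coords, dim, ax, hw)
    if dim != 3:
        raise ValueError("radial stretch requires a 3-D problem")
    return _solve_radial(p, bc, asm, coords, hw)


def _require_connected_load_path(p: ElasticProblem, ax: int) -> None:
    """The solid must connect the two loaded boundaries (deterministic
    check; a singular factorization is only the backstop)."""
    from scipy import ndimage

    lab, n = ndimage.label(p.fine_solid)
    if n == 0:
        raise RuntimeError("no solid")
    idx = np.moveaxis(np.indices(p.fine_solid.shape), 0, -1)[..., ax]
    lo, hi = idx[p.fine_solid].min(), idx[p.fine_solid].max()
    for c in range(1, n + 1):
        m = lab == c
        if idx[m].min() <= lo + 1 and idx[m].max() >= hi - 1:
            return
    raise RuntimeError("singular system: no solid component connects the "
                       "loaded boundaries (disconnected load path)")


def _solve_axial(p, bc, asm, coords, dim, ax, hw) -> MechResult:
    _require_connected_load_path(p, ax)
    z = coords[:, ax]
    L0 = z.max() - z.min()
    top = np.nonzero(_band(z, "max", hw))[0]
    bot = np.nonzero(_band(z, "min", hw))[0]
    dL = bc.strain * L0

    fixed, vals = [], []
    fixed += list(top * dim + ax)
    vals += [dL] * len(top)
    fixed += list(bot * dim + ax)
    vals += [0.0] * len(bot)
    if bc.constraint == "fixed_bottom":
        for comp in range(dim):
            if comp == ax:
                continue
            fixed += list(bot * dim + comp)
            vals += [0.0] * len(bot)
    else:
        # rollers: pin in-plane rigid modes only
        if dim == 2:
            mid = bot[np.argmin(np.abs(coords[bot, 0]
                                       - coords[:, 0].mean()))]
            fixed.append(int(mid) * dim + 0)
            vals.append(0.0)
        else:
            cx = coords[:, 0].mean()
            cy = coords[:, 1].mean()
            bx = coords[bot, 0] - cx
            by = coords[bot, 1] - cy
            # block x/y translation and rotation while leaving radial
            # breathing (approximately) free: fix ux on the +/-y axis,
            # uy on the +/-x axis
            for target, comp in [((0, 1), 0), ((0, -1), 0),
                                 ((1, 0), 1), ((-1, 0), 1)]:
                rr = np.hypot(bx, by)
                ang = np.arctan2(by, bx)
                want = np.arctan2(target[1], target[0])
                score = np.abs(np.angle(np.exp(1j * (ang - want))))
                i = bot[np.argmin(score - 1e-9 * rr)]
                dof = int(i) * dim + comp
                if dof not in fixed:
                    fixed.append(dof)
                    vals.append(0.0)
    fixed = np.asarray(fixed, dtype=int)
    vals = np.asarray(vals, float)
    u, reac = asm.solve(fixed, vals)

    if dim == 2:
        eps_lat = _band_lateral_strain(coords[:, 0], u[:, 0])
    else:
        eps_lat = _radial_strain(coords, u, z, hw)
    nu = -eps_lat / bc.strain
    reactions = {
        "top": float(reac.reshape(-1, dim)[top, ax].sum()),
        "bottom": float(reac.reshape(-1, dim)[bot, ax].sum()),
    }
    return MechResult(coords, u, bc.strain, eps_lat, nu, reactions)


def _band_lateral_strain(x: np.ndarray, ux: np.ndarray,
                         frac: float = 0.05) -> float:
    """dW/W from the mean lateral displacement of the extreme-x node bands,
    normalised by the band-centroid separation (exact for affine fields)."""
    W = x.max() - x.min()
    left = x <= x.min() + frac * W
    right = x >= x.max() - frac * W
    dx = x[right].mean() - x[left].mean()
    return (ux[right].mean() - ux[left].mean()) / dx


def _radial_strain(coords, u, z, hw) -> float:
    """Mean radial strain over the mid-height half of a cylinder."""
    zc = (z.max() + z.min()) / 2
    Lz = z.max() - z.min()
    mid = np.abs(z - zc) <= Lz / 4
    cx, cy = coords[:, 0].mean(), coords[:, 1].mean()
    rx = coords[mid, 0] - cx
    ry = coords[mid, 1] - cy
    r = np.hypot(rx, ry)
    ok = r > 1e-9
    ur = (u[mid, 0][ok] * rx[ok] + u[mid, 1][ok] * ry[ok]) / r[ok]
    return float(ur.mean() / r[ok].mean())


def _solve_radial(p, bc, asm, coords, hw) -> MechResult:
    """Uniform radial stretch (balloon mode).

    The radial displacement component is prescribed as u_r = strain * r at
    every solid node (tangential and axial components free; one tangential
    dof pinned to remove the rigid rotation, the bottom ring pinned
    axially), emulating balloon-type expansion of a stent.  The in-plane
    dofs are rotated into a per-node (radial, tangential) basis so that
    only the radial component is constrained.
    """
    z = coords[:, 2]
    top = np.nonzero(_band(z, "max", hw))[0]
    bot = np.nonzero(_band(z, "min", hw))[0]
    cx, cy = coords[:, 0].mean(), coords[:, 1].mean()
    rx = coords[:, 0] - cx
    ry = coords[:, 1] - cy
    r = np.hypot(rx, ry)
    safe = r > 1e-9
    cth = np.where(safe, rx / np.where(safe, r, 1.0), 1.0)
    sth = np.where(safe, ry / np.where(safe, r, 1.0), 0.0)

    # block-diagonal rotation T: (u_r, u_t, u_z) -> (u_x, u_y, u_z)
    n = len(coords)
    rows, cols, tvals = [], [], []
    for comp_r, comp_c, val in ((0, 0, cth), (0, 1, -sth),
                                (1, 0, sth), (1, 1, cth)):
        rows.append(np.arange(n) * 3 + comp_r)
        cols.append(np.arange(n) * 3 + comp_c)
        tvals.append(val)
    rows.append(np.arange(n) * 3 + 2)
    cols.append(np.arange(n) * 3 + 2)
    tvals.append(np.ones(n))
    T = sparse.coo_matrix((np.concatenate(tvals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(3 * n, 3 * n)).tocsr()
    K_rot = (T.T @ asm.K @ T).tocsr()

    fixed = list(np.arange(n) * 3 + 0)          # all radial dofs
    vals = list(bc.strain * r)
    fixed += list(bot * 3 + 2)                  # pin bottom ring axially
    vals += [0.0] * len(bot)
    # pin one tangential dof (rigid rotation about the axis)
    i_pin = int(np.argmax(r))
    fixed.append(i_pin * 3 + 1)
    vals.append(0.0)

    asm_rot = _Assembled.__new__(_Assembled)
    asm_rot.K = K_rot
    asm_rot.dim = 3
    u_cyl, _ = asm_rot.solve(np.asarray(fixed, int), np.asarray(vals, float))
    u = (T @ u_cyl.ravel()).reshape(-1, 3)

    dz = z[top].mean() - z[bot].mean()
    eps_ax = (u[top, 2].mean() - u[bot, 2].mean()) / dz
    nu = -eps_ax / bc.strain
    return MechResult(coords, u, eps_ax, bc.strain, nu, {})


def solve_cantilever(p: ElasticProblem, tip_load: float) -> float:
    """Transverse tip deflection of a strip fixed at its left edge.

    The total load is distributed over the right-edge nodes; returns the mean
    transverse displacement of that edge (positive = load direction).
    """
    if p.dim != 2:
        raise ValueError("cantilever benchmark is 2-D")
    asm = _Assembled(p)
    coords = asm.coords
    hw = 0.51 * p.spacing
    left = np.nonzero(_band(coords[:, 0], "min", hw))[0]
    right = np.nonzero(_band(coords[:, 0], "max", hw))[0]
    fixed = np.concatenate([left * 2, left * 2 + 1])
    vals = np.zeros(len(fixed))
    f = np.zeros(asm.K.shape[0])
    f[right * 2 + 1] = tip_load / len(right)
    u, _ = asm.solve(fixed, vals, f_ext=f)
    return float(u[right, 1].mean())


def poisson_ratio(r: MechResult) -> float:
    """nu = -(dW/W0)/(dL/L0) (axial) or -(dL/L0)/(dR/R0) (radial)."""
    if r.eps_axial == 0 and r.eps_lateral == 0:
        raise ValueError("no applied strain: Poisson's ratio undefined")
    if r.eps_axial == 0:
        raise ValueError("dL = 0: Poisson's ratio undefined")
    return float(r.nu)


# ---------------------------------------------------------------------------
# sweep driver
# ---------------------------------------------------------------------------

def sweep_poisson(designs, build_problem, bc: StretchBC) -> SweepResult:
    """Solve one stretch problem per design.

    ``designs`` is an iterable of design dataclasses; ``build_problem`` maps
    a design to an :class:`ElasticProblem`.  Failures are recorded per row
    (column ``error``), never fatal; nu is NaN for failed rows and excluded
    from the min/max summary.
    """
    rows = []
    for d in designs:
        row = {k: v for k, v in vars(d).items()}
        try:
            prob = build_problem(d)
            res = solve_elasticity(prob, bc)
            row["nu"] = res.nu
            row["error"] = ""
        except Exception as exc:   # noqa: BLE001 - per-row capture by contract
            row["nu"] = np.nan
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return SweepResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# reference screening libraries (the study conditions for the design screens)
# ---------------------------------------------------------------------------

#: planar screen: n1, n2 over {2..8}, element thickness spanning the printable
#: range (the printed meshes' measured features are ~0.26-0.29 mm) — 245
#: designs per mesh kind on the 10 x 10 mm sheet
PLANAR_SWEEP_N = tuple(range(2, 9))
PLANAR_SWEEP_T = tuple(np.linspace(0.1, 0.35, 5))

#: cylinder screen: ring/line counts in small ranges on the 4 mm x 12 mm
#: cylinder, strut thickness 0.6-0.8 mm (moderate slenderness, printable)
CYLINDER_SWEEP_H = (4, 6)
CYLINDER_SWEEP_V = (8, 12)
CYLINDER_SWEEP_T = (0.6, 0.7, 0.8)
CYLINDER_SWEEP_R = 4.0
CYLINDER_SWEEP_HEIGHT = 12.0


def planar_reentrant_library(n1_values=PLANAR_SWEEP_N,
                             n2_values=PLANAR_SWEEP_N,
                             t_values=PLANAR_SWEEP_T, kind="reentrant"):
    from .planar import PlanarDesign

    return [PlanarDesign(kind=kind, n1=a, n2=b, t=float(t))
            for a in n1_values for b in n2_values for t in t_values]


def cylinder_library(kinds=None, h_values=CYLINDER_SWEEP_H,
                     v_values=CYLINDER_SWEEP_V, t_values=CYLINDER_SWEEP_T):
    from .cylinder import CYLINDER_KINDS, CylinderDesign

    kinds = CYLINDER_KINDS if kinds is None else kinds
    return [CylinderDesign(kind=k, R=CYLINDER_SWEEP_R,
                           H=CYLINDER_SWEEP_HEIGHT, h=h, v=v, t=float(t))
            for k in kinds for h in h_values for v in v_values
            for t in t_values]


def screen_planar(designs, strain: float = 0.01) -> SweepResult:
    """Plane-stress screen of planar designs at the default resolution
    heuristic (spacing = t/2, clamped)."""
    from .planar import gen_planar_auxetic

    return sweep_poisson(
        designs,
        lambda d: problem_from_planar(gen_planar_auxetic(d)),
        StretchBC("axial", strain))


def screen_cylinders(designs, direction: str = "axial",
                     strain: float = 0.01) -> SweepResult:
    """3-D screen of cylindrical designs (spacing = max(t/2, 0.2) mm)."""
    from .cylinder import gen_cylindrical_auxetic

    return sweep_poisson(
        designs,
        lambda d: problem_from_network_3d(gen_cylindrical_auxetic(d),
                                          spacing=max(d.t / 2, 0.2)),
        StretchBC(direction, strain))
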