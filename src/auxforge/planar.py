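"""Planar auxetic mesh generators and the foamed porous matrix.

Four lattice topologies are produced from a small parameter set (counts of
vertical/horizontal elements ``n1``/``n2``, element thickness ``t``, mesh
extents and a vertex-offset amplitude):

* ``reentrant`` — vertical baselines hold vertices that are alternately
  offset ahead/behind the baseline, with the offset sign flipped on every
  consecutive baseline; vertices are chained into vertical zigzags and
  alternate opposite-offset vertex pairs are joined horizontally, producing
  the bow-tie (re-entrant honeycomb) cell.
* ``arrowhead`` — every baseline carries the same offset pattern; each
  negative-offset vertex is joined to the two nearest positive-offset
  vertices of the next baseline, forming chevrons (vertical zigzags are kept
  so the mesh is a single connected body).
* ``sinusoidal`` — the smooth analogue of the re-entrant mesh: vertical
  sinusoids whose extrema replace the offset vertices (period spanning two
  vertex rows, every other baseline phase-shifted by one row), with
  horizontal beams joining the far (opposite-extremum) pairs at alternating
  rows.
* ``pinwheel`` — sinusoids with no phase offset across the baselines: both
  curve families pass through a common node grid at their inflection
  points, so every lattice cell is bounded by four S-shaped edges of equal
  handedness (the rotating-unit pinwheel motif); the families fuse where
  they cross.

Sinusoids are discretized into polyline beams (16 segments per half-period,
<0.5% chord error at printed scales).  Meshes lie in the z = 0 plane within
``[0, width] x [0, height]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BeamNetwork, VoxelGrid, box_sdf, grid_from_bounds, sample_sdf

__all__ = ["PlanarDesign", "gen_planar_auxetic", "gen_foam",
            "PLANAR_KINDS"]

PLANAR_KINDS = ("reentrant", "arrowhead", "sinusoidal", "pinwheel")

#: polyline segments per sinusoid half-period
SINE_SEGMENTS_PER_HALF_PERIOD = 16

#: default vertex offset / sine amplitude as a fraction of baseline separation
DEFAULT_AMPLITUDE_RATIO = 0.25

#: the pinwheel's rotating-unit motif needs pronounced S-edges
PINWHEEL_AMPLITUDE_RATIO = 0.4


@dataclass
class PlanarDesign:
    """Parameter set for a planar auxetic mesh.

    ``n1`` counts vertical elements (vertical baselines / zigzag lines) and
    ``n2`` horizontal elements (rows of horizontal cells; each bow-tie cell
    spans two vertex rows, so the offset-baseline kinds carry ``2 * n2``
    vertex rows).  ``amplitude=None`` selects the default of 0.25 x baseline
    separation (0.4 for the pinwheel, whose rotating motif needs deep
    S-curves).
    """

    kind: str = "reentrant"
    n1: int = 6
    n2: int = 6
    t: float = 0.3
    width: float = 10.0
    height: float = 10.0
    amplitude: float | None = None

    def __post_init__(self):
        if self.kind not in PLANAR_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; valid: {PLANAR_KINDS}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if self.t <= 0:
            raise ValueError("thickness t must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def default_amplitude_ratio(self) -> float:
        return (PINWHEEL_AMPLITUDE_RATIO if self.kind == "pinwheel"
                else DEFAULT_AMPLITUDE_RATIO)

    def resolved_amplitude_and_separation(self, extent: float | None = None,
                                          n: int | None = None
                                          ) -> tuple[float, float]:
        """Amplitude and baseline separation consistent with the mesh extent.

        Baselines are inset by the amplitude so that offset vertices span
        exactly ``[0, extent]``.  With the default amplitude ratio r the
        separation solves ``sep * (n - 1) = extent - 2 r sep``.
        """
        extent = self.width if extent is None else extent
        n = self.n1 if n is None else n
        n_gaps = max(n - 1, 1)
        ratio = self.default_amplitude_ratio()
        if self.amplitude is None:
            sep = extent / (n_gaps + 2 * ratio)
            amp = ratio * sep
        else:
            amp = self.amplitude
            sep = (extent - 2 * amp) / n_gaps
            if sep <= 0:
                raise ValueError("amplitude too large for mesh extent")
        if amp >= sep / 2:
            raise ValueError(
                f"amplitude {amp:.4g} >= separation/2 = {sep / 2:.4g}: "
                "self-intersecting design")
        return amp, sep


def gen_planar_auxetic(design: PlanarDesign) -> BeamNetwork:
    """Generate one of the four planar auxetic topologies as a beam network."""
    if design.kind == "reentrant":
        net = _gen_reentrant(design)
    elif design.kind == "arrowhead":
        net = _gen_arrowhead(design)
    elif design.kind == "sinusoidal":
        net = _gen_sinusoidal(design)
    else:
        net = _gen_pinwheel(design)
    return net.merged()


# ---------------------------------------------------------------------------
# offset-baseline lattices
# ---------------------------------------------------------------------------

def _n_rows(design: PlanarDesign) -> int:
    """Vertex rows for the offset-baseline kinds: 2 per horizontal cell."""
    return 2 * design.n2


def _baseline_vertices(design: PlanarDesign, sign_fn):
    """Vertex array (n1 x rows) for offset-baseline kinds.

    ``sign_fn(i, j)`` gives the offset sign of row ``j`` on baseline ``i``.
    Returns (vertices, index) with ``index[i, j]`` the vertex id.
    """
    amp, sep = design.resolved_amplitude_and_separation()
    rows = _n_rows(design)
    xb = amp + sep * np.arange(design.n1)
    yb = np.linspace(0.0, design.height, rows)
    ii, jj = np.meshgrid(np.arange(design.n1), np.arange(rows),
                         indexing="ij")
    x = xb[:, None] + amp * sign_fn(ii, jj)
    y = np.broadcast_to(yb, (design.n1, rows))
    verts = np.stack([x, y, np.zeros_like(x)], axis=-1).reshape(-1, 3)
    index = np.arange(design.n1 * rows).reshape(design.n1, rows)
    return verts, index


def _gen_reentrant(design: PlanarDesign) -> BeamNetwork:
    # offset sign (-1)^(i+j): alternate vertices offset, flipped on every
    # consecutive baseline
    verts, idx = _baseline_vertices(design, lambda i, j: (-1.0) ** (i + j))
    rows = _n_rows(design)
    beams, labels = [], []
    for i in range(design.n1):          # vertical zigzags
        for j in range(rows - 1):
            beams.append((idx[i, j], idx[i, j + 1]))
            labels.append("vertical")
    for i in range(design.n1 - 1):      # horizontal bow-tie connectors
        for j in range(rows):
            # join the opposite-offset (far) vertex pair: baseline i at
            # negative offset, baseline i+1 at positive offset.  Between two
            # such connectors the zigzags pinch inward, giving the bow-tie
            # (re-entrant) cell; the near-pair phase would give the
            # conventional honeycomb instead.
            if (i + j) % 2 == 1:
                beams.append((idx[i, j], idx[i + 1, j]))
                labels.append("horizontal")
    return BeamNetwork(verts, np.array(beams), design.t, labels)


def _gen_arrowhead(design: PlanarDesign) -> BeamNetwork:
    # identical offset pattern on every baseline
    verts, idx = _baseline_vertices(design, lambda i, j: (-1.0) ** j)
    rows = _n_rows(design)
    beams, labels = [], []
    for i in range(design.n1):          # vertical zigzags keep the mesh whole
        for j in range(rows - 1):
            beams.append((idx[i, j], idx[i, j + 1]))
            labels.append("vertical")
    for i in range(design.n1 - 1):      # chevron diagonals
        for j in range(rows):
            if (-1) ** j < 0:           # negative-offset vertex
                for jn in (j - 1, j + 1):
                    if 0 <= jn < rows:
                        beams.append((idx[i, j], idx[i + 1, jn]))
                        labels.append("diagonal")
    return BeamNetwork(verts, np.array(beams), design.t, labels)


# ---------------------------------------------------------------------------
# sinusoid kinds (sinusoidal + pinwheel)
# ---------------------------------------------------------------------------

def _sine_curve_samples(base: float, amp: float, period: float, phase: float,
                        span: float) -> np.ndarray:
    """Sample offset(u) = base + amp*sin(2*pi*u/period + phase) over [0, span].

    The sample step is period/32 (16 segments per half-period), which places
    samples exactly on the sine extrema, so the polyline attains the full
    amplitude.
    """
    step = period / (2 * SINE_SEGMENTS_PER_HALF_PERIOD)
    u = np.arange(0.0, span + step / 2, step)
    if u[-1] < span - 1e-12:
        u = np.append(u, span)
    u[-1] = span
    off = base + amp * np.sin(2 * np.pi * u / period + phase)
    return u, off


def _gen_sinusoidal(design: PlanarDesign) -> BeamNetwork:
    """Smooth re-entrant analogue.

    Vertical sinusoid i attains extremum ``a * (-1)^(i+j+1)`` at row j
    (period = two rows, phase shifted by one row on every consecutive
    baseline), reproducing the alternating-offset vertex pattern; far-pair
    horizontal beams at alternating rows close the bow-tie cells.
    """
    amp, sep_x = design.resolved_amplitude_and_separation()
    rows = _n_rows(design)
    sy = design.height / (rows - 1)
    nets = []
    xb = amp + sep_x * np.arange(design.n1)
    for i in range(design.n1):
        # phase: extremum a*(-1)^(i+j+1) at row j (y = j*sy)
        y, x = _sine_curve_samples(xb[i], amp, 2 * sy,
                                   i * np.pi - np.pi / 2, design.height)
        pts = np.column_stack([x, y, np.zeros_like(x)])
        beams = np.column_stack([np.arange(len(x) - 1), np.arange(1, len(x))])
        nets.append(BeamNetwork(pts, beams, design.t,
                                ["vertical"] * (len(x) - 1)))
    for i in range(design.n1 - 1):      # far-pair links, alternating rows
        for j in range(rows):
            s_i = (-1.0) ** (i + j + 1)
            if s_i < 0:                 # curve i at -a, curve i+1 at +a
                p0 = [xb[i] - amp, j * sy, 0.0]
                p1 = [xb[i + 1] + amp, j * sy, 0.0]
                nets.append(BeamNetwork([p0, p1], [[0, 1]], design.t,
                                        ["horizontal"]))
    from .geometry import concat_networks
    return concat_networks(nets)


def _gen_pinwheel(design: PlanarDesign) -> BeamNetwork:
    """Rotating-unit pinwheel: in-phase perpendicular sinusoid families
    through a common node grid.

    Both families pass through the nodes at their inflection points with one
    full period per cell edge, so every edge is an S-curve of the same
    handedness and every cell a rotating unit; the families are fused at
    their crossings.
    """
    amp_v, sep_x = design.resolved_amplitude_and_separation()
    amp_h, sep_y = design.resolved_amplitude_and_separation(
        extent=design.height, n=design.n2)
    x0, y0 = amp_v, amp_h
    curves = []
    for i in range(design.n1):          # vertical S-curves x(y)
        y, x = _sine_curve_samples(x0 + i * sep_x, amp_v, sep_y,
                                   -2 * np.pi * y0 / sep_y, design.height)
        curves.append(("v", np.column_stack([x, y])))
    for j in range(design.n2):          # horizontal S-curves y(x)
        x, y = _sine_curve_samples(y0 + j * sep_y, amp_h, sep_x,
                                   -2 * np.pi * x0 / sep_x, design.width)
        curves.append(("h", np.column_stack([x, y])))
    return _fuse_polylines(curves, design.t)


def _fuse_polylines(curves, thickness: float) -> BeamNetwork:
    """Join polylines into one network, fusing crossings between the vertical
    and horizontal families by inserting shared vertices at the exact
    segment-segment intersection points."""
    v_segs, h_segs = [], []   # (curve_id, seg_id, p0, p1)
    for cid, (fam, pts) in enumerate(curves):
        segs = v_segs if fam == "v" else h_segs
        for s in range(len(pts) - 1):
            segs.append((cid, s, pts[s], pts[s + 1]))

    # parametric split positions per (curve, segment)
    splits: dict[tuple[int, int], list[tuple[float, np.ndarray]]] = {}
    if v_segs and h_segs:
        P0 = np.array([s[2] for s in v_segs])
        P1 = np.array([s[3] for s in v_segs])
        Q0 = np.array([s[2] for s in h_segs])
        Q1 = np.array([s[3] for s in h_segs])
        # bbox prefilter
        vlo = np.minimum(P0, P1)[:, None, :]
        vhi = np.maximum(P0, P1)[:, None, :]
        hlo = np.minimum(Q0, Q1)[None, :, :]
        hhi = np.maximum(Q0, Q1)[None, :, :]
        cand = np.all((vlo <= hhi + 1e-12) & (hlo <= vhi + 1e-12), axis=-1)
        iv, ih = np.nonzero(cand)
        d1 = P1[iv] - P0[iv]
        d2 = Q1[ih] - Q0[ih]
        denom = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        w = Q0[ih] - P0[iv]
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = (w[:, 0] * d2[:, 1] - w[:, 1] * d2[:, 0]) / denom
            ss = (w[:, 0] * d1[:, 1] - w[:, 1] * d1[:, 0]) / denom
        ok = (np.abs(denom) > 1e-14) & (tt >= -1e-12) & (tt <= 1 + 1e-12) \
            & (ss >= -1e-12) & (ss <= 1 + 1e-12)
        for k in np.nonzero(ok)[0]:
            p = P0[iv[k]] + np.clip(tt[k], 0, 1) * d1[k]
            vc, vs = v_segs[iv[k]][0], v_segs[iv[k]][1]
            hc, hs = h_segs[ih[k]][0], h_segs[ih[k]][1]
            splits.setdefault((vc, vs), []).append((float(tt[k]), p))
            splits.setdefault((hc, hs), []).append((float(ss[k]), p))

    verts, beams = [], []
    for cid, (_, pts) in enumerate(curves):
        chain = []
        for s in range(len(pts) - 1):
            chain.append(pts[s])
            for t, p in sorted(splits.get((cid, s), []), key=lambda e: e[0]):
                chain.append(p)
        chain.append(pts[-1])
        base = len(verts)
        verts.extend(chain)
        for k in range(len(chain) - 1):
            beams.append((base + k, base + k + 1))
    verts = np.array(verts)
    verts3 = np.column_stack([verts, np.zeros(len(verts))])
    return BeamNetwork(verts3, np.array(beams), thickness).merged(1e-9)


# ---------------------------------------------------------------------------
# foamed porous matrix
# ---------------------------------------------------------------------------

def gen_foam(region, porosity: float, pore_radius, seed: int,
             spacing: float | None = None, tol: float = 0.02,
             max_rejections: int = 10000) -> VoxelGrid:
    """Carve spherical pores out of a solid box until a target void fraction
    is reached.

    Pore centres are sampled uniformly inside the box, radii uniformly in
    ``pore_radius = (min, max)``; pores may overlap each other but are kept
    one voxel clear of the box boundary so the carved solid stays watertight.
    A candidate pore that would overshoot ``porosity + tol`` is rejected;
    the run errors out after ``max_rejections`` consecutive rejections
    (unreachable porosity for the given radii/box).  Deterministic per seed.
    """
    region = np.asarray(region, float)
    if region.shape != (3,) or np.any(region <= 0):
        raise ValueError("region must be three positive box dimensions (mm)")
    rmin, rmax = float(pore_radius[0]), float(pore_radius[1])
    if not (0 < rmin <= rmax):
        raise ValueError("pore radii must satisfy 0 < min <= max")
    if not (0 <= porosity < 1):
        raise ValueError("porosity must lie in [0, 1)")
    if spacing is None:
        spacing = max(rmin / 3.0, region.min() / 128.0)
    grid = grid_from_bounds([0, 0, 0], region, spacing)
    grid = sample_sdf(grid, box_sdf([0, 0, 0], region))
    inside = grid.values < 0
    n_box = int(inside.sum())
    if porosity == 0:
        return grid

    rng = np.random.default_rng(seed)
    cx, cy, cz = grid.centers()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    rejections = 0
    centers, radii = [], []

    def void_fraction(vals):
        return float((vals[inside] >= 0).sum()) / n_box

    while void_fraction(grid.values) < porosity - tol:
        r = rng.uniform(rmin, rmax)
        margin = r + spacing            # one-voxel clearance from the shell
        if np.any(region < 2 * margin):
            raise ValueError("pore radius too large for the box")
        c = rng.uniform(margin, region - margin)
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - r
        cand = np.maximum(grid.values, -d)   # subtract the sphere
        if void_fraction(cand) > porosity + tol:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"cannot reach porosity {porosity} within +/-{tol} using "
                    f"radii [{rmin}, {rmax}]; achieved "
                    f"{void_fraction(grid.values):.3f}")
            continue
        rejections = 0
        grid.values = cand
        centers.append(c)
        radii.append(r)
    grid.pore_centers = np.array(centers).reshape(-1, 3)   # type: ignore[attr-defined]
    grid.pore_radii = np.array(radii)                      # type: ignore[attr-defined]
    return grid
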