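"""Cylindrical auxetic mesh generators.

A planar design is carried onto a cylinder of radius R by the arc-length
preserving wrap ``(x, y) -> (R cos(x/R), R sin(x/R), y)``; every straight
beam is first subdivided so that the wrapped polyline follows the cylinder
coat (segments of at most 5 degrees of arc, <0.1% sagitta error).  The z
axis is the cylinder axis, ring index 0 sits at z = 0, and the lattice
closes seamlessly across theta = 0 / 2 pi (which requires an even number of
vertical lines ``v``).

Four topologies: vertically / horizontally oriented re-entrant honeycombs
(zigzag vertical lines or zigzag rings built from two phase-shifted circles)
and the sinusoidal / pinwheel families (phase-shifted and in-phase
perpendicular sinusoids fused at crossings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import BeamNetwork
from .planar import (DEFAULT_AMPLITUDE_RATIO, SINE_SEGMENTS_PER_HALF_PERIOD,
                     _fuse_polylines)

__all__ = ["CylinderDesign", "wrap_to_cylinder", "unwrap_from_cylinder",
           "gen_cylindrical_auxetic", "CYLINDER_KINDS"]

CYLINDER_KINDS = ("reentrant_vertical", "reentrant_horizontal",
                  "sinusoidal", "pinwheel")

#: max arc per wrapped sub-beam (radians): 5 degrees
MAX_ARC_PER_SEGMENT = math.radians(5.0)


@dataclass
class CylinderDesign:
    """Cylindrical auxetic mesh parameters.

    ``h`` counts horizontal rings top-to-bottom, ``v`` vertical lines per
    ring (must be even so the alternating pattern closes at the seam),
    ``t`` the element thickness and ``amplitude`` the corner-point offset
    (``None`` = 0.25 x the relevant baseline separation).
    """

    kind: str = "reentrant_vertical"
    R: float = 4.0
    H: float = 12.0
    h: int = 6
    v: int = 12
    t: float = 0.3
    amplitude: float | None = None

    def __post_init__(self):
        if self.kind not in CYLINDER_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; valid: {CYLINDER_KINDS}")
        if self.R <= 0 or self.H <= 0 or self.t <= 0:
            raise ValueError("R, H and t must be positive")
        if self.h < 2 or self.v < 2:
            raise ValueError("h and v must be >= 2")
        if self.v % 2:
            raise ValueError("v must be even: an odd count cannot close the "
                             "alternating pattern across the seam")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def wrap_to_cylinder(p, R: float) -> np.ndarray:
    """Arc-length preserving planar-to-cylinder map.

    Planar ``(x, y)`` goes to ``(R cos(x/R), R sin(x/R), y)``; x is read as
    arc length so distances along rings are preserved and every image point
    lies at distance exactly R from the z axis.  Accepts ``(N, 2)`` or
    ``(N, 3)`` input (a z column is ignored).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    p = np.atleast_2d(np.asarray(p, float))
    th = p[..., 0] / R
    return np.stack([R * np.cos(th), R * np.sin(th), p[..., 1]], axis=-1)


def unwrap_from_cylinder(q, R: float) -> np.ndarray:
    """Inverse of :func:`wrap_to_cylinder` (theta taken in [0, 2 pi))."""
    q = np.atleast_2d(np.asarray(q, float))
    th = np.mod(np.arctan2(q[..., 1], q[..., 0]), 2 * np.pi)
    return np.stack([R * th, q[..., 2]], axis=-1)


def gen_cylindrical_auxetic(design: CylinderDesign) -> BeamNetwork:
    """Generate a cylindrical auxetic lattice as a 3-D beam network."""
    if design.kind == "reentrant_vertical":
        net = _reentrant_vertical(design)
    elif design.kind == "reentrant_horizontal":
        net = _reentrant_horizontal(design)
    else:
        net = _sinusoid_cylinder(design)
    return net.merged(1e-9)


# ---------------------------------------------------------------------------
# arc-beam assembly in (theta, z) space
# ---------------------------------------------------------------------------

def _polylines_to_network(polys, R: float, thickness: float) -> BeamNetwork:
    """Wrap (theta, z) polylines onto the cylinder and join them.

    Each polyline is an (M, 2) array of (theta, z) samples; logical corner
    points must carry bit-identical canonical theta values so that seam and
    junction vertices fuse exactly.
    """
    verts, beams = [], []
    for pts in polys:
        pts = np.asarray(pts, float)
        base = len(verts)
        verts.extend(pts)
        beams.extend((base + k, base + k + 1) for k in range(len(pts) - 1))
    tz = np.array(verts)
    xyz = np.stack([R * np.cos(tz[:, 0]), R * np.sin(tz[:, 0]), tz[:, 1]],
                   axis=-1)
    return BeamNetwork(xyz, np.array(beams), thickness)


def _arc(th_a: float, z_a: float, th_b_canon: float, z_b: float,
         dtheta: float) -> np.ndarray:
    """(theta, z) polyline from corner a to corner b travelling ``dtheta``.

    Interior samples interpolate theta linearly over ``dtheta`` (which may
    wrap past the seam); the endpoints keep their canonical theta so shared
    corner points stay bit-identical across beams.
    """
    n = max(1, math.ceil(abs(dtheta) / MAX_ARC_PER_SEGMENT))
    t = np.linspace(0.0, 1.0, n + 1)
    th = th_a + t * dtheta
    z = z_a + t * (z_b - z_a)
    pts = np.column_stack([th, z])
    pts[0] = (th_a, z_a)
    pts[-1] = (th_b_canon, z_b)
    return pts


# ---------------------------------------------------------------------------
# re-entrant honeycombs
# ---------------------------------------------------------------------------

def _reentrant_vertical(d: CylinderDesign) -> BeamNetwork:
    """Vertical zigzag lines whose corner points alternate on two sides of a
    baseline; every second pair of neighbouring ring points is joined by an
    arc, with the arc rows alternating along the axis."""
    step = 2 * np.pi / d.v
    amp = (DEFAULT_AMPLITUDE_RATIO * step * d.R if d.amplitude is None
           else d.amplitude)
    if amp >= step * d.R / 2:
        raise ValueError("amplitude >= baseline separation / 2")
    a_th = amp / d.R
    z = np.linspace(0.0, d.H, d.h)
    # canonical corner angles theta[i, j]
    theta = np.empty((d.v, d.h))
    for i in range(d.v):
        for j in range(d.h):
            theta[i, j] = i * step + a_th * (-1.0) ** (i + j)
    polys = []
    for i in range(d.v):            # vertical zigzags
        for j in range(d.h - 1):
            dth = theta[i, j + 1] - theta[i, j]
            polys.append(_arc(theta[i, j], z[j], theta[i, j + 1], z[j + 1], dth))
    for i in range(d.v):            # alternating ring arcs (seam-aware)
        nxt = (i + 1) % d.v
        for j in range(d.h):
            # far-pair connection (baseline i at -a, i+1 at +a): bow-tie cell
            if (i + j) % 2 == 1:
                dth = (nxt * step + a_th * (-1.0) ** (nxt + j)) \
                    + (2 * np.pi if nxt < i else 0.0) - theta[i, j]
                polys.append(_arc(theta[i, j], z[j], theta[nxt, j], z[j], dth))
    return _polylines_to_network(polys, d.R, d.t)


def _reentrant_horizontal(d: CylinderDesign) -> BeamNetwork:
    """Zigzag rings built from two circles with angular step 2 pi / v and a
    phase shift of pi / v; neighbouring rings are tied by straight vertical
    beams at alternating positions."""
    m_tot = 2 * d.v                     # corner points per zigzag ring
    half = np.pi / d.v                  # phase shift between the two circles
    sz = d.H / (d.h - 1)
    amp = DEFAULT_AMPLITUDE_RATIO * sz if d.amplitude is None else d.amplitude
    if amp >= sz / 2:
        raise ValueError("amplitude >= ring separation / 2")
    zbase = np.linspace(0.0, d.H, d.h)
    theta = np.array([m * half for m in range(m_tot)])
    zc = np.empty((m_tot, d.h))
    for m in range(m_tot):
        for j in range(d.h):
            zc[m, j] = zbase[j] + amp * (-1.0) ** (m + j)
    polys = []
    for j in range(d.h):                # zigzag rings as wrapped arcs
        for m in range(m_tot):
            nxt = (m + 1) % m_tot
            th_b = theta[nxt]
            dth = (th_b + (2 * np.pi if nxt == 0 else 0.0)) - theta[m]
            polys.append(_arc(theta[m], zc[m, j], th_b, zc[nxt, j], dth))
    for j in range(d.h - 1):            # vertical connectors, alternating
        for m in range(m_tot):
            # far pair (ring j at -a, ring j+1 at +a): bow-tie cell
            if (m + j) % 2 == 1:
                polys.append(_arc(theta[m], zc[m, j], theta[m], zc[m, j + 1], 0.0))
    return _polylines_to_network(polys, d.R, d.t)


# ---------------------------------------------------------------------------
# sinusoidal / pinwheel
# ---------------------------------------------------------------------------

def _sinusoid_cylinder(d: CylinderDesign) -> BeamNetwork:
    if d.kind == "sinusoidal":
        return _sinusoidal_cylinder(d)
    return _pinwheel_cylinder(d)


def _sinusoidal_cylinder(d: CylinderDesign) -> BeamNetwork:
    """Smooth re-entrant analogue on the cylinder: axial sinusoids whose
    extrema alternate on the two sides of each baseline (consecutive
    baselines phase-shifted by one ring gap), tied by far-pair ring arcs at
    alternating rings."""
    step_th = 2 * np.pi / d.v
    sz = d.H / (d.h - 1)
    amp = (DEFAULT_AMPLITUDE_RATIO * step_th * d.R if d.amplitude is None
           else d.amplitude)
    if amp >= step_th * d.R / 2:
        raise ValueError("amplitude >= baseline separation / 2")
    a_th = amp / d.R

    dz = sz / (2 * SINE_SEGMENTS_PER_HALF_PERIOD)
    z = np.arange(0.0, d.H + dz / 2, dz)
    z[-1] = d.H
    rows = np.arange(0, len(z), 2 * SINE_SEGMENTS_PER_HALF_PERIOD)

    thetas = []                 # per-curve theta samples (canonical values)
    polys = []
    for i in range(d.v):
        th = i * step_th + a_th * np.sin(np.pi * z / sz + i * np.pi
                                         - np.pi / 2)
        thetas.append(th)
        polys.append(np.column_stack([th, z]))
    for i in range(d.v):        # far-pair arcs at alternating rings
        nxt = (i + 1) % d.v
        for j_idx, row in enumerate(rows):
            # curve i sits at extremum a*(-1)^(i+j+1); link where it is -a
            if (-1.0) ** (i + j_idx + 1) < 0:
                th_a = thetas[i][row]
                th_b = thetas[nxt][row]
                dth = (nxt * step_th + (2 * np.pi if nxt < i else 0.0)
                       + a_th) - th_a
                polys.append(_arc(th_a, z[row], th_b, z[row], dth))
    return _polylines_to_network(polys, d.R, d.t)


def _pinwheel_cylinder(d: CylinderDesign) -> BeamNetwork:
    """Rotating-unit pinwheel on the cylinder: in-phase perpendicular
    S-curve families through a common node grid in unwrapped (arc, z)
    coordinates, fused at crossings and wrapped; the circumferential period
    equals one node gap, so the family closes exactly around the seam."""
    from .planar import PINWHEEL_AMPLITUDE_RATIO

    C = 2 * np.pi * d.R
    su = C / d.v
    sz = d.H / (d.h - 1)
    amp_u = PINWHEEL_AMPLITUDE_RATIO * su if d.amplitude is None else d.amplitude
    amp_z = PINWHEEL_AMPLITUDE_RATIO * sz if d.amplitude is None else d.amplitude
    if amp_u >= su / 2 or amp_z >= sz / 2:
        raise ValueError("amplitude >= baseline separation / 2")

    def samples(period, span):
        step = period / (2 * SINE_SEGMENTS_PER_HALF_PERIOD)
        u = np.arange(0.0, span + step / 2, step)
        if u[-1] < span - 1e-12:
            u = np.append(u, span)
        u[-1] = span
        return u

    curves = []
    for i in range(d.v):        # axial S-curves through nodes at z = j*sz
        zz = samples(sz, d.H)
        uu = (i + 0.5) * su + amp_u * np.sin(2 * np.pi * zz / sz)
        curves.append(("v", np.column_stack([uu, zz])))
    for j in range(d.h):        # circumferential S-curves, nodes at (i+.5)*su
        uu = samples(su, C)
        zz = j * sz + amp_z * np.sin(2 * np.pi * (uu - 0.5 * su) / su)
        curves.append(("h", np.column_stack([uu, zz])))
    flat = _fuse_polylines(curves, d.t)
    u = np.mod(flat.vertices[:, 0], C)
    th = u / d.R
    xyz = np.stack([d.R * np.cos(th), d.R * np.sin(th), flat.vertices[:, 1]],
                   axis=-1)
    return BeamNetwork(xyz, flat.beams, flat.thickness, flat.labels)
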