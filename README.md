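# auxforge

Algorithmic design of auxetic lattices, organ-wrapped meshes and perfusable
tissue-engineering constructs, with an embedded-domain (finite cell) voxel
elasticity solver for screening Poisson's ratios across large design
libraries.

Auxetic structures — lattices with negative Poisson's ratio ν that expand
laterally when stretched — are increasingly used as stents, organ-conforming
patches and tissue grafts. Designing them by hand in CAD is slow: a single
patch may require screening hundreds of (n₁, n₂, t) combinations to match an
organ's compliance. `auxforge` generates whole design families from a few
parameters, converts them to printable geometry (beam networks → voxel
signed-distance grids → STL surfaces, ready for volumetric lithography), and
computes each design's ν in seconds without any body-fitted meshing.

## What it builds

* **Planar auxetic meshes** — re-entrant (bow-tie) honeycombs, arrowhead
  (chevron) lattices, sinusoidal-ligament meshes and rotating-unit pinwheel
  grids, parameterized by the counts of vertical/horizontal elements
  (n₁, n₂), element thickness t, and sheet extent.
* **Cylindrical auxetic meshes** (stent-like) — the same topologies carried
  onto a cylinder by an arc-length-preserving wrap, with seamless closure
  around the circumference (h rings, v vertical lines, thickness t).
* **Organ-wrapped meshes** — a planar sheet is clipped to a circle, wrapped
  onto a sphere by the azimuthal-equidistant map, and projected point-by-
  point onto an arbitrary closed surface (e.g. a heart STL, or the built-in
  synthetic organ fixture) by closest-point search.
* **Perfusable constructs** — hyperbolic-sine channel trees around a hollow
  core, budding alveolus solids (union of mini-spheres), icosahedron-derived
  capillary networks wrapped around the alveolus at a fixed fluid gap, and
  boolean assembly into printable blocks with inlet/outlet ports whose void
  space is verified connected by flood fill.
* **Porous matrices** — a seeded foaming algorithm carving spherical pores
  to a target void fraction.

## The mechanics screen

Each design is embedded in a regular voxel grid (the finite cell /
fictitious-domain method): bilinear quads in 2-D plane stress, trilinear
hexahedra in 3-D, with element stiffness integrated over sub-voxels whose
indicator is α = 1 in the solid and α = 10⁻⁶ in the void. An axial stretch
prescribes a displacement on the solid's top boundary with the bottom on
rollers; the Poisson's ratio follows the −ΔW/ΔL convention

    ν = −(ΔW/W₀) / (ΔL/L₀),

with the lateral strain measured from the mean displacement of the extreme
boundary-node bands. Radial (balloon-type) stretch of cylinders prescribes
the radial displacement component at every node and measures the axial
response, ν_r = −(ΔL/L₀)/(ΔR/R₀). On a fully solid plate the screen
recovers the material ν to three digits; a voxelized cantilever matches
Euler–Bernoulli beam theory within a few percent.

## Worked example

```python
import auxforge as ax
from auxforge.mechanics import problem_from_planar, StretchBC, solve_elasticity

design = ax.PlanarDesign(kind="reentrant", n1=6, n2=3, t=0.15)  # mm
net = ax.gen_planar_auxetic(design)
print(f"mesh: {net.n_vertices} vertices, {net.n_beams} beams")

problem = problem_from_planar(net)          # plane-stress finite-cell model
res = solve_elasticity(problem, StretchBC("axial", 0.01))
print(f"axial strain : {res.eps_axial:+.4f}")
print(f"lateral strain: {res.eps_lateral:+.4f}")
print(f"Poisson ratio : {res.nu:+.3f}")
```

prints

```
mesh: 36 vertices, 45 beams
axial strain : +0.0100
lateral strain: +0.0193
Poisson ratio : -1.928
```

i.e. stretching this bow-tie mesh axially by 1% widens it by 1.9% — strongly
auxetic. Exporting it for printing:

```python
grid = ax.voxelize_network(net)          # signed-distance voxel grid
surf = ax.extract_surface(grid)          # marching-cubes triangle mesh
ax.write_stl(surf, "mesh.stl")
```

The same is available from the shell, including sweeps and organ wrapping:

```bash
auxforge generate planar --kind reentrant --n1 6 --n2 3 --t 0.15 --out mesh.stl
auxforge sweep --kind reentrant --n1 2:8 --n2 2:8 --t 0.1:0.35:5 --out sweep.csv
auxforge wrap --kind sinusoidal --density 8 --clip 7 --sphere 10 --out wrapped.stl
auxforge design alveolus --Rp 3 --r 1.2 --o 0.8 --nbuds 9 --seed 1 --out alv.stl
```

Every artifact gets a JSON sidecar with the fully resolved parameters and
seed, so any output can be regenerated exactly; identical configurations
produce bit-identical files.

Voxel grids persist as NPZ containers with three arrays: `origin` (mm),
`spacing` (mm, isotropic) and `values` (signed distance, negative inside;
the voxel sample point is the voxel centre).

## Documentation

`docs/methods.md` describes the model, the lattice constructions and their
assumptions, the numerical choices and the known limitations.
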