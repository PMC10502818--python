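# Methods

## Scope and representations

`auxforge` couples parametric lattice generation with an embedded-domain
elasticity screen. Three representations carry all geometry:

* **Beam networks** — vertices (mm) plus thickness-attributed edges; the
  native form of every lattice and vessel tree. Beams are rendered as
  capsules (segment inflated by t/2), a choice made once and documented
  here: the engine is voxel-native and the literature leaves the strut
  cross-section unstated; capsules give orientation-independent thickness
  and exact signed distances.
* **Voxel grids** — isotropic, axis-aligned scalar grids holding signed
  distance (negative inside, stated once here and asserted in tests) or an
  indicator. Voxel sample point = voxel centre; the indicator is SDF < 0.
  Boolean CSG uses the standard SDF combines (union = min, subtract =
  max(A, −B), intersect = max).
* **Triangle surfaces** — marching-cubes output and STL I/O (binary and
  ASCII; float32 in both modes with 9 significant ASCII digits, so the two
  modes emit identical triangle soups).

Lengths are millimetres throughout. The default voxelization spacing is
min(thickness)/6, which resolves the thinnest strut while keeping grids
desk-scale; the mechanics screen uses its own coarser heuristic (below).

## Planar lattice constructions

All four topologies live on vertical baselines at uniform separation inside
a width × height sheet, with the baselines inset by the offset amplitude so
the finished mesh spans exactly [0, width] × [0, height].

* **Re-entrant honeycomb.** Vertices on baseline i, row j are offset by
  a·(−1)^(i+j) (alternate vertices ahead/behind, sign flipped on every
  consecutive baseline), chained into vertical zigzags; horizontal beams
  join the *opposite-offset* (far) vertex pair of neighbouring baselines at
  alternating rows. The far pairing is essential: joining the near pair
  produces the conventional honeycomb, which contracts laterally (computed
  ν ≈ +2.5) instead of the bow-tie cell (ν < 0). `n2` counts horizontal
  cells; each bow-tie spans two vertex rows, so the lattice carries 2·n2
  rows. This cell-row reading is what keeps the extreme corner of the
  design space physical: with rows = n2 the (n1 = 8, n2 = 2) corner has
  10 mm-tall cells and ν below −100, far outside the behaviour of any
  printed mesh family.
* **Arrowhead.** Same offset magnitude but the same pattern on every
  baseline; each negative-offset vertex joins the two nearest
  positive-offset vertices of the next baseline (chevrons). Vertical
  zigzags are retained so the mesh is one connected body.
* **Sinusoidal ligaments.** The smooth analogue of the re-entrant mesh:
  vertical sinusoids with period equal to two vertex rows, every other
  baseline phase-shifted by one row, so the extrema reproduce the
  alternating-offset pattern exactly; far-pair horizontal links close the
  smooth bow-ties. Sinusoids are discretized at 16 segments per
  half-period (< 0.5% chord error at printed scales) with samples landing
  exactly on the extrema.
* **Pinwheel.** Sinusoids with no phase offset across the baselines: both
  curve families pass through a common node grid at their inflection
  points with one full period per cell edge, so every cell is bounded by
  four S-curves of equal handedness — a rotating-unit motif — and the
  families fuse at the exact segment–segment crossings. Fused crossings
  reflect the printed reality (overlapping solids cure into one body).

Amplitude defaults to 0.25 × baseline separation, which visually matches
the published unit cells and keeps the design away from self-intersection
(amplitude ≥ separation/2 is rejected). The pinwheel uses 0.4 ×: the
rotating mechanism lives in the depth of its S-edges, and at 0.25 the
lattice is not auxetic at any thickness. These are defaults, not
constraints — both are exposed parameters.

During reconstruction the alternative readings of the sinusoid kinds were
evaluated mechanically: every fused perpendicular-sinusoid grid with
"period spanning two gaps" (all four phase combinations, amplitudes 0.25
and 0.4) gives ν between +0.2 and +1.0 and was therefore rejected as
inconsistent with the documented lateral expansion of all four mesh types.

## Cylindrical constructions

A planar point (x, y) maps to (R·cos(x/R), R·sin(x/R), y): arc-length
preserving, every image point exactly at radius R. Straight beams are
subdivided into sub-beams of at most 5° of arc before wrapping (< 0.1%
sagitta error), so they follow the cylinder coat. The z axis is the
cylinder axis and ring 0 sits at z = 0. The vertical line count v must be
even or the alternating pattern cannot close across the θ = 0 seam; seam
vertices are shared exactly (canonical angles, no floating-point stitching).

* *Vertical re-entrant*: vertical zigzag lines with corner points
  alternating on two sides of each baseline, ring arcs joining every second
  pair of neighbouring points, arc rows alternating along the axis.
* *Horizontal re-entrant*: zigzag rings built from two circles with angular
  step 2π/v and phase shift π/v (values chosen to tile the circumference
  exactly), straight axial connectors at alternating positions; far-pair
  parity as in the planar mesh.
* *Sinusoidal / pinwheel*: the planar constructions in unwrapped (arc, z)
  coordinates; the circumferential sinusoid period divides the
  circumference exactly, so the family closes seamlessly.

## Organ wrapping

Clipping keeps the portion of each beam inside the circle, inserting the
exact segment–circle intersection points. The sphere wrap is the
azimuthal-equidistant map (planar polar (ρ, φ) → polar angle ψ = ρ/R,
azimuth φ): the source material does not name the map, and equidistance
preserves the radial cell size best, matching the undistorted appearance of
the published wrapped meshes. ρ > πR (past the antipode) is an error.

Closest-point projection replaces every vertex and beam-subdivision point
by its globally nearest point on the target triangle mesh. The KD-tree
acceleration is contractual: a candidate upper bound from the 8 nearest
triangle centroids is refined by exactly evaluating every triangle whose
centroid could possibly beat it, so results equal exhaustive search to
machine precision (asserted against the brute-force oracle in tests).
Projection "onto the bottom" of an organ restricts candidates to faces with
downward normals; the default intersection depth sinks the organ 5% of its
bounding-box height into the curved sheet.

The synthetic organ fixture is a subdivided icosphere (5120 faces) radially
deformed into a two-lobed, apex-tapered star-shaped blob with a small
seeded low-frequency perturbation: watertight and genus 0 by construction,
deterministic per seed. It emulates the closed, smooth, heart-like surface
of a repository organ model; it does **not** emulate real anatomical
curvature distributions, so wrap tests demonstrate correctness of the
mapping, not anatomical fit.

## Perfusable constructs

* **Channel tree.** One radial-excursion profile ρ(u) = A·sinh(k·u) with k
  solving ρ(1) = D/2 (A → 0 degenerates to a straight taper), swept from
  the inlet on the axis to the offset circle of diameter D at the
  midplane, rotated into n copies at pitch 2π/n, mirrored through the
  midplane and joined by straight channels; thickness tapers linearly from
  the inlet diameter d to the channel thickness t. Inlet/outlet stubs
  pierce the block faces so the carved construct is open.
* **Alveolus.** Mini-sphere centres inside the parent sphere at mutual
  spacing ≥ o — deterministic spherical-Fibonacci shell at radius
  Rp − r/2 (buds poke outward past the periphery, giving the budding look)
  or seeded rejection sampling — each scaled to radius r and unioned as an
  exact SDF. Hollowing subtracts a concentric scaled copy resampled from
  the same grid (for a true SDF, f_s(p) = s·f(c + (p−c)/s)).
* **Capillary network.** Icosahedron (vertex up) subdivided 4-way per
  level; every face centroid joined to its three edge midpoints (60 beams
  at level 0, 240 at level 1; centroids degree 3, midpoints degree 2);
  thickness graded linearly along the inlet–outlet axis from the end
  thickness to the mid thickness; each beam interpolated into 11
  equidistant points (10 sub-beams) and projected radially onto the
  circumscribed sphere. The inlet window is then opened by scaling polar
  angles inside the apex cap by the enlargement factor (default 2) with a
  piecewise-linear monotone blend to identity — cutting the opening on the
  sphere rather than before projection, because a straight ×2 scaling
  about the apex maps cap centroids exactly onto neighbouring centroids (a
  midpoint-subdivision identity) and would silently fuse beams.
* **Offset wrapping.** Vessel points are projected onto the alveolar
  union-of-spheres surface dilated by the gap (default 0.25 mm) by damped
  gradient marching on the exact SDF; convergence to 10⁻⁹ mm in tens of
  iterations, connectivity untouched.
* **Assembly.** Outer solid (box or cylinder) minus voxelized channels
  minus cavity minus port cylinders sunk from the top face to the branch
  points (degree ≥ 3 vertices) nearest two antipodal top positions.
  Perfusability is checked by 6-connected flood fill from inlet to outlet.

## The finite-cell screen

Small-strain linear elasticity on the regular cell grid: bilinear quads
(plane stress) for planar sheets — thin printed membranes — and trilinear
hexahedra for cylinders. Element stiffness is pre-integrated per sub-voxel
(quadrature depth 2, i.e. 2×2(×2) sub-voxels with 2-point Gauss each) and
assembled as Σ_s α_s K_s with α = 1 in solid sub-voxels and α = 10⁻⁶ in
void. Cells with no solid sub-voxel are dropped entirely — they carry pure
fictitious stiffness and only bloat and ill-condition the system — while
cut cells keep their void-weighted quadrature, preserving the
α-insensitivity that the tests assert (ν changes < 1% between α = 10⁻⁶ and
10⁻⁸). Systems are solved by sparse LU; a relative residual above 10⁻⁶
or a non-finite solution raises, and a deterministic connected-component
check rejects geometries whose solid does not link the loaded boundaries.

Boundary conditions and measurement:

* *Axial*: prescribed displacement ε·L₀ on the top boundary nodes of the
  solid (band of half a cell), bottom band on rollers (normal fixed,
  tangential free) or fully fixed; in 2-D one bottom node is pinned
  laterally, in 3-D four bottom nodes on the coordinate axes pin the
  in-plane rigid modes while leaving radial breathing essentially free.
  Lateral strain = difference of mean lateral displacement between the 5%
  extreme-x boundary-node bands, normalised by the distance between the
  band centroids (exact for affine fields — plain band averaging biases a
  homogeneous plate by 5%). For cylinders the radial strain is averaged
  over the mid-height half.
* *Radial* (cylinders): balloon mode — the radial displacement component
  u_r = ε·r is prescribed at **every** solid node through a per-node
  cylindrical rotation of the in-plane dofs, with tangential and axial
  components free (one tangential dof pinned against rigid rotation, the
  bottom ring pinned axially). End-ring-only prescription was evaluated
  and rejected: it engages almost none of the lattice (ν_r ≈ 0.02–0.06,
  occasionally negative), whereas full in-plane clamping returns the
  material response 2ν/(1−ν) regardless of geometry. Balloon mode is the
  physically meaningful middle ground (stent expansion / foreshortening)
  and reproduces the documented positive radial range.

Material defaults: E = 50 kPa, ν_mat = 0.45 (near-incompressible
hydrogel); in the linear regime the lattice ν is geometry-dominated and E
cancels exactly. Applied strain 0.01 (linear regime; experimental stretches
of 10–50% are outside this model by design).

Screening resolution: spacing = t/2 clamped to [0.05, 0.3] mm in 2-D and
max(t/2, 0.2) mm in 3-D. At these settings a 2-D design solves in well
under a second and a 3-D cylinder in a few seconds; the solid-plate ν is
exact to 3 digits and ν of the extreme lattice cases is grid-converged to
a few percent (checked by refinement).

## Reference screening libraries

The published design libraries are not printed in full, so the screens are
reproductions anchored to the published extremes:

* **Planar re-entrant**: n₁, n₂ ∈ {2..8}, t ∈ {0.10, 0.1625, 0.225,
  0.2875, 0.35} mm — 245 designs on the 10 × 10 mm sheet, matching the
  documented count of 244 designs per mesh and the printed element scale
  (~0.26–0.29 mm measured features). Computed extremes: ν from −11.4 to
  +0.13.
* **Cylinders**: R = 4 mm, H = 12 mm, h ∈ {4, 6}, v ∈ {8, 12},
  t ∈ {0.6, 0.7, 0.8} mm, all four topologies (axial) and horizontal
  re-entrant (radial). Slenderer members (e.g. v = 12 with t = 0.4 mm)
  are physically valid but land far outside the published axial range
  (grid-converged ν ≈ −6.5), and thin many-ring members turn the radial
  response negative; the moderate range above is the reconstruction most
  consistent with the published anchors. Residual discrepancies are
  reported as-is: the axial sweep minimum computes to ≈ −3.0 (published
  −2.4) and the radial minimum to ≈ 0.32 (published 0.2), while the
  radial maximum ≈ 1.31 (published 1.1) and the radial non-negativity of
  every swept design match.

## Numerical choices and degenerate inputs

* Zero-length beams render as spheres (capsule SDF degenerates smoothly);
  generator corner cases need no special-casing.
* Vertex merging uses a KD-tree union-find at 10⁻⁹ mm, robust to
  rounding-bin straddles at seams.
* Voxelization evaluates each beam only in its padded bounding window;
  values are the exact union SDF within a 4-voxel band of every surface
  and a positive upper bound elsewhere, so indicators, volumes and
  extracted iso-surfaces are unaffected.
* Marching cubes is evaluated at iso 0 on SDF grids; an iso outside the
  value range warns and returns an empty surface; exact zero-area faces
  are dropped.
* Foam pores may overlap each other but keep one voxel clear of the box
  shell (watertight carved solid); a candidate pore overshooting the
  porosity band (±0.02) is rejected, and the run aborts after 10⁴
  consecutive rejections.

## Known limitations

* The elasticity model is linear and small-strain: no contact, no
  self-sticking of struts, no buckling; experimentally measured ν at large
  stretch will generally be smaller in magnitude than the screen's values.
* Strut cross-sections are circular (capsules); printed struts are closer
  to rounded-square at the voxel scale.
* Iso-surfaces of thin lattices can be non-manifold where capsules touch
  tangentially; watertightness is guaranteed only for solids whose surface
  stays away from grid borders (spheres, boxes, alveoli, shells).
* The pinwheel's auxetic window is narrow (thin struts, deep S-edges);
  its reconstruction is the least constrained by the source text.
* Fluid flow, organ deformation coupling and tomographic projection
  generation are out of scope.
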