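# Methods

## Input model and conventions

The unit of analysis is a *labeled volume*: a 3D integer array in
(z, y, x) axis order (multi-page TIFF, page = z) where 0 is background
and every positive value identifies one cell, plus a physical voxel
size in µm. Physical coordinates are reported as (x, y, z), with the
centre of voxel (iz, iy, ix) at (ix·vx, iy·vy, iz·vz) — 0-based
indices scaled by the voxel size. Only label 0 is background;
segmentations using an additional "outside" label must merge it
(`--background` accepts several labels and merges them) rather than
have the tool guess tool-specific conventions.

All annotation operates on three per-cell quantities: the centroid
(mean of voxel-centre coordinates), the volume (voxel count × voxel
volume, so cell volumes always sum exactly to the foreground volume),
and the nearest point on the tissue's outer surface mesh.

## Surface mesh

When no external PLY mesh is supplied, the surface is extracted by
binarizing the foreground, Gaussian-smoothing with σ (µm, default 2.0,
converted per axis to voxels), marching cubes at iso-level 0.5, and
keeping the largest connected component. The volume is padded by one
background voxel before contouring so the surface closes even where
tissue touches the stack border; `cut_base` then removes the flat cap
that closes the lower z boundary. Cutting the base matters whenever
the tissue was clipped at the bottom of the stack: without it, deep
cells near the base find their "nearest surface" on the artificial cap
below them, their cone axes point downward, and layer detection
misassigns them. The mesh is only required to be a faithful outer
surface; no further mesh repair is attempted.

Nearest-point queries project the centroid onto candidate triangles
exactly (point-to-triangle projection), never snapping to the nearest
vertex — vertex snapping on coarse meshes would bias the surface-vector
directions that the cone test depends on. Candidates are pruned with a
KD-tree over mesh vertices: any triangle that could beat the current
best has a vertex within the best distance plus the longest mesh edge,
so the pruned search is exact.

## Cone peeling and the membership inequality

Cell *j* is *inside* cell *i*'s cone iff the angle between
(x_c^j − x_c^i) and the outward axis −t^i is strictly less than θ.
Three conventions are fixed here and exposed rather than buried:

- **Orientation.** The cone is taken to open from the centroid *toward
  the surface* (axis −t^i), which is the configuration in which "L1 =
  cells with no other centroid in their cone" identifies the outermost
  layer. The alternative reading — applying the inequality
  (x_c^j − x_c^i)·t^i / (‖x_c^j − x_c^i‖‖t^i‖) < cos θ literally with
  the inward vector t^i — selects the *complement* of a cone about the
  inward direction and inverts the L1 criterion; it is available as
  `cone_convention="literal"` for comparison but is not the default.
- **Unbounded cone.** The cone is not truncated at the surface: no
  centroids exist outside the tissue, and truncation would make the
  test sensitive to mesh-fit error.
- **Strict inequality.** Points exactly on the lateral cone surface are
  outside — a deterministic tie-break.

Peeling runs exactly three strata: unoccluded cells → L1, removed;
unoccluded remainder → L2; everything else → L3. Deeper strata are not
enumerated, matching how SAM layers are conventionally reported.
Surface vectors are computed once against the original mesh and reused
across rounds (removing cells does not move the surface). Cells below
`min_cell_volume` (default 0, i.e. keep everything) are annotated
`unassigned` and excluded from occlusion tests entirely; they are
normally segmentation debris, and letting debris occlude real cells
would corrupt the layers. A cell whose centroid lies exactly on the
mesh has no cone axis; it is assigned L1 (it *is* at the surface) with
a warning.

θ defaults to 60°. Wider cones capture more occluders, so enlarging θ
can only shrink or preserve L1 (a monotonicity the tests verify); θ is
the knob to adjust for unusually flat or elongated cells.

## Organizing centre and the above-OC column

The user names the apex cell (the highest L1 cell is suggested by
`suggest_apex` / the `inspect` command, but the choice stays with the
user). With a = the apex's nearest surface point and n = the unit
inward normal there, the OC is the set of **L3** cells within `radius`
of c = a + depth·n — a Euclidean ball about a point at depth, which is
how a depth plus a width naturally compose; restricting to L3 keeps
the niche inside the inner stratum. The "cells above" the OC are those
in the axial cylinder of the same radius between the surface (axial
coordinate 0) and the OC depth; they keep their layer stratum and are
renamed L1/L2/L3_above_OC. Whether the original width parameter was
meant as a ball or a lateral cylinder radius is underdetermined; ball
for the OC and cylinder for the column is the simplest pair consistent
with a depth-plus-radius parameterization, and it is stated here as
this package's convention.

## Primordium delineation

With r = d_p/d_SAM computed from the three selected centroids and
ρ_i the per-cell distance ratio, the sets are evaluated literally:
P = {ρ < r − δ}, B = {r − δ ≤ ρ ≤ r + δ}, S = {ρ > r + δ}. δ is an
absolute half-width on the ratio scale. Two degenerate limits are
pinned so the selected cells land in their own zones: the
primordium-peak cell (d_p = 0) has ρ = 0 → P, the SAM-peak cell
(d_SAM = 0) has ρ = +∞ → S.

The boundary band of the pure ratio rule is an unbounded spherical
shell; the `absolute_distance` parameter caps its depth as a Euclidean
ball about the saddle centroid, applied to B membership only. Band
cells beyond the cap fall back to the δ = 0 rule (ρ < r → P, else S).
Capping at the saddle, rather than at the P/S interface or along
surface depth, is the least-structured cap that keeps the boundary a
local ring around the crease.

Sequential selections freeze earlier P and B cells against
reassignment (first selection wins — deterministic and documented).
Primordium cells compound with their layer: zone `primordium(k, layer)`
retains the L1/L2/L3 stratum so per-layer statistics inside each
primordium remain possible; boundary cells become `boundary(k)`. The
organizing centre and `unassigned` cells are never overwritten by a
primordium. With `same_label` every selection shares index 1.

## Morphometrics

Principal magnitudes are √eigenvalues of the *population* covariance
(divide by N) of the cell's voxel-centre coordinates in physical
units; anisotropy = largest magnitude / sum of the three. A perfect
cube gives exactly 1/3, an axis-aligned 1×1×9 rod exactly 1 (its only
nonzero magnitude is √(60/9) µm), and the value is invariant under
axis permutations and 90° rotations. Single-voxel cells have zero
extent; their anisotropy is reported as missing with a warning.

Adjacency uses 6-connectivity only: an edge exists iff two cells share
voxel faces, and its weight is the accumulated face area (the product
of the two voxel dimensions orthogonal to the contact axis). Corner
and edge contacts have zero area and create no edge. Because each face
is accumulated exactly once, the network satisfies an exact
conservation law — for every cell, edge areas + background/border-facing
area = total boundary face area — which the tests verify against an
independent 6V − 2·(internal adjacencies) count. Mesh-based sub-voxel
interface areas are out of scope.

Zone summaries report per-zone cell counts, volume mean/median/sd and
anisotropy mean/sd, and per zone-pair interface counts and area
mean/sd (sample sd, ddof = 1). Hypothesis testing is left to the
caller — the tables are tidy CSV on purpose.

## Synthetic phantoms

The generator emulates the *input class* (watershed-style segmentations
of dome-shaped meristems), not meristem biology. Seeds are placed on
concentric hemispherical shells (Fibonacci lattice, one shell per cell
layer, spacing = shell thickness) beneath a dome surface, the core
below the deepest shell is filled with a jittered cubic grid of
interior seeds, and every foreground voxel takes the label of its
nearest seed — producing convex-ish, watertight cells like watershed
output. Primordia are radial Gaussian bumps on the dome radius;
ground-truth primordium/boundary zones are angular sectors about each
bump axis, and per-bump peak/saddle cells are chosen on the surface
layer the way a user would click them. `layer_volume_profile`
rescales per-shell seed spacing ±15% to make cell volume increase or
decrease with depth, reproducing the two qualitative architectures
seen in real dicot SAMs (Arabidopsis-like: L1 smallest; tomato-like:
L1 largest).

Defaults — dome radius 40 µm, 3 shells of 5 µm (a typical cell
diameter), 1 µm isotropic voxels — give ≈1000 cells, the scale of a
real meristem segmentation; the smaller 24 µm phantom used in most unit
tests has ≈220 cells. Everything derives from one `numpy` Generator
seed, so phantoms are voxel-identical across runs.

What the phantom does *not* emulate: segmentation errors (over/under-
segmentation, leaked membranes), anisotropic confocal point-spread,
irregular (non-spherical) dome shapes, and cell-wall curvature. Perfect
layer recovery on phantoms therefore demonstrates correctness of the
geometry, not expected accuracy on noisy real data — on real stacks
accuracy is bounded by segmentation and mesh quality.

## Numerical choices and degenerate inputs

- Strict inequalities everywhere ties matter (cone boundary outside,
  B's band inclusive as printed) — deterministic without epsilons.
- Nearest-point pruning radius: nearest-vertex distance + longest mesh
  edge + 1e-9; the result is exact, the constant only guards float
  round-off.
- Degenerate marching-cubes triangles (area ≤ 1e-12 µm²) are dropped.
- Empty OC (depth/radius missing the tissue) warns rather than errors;
  empty cell sets, non-integer TIFFs, non-3D stacks, coincident
  selection centroids and mis-ordered pipeline stages raise typed
  errors (`meristem3d.errors`).
- All outputs are written in sorted order (labels, nodes, edges) with
  `repr`-exact floats, so identical runs are bit-identical.

## Known limitations

- Layer peeling reports exactly three strata; tissues where L3 should
  be subdivided need downstream processing.
- The boundary band B is geometrically defined; biologically faithful
  boundary-zone identification requires a genetic marker and is out of
  scope.
- Interface areas are voxel-face sums and overestimate the area of
  oblique walls by up to √3 in the worst case; comparisons between
  zones remain valid since the bias is shared.
- No automatic detection of the apex or primordium peaks/saddles; the
  workflow deliberately mirrors a user-click protocol with label IDs.
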