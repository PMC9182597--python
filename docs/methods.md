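# Methods

This note documents the models, conventions and numerical choices behind
`osteoprint`, and what the synthetic phantoms do and do not establish about
behaviour on clinical data.

## Grid and mesh conventions

Volumes are scalar grids of Hounsfield units indexed `(row, column, slice)`;
voxel indices address voxel centres, and world position is
`origin + index * spacing` (mm). Slices are stored ascending along the slice
axis; orientation matrices beyond this axis-aligned convention are out of
scope, and the DICOM reader/writer pair is self-consistent within it. HU
values are carried as floats in [−1100, 32767]; DICOM pixels are written as
16-bit signed integers with slope 1 / intercept −1024 when the data fit
(lossless for the CT range), falling back to intercept 0 and finally to a
coarser slope.

Meshes are indexed triangle lists in mm with winding-defined normals.
"Watertight" means every undirected edge has exactly two incident triangles;
"outward" means positive signed volume by the divergence theorem.

## Phantoms: what they emulate

`femur_implant_phantom` places a soft-tissue block (40 HU), a cortical
capsule shell (1400 HU) around a trabecular core (300 HU), a spherical
femoral head, a cement sleeve (1000 HU) and a metal nail (8000 HU), with
membership evaluated analytically at voxel centres — no partial-volume
blending; later primitives overwrite earlier ones. Degradation is additive:
streak spokes `A·cos(count·(φ−φ0))·exp(−d/decay)` about the implant axis
(alternating sign, hence near-zero slice mean; not a physical beam-hardening
model), then clipped zero-mean Gaussian noise. Standard artifact settings
used throughout the tests: noise sd 50 HU, streak amplitude 300 HU, 10
spokes, 25 mm decay.

Because voxels are binary-valued per tissue, these phantoms *overstate*
threshold robustness (no partial-volume ramp at boundaries on the original
grid) and *understate* it after interpolation (the interpolated ramp crosses
a low threshold almost a full coarse voxel outside the true boundary when
the threshold sits near the soft-tissue end, as the bone low threshold of
150 HU does against a 40→1400 HU edge). Passing tests therefore show the
pipeline's logic and its artifact suppression are correct, not that the
specific HU presets are clinically optimal. The signed-distance-field
helpers (`sphere_distance_volume` etc.) are the complementary tool: sampling
a smooth field gives marching cubes its design-point accuracy (vertices by
linear interpolation), which is what the convergence checks measure; binary
masks instead measure the staircase-limited case.

## Enhancement chain

Order is fixed: denoise → interpolate → unsharp. Defaults: 3-D median with
radius 1 (window 3³); in-plane cubic and across-slice linear interpolation at
factor 2 (output samples are voxel-centre aligned, so coincident positions
reproduce the input exactly for nearest/linear); unsharp mask
`out = in + 0.5·(in − G(in, σ=0.5 mm))` clipped to the HU range. The
minimum-rank filter is provided alongside (antiextensive: out ≤ in) for
bright-artifact suppression. All borders use edge replication, which cannot
produce out-of-range values.

The unsharp defaults were chosen at the scale of the *upsampled* voxel
(0.5 mm) with moderate gain: sharpening with a larger kernel or unit gain
re-amplifies the low-frequency metal streaks and can undo the denoising
gain. With these defaults the full chain raises bone-mask Dice on the
standard streaked phantom from ≈0.60 (raw) to ≈0.71, which the ablation test
asserts as a strict inequality.

## Segmentation

Thresholds are closed intervals; region growing is flood fill over the
in-range voxel graph (6- or 26-connectivity, default 26) from accepted
seeds, implemented via connected-component labelling and verified in the
tests against an independent breadth-first search. Local segmentation
restricts growing to axis-aligned boxes with per-box intervals; overlaps
resolve by list order (earlier wins), mirroring operator priority. Implant
separation takes the largest connected component at/above the metal
threshold (`keep="all"` for multiple implants) and subtracts it from the
bone mask after dilation by a metric margin (default 0.5 mm, computed by
Euclidean distance transform with anisotropic sampling) to remove the
blooming halo. Preset numeric defaults are the phantom palette; they are
configuration, not measured clinical values, and users load their own preset
YAML for real data.

`average_thresholds` records mean and sample standard deviation (n−1; zero
for a single case) of the per-case lows and highs separately.

## Marching cubes

The 2⁸ corner configurations are partitioned into orbits under the group
generated by the 24 proper rotations and global inside/outside
complementation; the partition has 15 classes (cross-checked against an
independent generator-closure enumeration in the tests). Note that adding
mirror symmetry would merge two of these classes and give 14; this package
uses rotations + complementation only.

The 256-entry triangulation table is built by boundary-loop tracing rather
than by propagating hand-made canonical triangulations: on each face, viewed
from outside the cube, every maximal run of inside corners contributes a
directed segment from its exit crossing to its entry crossing. This one rule
fixes the ambiguous face (two diagonal inside corners → two segments, each
isolating one corner), is identical for the two cubes sharing any face
(hence no cracks), and gives each crossed edge exactly one incoming and one
outgoing segment, so segments chain into closed loops. Loops are reversed
(making fanned normals outward) and fanned from a root chosen so that no fan
diagonal joins two crossings of a common cube face — an exhaustive check
shows such a root always exists — which makes non-manifold edges
structurally impossible even on noisy masks. Vertices are welded by global
edge identity (bit-stable), positioned by linear interpolation of the field
along the crossed edge.

Accuracy at iso 0 of the sampled signed-distance ball (r = 10 mm): area
within 3% and enclosed volume within 1.5% of the closed forms at 0.5 mm
spacing, with monotone error decrease over spacings 1.0 / 0.5 / 0.25 mm
(asserted in the tests).

## Density adjustment

`subdivide` marks all edges above the bound globally and splits each
triangle by its marked-edge pattern (1/2/3), sharing midpoints through an
edge dictionary: conformal, geometry-preserving, terminating (each pass
halves edge lengths). `decimate` collapses edges to their midpoint, shortest
first, subject to: a link condition (no pinch), a normal-rotation bound
(`angle_tol`), and a *cumulative* chord audit — every original vertex is
tracked by exactly one surviving vertex, and a collapse is admitted only if
all points tracked by every vertex of the modified neighbourhood stay within
`chord_tol` of that vertex's post-collapse fan. The invariant is inductive,
so the final surface deviates from the original by at most `chord_tol` at
the original vertices (asserted by a global distance audit on a sphere).

## Repair

Order: debris removal → hole filling → normal unification → inclusion
removal, re-diagnosing after; the composite is idempotent. Debris removal
deduplicates triangles and *welds* degenerate slivers (area < 10⁻⁶ mm²) by
collapsing their shortest edge when it is below 10⁻³ mm — deleting slivers
would puncture closed marching-cubes output whose crossings sit arbitrarily
close to grid corners; a degenerate triangle with only long edges is kept
and merely counted. Components with fewer than 4 triangles are free debris
and removed. Hole filling walks directed boundary loops and ear-clips them
(smallest valid ear first) with winding opposite to the surrounding faces;
loops longer than `max_loop_edges` (default 100) or non-simple loops are
left open with a warning — if inverted windings at a hole rim block the loop
walk, the chain retries hole filling once after orientation unification.
Normal unification floods orientation across shared edges per component and
flips closed components to positive signed volume. Inclusion removal deletes
closed components whose representative vertex lies inside another closed
component by deterministic ray parity (fixed direction list; grazing hits
retry with the next direction). Overlapping/intersecting triangle pairs are
detected only as exact duplicates and coplanar overlaps; general
intersection surgery is not attempted.

## Splitting

Planar cuts only. Vertices within 10⁻⁹ mm of the plane are snapped onto it;
crossing triangles are clipped with intersection points shared through an
edge dictionary, so the halves stay crack-free; capping reuses the
hole-filling ear clipper on the planar openings. Both halves triangulate the
same planar polygons, and the signed-volume contribution of a planar region
is triangulation-independent, so capped volumes sum to the input volume to
floating-point accuracy (tested at 10⁻⁶ relative). Limitation: cross
sections with *nested* loops (cutting a hollow shell produces an annulus)
are not paired into polygons-with-holes; splitting is intended for the solid
parts that are actually printed.

## Metrology

Best fit is point-to-point ICP: nearest point on any triangle
(KD-tree over triangle centroids preselects 48 candidates, then exact
point–triangle projection), closed-form orthogonal update (SVD/Kabsch),
stopping when the RMS residual changes by less than `tol` (default
0.001 mm). On nearly rotation-symmetric geometry the RMS-change rule can
stall in a shallow basin; verification runs use an asymmetric solid and a
tighter internal tol, recovering random displacements (≤ 20°, ≤ 10 mm) with
post-fit RMS below 10⁻³ mm. Signed deviations are positive outside the
closed surface (ray-parity containment); ȳ is the arithmetic mean and σ the
sample standard deviation about ȳ (n−1). Open meshes yield unsigned
distances only, on request.

Surface texture: form removal subtracts a least-squares bivariate
polynomial (degree 1 or 2; residual mean exactly zero over valid samples).
The roughness surface is the input minus a Gaussian-weighted mean whose
amplitude transmission is 50% at the cutoff wavelength λc (kernel scale
α·λc, α = √(ln 2/π); for the sampled implementation σ = α·λc/√(2π) in mm).
λc defaults to 0.8 mm and is an explicit input — no automatic
sampling-length selection. End effects are handled by marking a λc/2 border
band invalid rather than padding. Amplitude parameters over valid samples:
Sq = √(mean z²), Sa = mean |z| (so Sq ≥ Sa always), Sp = max z,
Sv = |min z|, in μm. Whether σ should be taken about ȳ or about zero is a
convention; this package uses the sample standard deviation about ȳ.

## Pipeline and reproducibility

`run_procedure` executes enhance → segment (implant and cement separated
from bone, cement taking priority over the bone interval) → extract →
repair → optional split → export (STL, uncompressed NIfTI masks, JSON
reports, resolved config). All randomness flows from the single config seed;
reruns are bit-identical, and DICOM UIDs are derived from a content hash so
identical data round-trips identically while distinct series remain
distinguishable.

Problem sizes in the test-suite: the standard phantom is 80×80×36 voxels at
1×1×1.5 mm (64×64×36 for the pipeline smoke tests); repair robustness runs
100 corruption trials on ~750-triangle spheres; best-fit recovery runs 100
trials of 300 points against a ~2300-triangle box; splitting conservation
runs 50 plane/solid pairs. These sizes exercise every code path while the
whole suite stays in the minutes range.

## Known limitations

- No partial-volume or beam-hardening physics in the phantoms; artifact
  amplitudes are free parameters, not fitted to scanner data.
- Single-interval thresholds per structure; atlas/learning segmentation and
  interactive workflows are out of scope.
- Marching cubes is the classic 15-class construction with a fixed
  ambiguous-face rule, not a trilinear-topology (MC33) decider; topology of
  the *field* inside ambiguous cells is not resolved, only consistency of
  the mesh.
- Self-intersections are counted, not repaired; hole filling is planar ear
  clipping without curvature-aware patching.
- Plane-cut capping does not pair nested cross-section loops (hollow
  shells).
- Profile (2-D) texture parameters and automatic cutoff selection are not
  implemented; the areal Gaussian filter with explicit λc is the only
  texture path.
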