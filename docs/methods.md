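# Methods

This document describes the model, the numerical choices, and their known
limitations. Parameter defaults are stated with their rationale; all of
them can be overridden through the API or CLI.

## 1. Symmetry model

A surface `S` is analysed for bilateral symmetry by:

1. estimating (or accepting) a midsagittal plane `P`;
2. reflecting `S` across `P` to obtain the mirror `S'`;
3. rigidly registering `S'` onto `S` (optionally through a stable
   reference sub-surface);
4. computing, at every vertex of `S`, the signed distance to the closest
   point of the aligned mirror;
5. segmenting the deviation field at a clinical band (default ±1 mm) and
   reducing it to indices.

The **global symmetry index (GSI)** is the fraction of surface area whose
deviation lies inside the band; the **local symmetry index (LSI)** is the
same quantity restricted to a named zone. GSI = 1 means every point of the
surface has a mirror counterpart within the band.

### Plane estimation

Candidate planes are the principal planes of the area-weighted vertex
covariance; each candidate is scored by the RMS mirror distance of a fixed,
seeded, area-weighted surface sample, and the best is refined by a
symmetric ICP step (registering the mirrored sample onto the surface and
extracting the reflection plane of the resulting improper transform).

Rotationally symmetric surfaces admit infinitely many symmetry planes.
When `ambiguity_tol` is set and two candidate planes score within it, a
`DegeneratePlaneError` is raised instead of silently picking one. A sphere
with a single bump is a practical example: any plane through the bump axis
is an exact symmetry plane, so for such inputs the plane should be supplied
anatomically.

### Registration

ICP uses point-to-plane minimisation with a point-to-point (Kabsch)
fallback whenever the point-to-plane step would increase the residual, so
the recorded `rms_trace` is monotone non-increasing by construction.
Samples are fixed area-weighted surface draws from a seeded generator:
repeated runs are bit-identical.

**Bias note.** Rigid registration of a *genuinely asymmetric* surface
absorbs part of the deformity into the alignment and raises GSI slightly.
When the midsagittal plane is known exactly and the question is "how
asymmetric is the surface about this plane", compare against the
unregistered mirror (`signed_deviation(mesh, mirror_mesh(mesh, plane))`).
Registration is the right choice when the plane itself is uncertain or the
two sides were acquired in different frames.

### Reference-based registration

`register_via_reference` estimates the transform on a stable reference
sub-surface (e.g. the skull vault, which is unaffected by orbital
pathology) and propagates it to all target structures. This avoids
registering small or nearly-symmetric targets directly.

### Signed deviation

Distances are exact point-to-triangle closest-point distances (vertex
KD-tree upper bound, centroid ball query, vectorised closest-point,
global argmin — no approximation). The sign is positive where the true
surface lies *outside* the mirror along the mirror's outward surface
normal at the closest point (over-projection), negative inside
(under-projection).

### Band segmentation

The band is a closed interval: a deviation of exactly ±1 mm counts as
within. Faces are labelled by vertex majority; two-way ties resolve to
"within" (conservative toward symmetry). All indices are **area**
fractions computed from face areas, not vertex counts, so they are
insensitive to non-uniform tessellation.

## 2. Surface partitioning

Surfaces are partitioned into ~25 mm² (5 × 5 mm) grid cells:

- **planar** surfaces are tiled with exact squares of side √(target area),
  faces assigned by centroid;
- **curved** surfaces are seeded by deterministic farthest-point sampling
  (`round(area / target)` seeds) and grown area-balanced over the face
  adjacency graph, followed by a merge/split rebalancing pass (cells below
  0.5× target merge into their smallest neighbour; cells above 1.5× target
  are bisected into two connected, area-balanced halves).

Invariants: every face belongs to exactly one cell, cells are
edge-connected, and cell areas sum to the mesh area exactly (the same
face-area array is summed either way). Small fragments produced when a
square tiling cuts the triangulation are folded back by the rebalancing
pass. The partition depends on face areas and Euclidean distances only, so
it is rigid-motion invariant up to floating-point tie-breaks near cell
boundaries.

Named zones are unions of cells, assigned either by explicit seed faces or
by proximity to 3-D seed points (optionally distance-limited, leaving
far cells unlabelled).

### Zone RMS: two definitions

`zone_rms(..., mode="area_weighted")` (default) pools squared deviations
over the zone's cells with area weights and returns mm — the physically
interpretable RMS. `mode="literal"` returns the sum of per-cell RMS values
divided by the zone area, in mm/mm²; this reproduces a formula found in
clinical literature whose units cannot be the intended mm quantity, and is
provided only for comparability. Reports carry both.

## 3. CT volume segmentation

Structures are segmented by closed Hounsfield-unit windows:

| window                            | HU range      |
|-----------------------------------|---------------|
| `orbital_fat`                     | [−200, 15]    |
| `extraocular_muscles_optic_nerve` | [−30, 205]    |
| `lacrimal_gland`                  | [−700, 200]   |
| `total_orbital_volume`            | [−700, 225]   |
| `periorbital_soft_tissue`         | [−700, 225]   |

Bounds are inclusive so boundary voxels are deterministic. Volumes are
voxel counts × voxel volume (cm³). Surfaces are extracted by marching
cubes on a Gaussian-smoothed (σ = 1 voxel) copy of the binary mask: the
raw binary staircase overestimates the area of a sphere by ~10%, while the
smoothed isosurface converges with resolution. If a feature is so small
that smoothing pulls the field below the iso level, extraction falls back
to the raw binary isosurface. Set `smooth_sigma=0` to disable smoothing.

## 4. Phantoms and ground truth

The phantom generator produces surfaces whose symmetry properties are
known in closed form:

- base shapes (`sphere`, `orbit_like`, `hemisphere_pair`, `flat_sheet`)
  are *exactly* mirror-symmetric in IEEE floating point: vertices are
  constructed so that negating x maps the vertex set onto itself
  bit-for-bit;
- cosine-tapered bumps displace the surface radially by
  `A/2 · (1 + cos(π g / R))` inside geodesic radius `R`. The radius where
  the displacement crosses a band half-width `b` is
  `R/π · arccos(2b/A − 1)`, giving an analytic asymmetric footprint
  (bump cap plus its mirror ghost). `solve_bump_radius` inverts the
  footprint fraction, so phantoms can be built to a target expected GSI;
- bumps with amplitude below the band half-width have zero footprint and
  expected GSI exactly 1;
- optional rigid perturbations and Gaussian vertex noise are recorded in
  the ground truth;
- `make_phantom_volume` builds a CT volume (background −1000 HU, fat −100,
  muscle 60, bone 700; clinical spacing 0.4 × 0.4 × 0.6 mm) with exact
  per-class masks and analytic sphere volumes;
- `make_cohort` draws per-subject hard/soft-tissue GSI values and converts
  them to bump specifications, returning both renderable specs and an
  analytic expected table.

`expected_bump_rms` uses a flat-patch closed form for the mean-square
displacement of a cosine bump. It overestimates the measured
closest-point RMS by ~35–40% because the nearest mirrored point along the
taper is closer than the radial gap. It is used only to couple GSI and RMS
in the cohort generator (only the sign of their relationship matters
there); treat it as an upper bound, not a calibration.

## 5. Statistics

`cohort_stats` delegates to scipy: Shapiro–Wilk normality (`normality_test`),
Student/paired t, Wilcoxon rank-sum/signed-rank, one-way ANOVA with Tukey
HSD post-hoc, Kruskal–Wallis with Holm-corrected pairwise rank-sum
post-hoc, and Pearson correlation with pairwise-complete correlation
matrices. `parametric="auto"` switches to the non-parametric test when
Shapiro–Wilk rejects normality at α = 0.05 in any group. Test choices and
directions are recorded in every result.

## 6. Defaults

| parameter           | default       | rationale                              |
|---------------------|---------------|----------------------------------------|
| band                | ±1.0 mm       | clinical threshold for relevant asymmetry |
| cell area           | 25 mm²        | 5 × 5 mm grid used in regional reporting |
| ICP samples         | 10 000        | < 0.1° / 0.05 mm recovery at ~1 s      |
| ICP tolerance       | 1e-6 mm       | below measurement noise                 |
| smoothing sigma     | 1 voxel       | removes staircase bias, preserves 3-voxel features |
| phantom radius      | 40 mm         | skull-scale                             |
| phantom subdivisions| 6 (~33k faces)| ~0.6 mm edge length at 40 mm radius     |

## 7. Limitations

- Rigid registration cannot separate true asymmetry from misalignment;
  see the bias note above.
- GSI quantises at the scale of a triangle: footprint recovery on the
  default phantom is accurate to ~0.01.
- The grid partition of a curved surface is not unique; only its
  invariants (coverage, connectivity, area balance, area conservation) are
  guaranteed, not the exact cell shapes.
- Volume measurements are voxel-counting: accuracy is limited by
  partial-volume effects at the stated spacing (~1.5% for a 5 mm-radius
  sphere).
- Statistical helpers assume independent subjects; no mixed-effects
  modelling is provided.
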