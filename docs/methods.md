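# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `condylometry`. It is written for a reader who wants
to know *why* the package behaves the way it does, not just what it
computes.

## Measurement model

The quantity of interest is the mineralized bone volume of the
mandibular condyle within a standardized region, at two time points, on
a common isotropic grid. Three observer-dependent steps determine it:
the bone threshold, the rigid alignment of the two scans, and the
placement of the condylar volume of interest (VOI). The package
automates all three and quantifies the residual variability of each.

### Working resolution

Volumes are resliced to isotropic voxels (default **0.4 mm**, matching
the native resolution of typical cone-beam CT protocols for the
temporomandibular joint) with trilinear interpolation; masks, when
resampled, use nearest-neighbour. The grid size is `ceil(extent / t)`
per axis, world extent preserved within one voxel. All coordinates are
world millimetres with `world = origin + index · spacing` and identity
axis directions after reading (oblique acquisitions are resampled onto
an axis-aligned grid at load time).

### Segmentation

Mineralized bone is `intensity ≥ T` for one global threshold `T`.
The automatic suggestion restricts the histogram to intensities
strictly above the volume median — discarding the air/soft-tissue bulk
that would otherwise dominate a two-class criterion — and takes the
maximal between-class-variance (Otsu) split of 256 bins; exact ties
(empty bins between well-separated classes) resolve to the lowest
threshold. The suggestion is deterministic and can be overridden, which
is also how observer variability in thresholding is modelled in the
reproducibility tools. No morphological clean-up is applied: internal
trabecular gaps are part of the mineralized-volume definition. The
largest 26-connected component isolates the mandible from other bone in
the field of view.

Two surface representations serve different purposes:

* `mask_to_mesh` — marching cubes at 0.5 on the binary mask. Its
  enclosed volume matches the voxel count (within ~5% at 0.4 mm), so it
  is the volume-faithful cross-check. Its vertices, however, sit at
  voxel-edge midpoints: a half-voxel quantization.
* `threshold_isosurface` — marching cubes on the grayscale volume at
  the applied threshold, restricted to the mandible component's
  neighbourhood. Vertices interpolate the intensity field and localize
  the thresholded boundary with sub-voxel accuracy. This is the surface
  used for registration, VOI geometry and part-comparison. The
  restriction cannot cut the isosurface because the component is by
  construction bounded by sub-threshold voxels.

Using the binary mesh for registration was tried first and abandoned:
between two independently voxelized renderings of the same anatomy its
quantization floor limits rigid-pose recovery to roughly 0.3 mm, an
order of magnitude worse than the grayscale isosurface.

### Registration

The postoperative frame is fixed; the preoperative surface moves.

1. **Landmark initialization.** Least-squares rigid fit (Kabsch:
   centroid demeaning, cross-covariance SVD, determinant correction) of
   at least three matched, non-collinear anatomical landmarks, by
   convention named `coronoid`, `ramus`, `angle`, `condyle`.
2. **Region restriction.** ICP sees only vertices within 15 mm of a
   landmark and below the sigmoid-notch level. The condylar head — the
   structure expected to change — cannot drive the fit; the mandibular
   body and symphysis — altered by the osteotomy — are outside the
   landmark balls.
3. **ICP refinement.** Correspondences are *exact closest points on the
   fixed surface* (closest point of the nearest triangle via a
   KD-tree-pruned, certificate-checked search), not nearest vertices:
   nearest-vertex matching between two differently-voxelized surfaces
   carries a bias of a substantial fraction of a voxel. Pairs beyond 5×
   the median distance are rejected per iteration (robustness to
   residual geometry changes). The rigid update minimizes the
   **point-to-plane** residual (linearized 6-dof least squares with a
   Rodrigues retraction). Point-to-point (Kabsch) updates are available
   (`metric="point_to_point"`) but converge into a shallow
   tangential-sliding valley on plate-like anatomy — measured on the
   phantom they stall at ~0.2–0.4° / 0.2–0.4 mm, whereas point-to-plane
   reaches ~0.03–0.05° / 0.03 mm. Iteration stops when the
   point-to-point RMS improves by < 1e-4 mm or after 100 iterations; an
   update that would worsen the RMS is reverted, making the reported
   RMS history non-increasing by construction.

Registration accuracy is reported at the object: rotation magnitude plus
the mean displacement of anatomy-anchored probe points. The raw
translation-vector norm conflates rotation error with the lever arm of
the world origin and is not a meaningful accuracy number.

### Condylar sphere VOI

The condyle is isolated by the smallest sphere that encloses the whole
condylar head while its boundary passes through the lowest point of the
sigmoid notch — a fully automatic construction replacing manual sphere
centring (a manual center override is retained as an observer-choice
parameter).

* **Notch point.** Among mesh vertices whose projection onto the
  coronoid→condyle axis falls in the interior 20–80% band *and* whose
  smoothed vertex normal points upward (cosine ≥ 0.5 with the superior
  axis), the vertex with minimal superior coordinate is returned, ties
  to the lowest index. The normal filter is required on a closed
  mandible mesh: without it the band also contains the inferior
  mandible border and the vertical ramus walls (including rare
  staircase vertices whose raw normals point diagonally — hence the
  1-ring normal smoothing). Along a shallow notch groove the exact
  antero-posterior position of the minimum is weakly identified; the
  meaningful error measure is the distance to the groove surface, which
  the phantom harness reports.
* **Condyle vertex set.** The mesh is cut by the plane through the
  notch point normal to the superior axis and the connected component
  containing the condylar-head landmark is kept. The pipeline raises
  the cutting plane by one voxel: on voxelized surfaces, slivers of the
  notch groove just above the exact notch level can bridge the condyle
  to the coronoid side and collapse the separation.
* **Sphere fit.** With the boundary pinned at notch point *n*, a sphere
  with center direction *u* needs radius
  `r(u) = max_v ‖v−n‖² / (2 u·(v−n))`; `r(u)` is minimized over the
  unit sphere (two angles) by multi-start Nelder–Mead (starts: head
  landmark direction, condyle centroid direction, superior axis).
  Enclosure is verified to 1e-4 mm and the boundary-through-notch
  invariant to 1e-6 mm at construction.
* **Shared sphere.** The sphere is fitted once per side per case — on
  the *preoperative* surface — and rigidly transferred. Fitting on the
  preoperative frame matters: under resorption the postoperative
  condyle is a subset of the preoperative one, so a minimal sphere
  fitted postoperatively clips the preoperative head at its binding
  contact points and systematically under-counts the loss (~3
  percentage points on the 20%-loss phantom). The preoperative sphere
  contains both condyles by construction. Radius is untouched by the
  transfer, so VOI placement cannot generate a volume difference.

### Quantification

`mask_volume` = foreground count × voxel volume (exact integer count;
isotropy required). `mesh_volume` (signed-tetrahedron divergence
theorem, cavities wound oppositely subtract) cross-checks it on closed
meshes. Percent change is referenced to the preoperative volume; cohort
summaries report per-side and pooled mean ± sample (n−1) SD, loss/gain
counts, and per-patient left–right asymmetry.

### Validation metrics

* **Part-comparison:** for every vertex of the query model (all sheets,
  interior included), the exact unsigned shortest distance to the
  reference surface. The spatial index prunes candidate triangles with
  a KD-tree over centroids and escalates the candidate count until the
  best exact distance is provably global (missed triangles would need a
  centroid farther than the k-th candidate minus the largest triangle
  circumradius). Distances are unsigned; over/under-estimation is
  carried by the sign of the volume difference. The colour-map cutoff
  defaults to 0.375 mm, just under one working voxel.
* **Distance-to-curve:** open-boundary edges of a sphere-cropped mesh
  are chained into polylines; the lower border is the polyline with the
  lowest mean superior coordinate; point-to-segment distances from
  border A to border B quantify VOI-selection discrepancy
  (asymmetric; direction recorded).
* **VOI-mismatch subtraction:** both masks restricted to the
  intersection of the two spheres, after which part-comparison measures
  threshold discrepancy only.
* **Gold-standard accuracy:** the test mask is meshed, mapped by an
  externally supplied rigid transform onto the gold frame, and compared
  test→gold; the volume excess (test − gold) signs the over- or
  underestimation. Intensity-based (mutual-information) registration to
  the gold standard is out of scope; the transform is an input.

### Reliability statistics

The ICC is the two-way mixed-effects, single-measures, *consistency*
form ICC(3,1) = `(MS_rows − MS_err) / (MS_rows + (k−1) MS_err)` from
the subjects × raters ANOVA without replication — insensitive to a
fixed rater offset, which is the appropriate convention when the raters
are the only raters of interest. Absolute agreement ICC(2,1) is
available behind a flag. Qualitative labels follow the
good (> 0.6) / excellent (> 0.9) convention.

Paired-design sample size iterates n from 2 upward and returns the
first n whose two-sided paired *t* power — computed exactly from the
noncentral *t* distribution with noncentrality `d·√n` and `n−1` degrees
of freedom — reaches the target; no normal approximation. A one-sided
flag exists. Note the n = 2 floor is reachable only for very large
effects: with one degree of freedom, power is capped at
`P(χ₁ < d√2 / t_crit)`, e.g. 0.73 at d = 10.

For the design inputs d = 105/90, α = 0.05 two-sided and target power
0.95, the exact iteration yields **n = 12** (power 0.9354 at n = 11,
0.9563 at n = 12); this is cross-checked in the tests against an
independent continuous-power solver and a 200k-replicate simulation.

## The phantom

The generator produces a stylized left hemi-mandible: a ramus plate
(10 × 40 × 46 mm) carrying a coronoid cone, a circular-carve sigmoid
notch (lowest point 42 mm up), a condylar neck cylinder and an
ellipsoidal condylar head (semi-axes 10 × 9 × 8 mm, sized so the fitted
VOI sphere lands in the anatomically reported 14–19 mm radius band),
inside a soft-tissue ellipsoid, plus a small detached bone speck that
exercises component extraction. Contrast is air 0 / soft tissue 150 /
trabecular 600 / cortical 1200 (arbitrary CT units); the 1.5 mm
cortical shell is the morphological boundary layer of the mineralized
solid. Acquisition is modelled as partial-volume sampling (see below),
additive Gaussian noise of SD 80 *before* a Gaussian PSF of σ 0.3 mm
(≈ 0.7 mm FWHM — reconstructed CT noise is correlated at the
resolution scale; voxel-independent noise after the blur would punch
unphysical holes through trabecular bone), at 0.4 mm voxels. A finer
spacing option emulates an ex-vivo high-resolution scan of the condylar
region.

Between "pre" and "post" the head semi-axes shrink by the resorption
depth (default 1.0 mm ⇒ ≈ 19% condylar loss; `calibrate_resorption_depth`
bisects the depth for any target loss) and the whole object moves by a
rigid pose delta (default 5° about the superior axis + 2 mm). The post
volume is re-rendered in its own frame — not resampled from the pre
volume — so the pair carries genuinely independent voxelizations, as
two scans would.

**Partial-volume rendering.** Labels are center-in-solid binary, but
intensities come from signed-distance-derived occupancy fractions of
boundary voxels (linear over one voxel). This matches the physics of CT
partial-volume averaging and is essential for geometric fidelity: pure
binary rasterization quantizes flat faces that align with the sampling
lattice by half a voxel, which injected a spurious 0.19 mm offset
between the axis-aligned pre and the rotated post rendering —
registration error unrelated to the method under test. With
partial-volume rendering and an air background, the intensity-600
contour coincides exactly with the label grid, which the tests exploit
for voxel-exact checks.

**Ground truth.** The truth condylar region is the pinned minimal
sphere fitted to the mineralized label voxels above the notch plane
(component of the head center), with the analytic notch point as pin;
truth volumes are integer label counts inside it (pre frame and the
rigidly posed post frame).

### What the phantom does and does not establish

The phantom has ideal landmarks (known up to injected jitter of 0.5 mm
SD), simple convex-ish geometry, uniform tissue intensities, a
shift-invariant Gaussian PSF and stationary noise. It contains no metal
or motion artefacts, no beam hardening, no genuine trabecular
micro-architecture, no intensity calibration differences between
scanner types, and its resorption is a uniform semi-axis reduction
rather than the patchy cortical demineralization seen clinically.
Passing the phantom suite therefore demonstrates the *numerical and
geometric* correctness of the pipeline — threshold behaviour, exact
metric computations, pose recovery, VOI invariance, volume arithmetic —
under realistic resolution, blur and noise. It does not certify
clinical accuracy on patient scans, where artefact handling and
scanner-dependent thresholds dominate.

Known residual biases, measured on the phantom at 0.4 mm: segmentation
overestimates thin-boundary volume by ~4–5% (partial volume; analogous
to the sub-voxel overestimation the gold-standard comparison is
designed to detect), which dilutes relative changes by ~1–2 percentage
points at a 20% loss; a null-change pair shows a ~0.7% apparent change
driven by sampling-phase differences between the axis-aligned and
rotated grids. Both are inherent to sampled imaging at this resolution,
not implementation artefacts, and both sit well inside the acceptance
bands (±3 pp; < 1%).

## Problem sizes and runtimes

Default test/acceptance problem sizes were chosen so the full suite
runs in a few minutes on one core: phantom grids of ~1.9M voxels
(70 × 140 × 195 at 0.4 mm), meshes of ~2–4 × 10⁵ triangles, ICP capped
at 20k region vertices (deterministic stride subsampling), ten noise
seeds per end-to-end criterion, and 0.1 mm renderings only for cropped
condylar regions. Multi-resolution truth consistency is checked at
0.4 mm vs 0.1 mm (< 2% voxelization difference).

## Numerical conventions

* Thresholding is inclusive (≥); voxel-in-sphere is inclusive (≤).
* Notch ties break to the lowest vertex index; Otsu plateau ties to the
  lowest threshold.
* Rotations are validated orthonormal (det +1, 1e-8); sphere invariants
  are asserted at construction (1e-6 mm).
* Sample SD (n−1) throughout; SD of a singleton reports 0 with an
  explicit flag.
* STL round-trips weld vertices on exact (float32) coordinate equality
  and drop degenerate triangles.
* All stochastic elements (phantom noise, landmark jitter) derive from
  a single integer seed; identical seeds give bit-identical volumes and
  reports.
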