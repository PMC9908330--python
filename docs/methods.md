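# Methods

`rssm` builds linear statistical shape models (SSMs) of a bone surface from
a cohort of triangulated meshes, both globally and per surface region, and
compares the two model families. This note describes the models, the
synthetic validation cohort, the numerical choices, and the limits of what
the tests establish.

## The shape model

Given `n` corresponded, rigidly aligned surfaces with `V` shared vertices,
each surface is the flattened coordinate vector `x ∈ R^{3V}` (mm). The
model is the PCA form

    x = x̄ + Σᵢ wᵢ Φᵢ ,

with `x̄` the per-coordinate mean, `Φᵢ` orthonormal modes, and `λᵢ` the
variance of the training weights along mode `i` (1/(n−1) convention, so
`±2√λᵢ` has its usual "±2 SD" meaning). At most `n − 1` modes exist.
Eigenpairs come from the `n × n` Gram (dual) eigenproblem, which is exact
and keeps memory linear in `V`; a dense-covariance eigendecomposition
serves as an independent oracle in the tests. Mode signs are fixed by
making each column's largest-magnitude entry positive, because PCA signs
are otherwise arbitrary and would break bit-reproducibility.

The *region-based* model (rSSM) fits one independent SSM per surface
region of a curvature-derived vertex partition; the *nonregion-based*
model (nrSSM) is the single whole-surface fit. For cross-model comparison
the regional modes are pooled across regions and sorted by variance; the
pooled cumulative-variance curve is normalised by the pooled total. The
pooling rule is this package's convention — nothing canonical forces it —
and is therefore isolated in `cumulative_variance` where it can be swapped.
A regional ±kSD shape perturbs one region's mode while every other region
stays at its mean; region boundaries are not blended (an explicit
modelling choice: blending would mix regional models and obscure the
independence the rSSM is meant to provide).

## Registration and alignment

Pairwise registration is rigid coherent point drift (CPD): the source
cloud is the centroid set of an isotropic Gaussian mixture fit to the
target by EM, with the closed-form rigid update from an SVD of the
weighted cross-covariance. Defaults: `max_iter 100`, objective tolerance
`1e−6`, outlier weight 0, uniform mixture weights. There is deliberately
no scaling anywhere in the pipeline (CPD and the Procrustes steps are
rotation + translation only) so that overall size remains in the data and
can appear in the first principal component.

Two performance details matter at desk scale and do not change the fixed
point the EM converges to:

* when `N·M > 120 000` the coarse annealing phase (σ still larger than
  the point spacing) runs on a deterministic strided subsample of both
  clouds, and the full-resolution EM is warm-started from its pose;
* once σ falls below half the target's median point spacing, the E-step
  truncates to the 48 nearest centroids per point (KD-tree); beyond that
  radius responsibilities are zero to float precision.

The template subject is the mesh minimising the mean post-registration
RMS nearest-point distance to all others (ties to the lowest index); the
observed minimum is reported, not thresholded. Dense correspondence maps
the template onto each subject by rigid CPD followed by projection of
every template vertex to the closest point on the subject's surface
(exhaustive vectorised point-to-triangle projection). Cohorts that already
share connectivity — every synthetic cohort — may use identity
correspondence instead (`identity_correspondence`, default on). The cohort
is then aligned by rigid-only generalized Procrustes analysis: align each
mesh to the running consensus, re-estimate the consensus, stop when it
moves < `1e−8` mm RMS; the sum of squared deviations is non-increasing.

## Curvature and regions

Gaussian curvature is discretised by the angle deficit over the mixed
(Voronoi with obtuse fallback) vertex area. The discrete Gauss–Bonnet
identity `Σ κᵢAᵢ = 2πχ` holds exactly by construction for closed meshes
and is asserted at `1e−6` relative in the tests; the analytic sphere and
the 1/s² scaling law bound the pointwise error. Boundary vertices of open
meshes use a π deficit.

The partition is the concave/convex split: the curvature field is smoothed
by 3 rounds of area-weighted one-ring averaging (raw discrete curvature is
sign-noisy), vertices with positive smoothed curvature form region 1 and
the rest region 0 (κ = 0 ties go to region 0), and connected components
smaller than 1% of the vertices are absorbed into the surrounding label.
Two regions is the default configuration — the sign split produces
exactly two label classes; a single-sign surface degrades to one region
with a warning rather than failing. Labels are
computed once on the template and copied positionally to every subject —
well-defined exactly because of correspondence.

## The synthetic cohort

No real CT cohort ships with the package, so validation uses a generative
stand-in whose ground truth is known. The template is a closed genus-0
tube along `z` (distal = +z): 45 mm long, base radius 7 mm tapering to
4 mm at mid-shaft and widening to 6 mm at the distal head (PCHIP radius
profile), cross-sections flattened to 0.85 ellipticity, rounded by two
2.5 mm apex caps. The ellipticity matters: on a perfect surface of
revolution an axial twist would slide the surface onto itself and be
invisible to any correspondence built from geometry alone.

Four independent latent modes deform the template, applied in the fixed
order width → torsion → bending → size on template coordinates:

| mode    | action                                                     | default SD |
|---------|------------------------------------------------------------|-----------|
| size    | global scaling by `exp(w)`                                 | 0.05      |
| width   | radial scaling about the long axis by `1 + w`              | 0.08      |
| torsion | axial twist ramping 0 → `w` from mid-shaft to distal tip   | 5°        |
| bending | rigid rotation of the distal half about the mid-shaft `x` axis | 4°    |

Weights are zero-mean normal. The SDs were fixed once, at design time,
from measured per-unit-weight displacement norms on the template
(26.8 mm, 4.6 mm, 0.033 mm/°, 0.172 mm/° respectively) so that the four
modes have clearly separated displacement variances in the order
size > bending > width > torsion, with ≥ 1.8× rms separation between
neighbours. Separated variances are what make the modes identifiable by
PCA at cohort sizes of a few hundred; the magnitudes themselves (≈5% size
variation, ≈8% width variation, single-digit-degree twist and bend) are in
the range one expects of healthy inter-subject long-bone variation. On
top of the latent shape, each subject gets isotropic vertex noise
(default SD 0.05 mm, the order of a CT segmentation error) and a random
rigid misalignment (rotation SD 5°, translation SD 5 mm) whose transform
is recorded as ground truth. The default cohort has 31 subjects.

What the generator does *not* emulate: anatomically exact metacarpal
geometry (articular facets, cortical detail), correlated or non-Gaussian
mode weights, spatially correlated segmentation error, remeshing
differences between subjects (all synthetic subjects share connectivity).
Passing tests therefore demonstrate that the pipeline recovers structure
of this linear-mode, shared-topology kind; they do not certify performance
on real segmentations, where correspondence itself is the hard part.

## Numerical and degenerate-input choices

* PCA modes with eigenvalue below `1e−12 ×` trace are reported with
  `λ = 0` and deterministically completed to an orthonormal basis, so a
  cohort of identical meshes still yields a valid (all-zero-variance)
  model.
* `±kSD` synthesis on a zero-variance mode returns the mean with a
  warning instead of failing.
* CPD refuses collinear/coincident clouds (`DegenerateInputError`);
  non-convergence at `max_iter` returns the current estimate with a
  warning flag.
* STL input (no shared-vertex indexing) is merged by exact coordinate
  equality, not tolerance, so round-trips are deterministic; PLY output
  stores float64 and round-trips bit-exactly.
* All randomness flows from explicit integer seeds; a pipeline run writes
  a byte-identical report when repeated (timings go to the log, not the
  report).

## Problem sizes

Default template resolution is 24 rings × 16 vertices (386 vertices,
768 faces) — enough that the curvature bands and the four modes are
well-resolved while the all-pairs template search (n(n−1) CPD runs) and
the full pipeline stay in the minutes range on one core. Mode-recovery
checks use cohorts of 200; the Monte-Carlo sampler check uses 2000.

## Known limitations

* Correspondence by closest-point projection after rigid CPD is the
  simplest dense scheme consistent with a rigid-only pipeline; it cannot
  slide around large non-rigid differences and would alias a twist on a
  rotationally symmetric shape. Non-rigid CPD is out of scope.
* The two-region partition is the only configuration exercised end to
  end; more regions would need a different labeling rule than the sign
  split.
* The rSSM pooled-variance curve depends on the pooling convention above;
  comparisons against other implementations should state theirs.
* No hypothesis testing on mode weights is provided.
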