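# Methods

This document describes the models and algorithms implemented in `oartsim`
and the reasoning behind the main design choices. Notation: t1 is the moment
the plan is adapted to the imaged anatomy, t2 the verification moment just
before delivery, and the adaptation time is t2 − t1 in minutes.

## 1. Phantom generation (`oartsim.phantom`)

Each treatment **series** (one simulated patient course) draws, per fraction:

- a start-of-session bladder volume V1 ~ Normal around the series baseline,
  digitized as an axis-aligned ellipsoid with fixed axis ratios; the radii
  are solved so the voxelized volume matches V1 to < 2%;
- a linear filling rate r (mL/min), so V(t) = V1 + r·t;
- an adaptation time t2 from a lognormal (median 18.8 min, log-sd 0.27)
  truncated to [8.6, 33.3] min;
- a small interfraction jitter of the bladder center.

The **CTV** is a spherical-cap patch of the bladder wall (wall thickness
5 mm), taken as the principal connected component of the cap/wall
intersection; its size is set by a patch fraction of the wall surface. The
**PTV** is the CTV expanded by the planning margin (5 mm by default).

Between t1 and t2 the bladder both scales (volume from V1 to V2 = V1 + r·t2,
radii scaling with the cube root) and drifts (a dorsal translation at a
per-series rate). The per-point displacement of this motion is available in
closed form, which provides a ground-truth displacement field to validate
the registration-free deformation model below.

The **default cohort** has 9 series: 5 "time-sensitive" (smaller bladders,
90–140 mL, fast dorsal drift) and 4 "time-insensitive" (larger bladders,
200–310 mL, slow drift). This mirrors the clinical observation that small,
fast-filling bladders are the ones whose coverage degrades with adaptation
time.

## 2. Voxel geometry with subvoxel margins (`oartsim.geometry`)

Margin operations (contract/expand) are based on the Euclidean distance
transform (EDT), but the raw voxel-center EDT localizes the structure
interface only to the voxel grid, which biases contracted volumes high and
expanded volumes low by ~0.2–0.25·spacing of effective margin. We therefore
estimate a **subvoxel interface offset** per boundary voxel: the indicator
function is Gaussian-smoothed at σ = 1 and 1.5 voxels, each smoothed field φ
gives a signed offset (φ − 0.5)/|∇φ| to the 0.5-level set, and the two are
Richardson-extrapolated in σ² to cancel the leading curvature bias. Each
voxel's EDT distance is then corrected by the offset stored at its nearest
opposite-side voxel. Contraction keeps voxels whose corrected interior depth
exceeds the margin; expansion keeps voxels within the corrected exterior
distance. The two are exact duals (contracting a mask equals expanding its
complement), and margin sweeps preserve exact nesting by construction.

The corrected interface localization is better than spacing/6, which bounds
the relative volume error of a sphere of radius r by roughly spacing/(2r) —
the bound asserted in the unit tests. Structure comparison uses Dice overlap
and the directed Hausdorff distance between surface voxel sets, optionally
restricted to a local region and/or to surface normals facing a given
direction. The **adjusted local Hausdorff** subtracts the equivalent-sphere
radius increase between two bladder volumes from the local wall-to-wall
Hausdorff near the CTV, so isotropic filling scores ≈ 0 and only local
deformation remains.

## 3. Deformation model (`oartsim.deformation`)

**Surface correspondence.** For a star-shaped structure pair (checked
explicitly; a nearest-surface-point fallback with a warning handles
non-star-shaped inputs) the wall at t1 is mapped to the wall at t2 radially
about the common centroid, per direction. Optional steering pairs (e.g. the
CTV at t1/t2) pin substructures: their own correspondence is blended into
the field with inverse-square weights in the radial excess. Displacements
decay linearly to zero over a 10 mm band outside the structure.

**Time scaling.** For linearly growing volume V(t), wall displacement scales
with the cube root of volume, giving

    K(t) = (V(t)^1/3 − V1^1/3) / (V2^1/3 − V1^1/3),

with K(0) = 0 and K(t2) = 1 exactly. Because the cube root of a linear
function is concave, K(t) lies strictly *above* the linear time ratio
(t − t1)/(t2 − t1) for V2 > V1: the wall moves fastest early, when the
bladder is smallest. For V2 ≈ V1 the model degenerates and falls back to the
linear ratio with a warning. The anatomy at intermediate time t is the t1
anatomy propagated through the K(t)-scaled t1→t2 field.

**Propagation and composition.** Masks are propagated by moving their voxel
centers and re-rasterizing (round to nearest, morphological closing, hole
fill). Fields compose as x ↦ x + f1(x) + f2(x + f1(x)).

## 4. Dosimetry (`oartsim.dosimetry`)

The adapted dose is synthetic and conformal: full prescription inside the
PTV, Gaussian penumbra (σ = 4 mm) outside, as a function of distance to the
PTV. Coverage is summarized by the generalized equivalent uniform dose

    gEUD_a = (mean_i d_i^a)^(1/a),   a = −20,

computed in log space with `logsumexp` so extreme dynamic ranges cannot
overflow; a voxel with zero dose sends gEUD to 0 for a < 0 (with a warning).
nEUD is gEUD divided by the prescribed dose. For per-fraction analysis the
CTV is represented by its voxel-center material points displaced by the
K-scaled field and the dose is sampled trilinearly at the displaced points —
equivalent to re-rasterizing but exact per material point. Accumulation
warps each fraction's dose contribution onto the reference anatomy
(composition of inter- and intrafraction correspondences) and sums over
fractions; accumulated nEUD is normalized by the summed prescription.

## 5. Statistics (`oartsim.stats`)

- **Rank-scaled ANCOVA.** Per-fraction t2 nEUDs are rank-transformed within
  series to [0, 1] and regressed on adaptation time with series intercepts;
  a series-by-time interaction F-test quantifies slope heterogeneity. The
  rank transform stabilizes variance when nEUD saturates near 0 or 1, but it
  also removes amplitude, so **sensitivity labels** (time-sensitive =
  steeper-than-common slope) are taken from a second ANCOVA on the raw nEUD
  values.
- **Repeated-measures slopes** for interfraction (per-series) and
  intrafraction (per-fraction, across model times) trends, with a
  heteroscedasticity-weighted refit.
- **Percentile CIs** from order statistics (binomial method), widened to the
  sample range with a warning at extreme percentiles/small n. Model
  evaluation times are the cohort tercile medians of the adaptation-time
  draws.
- **Logistic time/margin model.** P(accumulated nEUD < 0.95) is modeled as
  logit = β0 + β_t·time + β_m·margin. The **margin compensation** for an
  extra Δt minutes is Δm = −(β_t/β_m)·Δt, with a delta-method SE from the
  coefficient covariance. Because the coefficient ratio is heavy-tailed, the
  SE is validated against the central 68.27% half-width of a parametric
  bootstrap rather than the bootstrap SD. **Maximum safe time** per margin
  is found by bisection on the upper confidence limit of the predicted
  exceedance probability.
- Group contrasts (bladder volume, t2 nEUD by sensitivity class) use
  Kruskal–Wallis; correlations use Spearman with Fisher CIs.

## 6. Pipeline and outputs (`oartsim.pipeline`)

`run_experiment` generates each series on a per-series grid, computes
per-fraction nEUD at t1, a fixed 10-min model time, the per-fraction t2 and
the cohort tercile times, then accumulates dose over a PTV-margin sweep
(2–13 mm) at the model times (and/or the clinical t2). Evaluation masks for
margin m are the reference PTV contracted by m, so they are exactly nested;
the accumulated table records each mask's voxel count (`n_voxels`), which
makes the volume-corrected monotonicity inequality for the order-(−20) power
mean checkable downstream. Reports include trend fits, tercile times, group
tests, the logistic fit with margin compensation and safe times, and
CSV/JSON/SVG artifacts. All randomness flows from a single base seed through
fixed per-series offsets, and regeneration of the report from the saved
tables is byte-identical.
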