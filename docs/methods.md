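# Methods

## Scanner forward model and calibration

A synthetic scan is generated as `HU = k·ρ + c` on bone and phantom
voxels, where ρ is true density in mgHA/cm³, with defaults k = 1 HU per
mgHA/cm³ and c = 0.  Soft tissue fills the body outline at 40 HU and air
sits at −1000 HU outside it — typical CT values, both far below the
bone window.  The affine form is the point: the two-point phantom
calibration `BMD = 200·HUt/(HUb − HUw)` inverts it exactly, so with zero
noise and zero blur the calibrated map equals the ground-truth density
voxel for voxel (the round-trip test asserts ≤ 1e-6), and miscalibration
can be injected by changing k, c.

The calibration equation is implemented verbatim.  As printed it does not
subtract HUw from the tissue value, so when HUw ≠ 0 the line is anchored
at the origin rather than interpolating through the water point.  Both
behaviours are supported — `water_correct=True` computes
`200·(HUt − HUw)/(HUb − HUw)` — but the verbatim form stays the default
and is never silently substituted.  Phantom cylinders are read as the
mean HU over a centred ROI at 70 % of the cylinder radius, pooled across
all phantom-bearing slices; the margin avoids partial-volume edge voxels.
A least-squares mode (density on HU over all three cylinders, OLS) is
available for robustness studies.

## Synthetic tibia geometry and density

The diaphysis is modelled as a constant elliptic annulus along the shaft:
outer semi-axes 4.2 × 3.4 mm, cortical thickness 1.3 mm (jittered per bone
by ±8 % to vary the medullary fraction), on a 128×128 grid at 0.25 mm
in-plane pixels and 1 mm slices over a 110 mm bone.  Densities:

| parameter | default | why |
| --- | --- | --- |
| cortical mean (between-bone SD) | 900 (80) mgHA/cm³ | mid-range of reported hen cortical QCT values |
| medullary mean (SD) | 300 (30) mgHA/cm³ | low-density woven bone, inside the 200–2000 window |
| azimuthal modulation | amplitude 0.12 ± 0.05 (per bone), random phase | gives the ROI search a genuinely inhomogeneous cortex |
| radial gradient | ±8 % inner→outer | denser periosteal side |
| regional multipliers | 0.972 / 1.028 / 1.000 (proximal / medial / distal thirds) | midshaft densest, proximal weakest — the regional ordering seen in laying hens |
| HU noise SD | 15 HU | realistic quantum noise for an ex-vivo protocol |
| partial-volume blur | Gaussian σ = 0.6 px in-plane | edge mixing between bone, soft tissue and marrow |

The per-bone azimuthal amplitude is the lever that separates the methods:
M1's max-density ROI lands on the azimuthal peak, so its reading is
`cortical·(1 + amplitude + radial)` — a quantity with extra between-bone
variance that is not shared with the whole-bone mean.  M2's reading is
essentially the bone-mask mean.  This reproduces, structurally rather
than by tuning, the observed signature: strong correlation between
methods, M1 always above M2, proportional bias (Deming slope < 1), and
weaker trait associations for M1.

What the generator does **not** emulate: X-ray projection physics (no
sinograms, beam hardening or reconstruction artifacts), anatomically
curved or flared tibiae, trabecular microarchitecture, or operator
variability beyond sub-pixel ROI-grid jitter.  Passing tests therefore
demonstrate the *algorithms* are correct and the *mechanistic* bias
story is coherent — not that absolute densities match any particular
scanner.

## Method M1 (quadrant ROIs)

The bone mask is the largest 8-connected component inside the density
window, with the phantom region excluded.  Quadrants are 90° sectors
about the area centroid with boundaries on the image diagonals, so each
sector is centred on a cardinal direction (up = anterior, down =
posterior, left = medial, right = lateral; the mapping is a config
table).  Pixels exactly on a diagonal join the counter-clockwise sector;
the slice statistic (mean of four ROI means) is invariant to that
convention.

The ROI search is exhaustive: every pixel whose disk fits inside the
quadrant's bone mask is a candidate; among candidates with
SD ≤ 0.15·mean ("homogeneous", configurable) the highest mean wins,
falling back to the unconstrained maximum when none qualifies, with ties
broken to the smallest (row, col).  The default radius is 2 px (~0.5 mm);
if a quadrant cannot hold the disk the radius shrinks 1 px at a time to
a floor before erroring.  Replicates jitter the candidate-grid origin by
a uniform sub-pixel offset.  One rasterization detail: a jittered
radius-2 disk can cover 10–14 grid points depending on the offset, so the
footprint is defined as the N grid offsets nearest the jittered centre
with N fixed at the zero-offset count (13).  Replicates therefore compare
equal-area ROIs and the ≥12-pixel minimum always holds.

## Method M2 (region growing)

Growth is 2-D per slice, 8-connected, within the window [200, 2000]
mgHA/cm³ applied by default to the calibrated map (a `threshold_space`
switch applies it to raw HU instead).  Replicate r seeds at the r-th
highest in-window pixel at least 3 px from earlier seeds (ties
lexicographic).  All seeds of a simply connected section grow the same
mask, so M2's replicate CV is ~0 by construction.  Within-mask SD uses
divisor n (the mask is the full population of selected pixels);
between-bone statistics use divisor n−1.  The phantom region is masked
out before seeding so growth cannot leak into the 200 mgHA/cm³ cylinder.

## Aggregation and precision

Slices are standardized at round(0.25·L), round(0.50·L), round(0.75·L)
of the slice count L, half-integers rounding to the lower index.
Aggregation is replicates → region mean → whole-bone mean (unweighted);
a pooled grand mean over raw records is never used.  Precision is the
CV% across the three replicates per (bone, region) cell, averaged per
method; on generator defaults it is ≈ 0.2 % for M1 and ≈ 0 for M2,
comfortably inside the 5 % protocol bound.

## Agreement statistics

CCC uses population moments and Cb = CCC/r exactly; its CI is a Fisher-z
interval with Lin's asymptotic SE.  Bland–Altman differences are
d = M2 − M1 (the fixed bias direction), limits bias ± 1.96·SD(d) with
sample SD, plus an OLS slope of d on the pair mean for proportional
bias.  Deming regression uses the closed-form slope with λ = error
variance ratio (default 1, orthogonal; the study gives no basis for
another value) and leave-one-out jackknife CIs with t(n−2) quantiles —
λ and both CI methods are recorded in the report metadata since there is
no single convention.  A Shapiro–Wilk screen is available as a warning
only; it never gates computation.

## Trait model and the regression screen

Traits are linear in true whole-bone density,
`t = a + b·ρ̄ + N(0, s)`, with residual SDs set from target population
R² values via `s = |b|·√(var(ρ̄)(1−R²)/R²)` at an assumed cohort spread
of SD(ρ̄) = 46 mgHA/cm³ (what the default generator produces).  Signs:
bone weight and volume positive, mineral matter (g) and all three
eggshell traits negative — denser skeletons route less calcium to the
shell — and bone length, mineral %, and Seedor index uninformative.
Target R² values (0.54–0.79 for the informative traits) sit in the range
such QCT trait studies report.

Screens are run on both raw and volume-normalized BMD and labeled.  The
normalized screen follows the study's stated procedure; note, however,
that because the simulated traits are linear in *raw* density, dividing
by a noisy volume trait injects a shared 1/V term that attenuates every
association and flips the bone-volume sign (cov(V, D/V) < 0 at these
effect sizes).  Sign-pattern validation in the tests therefore reads the
raw-scale screen; both result sets are always emitted so the effect of
normalization is itself inspectable.  Negative printed "R²" values are
interpreted as signed R² = sign(slope)·R², since a true coefficient of
determination cannot be negative; both columns appear in the output.  A
Benjamini–Hochberg column is supplementary only — the primary screen is
unadjusted at α = 0.05, matching the study design.

## Problem sizes and determinism

Default study scale is 48 bones × 110 slices × 128×128 voxels (~7 s for
the full pipeline on one core); tests use a reduced 64×64 / 36 mm
geometry with identical density parameters where full scale adds
nothing.  All randomness flows from a single integer seed through
`numpy` SeedSequence spawning (per-bone generation, per-replicate
jitter, trait residuals), so a (config, seed) pair is bit-reproducible,
which the suite asserts at the CSV byte level.

## Known limitations

* The cross-section is a straight elliptic annulus; no epiphyses, so the
  25/75 % levels are still pure diaphysis.
* No DICOM writer (NIfTI covers volume export); DICOM series reading is
  supported.
* M2's replicate scheme cannot probe segmentation instability because
  thresholded growth is deterministic; replicate variation in real
  operator workflows (manual seed choice, slice re-selection) is wider.
* The λ = 1 Deming default is an assumption, not an estimate; supply a
  measured error-variance ratio when one exists.
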