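# Methods

## Problem setting

Bi-parametric prostate MRI (bpMRI) combines a high-resolution anatomical
T2-weighted (T2w) scan with diffusion sequences (a high-b-value DWI and
the derived ADC map) acquired minutes apart.  Patient motion and the
susceptibility distortion of echo-planar diffusion imaging displace the
diffusion channels relative to the T2w reference, so the modalities that
a segmentation-based CAD system consumes are not voxelwise aligned.
This package implements the full alignment-handling stack around that
problem: a *misalignment augmentation* that makes training robust to
such displacements, two registration methods that remove them, and the
evaluation machinery (lesion-overlap surrogates and patient-level ROC
statistics) that measures what alignment handling buys on the
diagnostic task.

All 3-D volumes are indexed `[x, y, z]` with x = left–right,
y = dorsal–ventral (anterior–posterior) and z = the slice axis; NIfTI
input is canonicalized to RAS so these names are unambiguous.
Transforms act on physical millimetre coordinates (`index * spacing`),
which keeps amplitudes meaningful on the strongly anisotropic grids
typical of prostate MRI (0.3125 mm in-plane, 3 mm slices).

## Misalignment augmentation

One augmentation draw consists of three components, each sampled
uniformly on a symmetric interval:

| component | axis restriction | default bound |
|---|---|---|
| translation | none | (10, 10, 6) mm along x, y, z |
| rotation | x–y plane only | 15° |
| squeeze (scale) | dorsal–ventral (y) only | ratio 0.1, factor ∈ [0.9, 1.1] |

The in-plane restriction of the rotation reflects the coarse slice
spacing (through-plane rotation of a 3 mm-slice stack is not a
plausible acquisition artifact), and the squeeze emulates the
dorsal–ventral distortion of echo-planar DWI by B0 inhomogeneity.

A single Bernoulli(p) gate per exam decides whether the three
components apply *jointly*; p is the tuning knob explored over
{0.0, 0.1, 0.2, 0.4} (package default 0.2).  When the gate fires, the
composed affine — Translate ∘ RotateZ ∘ ScaleY, all about the grid
center — is applied to the T2w channel (linear interpolation) and its
lesion annotations (nearest neighbor) by pull-resampling; every
DWI-domain channel and mask passes through untouched.  Displacing the
T2w side rather than the diffusion side leaves the physically
quasi-quantitative ADC values unresampled in the common case.

Design choices made where the design was genuinely open:

* **Composition order** translate∘rotate∘squeeze is a fixed package
  convention; at the bounded amplitudes the components nearly commute
  (sub-voxel commutator error), so the order does not change the
  statistics of the induced misalignments.
* **Rotation/squeeze center** is the geometric center of the voxel
  grid.  Exams are prostate-cropped in this pipeline, so the grid
  center is a good proxy for the gland center; an explicit center can
  be passed for uncropped data.
* **Draw order** per exam is fixed (gate, tx, ty, tz, rotation,
  squeeze) from one seeded generator, making whole pipelines
  bit-reproducible.
* **Fill value** for pull-resampling is the per-volume minimum
  (background), 0 for label volumes.
* **Ordering contract**: the augmentation emulates an
  acquisition-time inter-modality offset, which only makes sense before
  any transform that moves all channels jointly.  The pipeline helper
  therefore rejects compositions in which a misalignment stage follows
  a global spatial stage.

## Registration

Both methods treat the T2w domain as fixed; only DWI-domain data are
resampled, and the fitted transform is propagated identically to the
high-b DWI, the ADC map and the DWI-domain masks (linear for images,
nearest for masks), so sibling channels keep their mutual alignment.

**B-spline mutual information.**  The moving image is the lowest-b-value
DWI — the diffusion image whose contrast is closest to T2w — and the
similarity is Mattes mutual information (32 bins).  The deformation is
a cubic B-spline with ~40 mm control-point spacing, optimized by
bounded LBFGSB over a 3-level multi-resolution pyramid (shrink factors
8/4/2).  The coefficient bounds (±20 mm) keep the deformation within
the plausible misalignment range and prevent the optimizer from
leaving the image buffer on flat metric landscapes (e.g.
self-registration).  When no low-b DWI is available the ADC map is
used with a warning.  The reported similarity value is the mutual
information between the fixed image and the warped moving image,
recomputed from the joint histogram in nats.

**GT-matching.**  A segmentation-driven affine reference: the transform
is parameterized exactly like a misalignment (translation, in-plane
rotation, dorsal–ventral squeeze) about the grid center and fitted by
maximizing the soft Dice of Gaussian-smoothed (σ = 2 mm) prostate plus
lesion masks, initialized by prostate-centroid alignment and optimized
with Powell's method.  The smoothed masks are band-limited, so the
objective is evaluated on a 3×3×1-strided lattice, which cuts the cost
per evaluation an order of magnitude without moving the optimum; on
noise-free phantoms the recovered parameters match the injected truth
to well under one voxel and one degree.  Because the estimated motion
has the misalignment parameterization, the method doubles as a
parameter-recovery oracle in the test suite.

## Preprocessing

* Linear resampling of all channels (nearest for masks) to
  0.3125 × 0.3125 × 3 mm, preserving physical extent within one voxel.
* Z-scoring of T2w and high-b DWI per exam; ADC is z-scored with
  mean/sd pooled across a training set (ADC is quasi-quantitative, so
  dataset-level statistics preserve its scale).  The pooled statistics
  are computed over prostate-masked voxels by default (the gland is
  the region the normalization must stabilize); whole-volume pooling
  is available.
* Cropping to the prostate bounding box with a 10 mm default margin.
* A balanced sampler (pick a class uniformly, then an exam uniformly
  within it) counters the ~34% csPCa prevalence during training.

## Evaluation

* **Dice** is 2|A∩B|/(|A|+|B|); two empty masks score 1 (no
  disagreement).  **Lesion-wise** Dice pairs lesions between the two
  label volumes greedily by maximal voxel overlap; unmatched lesions on
  either side score 0 — so a lesion annotated in only one modality
  counts as total disagreement rather than being dropped.
* **Dice distributions** report the sample mean/sd and a Gaussian-kernel
  density (Silverman bandwidth) on [0, 1] with two orders of boundary
  reflection, which keeps the density integrating to 1 within 1e-3 for
  any sample.
* **Patient score** is the global maximum of the voxelwise lesion
  probability map.
* **AUROC** is computed as the Mann–Whitney statistic via midranks
  (ties count 0.5) — exactly the fraction of correctly ordered
  (positive, negative) pairs.
* **Confidence intervals** are percentile bootstrap over B = 1000 case
  resamples; single-class replicates are redrawn.
* **DeLong test** compares paired AUROCs through the
  structural-component covariance estimator with a two-sided normal
  p-value.  When the estimated variance of the difference is zero
  (identical score vectors) the difference carries no evidence and the
  test returns p = 1 with a warning.
* **PI-RADS operating points** report sensitivity/specificity of the
  rule "positive iff PI-RADS ≥ t" for t ∈ {3, 4}.

## The phantom generator

The phantom emulates the *structure* of a bpMRI exam, not its
radiological appearance: an elliptical body, a prostate ellipsoid
(half-axes ≈ 16 × 13 × 18 mm) with a transition-zone core (55% of the
gland axes) and a peripheral-zone shell, and spherical lesions placed
rejection-sampled inside the gland.  Contrast polarity per modality
follows clinical convention: lesions hyperintense on high-b DWI
(0.90 vs ≤ 0.35 gland), hypointense on ADC (0.30 vs ≥ 0.85) and
hypointense on T2w (0.42–0.45 vs 0.55 TZ / 0.80 PZ).  The low-b DWI is
a smoothed, contrast-reduced copy of the T2w scene rendered in the DWI
domain, reproducing the similarity ordering that makes low-b the
registration driver.  Noise is additive Gaussian at a configurable
fraction of the gland–body contrast (default 0.05); Rician magnitude
bias is irrelevant to the operators under test and is not modelled.

Everything is rendered analytically from one scene description, so an
injected misalignment is exact: DWI-domain channels evaluate the scene
through the inverse truth transform rather than resampling a rendered
volume.  Phantom cohorts draw their per-exam seeds from one master
stream *before* any misalignment is sampled, so cohorts generated with
and without injected misalignment are exam-by-exam twins — the basis
of the aligned-vs-misaligned comparisons.  Cohorts carry a controlled
csPCa prevalence of 34.4% (the prevalence typical of mixed
PROSTATEx/clinical cohorts); an exam is positive when it contains a
lesion of radius ≥ 5 mm, and a synthetic PI-RADS score is assigned as
a monotone function of lesion volume × DWI contrast with reader noise.

What the phantom does **not** emulate: bladder/rectum anatomy, bias
fields, Rician noise, pharmacokinetic DCE, susceptibility artifacts
beyond the affine squeeze, and the texture heterogeneity of real
lesions.  Passing phantom tests therefore demonstrates that the
geometric and statistical machinery is correct — not that any specific
clinical performance would be reached on patient data.

## The toy segmenter

End-to-end experiments need a stand-in for a trained segmentation CNN.
The toy scorer multiplies per-modality evidence factors
(sigmoid-thresholded: bright on high-b DWI, dark on ADC, dark on T2w)
inside the prostate mask, smooths the product with a 3 mm Gaussian and
takes the maximum.  Multiplying evidence *across* domains makes the
score collapse when the modalities are misaligned — the sensitivity to
alignment that motivates the whole package — and the smoothing makes
larger (clinically significant) lesions peak higher than punctate
ones.  Its thresholds are fixed to the phantom's contrast levels; it
is a test harness, not a segmentation method.

## Problem sizes and numerical choices

Phantom experiments use 20 exams on a 160 × 160 × 20 grid at
0.3125 × 0.3125 × 3 mm (a 50 × 50 × 60 mm field of view), sampling-law
checks use 1e5 draws, permutation oracles 1e5 replicates, bootstrap
coverage 200 trials of B = 1000 — sizes chosen so the full suite runs
on a single CPU in minutes while keeping every statistical check
well-powered.  Degenerate inputs fail loudly: empty prostate masks,
single-class label vectors, zero per-exam standard deviations,
singular transforms and malformed manifests all raise typed errors
naming the offending object.

## Known limitations

* The B-spline registration is tuned for the phantom's scale of
  misalignment; real multi-center data would need heavier multi-start
  or mask-constrained variants.
* GT-matching assumes the misalignment parameterization (affine with
  in-plane rotation and y-squeeze); it cannot represent deformable
  misalignment, which is exactly why it serves as a reference rather
  than a product.
* CNN training is out of scope by design; the augmentation is exposed
  as a batch-transform contract so it can be dropped into an external
  training pipeline.
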