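# misalign

Alignment handling for multi-modal prostate MRI: misalignment
augmentation, registration, and patient-level evaluation.

Bi-parametric prostate MRI combines an anatomical T2-weighted scan with
diffusion sequences (high-b-value DWI and the ADC map) acquired minutes
apart, so the modalities a segmentation-based CAD system consumes are
routinely displaced against each other by patient motion and
echo-planar distortion.  This package implements, end to end, the two
strategies for dealing with that — and the machinery to measure what
they buy on the diagnostic task:

* **Misalignment augmentation** (`misalign.spatial`): at training time,
  the T2w channel and its lesion annotations are displaced relative to
  the DWI channels by a uniformly sampled translation (bounds
  (10, 10, 6) mm), in-plane rotation (≤ 15°) and dorsal–ventral squeeze
  (ratio ≤ 0.1), gated per exam by a Bernoulli(p) draw,
  p ∈ {0.0, 0.1, 0.2, 0.4}.  The transform acts in physical mm
  coordinates, and a pipeline helper enforces that the augmentation runs
  before any global spatial augmentation.
* **Registration** (`misalign.registration`): B-spline registration
  maximizing mutual information between T2w and the low-b DWI (the
  diffusion image most similar to T2w), propagated to the high-b DWI,
  ADC and DWI-domain masks; and a segmentation-driven *GT-matching*
  affine reference that maximizes prostate+lesion mask overlap.
* **Evaluation** (`misalign.metrics`): lesion-wise Dice distributions
  between T2w- and ADC-domain annotations (greedy maximal-overlap
  pairing, orphans score 0), patient scores as the maximum of a
  voxelwise lesion-probability map, AUROC as the Mann–Whitney
  statistic, percentile-bootstrap 95% CIs (B = 1000), the DeLong test
  for paired AUROCs, and PI-RADS ≥ 3 / ≥ 4 operating points.
* **Phantoms** (`misalign.phantom`): synthetic multi-modal prostate
  exams with clinically polarized contrasts and *known* ground-truth
  inter-modality misalignments, so every stage is testable without
  patient data.  `misalign.preprocess` adds the deterministic
  resampling / normalization / cropping / balanced-sampling steps, and
  `misalign.io` the NIfTI + manifest + cohort arithmetic layer.

In notation: for masks A, B the Dice score is 2|A∩B|/(|A|+|B|); the
patient score of a probability map P is max_v P(v); the AUROC equals
P(S⁺ > S⁻) + ½·P(S⁺ = S⁻) for random positive/negative scores; DeLong's
test compares paired AUROCs via the structural-component covariance of
the Mann–Whitney kernel.

## Worked example

`examples/03_registration.py` injects a known misalignment into a
noise-free phantom and corrects it with both methods:

```text
injected truth: t=(6.0, -4.0, 3.0) mm, rot=8.0 deg, squeeze=1.05
unregistered lesion Dice: 0.147

bspline_mi: lesion Dice 0.147 -> 0.878
  final mutual information: 0.719 nats
gt_matching: lesion Dice 0.147 -> 0.983
  recovered: t=(6.00, -4.00, 3.01) mm, rot=7.95 deg, squeeze=1.049
```

The GT-matching reference recovers the injected transform to a small
fraction of a voxel; both methods lift the inter-domain lesion overlap
from near-disjoint (0.15) to near-perfect.

`examples/04_evaluation.py` runs the full pipeline on 20 phantoms —
misaligned, perfectly aligned, and registered variants, each scored by
a toy threshold segmenter — and prints the evaluation table:

```text
configuration  auroc  ci_lo  ci_hi  p_value  reference   n
   misaligned  0.989  0.941    1.0      NaN       True   20
      aligned  1.000  1.000    1.0     0.48      False   20
   bspline_mi  1.000  1.000    1.0     0.48      False   20
  gt_matching  1.000  1.000    1.0     0.48      False   20

configuration  dice_mean  dice_sd  n_lesions
   misaligned      0.096    0.140         13
      aligned      1.000    0.000         10
   bspline_mi      0.891    0.044         10
  gt_matching      0.926    0.051         10
```

Misalignment costs lesion overlap (Dice 1.00 → 0.10) and patient-level
discrimination; alignment handling recovers both.  The other examples
cover phantom generation, the augmentation sampling law and the
ordering contract, and cohort prevalence arithmetic.

## Command line

The same stages are exposed as a thin CLI, each command deterministic
under `--seed` and writing a JSON run log next to its output:

```bash
misalign phantom  --n 20 --seed 7 --out data/ --misalign random
misalign augment  --manifest data/manifest.csv --probability 0.4 --out aug/
misalign register --manifest data/manifest.csv --method bspline_mi --out reg/
misalign dice-density --manifest data/manifest.csv --out density.csv
misalign evaluate --n 20 --seed 7 --out table.csv
misalign summarize --manifest data/manifest.csv --out summary.csv
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the
parameters and defaults, what the phantom does and does not emulate,
and the numerical choices (optimizers, tolerances, tie-breaks,
degenerate-input policies).
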