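"""Correct a known inter-modality misalignment with both registration
methods and compare the lesion-overlap improvement.

B-spline registration maximizes mutual information between T2w and the
low-b DWI (the diffusion image most similar to T2w) and propagates the
transform to the other DWI-domain channels; GT-matching fits an affine
that maximizes the overlap of the prostate and lesion masks.
"""

import numpy as np

from misalign import (MisalignmentParams, PhantomConfig, generate_phantom,
                      lesionwise_dice, register_exam)

truth = MisalignmentParams((6.0, -4.0, 3.0), 8.0, 1.05)
exam = generate_phantom(PhantomConfig(
    n_lesions=1, noise_sigma=0.0, lesion_radius_range=(5.5, 8.0),
    true_misalignment=truth, seed=3))

pre = np.mean(lesionwise_dice(exam.lesion_mask_t2w, exam.lesion_mask_dwi))
print(f"injected truth: t={truth.translation_mm} mm, "
      f"rot={truth.rotation_deg} deg, squeeze={truth.squeeze_factor}")
print(f"unregistered lesion Dice: {pre:.3f}\n")

for method in ("bspline_mi", "gt_matching"):
    registered, result = register_exam(exam, method=method)
    post = np.mean(lesionwise_dice(registered.lesion_mask_t2w,
                                   registered.lesion_mask_dwi))
    print(f"{method}: lesion Dice {pre:.3f} -> {post:.3f}")
    if result.estimated_params is not None:
        est = result.estimated_params
        print(f"  recovered: t=({est.translation_mm[0]:.2f}, "
              f"{est.translation_mm[1]:.2f}, {est.translation_mm[2]:.2f}) mm, "
              f"rot={est.rotation_deg:.2f} deg, "
              f"squeeze={est.squeeze_factor:.3f}")
    else:
        print(f"  final mutual information: {result.similarity_value:.3f} nats")
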