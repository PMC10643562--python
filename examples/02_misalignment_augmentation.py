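"""Sample and apply misalignment augmentation inside a pipeline.

The augmentation displaces the T2w channel (and its lesion annotations)
relative to the DWI-domain channels with uniformly sampled translation
(up to (10, 10, 6) mm), in-plane rotation (up to 15 degrees) and
dorsal-ventral squeeze (ratio up to 0.1), gated per exam by a
Bernoulli(p) draw.  It must run before any global augmentation, an
ordering the pipeline helper enforces.
"""

import numpy as np

from misalign import (AugmentationPipeline, MisalignmentAugmentation,
                      MisalignmentConfig, PhantomConfig, RandomGlobalAffine,
                      generate_phantom, sample_misalignment)
from misalign.errors import PipelineOrderError

rng = np.random.default_rng(0)
config = MisalignmentConfig(probability=0.4)

print("five sampled misalignments (tx, ty, tz | rotation | squeeze):")
for _ in range(5):
    p = sample_misalignment(config, rng)
    print(f"  ({p.translation_mm[0]:+6.2f}, {p.translation_mm[1]:+6.2f}, "
          f"{p.translation_mm[2]:+6.2f}) mm | {p.rotation_deg:+6.2f} deg | "
          f"x{p.squeeze_factor:.3f}")

exam = generate_phantom(PhantomConfig(seed=3))
augment = MisalignmentAugmentation(config, seed=1)
pipeline = AugmentationPipeline([augment, RandomGlobalAffine(seed=2)])

applied = 0
for _ in range(10):
    pipeline(exam)
    applied += augment.last_params is not None
print(f"\ngate fired for {applied}/10 pipeline passes "
      f"(expected about {config.probability:.0%})")

try:
    AugmentationPipeline([RandomGlobalAffine(seed=2), augment])
except PipelineOrderError as exc:
    print(f"misordered pipeline rejected: {exc}")
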