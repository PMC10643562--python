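"""Cohort arithmetic: csPCa prevalence per center and per split.

Feeding the printed counts of a two-center prostate MRI cohort through
the summary reproduces its prevalence percentages; the same helper
works on any manifest via `misalign.cohort_summary`.
"""

from misalign import counts_summary

by_center = counts_summary({"prostatex": (134, 70), "inhouse": (276, 145)})
print("per-center csPCa prevalence:")
print(by_center.to_frame().to_string(index=False))

by_split = counts_summary({"train": (327, 169), "test": (83, 46)})
print("\ntrain/test split:")
print(by_split.to_frame().to_string(index=False))
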