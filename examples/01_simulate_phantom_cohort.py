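"""Simulate an image-level phantom cohort and write it to disk.

Each case carries aligned T2 and ADC volumes, an ellipsoidal lesion mask,
and — for PLNM-positive cases — one or two node masks whose radiological
short-axis diameter respects the >= 15 mm inclusion rule.  Lesion and node
texture share a case-level latent in positives, which is what makes their
extracted features correlate across tissues.
"""

import numpy as np

from plnm_radiomics import SimConfig, simulate_cohort, write_cohort

config = SimConfig(
    n_train_pos=4, n_train_neg=6, n_internal=6, n_external=6,
    prevalence_internal=0.34, prevalence_external=0.34, seed=7,
)
cohort = simulate_cohort(config, split="train")
manifest = write_cohort(cohort, "scratch/phantom_cohort")

print(f"wrote {len(cohort.cases)} cases -> {manifest}")
for case in cohort.cases[:5]:
    widths = []
    for m in case.node_masks:
        idx = np.argwhere(m.values)
        widths.append(int(np.sort(idx.max(0) - idx.min(0) + 1)[1]))
    print(
        f"  {case.case_id}: label={case.label} lesion={case.lesion_mask.n_voxels} vox"
        f"  nodes={len(case.node_masks)} short-axis(vox)={widths}"
    )
# Positive cases list at least one node of short axis >= 15 voxels (15 mm at
# 1 mm spacing); negatives have none.
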