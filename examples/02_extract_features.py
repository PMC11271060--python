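"""Extract the full 3748-dimensional radiomic feature vector from one case.

The feature space is 2 modalities (T2, ADC) x [14 shape + 20 filter-bank
images x (18 first-order + 93-18 texture)] = 2 x 1874 named features per
VOI.  Names follow "<modality>_<tissue>_<image>_<class>_<feature>".
"""

import time

from plnm_radiomics import SimConfig, extract_all, simulate_cohort

config = SimConfig(n_train_pos=1, n_train_neg=0, n_internal=4, n_external=4,
                   prevalence_internal=0.3, prevalence_external=0.3, seed=3)
case = simulate_cohort(config, "train").cases[0]

t0 = time.time()
lesion = extract_all(case, tissue="tumor")
node = extract_all(case, tissue="node")
print(f"extracted {len(lesion)} lesion + {len(node)} node features "
      f"in {time.time() - t0:.1f} s")

for name in [
    "T2_tumor_original_shape_Maximum2DDiameterColumn",
    "T2_tumor_wavelet_LLL_glszm_ZoneEntropy",
    "ADC_tumor_original_firstorder_Mean",
    "T2_node_log_sigma_1_0_glcm_Contrast",
]:
    table = lesion if "_tumor_" in name else node
    print(f"  {name:55s} = {table[name]:.4f}")
# The two names printed first are the highest-weight features of the study's
# lesion and lesion-correlation models, respectively.
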