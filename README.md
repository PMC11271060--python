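# plnm-radiomics

Biparametric-MRI (T2WI + ADC) radiomics for predicting **pelvic lymph node
metastasis (PLNM)** in prostate cancer, built around a cross-tissue feature
filter: primary-lesion radiomic features are kept only when they correlate
strongly (Pearson |r| > 0.9) with the matching features of metastatic lymph
nodes.  The premise is biological — nodal metastases grow from cells shed by
the primary tumour, so lesion features that covary with node features across
patients plausibly carry the metastatic signature.

The package is a complete, tested pipeline:

1. **Feature extraction** — 3748 named features per VOI: 2 modalities x
   [14 shape + 20 filter-bank images x (18 first-order + 24 GLCM + 16 GLRLM +
   16 GLSZM + 5 NGTDM + 14 GLDM)].  The bank is the original image plus
   Laplacian-of-Gaussian (sigma 0.5/1/1.5 mm), logarithm, square, square
   root, exponential, gradient, three LBP-3D maps and the eight sub-bands of
   a stationary 3D Haar wavelet.  Extraction settings: z-score normalization
   scaled by 100, resampling to 1 mm, bounding-box pad 10, fixed bin width
   25, voxel-array shift 300 for the energy features.
2. **Selection** — cross-tissue Pearson filter (|r| > 0.9 over PLNM-positive
   training cases) -> per-feature Welch t test (p < 0.05) -> LASSO-penalized
   logistic model with penalty chosen by 5-fold CV repeated 5 times.
3. **Modelling** — RBF SVM on the retained features, hyperparameters by
   repeated stratified CV with SMOTE applied inside each training fold;
   decision threshold by Youden's J on training data.
4. **Evaluation** — AUC with DeLong 95% CIs, accuracy/sensitivity/
   specificity, and the paired DeLong z-test between the *lesion* model
   (no correlation filter) and the *lesion-correlation* model.
5. **Synthetic cohorts** — the clinical MRI data behind this design are
   private, so a phantom generator reproduces the study's statistical
   structure: 263 training / 74 internal / 57 external cases at the study's
   prevalences, node masks obeying the >= 15 mm short-axis rule, and a
   planted lesion-node shared feature signature with controllable
   cross-tissue correlation.

## Worked example

`examples/04_train_and_compare_models.py` trains both arms on one synthetic
cohort (263 training cases, 500 features of which 20 carry the planted
signature at cross-tissue r = 0.95) and evaluates on the 74 held-out cases:

```
lesion model:             AUC = 0.6325 (37 features)
lesion-correlation model: AUC = 0.8144 (8 features)
AUC gain = +0.1818, paired DeLong p = 0.0268
```

The correlation-filtered arm reaches a higher held-out AUC with far fewer
features: the cross-tissue filter removes noise features that the t test
alone lets through.  Averaged over 20 simulation seeds the gain is ≈ +0.05
(see the reproduction script below); individual seeds vary, and the lesion
arm occasionally wins.

The other examples cover phantom simulation (`01`), full feature extraction
(`02`), the selection trace (`03`) and the end-to-end persisted pipeline
(`05`).  A thin CLI mirrors the stages:

```bash
plnm-radiomics simulate --out cohort_dir --seed 7
plnm-radiomics extract --manifest cohort_dir/manifest.csv --out features/
plnm-radiomics train --lesion features/features_tumor_train.csv --labels labels.csv \
    --arm lesion-correlation --node features/features_node_train.csv --out model.pkl
plnm-radiomics reproduce-synthetic --out run_dir
```

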