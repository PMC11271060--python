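"""Synthetic cohorts emulating the two-hospital PLNM study structure.

The study's MRI data are private, so two generators stand in for them:

* :func:`simulate_feature_tables` — fast, draws paired lesion/node feature
  tables directly.  A planted subset of "metastatic signature" features is
  (a) mean-shifted in PLNM-positive cases and (b) correlated between the
  primary-lesion and metastatic-node tissues of positive cases with a chosen
  Pearson coefficient.  This mirrors the premise that node radiomics reflect
  the metastatic character of the primary lesion, and gives exact control of
  the correlation the cross-tissue filter is meant to detect.
* :func:`simulate_cohort` / :func:`simulate_study` — image-level phantoms:
  ellipsoidal lesions with Gaussian-random-field texture on T2 (heterogeneous
  signal) and a hypointense ADC map; positive cases additionally carry
  ellipsoidal node masks whose radiological short-axis diameter (middle
  principal axis) respects the >= 15 mm inclusion rule, and whose texture
  parameters share a case-level latent with the lesion so that extracted
  features correlate across tissues.

Default cohort sizes are the study's: 263 training (93 positive / 170
negative), 74 internal and 57 external validation cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import Case, Cohort
from .imaging import ImageVolume, Mask


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-shape and signal parameters for both generators.

    ``effect_size`` is the standardized mean difference (in units of
    ``noise_sd``) of informative lesion features between positive and
    negative cases; ``cross_tissue_rho`` the Pearson correlation planted
    between matching lesion/node features across positive cases.
    """

    n_train_pos: int = 93
    n_train_neg: int = 170
    n_internal: int = 74
    n_external: int = 57
    prevalence_internal: float = 19 / 74
    prevalence_external: float = 14 / 57
    n_features: int = 500
    n_informative: int = 20
    cross_tissue_rho: float = 0.95
    effect_size: float = 0.8
    #: equicorrelation among the informative features of one tissue.  A
    #: radiomic signature measures one underlying phenotype, so its features
    #: are strongly inter-correlated rather than independent; 0.7 is typical
    #: of within-cluster feature correlation in radiomics panels, and it puts
    #: the benchmark classifiers in the mid-AUC regime rather than at ceiling.
    signature_corr: float = 0.7
    noise_sd: float = 1.0
    min_node_short_axis_mm: float = 15.0
    seed: int = 0
    # image-phantom geometry
    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative must not exceed n_features")
        if not 0.0 <= self.cross_tissue_rho <= 1.0:
            raise ConfigError("cross_tissue_rho must be in [0, 1]")
        if not 0.0 <= self.signature_corr < 1.0:
            raise ConfigError("signature_corr must be in [0, 1)")
        if self.min_node_short_axis_mm < 0:
            raise ConfigError("min_node_short_axis_mm must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for name in ("n_train_pos", "n_train_neg", "n_internal", "n_external"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("prevalence_internal", "prevalence_external"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1)")

    def split_counts(self) -> Dict[str, Tuple[int, int]]:
        """(n_positive, n_negative) per split; labels are assigned exactly."""
        n_int_pos = int(round(self.prevalence_internal * self.n_internal))
        n_ext_pos = int(round(self.prevalence_external * self.n_external))
        return {
            "train": (self.n_train_pos, self.n_train_neg),
            "internal": (n_int_pos, self.n_internal - n_int_pos),
            "external": (n_ext_pos, self.n_external - n_ext_pos),
        }


@dataclass
class FeatureTables:
    """Output of :func:`simulate_feature_tables`."""

    lesion: pd.DataFrame  # all cases x n_features
    node: pd.DataFrame  # positive cases x n_features
    labels: pd.Series  # 0/1 per case
    splits: pd.Series  # train | internal | external per case
    informative: List[str] = field(default_factory=list)

    def __iter__(self):  # tuple-style unpacking: lesion, node, labels
        return iter((self.lesion, self.node, self.labels))


def simulate_feature_tables(config: SimConfig) -> FeatureTables:
    """Draw paired lesion/node feature tables with a planted shared signature.

    Informative features (the first ``n_informative`` columns) follow a
    bivariate Gaussian copula across tissues with correlation
    ``cross_tissue_rho`` (realised via a shared latent:
    ``x = sqrt(rho) z + sqrt(1-rho) e``), plus an ``effect_size`` mean shift
    in positives on the lesion side.  All other features are independent
    noise.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    counts = config.split_counts()
    ids, labels, splits = [], [], []
    for split, (npos, nneg) in counts.items():
        for i in range(npos + nneg):
            ids.append(f"{split}_{i:03d}")
            labels.append(1 if i < npos else 0)
            splits.append(split)
    y = np.array(labels)
    n_cases = len(ids)
    nf, ni = config.n_features, config.n_informative
    sd, rho = config.noise_sd, config.cross_tissue_rho

    cols = [f"feat_{j:04d}" for j in range(nf)]
    informative = cols[:ni]

    lesion = rng.normal(0.0, sd, size=(n_cases, nf))
    pos_idx = np.flatnonzero(y == 1)
    node = rng.normal(0.0, sd, size=(len(pos_idx), nf))

    if ni:
        c = config.signature_corr
        sc, sf = np.sqrt(c), np.sqrt(1.0 - c)
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        npos = len(pos_idx)
        # positives: a case-level latent (shared across the signature) and
        # per-feature latents, each split across tissues at correlation rho
        t = rng.normal(size=(npos, 1))
        case_les = a * t + b * rng.normal(size=(npos, 1))
        case_nod = a * t + b * rng.normal(size=(npos, 1))
        z = rng.normal(size=(npos, ni))
        feat_les = a * z + b * rng.normal(size=(npos, ni))
        feat_nod = a * z + b * rng.normal(size=(npos, ni))
        lesion[pos_idx, :ni] = sd * (sc * case_les + sf * feat_les)
        node[:, :ni] = sd * (sc * case_nod + sf * feat_nod)
        # negatives: same equicorrelated signature structure, no node tissue
        neg_idx = np.flatnonzero(y == 0)
        g = rng.normal(size=(len(neg_idx), 1))
        lesion[neg_idx, :ni] = sd * (sc * g + sf * rng.normal(size=(len(neg_idx), ni)))
        # class separation on the lesion side (positives shifted)
        lesion[:, :ni] += config.effect_size * sd * y[:, None]

    lesion_df = pd.DataFrame(lesion, index=pd.Index(ids, name="case_id"), columns=cols)
    node_df = pd.DataFrame(
        node, index=pd.Index([ids[i] for i in pos_idx], name="case_id"), columns=cols
    )
    return FeatureTables(
        lesion=lesion_df,
        node=node_df,
        labels=pd.Series(y, index=lesion_df.index, name="label"),
        splits=pd.Series(splits, index=lesion_df.index, name="split"),
        informative=informative,
    )


# ---------------------------------------------------------------------------
# Image phantoms
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


def _grf(rng, shape, corr_len_vox, amplitude) -> np.ndarray:
    """Gaussian random field: smoothed white noise rescaled to sd=amplitude."""
    w = rng.normal(size=shape)
    f = ndimage.gaussian_filter(w, sigma=corr_len_vox, mode="wrap")
    sdv = f.std()
    return amplitude * f / sdv if sdv > 0 else f


def node_short_axis_mm(semi_axes_mm) -> float:
    """Radiological short-axis diameter of an ellipsoid: the full length of
    its middle principal axis."""
    return 2.0 * float(np.sort(semi_axes_mm)[1])


def _simulate_case(
    case_id: str,
    label: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> Case:
    shape, spacing = config.grid_shape, config.spacing
    extent = np.asarray(shape) * np.asarray(spacing)

    # -- case-level texture parameters -------------------------------------
    # positives share a latent t between lesion and node texture so features
    # extracted from the two tissues correlate across cases
    rho = config.cross_tissue_rho
    t = rng.normal()
    u_les, u_nod = rng.normal(size=2)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    g_les = a * t + b * u_les
    g_nod = a * t + b * u_nod
    # heterogeneity amplitude: higher in positives (the planted effect)
    amp_les = 18.0 * np.exp(0.35 * g_les) * (1.0 + 0.3 * config.effect_size * label)
    corr_les = float(np.clip(1.6 + 0.5 * g_les, 0.8, 3.5))

    # -- lesion geometry ----------------------------------------------------
    les_axes = rng.uniform(5.0, 9.0, size=3)
    les_center = extent * 0.28 + rng.uniform(-2.0, 2.0, size=3)
    lesion = _ellipsoid_mask(shape, spacing, les_center, les_axes)

    # -- base images ---------------------------------------------------------
    t2 = 100.0 + rng.normal(0.0, 5.0, size=shape)
    adc = 1000.0 + rng.normal(0.0, 30.0, size=shape)
    t2 = t2 + lesion * (20.0 + _grf(rng, shape, corr_les, amp_les))
    adc = adc + lesion * (-400.0 + _grf(rng, shape, corr_les, 0.8 * amp_les))

    node_masks: List[Mask] = []
    if label == 1:
        n_nodes = int(rng.integers(1, 3))
        for k in range(n_nodes):
            short = config.min_node_short_axis_mm
            b2 = rng.uniform(short / 2.0, short / 2.0 + 1.5)  # middle semi-axis
            b1 = rng.uniform(b2, b2 + 3.0)
            b3 = rng.uniform(max(short / 2.0 - 2.0, 2.0), b2)
            axes = np.array([b1, b2, b3])
            rng.shuffle(axes)
            center = extent * 0.70 + rng.uniform(-2.5, 2.5, size=3)
            center[k % 3] += (k - 0.5) * 4.0  # separate multiple nodes a bit
            nmask = _ellipsoid_mask(shape, spacing, center, axes)
            amp_nod = 18.0 * np.exp(0.35 * g_nod) * (1.0 + 0.3 * config.effect_size)
            corr_nod = float(np.clip(1.6 + 0.5 * g_nod, 0.8, 3.5))
            t2 = t2 + nmask * (15.0 + _grf(rng, shape, corr_nod, amp_nod))
            adc = adc + nmask * (-380.0 + _grf(rng, shape, corr_nod, 0.8 * amp_nod))
            node_masks.append(Mask(nmask, spacing))

    return Case(
        case_id=case_id,
        label=label,
        volumes={
            "T2": ImageVolume(t2, spacing, modality="T2"),
            "ADC": ImageVolume(adc, spacing, modality="ADC"),
        },
        lesion_mask=Mask(lesion, spacing),
        node_masks=node_masks,
    )


def simulate_cohort(config: SimConfig, split: str = "train") -> Cohort:
    """Image-level phantom cohort for one split; labels assigned exactly."""
    counts = config.split_counts()
    if split not in counts:
        raise ConfigError(f"unknown split {split!r}")
    extent = np.asarray(config.grid_shape) * np.asarray(config.spacing)
    # the node must fit with its largest admissible extent; require the grid
    # to hold lesion and node regions without clipping
    if extent.min() < 2.0 * config.min_node_short_axis_mm:
        raise ConfigError(
            f"grid extent {tuple(extent)} mm too small for nodes of short axis "
            f">= {config.min_node_short_axis_mm} mm"
        )
    split_offset = {"train": 0, "internal": 1, "external": 2}[split]
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7, split_offset]))
    npos, nneg = counts[split]
    cases = [
        _simulate_case(f"{split}_{i:03d}", 1 if i < npos else 0, config, rng)
        for i in range(npos + nneg)
    ]
    return Cohort(cases, split=split)


def simulate_study(config: SimConfig) -> Dict[str, Cohort]:
    """All three splits (train, internal, external)."""
    return {s: simulate_cohort(config, s) for s in ("train", "internal", "external")}
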