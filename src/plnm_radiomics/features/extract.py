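"""Feature-vector assembly: the full (modality x image x class) feature space.

With the complete 20-image filter bank, one VOI yields per modality
``14 shape + 20 x (18 first-order + 93 texture - 18) = 14 + 20 x 93 = 1874``
named features, hence 3748 over T2 + ADC — shape is computed once (original
image only) while first-order and the five texture families run on every
bank image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from ..cohort import Case
from ..filterbank import BankConfig, apply_filter_bank, enumerate_feature_images
from ..imaging import DegenerateInputError, ImageVolume, Mask, discretize, normalize_intensity
from .firstorder import FIRSTORDER_FEATURES, first_order_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES, GLDM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES,
    NGTDM_FEATURES, glcm_features, gldm_features, glrlm_features,
    glszm_features, ngtdm_features,
)

MODALITIES = ("T2", "ADC")
TEXTURE_CLASSES = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier rendering to
    ``<modality>_<tissue>_<image>_<class>_<feature>``."""

    modality: str
    tissue: str
    image: str
    feature_class: str
    feature: str

    def __str__(self) -> str:
        return f"{self.modality}_{self.tissue}_{self.image}_{self.feature_class}_{self.feature}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        modality, tissue, rest = name.split("_", 2)
        for fc in ("firstorder", "shape", *TEXTURE_CLASSES):
            token = f"_{fc}_"
            if token in rest:
                image, feature = rest.split(token)
                return cls(modality, tissue, image, fc, feature)
        raise ValueError(f"unparseable feature name {name!r}")


@dataclass
class ExtractionSettings:
    """Extraction parameters; defaults are the study settings."""

    bin_width: float = 25.0
    normalize_scale: float = 100.0
    voxel_shift: float = 300.0
    pad_distance: int = 10
    gldm_alpha: float = 0.0
    normalize: bool = True
    #: how to summarise multiple node masks: 'largest' (by voxel volume) or 'mean'
    node_policy: str = "largest"


def expected_feature_count(bank_config: BankConfig | None = None) -> int:
    """``2 modalities x (14 shape + 93 x n_bank_images)``."""
    n_images = len(enumerate_feature_images(bank_config))
    per_image = len(FIRSTORDER_FEATURES) + sum(len(v) for v in TEXTURE_CLASSES.values())
    return 2 * (len(SHAPE_FEATURES) + per_image * n_images)


def _bbox_crop(volume: ImageVolume, mask: Mask, pad: int) -> tuple[ImageVolume, Mask]:
    """Crop to the mask bounding box padded by ``pad`` voxels (clipped to the
    grid) so filter supports do not truncate at the crop edge."""
    idx = np.argwhere(mask.values)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.values.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(o + l * s for o, l, s in zip(volume.origin, lo, volume.spacing))
    v = ImageVolume(volume.values[sl].copy(), volume.spacing, origin, volume.modality)
    m = Mask(mask.values[sl].copy(), volume.spacing, origin)
    return v, m


def features_for_image(
    image: ImageVolume,
    mask: Mask,
    settings: ExtractionSettings,
) -> Dict[str, Dict[str, float]]:
    """First-order + five texture families for one (already filtered) image."""
    disc = discretize(image, mask, settings.bin_width)
    out = {
        "firstorder": first_order_features(
            image.values, mask.values, settings.bin_width,
            settings.voxel_shift, image.voxel_volume,
        ),
        "glcm": glcm_features(disc),
        "glrlm": glrlm_features(disc),
        "glszm": glszm_features(disc),
        "ngtdm": ngtdm_features(disc),
        "gldm": gldm_features(disc, settings.gldm_alpha),
    }
    return out


def extract_for_mask(
    volume: ImageVolume,
    mask: Mask,
    modality: str,
    tissue: str,
    bank_config: BankConfig | None = None,
    settings: ExtractionSettings | None = None,
) -> Dict[str, float]:
    """All features for one modality over one mask (names fully qualified)."""
    settings = settings or ExtractionSettings()
    bank_config = bank_config or BankConfig()
    mask.require_nonempty()
    vol = normalize_intensity(volume, scale=settings.normalize_scale) if settings.normalize else volume
    crop, mcrop = _bbox_crop(vol, mask, settings.pad_distance)

    result: Dict[str, float] = {}
    for name, value in shape_features(mcrop.values, crop.spacing).items():
        result[str(FeatureName(modality, tissue, "original", "shape", name))] = value

    for img_name, img in apply_filter_bank(crop, bank_config, stats_mask=mcrop.values).items():
        fam = features_for_image(img, mcrop, settings)
        for fc, feats in fam.items():
            for fname, value in feats.items():
                result[str(FeatureName(modality, tissue, img_name, fc, fname))] = value
    return result


def _select_node_mask(case: Case, policy: str) -> List[tuple[Mask, float]]:
    """Node masks to extract from, with averaging weights."""
    if not case.node_masks:
        raise DegenerateInputError(f"case {case.case_id} has no node masks")
    if policy == "largest":
        biggest = max(case.node_masks, key=lambda m: m.n_voxels)
        return [(biggest, 1.0)]
    if policy == "mean":
        w = 1.0 / len(case.node_masks)
        return [(m, w) for m in case.node_masks]
    raise ValueError(f"unknown node policy {policy!r}")


def extract_all(
    case: Case,
    tissue: str = "tumor",
    bank_config: BankConfig | None = None,
    settings: ExtractionSettings | None = None,
) -> Dict[str, float]:
    """Full feature vector for one case and tissue ('tumor' or 'node').

    For multi-node cases the default policy extracts from the largest node
    by voxel volume; the 'mean' policy averages feature values over nodes.
    """
    settings = settings or ExtractionSettings()
    for mod in MODALITIES:
        if mod not in case.volumes:
            raise DegenerateInputError(f"case {case.case_id} lacks {mod} volume")
    if tissue == "tumor":
        targets = [(case.lesion_mask, 1.0)]
    elif tissue == "node":
        targets = _select_node_mask(case, settings.node_policy)
    else:
        raise ValueError(f"unknown tissue {tissue!r}")

    acc: Dict[str, float] = {}
    for mask, weight in targets:
        for mod in MODALITIES:
            feats = extract_for_mask(
                case.volumes[mod], mask, mod, tissue, bank_config, settings
            )
            for k, v in feats.items():
                acc[k] = acc.get(k, 0.0) + weight * v
    return acc


def extract_table(
    cases: Iterable[Case],
    tissue: str = "tumor",
    bank_config: BankConfig | None = None,
    settings: ExtractionSettings | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Feature table (cases x features) for one tissue; index is case_id."""
    rows = {}
    for case in cases:
        rows[case.case_id] = extract_all(case, tissue, bank_config, settings)
        if progress:  # pragma: no cover - cosmetic
            print(f"extracted {tissue} features for {case.case_id}")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "case_id"
    return df
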