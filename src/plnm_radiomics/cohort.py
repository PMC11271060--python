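"""Patient-level containers: a case (volumes + masks + label) and a cohort."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .imaging import ImageVolume, Mask, read_mask, read_volume


@dataclass
class Case:
    """One patient: per-modality volumes, a lesion mask (VOI-1) and zero or
    more metastatic-node masks (VOI-2), plus the PLNM label."""

    case_id: str
    label: int
    volumes: Dict[str, ImageVolume] = field(default_factory=dict)
    lesion_mask: Optional[Mask] = None
    node_masks: List[Mask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class Cohort:
    """A list of cases tagged with its split (train | internal | external)."""

    cases: List[Case]
    split: str = "train"

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids must be unique within a cohort")

    @property
    def labels(self) -> List[int]:
        return [c.label for c in self.cases]

    def positives(self) -> List[Case]:
        return [c for c in self.cases if c.label == 1]


# ---------------------------------------------------------------------------
# Manifest-based disk layout
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["case_id", "split", "label", "t2", "adc", "lesion_mask", "node_masks"]


def write_cohort(cohort: Cohort, out_dir: str) -> str:
    """Write NIfTI volumes/masks plus a manifest CSV; returns manifest path."""
    from .imaging import write_mask, write_volume

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for case in cohort.cases:
        paths = {}
        for mod in ("T2", "ADC"):
            p = os.path.join(out_dir, f"{case.case_id}_{mod}.nii.gz")
            write_volume(case.volumes[mod], p)
            paths[mod.lower()] = os.path.basename(p)
        lp = os.path.join(out_dir, f"{case.case_id}_lesion.nii.gz")
        write_mask(case.lesion_mask, lp)
        node_paths = []
        for i, nm in enumerate(case.node_masks):
            np_ = os.path.join(out_dir, f"{case.case_id}_node{i}.nii.gz")
            write_mask(nm, np_)
            node_paths.append(os.path.basename(np_))
        rows.append(
            {
                "case_id": case.case_id,
                "split": cohort.split,
                "label": case.label,
                "t2": paths["t2"],
                "adc": paths["adc"],
                "lesion_mask": os.path.basename(lp),
                "node_masks": ";".join(node_paths),
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    header = not os.path.exists(manifest)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, mode="a" if not header else "w", header=header, index=False
    )
    return manifest


def read_cohorts(manifest_path: str) -> Dict[str, Cohort]:
    """Load every split recorded in a manifest CSV."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path, keep_default_na=False)
    cohorts: Dict[str, Cohort] = {}
    for split, grp in df.groupby("split", sort=False):
        cases = []
        for _, row in grp.iterrows():
            case = Case(
                case_id=str(row["case_id"]),
                label=int(row["label"]),
                volumes={
                    "T2": read_volume(os.path.join(base, row["t2"]), "T2"),
                    "ADC": read_volume(os.path.join(base, row["adc"]), "ADC"),
                },
                lesion_mask=read_mask(os.path.join(base, row["lesion_mask"])),
                node_masks=[
                    read_mask(os.path.join(base, p))
                    for p in str(row["node_masks"]).split(";")
                    if p
                ],
            )
            cases.append(case)
        cohorts[str(split)] = Cohort(cases, split=str(split))
    return cohorts
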