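"""End-to-end orchestration: simulate -> extract -> select -> train ->
evaluate -> compare, with every intermediate persisted and the resolved
configuration echoed beside the outputs.

A single master seed fans out to per-stage seeds by fixed offsets
(simulation +0, selection/LASSO +1, SVM +2), so a rerun with the same config
reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import pickle
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, read_cohorts
from .evaluation import compare_models, delong_ci, format_report
from .features import ExtractionSettings, extract_table
from .filterbank import BankConfig
from .modeling import TrainedModel, predict_scores, train_arm
from .synthetic_cohort import SimConfig, simulate_study

log = logging.getLogger("plnm_radiomics")

SEED_SIM, SEED_SELECT, SEED_SVM = 0, 1, 2


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; defaults are the study settings."""

    out_dir: str = "run_output"
    manifest: Optional[str] = None  # load cohorts from disk instead of simulating
    seed: int = 0
    arms: Tuple[str, ...] = ("lesion", "lesion-correlation")
    # simulation (ignored when a manifest is given)
    sim: SimConfig = field(default_factory=SimConfig)
    # extraction
    extraction: ExtractionSettings = field(default_factory=ExtractionSettings)
    bank: BankConfig = field(default_factory=BankConfig)
    # selection
    corr_threshold: float = 0.9
    corr_mode: str = "paired"
    ttest_alpha: float = 0.05
    # modeling
    n_folds: int = 5
    n_repeats: int = 5

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("sim", SimConfig), ("extraction", ExtractionSettings), ("bank", BankConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(**raw)


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    log.info("stage %-12s %6.1f s", name, t1 - t0)
    return t1


def extract_cohort_tables(
    cohorts: Dict[str, Cohort],
    config: RunConfig,
    need_node: bool = True,
) -> tuple[Dict[str, pd.DataFrame], Optional[pd.DataFrame], Dict[str, np.ndarray]]:
    """Lesion table per split, node table for training positives, labels."""
    lesion_tables = {
        split: extract_table(c.cases, "tumor", config.bank, config.extraction)
        for split, c in cohorts.items()
    }
    labels = {
        split: np.array(c.labels) for split, c in cohorts.items()
    }
    node_table = None
    if need_node:
        node_table = extract_table(
            cohorts["train"].positives(), "node", config.bank, config.extraction
        )
    return lesion_tables, node_table, labels


def run_end_to_end(config: RunConfig) -> pd.DataFrame:
    """Execute the full workflow and return the comparison report.

    Artifacts written under ``config.out_dir``: the resolved config, the
    lesion/node feature tables (CSV), per-arm selection traces (JSON) and
    LASSO weights (CSV), pickled models with JSON metadata, and the report
    as CSV + formatted text.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    config.save(os.path.join(config.out_dir, "resolved_config.yaml"))
    t0 = time.time()

    # --- cohorts ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.manifest:
            cohorts = read_cohorts(config.manifest)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed + SEED_SIM)
            cohorts = simulate_study(sim)
        for split in ("train", "internal", "external"):
            if split not in cohorts:
                raise ValueError(f"cohort set lacks the {split!r} split")
        t0 = _stage(stage, t0)

        # --- extraction ---------------------------------------------------
        stage = "extract"
        need_node = "lesion-correlation" in config.arms
        lesion_tables, node_table, labels = extract_cohort_tables(
            cohorts, config, need_node=need_node
        )
        for split, tab in lesion_tables.items():
            tab.to_csv(os.path.join(config.out_dir, f"features_tumor_{split}.csv"))
        if node_table is not None:
            node_table.to_csv(os.path.join(config.out_dir, "features_node_train.csv"))
        log.info("feature space: %d features per VOI", lesion_tables["train"].shape[1])
        t0 = _stage(stage, t0)

        # --- selection + training ------------------------------------------
        stage = "train"
        models: List[TrainedModel] = []
        for arm in config.arms:
            model = train_arm(
                lesion_tables["train"],
                labels["train"],
                arm=arm,
                node_train_pos=node_table if arm == "lesion-correlation" else None,
                threshold=config.corr_threshold,
                mode=config.corr_mode,
                alpha=config.ttest_alpha,
                n_folds=config.n_folds,
                n_repeats=config.n_repeats,
                seed=config.seed + SEED_SVM,
            )
            models.append(model)
            tag = arm.replace("-", "_")
            model.trace.to_json(os.path.join(config.out_dir, f"trace_{tag}.json"))
            model.trace.weights_frame().to_csv(
                os.path.join(config.out_dir, f"weights_{tag}.csv"), index=False
            )
            with open(os.path.join(config.out_dir, f"model_{tag}.pkl"), "wb") as fh:
                pickle.dump(model, fh)
            meta = {
                "format_version": 1,
                "arm": arm,
                "params": model.params,
                "threshold": model.threshold,
                "n_features": len(model.features),
                "features": model.features,
                "cv_auc": model.cv_auc,
            }
            with open(os.path.join(config.out_dir, f"model_{tag}.json"), "w") as fh:
                json.dump(meta, fh, indent=2)
            log.info("%s: %d features, CV AUC %.3f", arm, len(model.features), model.cv_auc)
        t0 = _stage(stage, t0)

        # --- evaluation -----------------------------------------------------
        stage = "evaluate"
        eval_tables = {s: (lesion_tables[s], labels[s]) for s in lesion_tables}
        if len(models) == 2:
            report = compare_models(models[0], models[1], eval_tables)
        else:
            rows = []
            for split, (X, y) in eval_tables.items():
                model = models[0]
                res = delong_ci(predict_scores(model, X), y, threshold=model.threshold)
                rows.append(
                    {
                        "split": split, "arm": model.arm, "auc": res.auc,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "accuracy": res.accuracy, "sensitivity": res.sensitivity,
                        "specificity": res.specificity, "delong_p": float("nan"),
                    }
                )
            report = pd.DataFrame(rows)
        report.to_csv(os.path.join(config.out_dir, "report.csv"), index=False)
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(format_report(report) + "\n")
        _stage(stage, t0)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
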