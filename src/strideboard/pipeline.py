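"""End-to-end orchestration: simulate -> extract -> split -> select -> train
-> evaluate -> explain, from one validated config and one master seed.

The master seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so stages are reproducible and
statistically independent.  A manifest records the config, the per-stage
seeds, every open design choice in effect, and the SHA-256 hash of every
written artifact; rerunning with the same config reproduces the hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .dataset_assembly import LABEL_COLUMNS, add_split_and_weights, assemble_feature_table
from .evaluation import evaluate_models, panel_icc
from .explanation import (
    dt_importance,
    export_tree,
    permutation_importance,
    side_shares,
    tree_to_dot,
)
from .expert_board import SUBSCORES
from .feature_selection import select_features
from .model_training import grid_search, save_bundle
from .synthetic_cohort import Cohort, SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 100
    strides_per_patient: tuple[int, int] = (4, 12)
    sigma_rater: float = 0.25
    sigma_kin: float = 1.0
    severity_correlation: float = 0.5


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    test_fraction: float = 0.30
    alpha: float = 0.05
    families: tuple[str, ...] = ("dt", "mlp")
    targets: tuple[str, ...] = tuple(SUBSCORES)
    cv_folds: int = 10
    mlp_epochs: int = 120
    mlp_batch_size: int = 32
    permutation_repetitions: int = 100
    seed: int = 0
    write_stride_files: bool = False
    # open design choices, recorded in the manifest
    group_by_patient_cv: bool = False
    limp_index_definition: str = "ipsi_over_contra_stance_time"
    max_features_interpretation: str = "sqrt_n_log2"


def stage_seeds(master: int, stages: list[str]) -> dict[str, int]:
    """Derive one sub-2^31 integer seed per stage from the master seed."""
    children = np.random.SeedSequence(master).spawn(len(stages))
    return {name: int(c.generate_state(1, dtype=np.uint32)[0] % 2**31)
            for name, c in zip(stages, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, writing all artifacts below ``out_dir``.

    Returns the manifest dictionary (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "split"] + [f"train_{t}" for t in config.targets] + ["explain"]
    seeds = stage_seeds(config.seed, stages)
    written: list[Path] = []

    def save_json(obj, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=1, sort_keys=True))
        written.append(path)

    # 1. simulate ----------------------------------------------------------
    logger.info("stage simulate")
    sim = SimulationConfig(seed=seeds["simulate"], **config.simulation.model_dump())
    cohort = simulate_cohort(sim)
    if config.write_stride_files:
        write_cohort(cohort, out / "cohort")
        written.extend(sorted((out / "cohort").glob("*")))
    else:
        write_cohort_metadata(cohort, out / "cohort")
        written.append(out / "cohort" / "cohort.json")

    # 2. extract + split ---------------------------------------------------
    logger.info("stage extract/split")
    table = assemble_feature_table(cohort)
    table = add_split_and_weights(table, config.test_fraction, seed=seeds["split"])
    table.to_csv(out / "features.csv", index=False)
    written.append(out / "features.csv")
    train = table[table["split"] == "train"]
    test = table[table["split"] == "test"]

    # 3-5. per-target selection + training --------------------------------
    models: dict[str, dict] = {fam: {} for fam in config.families}
    for target in config.targets:
        logger.info("stage select/train: %s", target)
        mask, rep_idx, report = select_features(train, target, alpha=config.alpha)
        sel_path = out / f"selected_{target}.txt"
        sel_path.write_text("\n".join(mask.features) + "\n")
        written.append(sel_path)
        report.to_csv(out / f"ag_report_{target}.csv", index=False)
        written.append(out / f"ag_report_{target}.csv")
        if len(mask) == 0:
            raise RuntimeError(f"stage select: no feature retained for {target}")
        groups = train["patient_id"] if config.group_by_patient_cv else None
        for fam in config.families:
            model = grid_search(
                target, fam, train, mask.features,
                weights=table[f"weight_{target}"], rep_index=rep_idx,
                k=config.cv_folds, seed=seeds[f"train_{target}"],
                mlp_epochs=config.mlp_epochs, mlp_batch=config.mlp_batch_size,
                groups=groups,
            )
            bundle_dir = out / "models" / f"{fam}_{target}"
            save_bundle(model, bundle_dir)
            written.extend([bundle_dir / "model.json", bundle_dir / "cv_results.csv"])
            models[fam][target] = model

    # 6. evaluate ----------------------------------------------------------
    logger.info("stage evaluate")
    icc = panel_icc({p.patient_id: p.rater_panels for p in cohort.patients})
    report_doc: dict = {"icc_1_1": icc, "r2": {}, "cv_mean_r2": {}}
    scatter_frames = []
    for fam in config.families:
        r2, scatter = evaluate_models(models[fam], test)
        report_doc["r2"][fam] = r2
        report_doc["cv_mean_r2"][fam] = {
            t: models[fam][t].cv_mean_r2 for t in config.targets}
        scatter["family"] = fam
        scatter_frames.append(scatter)
    save_json(report_doc, out / "report.json")
    pd.concat(scatter_frames).to_csv(out / "scatter.csv", index=False)
    written.append(out / "scatter.csv")

    # 7. explain -----------------------------------------------------------
    logger.info("stage explain")
    explain_doc: dict = {}
    for fam in config.families:
        explain_doc[fam] = {}
        for target in config.targets:
            model = models[fam][target]
            if fam == "dt":
                ranking = dt_importance(model.predictor, list(model.features))
                doc = export_tree(model.predictor, list(model.features))
                dot_path = out / "trees" / f"{target}.dot"
                dot_path.parent.mkdir(exist_ok=True)
                dot_path.write_text(tree_to_dot(doc, title=f"{target} DT"))
                written.append(dot_path)
                extra = {"tree": doc}
            else:
                ranking = permutation_importance(
                    model.predict, test, test[target].to_numpy(float),
                    features=list(model.features),
                    repetitions=config.permutation_repetitions,
                    seed=seeds["explain"])
                extra = {"repetitions": config.permutation_repetitions}
            explain_doc[fam][target] = {
                "ranking": ranking.head(20).to_dict(orient="records"),
                "side_shares": side_shares(ranking),
                **extra,
            }
    save_json(explain_doc, out / "explanations.json")

    # manifest -------------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stage_seeds": seeds,
        "decision_flags": {
            "limp_index_definition": config.limp_index_definition,
            "max_features_interpretation": config.max_features_interpretation,
            "group_by_patient_cv": config.group_by_patient_cv,
            "stance_swing_boundary": "closed_windows",
            "nav_scheme": "central_differences",
            "representative_pair_rule": "zscore_median_euclidean",
            "cv_fold_stratification": "stride_pair_label",
            "permutation_shuffling": "global_within_column",
        },
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def write_cohort_metadata(cohort: Cohort, out_dir) -> None:
    """Write cohort.json only (severities, panels, aid flags), no stride files."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": {**asdict(cohort.config),
                   "strides_per_patient": list(cohort.config.strides_per_patient)},
        "patients": [
            {"patient_id": p.patient_id,
             "affected_side": p.profile.affected_side,
             "severities": p.profile.severities,
             "rater_panels": p.rater_panels,
             "walking_cane": p.walking_cane,
             "afo": p.afo}
            for p in cohort.patients
        ],
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
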