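"""End-to-end driver: read -> QC -> outlier removal -> split -> grid
search -> selection -> revalidation -> final model -> importance profile.

Stage order mirrors the analysis workflow: outliers are removed once,
before the train/test split; SMOTE balancing happens inside training
folds only. Every run writes a manifest (config, seeds, artifact list)
so a search is auditable and exactly re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .spectra import read_spectra
from .preprocess import PreprocessConfig, apply_pipeline, default_config_space
from .qc import qc_report
from .outliers import pcout_flag, remove_outliers
from .resampling import grouped_split, stratified_group_kfold
from .models import (
    SelectionCriteria,
    _labeled_patients,
    default_model_registry,
    enumerate_grid,
    records_to_frame,
    revalidate,
    run_search,
    select_models,
)
from .importance import locate_peaks, profile_cohort

logger = logging.getLogger("ftir_recur")

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    spectra_path: str = ""
    metadata_path: str = ""
    spectra_format: str = "csv_wide"
    output_dir: str = "run"
    config_space: dict = field(default_factory=default_config_space)
    models: list = field(default_factory=lambda: ["rf", "RRF", "gbm"])
    split_ratio: float = 0.7
    split_seed: int = 0
    cv_k: int = 10
    cv_repeats: int = 3
    search_seed: int = 0
    min_cv_roc: float = 0.8
    min_test_f1: float = 0.5
    revalidation_repeats: int = 10
    outlier_cutoff: float = 0.25
    importance_permutations: int = 10

    def __post_init__(self):
        registry = default_model_registry()
        unknown = [m for m in self.models if m not in registry]
        if unknown:
            raise ValueError(
                f"unknown model name(s) {unknown}; registered: {sorted(registry)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def run_full_pipeline(config: PipelineConfig, spectra_set=None) -> str:
    """Execute all stages; returns the run directory path.

    ``spectra_set`` may be passed directly (e.g. a simulated cohort) to
    skip the file-reading stage.
    """
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.digest(),
                "stages": [], "artifacts": []}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    stage("read")
    if spectra_set is None:
        spectra_set = read_spectra(config.spectra_path, config.spectra_format,
                                   metadata=config.metadata_path or None)

    stage("qc")
    qc_path = os.path.join(outdir, "qc.json")
    qc_report(spectra_set, path=qc_path)
    manifest["artifacts"].append("qc.json")

    stage("outlier_removal")
    # exploratory representation: full range, no derivative, vector norm
    explore = apply_pipeline(
        spectra_set,
        PreprocessConfig(range="full", sg_derivative=0, normalization="vector"),
    )
    report = pcout_flag(explore, cutoff=config.outlier_cutoff)
    report.to_csv(os.path.join(outdir, "outliers.csv"))
    manifest["artifacts"].append("outliers.csv")
    cleaned = remove_outliers(spectra_set, report)

    stage("split")
    patients = _labeled_patients(cleaned)
    split = grouped_split(patients, ratio=config.split_ratio, seed=config.split_seed)
    split.to_json(os.path.join(outdir, "split.json"))
    manifest["artifacts"].append("split.json")
    train_lab = [(p, l) for p, l in patients if p in set(split.train_patients)]
    folds = stratified_group_kfold(train_lab, k=config.cv_k,
                                   repeats=config.cv_repeats, seed=config.split_seed)
    folds.to_json(os.path.join(outdir, "folds.json"))
    manifest["artifacts"].append("folds.json")

    stage("search")
    grid = enumerate_grid(config.config_space, config.models)
    records = run_search(cleaned, grid, split, folds, seed=config.search_seed)
    records_to_frame(records).to_csv(os.path.join(outdir, "records.csv"), index=False)
    manifest["artifacts"].append("records.csv")

    stage("selection")
    criteria = SelectionCriteria(config.min_cv_roc, config.min_test_f1)
    selection = select_models(records, criteria)
    _write_json({"criteria": asdict(criteria), "frequency": selection},
                os.path.join(outdir, "selection.json"))
    manifest["artifacts"].append("selection.json")

    ok = [r for r in records if not r.failed]
    if not ok:
        manifest["error"] = "every grid point failed"
        _write_json(manifest, os.path.join(outdir, "manifest.json"))
        return outdir
    # final model: best passing record, else best by (test_f1, cv_roc)
    passing = [r for r in ok if criteria.passes(r)]
    pool = passing or ok
    best = max(pool, key=lambda r: (r.test_f1, r.cv_roc))
    manifest["final_model"] = {"model": best.model, "config": best.config.to_dict(),
                               "cv_roc": best.cv_roc, "test_f1": best.test_f1,
                               "test_auroc": best.test_auroc}

    stage("revalidation")
    reval = revalidate(best.model, best.config, cleaned,
                       n_repeats=config.revalidation_repeats,
                       k=config.cv_k, cv_repeats=1)
    reval.to_csv(os.path.join(outdir, "revalidation.csv"), index=False)
    manifest["artifacts"].append("revalidation.csv")

    stage("final_fit_importance")
    profile = profile_cohort(cleaned, best.config,
                             n_permutations=config.importance_permutations,
                             seed=config.search_seed)
    profile.to_csv(os.path.join(outdir, "importance.csv"))
    manifest["artifacts"].append("importance.csv")
    manifest["importance_peaks"] = [
        {"wavenumber": w, "importance": h} for w, h in locate_peaks(profile, 5)
    ]

    _write_json(manifest, os.path.join(outdir, "manifest.json"))
    manifest_art = manifest["artifacts"] + ["manifest.json"]
    logger.info("run complete: %s (%s)", outdir, ", ".join(manifest_art))
    return outdir
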