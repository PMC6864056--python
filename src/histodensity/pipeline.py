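"""End-to-end orchestration: simulate -> extract -> model -> evaluate.

Each stage writes plain artifacts (CSV tables, JSON reports) into a run
directory and consumes only files produced by earlier stages, so any stage
can be re-run from its inputs.  All randomness flows from the named seeds
recorded in the run manifest; re-running with the same config reproduces
every numeric artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateStratumError
from .evaluation import bootstrap_auc_ci, compare_auc_bootstrap
from .features import DEFAULT_MIN_REGION_AREA, extract_cohort_features
from .io import read_map_png
from .modeling import (predict_and_correlate, stratify_by_median,
                       train_cancer_classifier, train_fgv_regressor)
from .simulate import SimulationConfig, generate_cohort

FGV_TARGETS = ("global_fgv", "localized_fgv")


@dataclass
class PipelineConfig:
    """Everything one full run needs; serialisable to/from YAML."""

    out_dir: str = "runs/default"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_region_area: float = DEFAULT_MIN_REGION_AREA
    rf_params: dict = field(default_factory=dict)
    pruning_threshold: float = 0.85
    covariates: tuple = ()
    subgroup: str | None = None          # optional menopause filter
    n_bootstrap: int = 2000
    ci_level: float = 0.95
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("simulation", {})
        cfg = cls(**data)
        cfg.simulation = SimulationConfig(**sim)
        cfg.covariates = tuple(cfg.covariates)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_maps_from_table(table: pd.DataFrame, microns_per_pixel: float,
                         base_dir: str | Path | None = None) -> dict:
    """Read the label maps referenced by a cohort table; fail fast on gaps.

    Relative ``path`` entries are resolved against ``base_dir`` (typically
    the directory holding the cohort CSV).
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    missing = [r.slide_id for r in table.itertuples(index=False)
               if not resolve(r.path).is_file()]
    if missing:
        raise FileNotFoundError(
            f"label maps missing for slide_ids: {missing[:20]}"
            + (" ..." if len(missing) > 20 else ""))
    return {r.slide_id: read_map_png(resolve(r.path), microns_per_pixel,
                                     r.slide_id)
            for r in table.itertuples(index=False)}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a summary dict (also written as JSON).

    Regression artifacts are always produced first; a degenerate
    classification stratum aborts the run *after* they are on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # stage 1: synthetic cohort
    sim = config.simulation
    table, maps = generate_cohort(sim, out_dir=out)

    # stage 2: features
    slide_df, patient_df = extract_cohort_features(
        table, maps, min_region_area=config.min_region_area)
    if config.subgroup:
        patient_df = patient_df[patient_df["menopause"] == config.subgroup]
    slide_df.to_csv(out / "features_slides.csv", index=False)
    patient_df.to_csv(out / "features_patients.csv", index=False)

    summary: dict = {"fgv_regression": {}, "classification": {},
                     "comparisons": {}}

    # stage 3: FGV regression for both density targets
    for target in FGV_TARGETS:
        model, ranking = train_fgv_regressor(
            patient_df, target, rf_params=config.rf_params, seed=seed,
            covariates=config.covariates)
        r = predict_and_correlate(model, patient_df, target)
        ranking.to_csv(out / f"ranking_{target}.csv", index=False)
        report = {"target": target, "spearman_r": r,
                  "top_features": ranking.head(10)["feature"].tolist(),
                  "n_train": int((patient_df["split"] == "train").sum()),
                  "n_test": int((patient_df["split"] == "test").sum())}
        (out / f"fgv_{target}.json").write_text(json.dumps(report, indent=2))
        summary["fgv_regression"][target] = report

    # stage 4: stratified cancer classification + evaluation
    roc_reports = []
    try:
        for target in FGV_TARGETS:
            cutpoint, strata = stratify_by_median(patient_df, target)
            stratum_scores = {}
            for level in ("high", "low"):
                part = patient_df[strata == level]
                fit = train_cancer_classifier(
                    part, rf_params=config.rf_params, seed=seed,
                    covariates=config.covariates)
                scores = fit["scores"]
                rep = bootstrap_auc_ci(
                    scores["score"], scores["truth"],
                    n_bootstrap=config.n_bootstrap, level=config.ci_level,
                    seed=seed + 101, stratum=f"{level}_{target}")
                stratum_scores[level] = scores
                fit["ranking"].to_csv(
                    out / f"ranking_cancer_{level}_{target}.csv", index=False)
                scores.to_csv(
                    out / f"scores_cancer_{level}_{target}.csv", index=False)
                rep_dict = rep.to_dict()
                rep_dict.update(cutpoint=cutpoint, n_train=fit["n_train"],
                                n_test=fit["n_test"])
                (out / f"roc_{level}_{target}.json").write_text(
                    json.dumps(rep_dict, indent=2))
                roc_reports.append(rep_dict)
                summary["classification"][f"{level}_{target}"] = rep_dict
            comp = compare_auc_bootstrap(
                stratum_scores["high"]["score"], stratum_scores["high"]["truth"],
                stratum_scores["low"]["score"], stratum_scores["low"]["truth"],
                n_bootstrap=config.n_bootstrap, seed=seed + 202)
            (out / f"auc_comparison_{target}.json").write_text(
                json.dumps(comp.to_dict(), indent=2))
            summary["comparisons"][target] = comp.to_dict()
    finally:
        manifest = {
            "config_hash": config.config_hash(),
            "seed": seed,
            "version": __version__,
            "n_patients": int(patient_df["patient_id"].nunique()),
            "n_slides": int(len(slide_df)),
            "n_roc_reports": len(roc_reports),
            "n_auc_comparisons": len(summary["comparisons"]),
            "per_stratum_counts": {
                k: {"n_train": v["n_train"], "n_test": v["n_test"]}
                for k, v in summary["classification"].items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, default=str))
    return summary
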