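"""End-to-end orchestration: simulate/load -> build -> filter -> tune -> fit
-> contributions -> validate, with a manifest of content-hashed artifacts.

A run is fully determined by its :class:`RunConfig` (which embeds every
seed); re-running the same config into a fresh directory reproduces
byte-identical artifacts.  Stage timings go to ``run.log`` only, so logs
never perturb reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contributions import contribution_stability, tissue_contributions
from .data_io import (EqtlReferenceTable, GenotypeMatrix, harmonize_alleles,
                      load_eqtl_table, load_genotypes, write_dosage_tsv,
                      write_phenotypes)
from .errors import DataError, PipelineError, ValidationError
from .feature_matrix import build_feature_matrix, standardize, write_matrix
from .feature_filter import filter_features, filter_report_frame
from .risk_model import (FittedRiskModel, HyperParams, ModelEnsemble, auc,
                         fast_grid, fit_final_model, predict_scores,
                         tune_hyperparameters)
from .synthetic_data import SimConfig, simulate_cohort, simulate_reference

logger = logging.getLogger(__name__)

_VAL_SEED_OFFSET = 1_000_003  # validation cohort uses a distinct seed stream


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source.

    Either ``sim`` (synthetic cohort) or the three real-data paths must be
    given, never both.  ``grid=None`` uses the reduced desk-scale grid
    (:func:`eqtlrank.risk_model.fast_grid`).
    """

    sim: SimConfig | None = None
    eqtl_table_path: str | None = None
    genotypes_path: str | None = None
    genotype_format: str = "tsv"
    phenotypes_path: str | None = None
    alpha: float = 0.05
    grid: list[HyperParams] | None = None
    repeats: int = 5
    folds: int = 10
    seed: int = 0
    standardize_features: bool = True
    filter_in_folds: bool = False
    n_subsets: int = 30
    subset_n_cases: int | None = None
    subset_n_controls: int | None = None

    def __post_init__(self) -> None:
        real = all(p is not None for p in
                   (self.eqtl_table_path, self.genotypes_path,
                    self.phenotypes_path))
        some_real = any(p is not None for p in
                        (self.eqtl_table_path, self.genotypes_path,
                         self.phenotypes_path))
        if self.sim is not None and some_real:
            raise ValidationError(
                "RunConfig: give either a SimConfig or real input paths, not both"
            )
        if self.sim is None and not real:
            raise ValidationError(
                "RunConfig: need a SimConfig or all three input paths"
            )

    def to_dict(self) -> dict:
        d = {
            "sim": dataclasses.asdict(self.sim) if self.sim else None,
            "eqtl_table_path": self.eqtl_table_path,
            "genotypes_path": self.genotypes_path,
            "genotype_format": self.genotype_format,
            "phenotypes_path": self.phenotypes_path,
            "alpha": self.alpha,
            "grid": [hp.to_dict() for hp in self.grid] if self.grid else None,
            "repeats": self.repeats, "folds": self.folds, "seed": self.seed,
            "standardize_features": self.standardize_features,
            "filter_in_folds": self.filter_in_folds,
            "n_subsets": self.n_subsets,
            "subset_n_cases": self.subset_n_cases,
            "subset_n_controls": self.subset_n_controls,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim"):
            sim = dict(d["sim"])
            if "maf_range" in sim and sim["maf_range"] is not None:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["sim"] = SimConfig(**sim)
        if d.get("grid"):
            d["grid"] = [HyperParams.from_dict(g) for g in d["grid"]]
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def subsample_validation(
    model: FittedRiskModel,
    gm: GenotypeMatrix,
    table: EqtlReferenceTable,
    n_subsets: int,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    ensemble: ModelEnsemble | None = None,
) -> tuple[list[float], dict]:
    """Score a validation cohort on stratified random subsets.

    Draws ``n_subsets`` subsets (without replacement within a subset,
    independently across subsets), scores each with the fitted model, and
    reports per-subset AUCs plus their mean.  When an ensemble is given the
    summary also states whether the mean falls inside the ensemble's
    2.5-97.5 fold-AUC percentile range.
    """
    fm_val, _ = build_feature_matrix(gm, table)
    scores = predict_scores(model, fm_val)
    labels = fm_val.labels
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    if n_cases > case_idx.size or n_controls > ctrl_idx.size:
        raise DataError(
            f"subset sizes ({n_cases}/{n_controls}) exceed cohort class "
            f"counts ({case_idx.size}/{ctrl_idx.size})"
        )
    rng = np.random.default_rng([seed, 11])
    aucs: list[float] = []
    for _ in range(n_subsets):
        sel = np.concatenate([
            rng.choice(case_idx, n_cases, replace=False),
            rng.choice(ctrl_idx, n_controls, replace=False),
        ])
        aucs.append(auc(scores[sel], labels[sel]))
    summary: dict = {
        "n_subsets": n_subsets,
        "subset_n_cases": n_cases,
        "subset_n_controls": n_controls,
        "aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
    }
    if ensemble is not None:
        lo, hi = ensemble.auc_range()
        summary["ensemble_auc_range"] = [lo, hi]
        summary["mean_within_ensemble_range"] = bool(lo <= summary["mean_auc"] <= hi)
    return aucs, summary


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage, writing artifacts + a manifest under ``outdir``.

    Returns the manifest dict.  Any stage error aborts with the stage name;
    artifacts of completed stages remain on disk for inspection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("eqtlrank")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stages: dict[str, dict] = {}
    state: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            artifacts = fn()
        except Exception as exc:
            root.removeHandler(handler)
            raise PipelineError(
                f"stage '{name}' failed: {exc}; partial outputs in {outdir}"
            ) from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        stages[name] = {
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }

    def stage_inputs() -> list[Path]:
        arts: list[Path] = []
        if cfg.sim is not None:
            table = simulate_reference(cfg.sim)
            gm, truth = simulate_cohort(cfg.sim, table)
            table.write_tsv(outdir / "eqtl_table.tsv")
            write_dosage_tsv(gm, outdir / "genotypes.tsv")
            write_phenotypes(gm, outdir / "phenotypes.tsv")
            truth.write_json(outdir / "truth.json")
            arts = [outdir / n for n in
                    ("eqtl_table.tsv", "genotypes.tsv", "phenotypes.tsv",
                     "truth.json")]
            state.update(table=table, gm=gm, truth=truth)
        else:
            gm_raw = load_genotypes(cfg.genotypes_path, cfg.genotype_format,
                                    cfg.phenotypes_path)
            table = load_eqtl_table(cfg.eqtl_table_path,
                                    study_snps=set(gm_raw.snp_ids))
            gm, report = harmonize_alleles(gm_raw, table)
            report.to_csv(outdir / "harmonization_report.tsv", sep="\t",
                          index=False)
            arts = [outdir / "harmonization_report.tsv"]
            state.update(table=table, gm=gm, truth=None)
        return arts

    def stage_features() -> list[Path]:
        fm, report = build_feature_matrix(state["gm"], state["table"])
        if cfg.standardize_features:
            fm = standardize(fm)
        (outdir / "feature_build_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        v, m = write_matrix(fm, outdir / "features")
        state["fm"] = fm
        return [v, m, outdir / "feature_build_report.json"]

    def stage_filter() -> list[Path]:
        fm_kept, results = filter_features(state["fm"], alpha=cfg.alpha)
        filter_report_frame(results).to_csv(outdir / "filter_report.tsv",
                                            sep="\t", index=False)
        v, m = write_matrix(fm_kept, outdir / "features_filtered")
        state["fm_kept"] = fm_kept
        return [outdir / "filter_report.tsv", v, m]

    def stage_tune() -> list[Path]:
        grid = cfg.grid if cfg.grid is not None else fast_grid()
        fm_kept = state["fm_kept"]
        if fm_kept.n_features == 0:
            # nothing survived the filter: intercept-only "ensemble"
            from .risk_model import cv_ensemble
            hp = grid[0]
            ens = cv_ensemble(fm_kept, hp, repeats=cfg.repeats,
                              folds=cfg.folds, seed=cfg.seed)
        else:
            hp, ens = tune_hyperparameters(fm_kept, grid, repeats=cfg.repeats,
                                           folds=cfg.folds, seed=cfg.seed)
        (outdir / "tuning.json").write_text(json.dumps({
            "best_hyperparams": hp.to_dict(),
            "fold_aucs": [float(a) for a in ens.fold_aucs],
            "mean_auc": ens.mean_auc, "sd_auc": ens.sd_auc,
        }, indent=1, sort_keys=True))
        (outdir / "ensemble.json").write_text(
            json.dumps(ens.to_dict(), indent=1, sort_keys=True))
        state.update(hp=hp, ensemble=ens)
        return [outdir / "tuning.json", outdir / "ensemble.json"]

    def stage_final_model() -> list[Path]:
        model = fit_final_model(state["fm_kept"], state["hp"], seed=cfg.seed)
        (outdir / "model.json").write_text(
            json.dumps(model.to_dict(), indent=1, sort_keys=True))
        state["model"] = model
        return [outdir / "model.json"]

    def stage_contributions() -> list[Path]:
        descs = state["fm"].descriptors
        report = tissue_contributions(state["model"], descs)
        report.as_frame().to_csv(outdir / "contributions.tsv", sep="\t",
                                 index=False)
        report.members_frame().to_csv(outdir / "contribution_members.tsv",
                                      sep="\t", index=False)
        stability = contribution_stability(state["ensemble"], descs)
        stability.table.to_csv(outdir / "contribution_stability.tsv",
                               sep="\t", index=False)
        state.update(contrib=report, stability=stability)
        return [outdir / "contributions.tsv",
                outdir / "contribution_members.tsv",
                outdir / "contribution_stability.tsv"]

    def stage_validation() -> list[Path]:
        if cfg.sim is None:
            (outdir / "validation.json").write_text(json.dumps(
                {"skipped": "no validation cohort configured"}, indent=1))
            return [outdir / "validation.json"]
        val_cfg = replace(cfg.sim,
                          seed=(cfg.sim.seed + _VAL_SEED_OFFSET) % (2 ** 31))
        val_table = state["table"]  # same reference table as training
        gm_val, _ = simulate_cohort(val_cfg, val_table)
        n_cases = cfg.subset_n_cases or max(10, val_cfg.n_cases // 2)
        n_controls = cfg.subset_n_controls or max(10, val_cfg.n_controls // 2)
        _, summary = subsample_validation(
            state["model"], gm_val, val_table, cfg.n_subsets, n_cases,
            n_controls, seed=cfg.seed, ensemble=state["ensemble"],
        )
        (outdir / "validation.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        state["validation"] = summary
        return [outdir / "validation.json"]

    try:
        _stage("inputs", stage_inputs)
        _stage("features", stage_features)
        _stage("filter", stage_filter)
        _stage("tune", stage_tune)
        _stage("final_model", stage_final_model)
        _stage("contributions", stage_contributions)
        _stage("validation", stage_validation)
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
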