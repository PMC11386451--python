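"""End-to-end experiment drivers.

The full flow: simulate a cohort, decompose the MSI class by a genomic
scheme, balance patches, build stratified patient folds, train a binary
baseline and a three-class decomposed model per fold on byte-identical
patch sets, score the held-out test cohort patient-wise, and compare the
two fold-wise.  A second driver fuses two decomposed models (SNP- and
CIMP-keyed) through the probability-level MLP.

All randomness derives from one master seed per repetition via fixed
offsets, so every artifact is reproducible from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .aggregation import aggregate, combine_predict, train_fusion
from .classifier import TrainedModel, TrainingConfig, predict, train
from .cohort_prep import FoldAssignment, balance_patches, stratified_folds
from .evaluation import MetricReport, auroc, paired_fold_test
from .sublabels import (
    SubLabelScheme,
    apply_training_exclusion,
    assign_sublabels,
    cimp_scheme,
    snp_scheme,
)
from .synthetic_cohort import GeneratorConfig, PatchRecord, PatientRecord, generate_cohort

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "run_combined_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scheme: SubLabelScheme = field(default_factory=snp_scheme)
    k: int = 5
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seeds: Sequence[int] = (0,)
    output_dir: str | Path | None = None

    def validate(self) -> None:
        self.generator.validate()
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class ExperimentResult:
    baseline: MetricReport
    bp: MetricReport
    comparison: dict

    def to_json(self) -> dict:
        return {
            "baseline": self.baseline.summary(),
            "bp": self.bp.summary(),
            "comparison": self.comparison,
            "version": __version__,
        }


def _patient_patches(
    patches: Sequence[PatchRecord], ids: set[str]
) -> list[PatchRecord]:
    return [q for q in patches if q.patient_id in ids]


def _prepare_seed(
    config: ExperimentConfig, seed: int
) -> tuple[
    list[PatientRecord], list[PatchRecord], dict, dict[str, str],
    list[PatchRecord], FoldAssignment, list[PatchRecord],
]:
    """Generate one repetition's cohort and training material."""
    gen = replace(config.generator, seed=seed)
    patients, patches, images = generate_cohort(gen)
    train_patients = [p for p in patients if p.split == "train"]
    test_patients = [p for p in patients if p.split == "test"]

    sublab = assign_sublabels(patients, config.scheme)
    kept_train = apply_training_exclusion(train_patients, config.scheme)
    kept_ids = {p.patient_id for p in kept_train}

    train_patches = _patient_patches(patches, kept_ids)
    base_labels = {q.patch_id: q.base_label for q in patches}
    balanced = balance_patches(
        train_patches, base_labels, np.random.default_rng(seed + 1_000_003)
    )
    balanced_ids = {q.patient_id for q in balanced}
    fold_patients = [p for p in kept_train if p.patient_id in balanced_ids]
    folds = stratified_folds(fold_patients, sublab, k=config.k, seed=seed)

    test_patches = _patient_patches(patches, {p.patient_id for p in test_patients})
    return patients, patches, images, sublab, balanced, folds, test_patches


def _train_fold_pair(
    balanced: Sequence[PatchRecord],
    folds: FoldAssignment,
    fold: int,
    sublab: Mapping[str, str],
    scheme: SubLabelScheme,
    training: TrainingConfig,
    images,
    cache,
    seed: int,
) -> tuple[TrainedModel, TrainedModel]:
    """Baseline (2-class) and decomposed (3-class) models on identical data."""
    val_ids = set(folds.patients_in_fold(fold))
    tr = [q for q in balanced if q.patient_id not in val_ids]
    va = [q for q in balanced if q.patient_id in val_ids]
    base_labels = {q.patch_id: q.base_label for q in tr + va}
    sub_labels = {q.patch_id: sublab[q.patient_id] for q in tr + va}
    model_seed = seed * 1000 + fold
    cfg2 = replace(training, n_classes=2, seed=model_seed)
    cfg3 = replace(training, n_classes=3, seed=model_seed)
    baseline = train(tr, va, base_labels, cfg2, images, cache, class_names=["MSS", "MSI"])
    bp = train(tr, va, sub_labels, cfg3, images, cache, class_names=scheme.class_names)
    return baseline, bp


def _test_scores(
    model: TrainedModel, test_patches: Sequence[PatchRecord], images, cache
) -> tuple[np.ndarray, np.ndarray]:
    preds = predict(model, test_patches, images, cache)
    scores = aggregate(preds)
    truth = {q.patient_id: 1 if q.base_label == "MSI" else 0 for q in test_patches}
    y = np.array([truth[pid] for pid in scores["patient_id"]])
    return scores["p_msi"].to_numpy(), y


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Paired baseline-vs-decomposed comparison over folds and seeds.

    For every (seed, fold): the two heads are trained on byte-identical
    balanced patch sets and fold splits, and both are scored on the same
    held-out test cohort.  The paired t-test is computed across per-seed
    mean test AUROCs (and, as a secondary view, across all fold values).
    """
    config.validate()
    base_scores: list[tuple[np.ndarray, np.ndarray]] = []
    bp_scores: list[tuple[np.ndarray, np.ndarray]] = []
    per_seed_base: list[float] = []
    per_seed_bp: list[float] = []

    for seed in config.seeds:
        logger.info("experiment seed %d: generating cohort", seed)
        _, _, images, sublab, balanced, folds, test_patches = _prepare_seed(config, seed)
        cache: dict = {}
        seed_base, seed_bp = [], []
        for fold in range(config.k):
            baseline, bp = _train_fold_pair(
                balanced, folds, fold, sublab, config.scheme,
                config.training, images, cache, seed,
            )
            sb, yb = _test_scores(baseline, test_patches, images, cache)
            sp, yp = _test_scores(bp, test_patches, images, cache)
            base_scores.append((sb, yb))
            bp_scores.append((sp, yp))
            seed_base.append(auroc(sb, yb))
            seed_bp.append(auroc(sp, yp))
            logger.info(
                "seed %d fold %d: baseline AUROC %.3f, decomposed AUROC %.3f",
                seed, fold, seed_base[-1], seed_bp[-1],
            )
        per_seed_base.append(float(np.mean(seed_base)))
        per_seed_bp.append(float(np.mean(seed_bp)))

    base_report = MetricReport.from_folds(*zip(*[(s, y) for s, y in base_scores]))
    bp_report = MetricReport.from_folds(*zip(*[(s, y) for s, y in bp_scores]))
    comparison: dict = {
        "per_seed_mean_auroc_baseline": per_seed_base,
        "per_seed_mean_auroc_bp": per_seed_bp,
        "mean_auroc_baseline": float(np.mean(per_seed_base)),
        "mean_auroc_bp": float(np.mean(per_seed_bp)),
        "mean_auroc_difference": float(np.mean(per_seed_bp) - np.mean(per_seed_base)),
    }
    if len(config.seeds) >= 2:
        comparison["paired_t_across_seeds"] = paired_fold_test(per_seed_bp, per_seed_base)
    comparison["paired_t_across_folds"] = paired_fold_test(
        bp_report.auroc_per_fold, base_report.auroc_per_fold
    )
    base_report.paired_t_p = comparison["paired_t_across_folds"]["p"]

    result = ExperimentResult(baseline=base_report, bp=bp_report, comparison=comparison)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = result.to_json()
        payload["provenance"] = {
            "generator": asdict(config.generator),
            "scheme": asdict(config.scheme),
            "training": asdict(config.training),
            "k": config.k,
            "seeds": list(config.seeds),
        }
        (out / "metrics.json").write_text(json.dumps(payload, indent=2, default=str))
    return result


def run_combined_experiment(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    k: int = 5,
    seeds: Sequence[int] = (0, 1, 2),
    fusion_epochs: int = 300,
    fusion_batch_size: int = 64,
) -> dict:
    """Fuse SNP- and CIMP-decomposed models through the 6-input MLP.

    Per seed, a cross-validated stacking protocol: each constituent is
    trained once per fold of a shared stratified partition (the CIMP
    constituent keeps its MSS/CIMP-H training exclusion); the fusion MLP
    trains on the pooled *out-of-fold* constituent predictions — every
    training patch scored by the one model that did not see it — and is
    applied to the fold-averaged constituent predictions on the test
    cohort.  Constituent reference AUROCs use the same fold-averaged
    test predictions, so the combined model is compared against exactly
    the inputs it consumes.
    """
    import pandas as pd

    generator = generator or GeneratorConfig()
    training = training or TrainingConfig()
    schemes = {"snp": snp_scheme(), "cimp": cimp_scheme()}
    out: dict = {"per_seed": []}

    for seed in seeds:
        gen = replace(generator, seed=seed)
        patients, patches, images = generate_cohort(gen)
        train_patients = [p for p in patients if p.split == "train"]
        test_patches = _patient_patches(
            patches, {p.patient_id for p in patients if p.split == "test"}
        )
        base_labels = {q.patch_id: q.base_label for q in patches}
        truth = {q.patient_id: 1 if q.base_label == "MSI" else 0 for q in test_patches}
        cache: dict = {}

        # shared fold partition, stratified on the SNP sub-labels
        snp_sub = assign_sublabels(patients, schemes["snp"])
        balanced_all = balance_patches(
            _patient_patches(patches, {p.patient_id for p in train_patients}),
            base_labels,
            np.random.default_rng(seed + 1_000_003),
        )
        fold_patients = [
            p for p in train_patients
            if p.patient_id in {q.patient_id for q in balanced_all}
        ]
        folds = stratified_folds(fold_patients, snp_sub, k=k, seed=seed)

        oof_preds = {}
        test_mean_preds = {}
        constituent_auroc = {}
        for name, scheme in schemes.items():
            sublab = assign_sublabels(patients, scheme)
            kept = {p.patient_id for p in apply_training_exclusion(train_patients, scheme)}
            oof_parts, test_parts = [], []
            for fold in range(k):
                val_ids = set(folds.patients_in_fold(fold))
                tr = [
                    q for q in balanced_all
                    if q.patient_id not in val_ids and q.patient_id in kept
                ]
                va = [q for q in balanced_all if q.patient_id in val_ids]
                sub_labels = {q.patch_id: sublab[q.patient_id] for q in tr + va}
                cfg3 = replace(
                    training, n_classes=3,
                    seed=seed * 1000 + 100 * fold + (7 if name == "cimp" else 3),
                )
                model = train(
                    tr, va, sub_labels, cfg3, images, cache, class_names=scheme.class_names
                )
                oof_parts.append(predict(model, va, images, cache))
                test_parts.append(
                    predict(model, test_patches, images, cache)
                    .sort_values("patch_id")
                    .reset_index(drop=True)
                )
            oof_preds[name] = pd.concat(oof_parts, ignore_index=True)
            mean_tbl = test_parts[0][["patch_id", "patient_id"]].copy()
            for col in test_parts[0].columns[2:]:
                mean_tbl[col] = np.mean([tp[col].to_numpy() for tp in test_parts], axis=0)
            test_mean_preds[name] = mean_tbl
            scores = aggregate(mean_tbl)
            y = np.array([truth[pid] for pid in scores["patient_id"]])
            constituent_auroc[name] = auroc(scores["p_msi"].to_numpy(), y)

        fusion = train_fusion(
            oof_preds["snp"],
            oof_preds["cimp"],
            base_labels,
            epochs=fusion_epochs,
            batch_size=fusion_batch_size,
            seed=seed,
        )
        combined = combine_predict(
            test_mean_preds["snp"], test_mean_preds["cimp"], fusion
        )
        scores = aggregate(combined)
        y = np.array([truth[pid] for pid in scores["patient_id"]])
        combined_auroc = auroc(scores["p_msi"].to_numpy(), y)
        out["per_seed"].append(
            {
                "seed": seed,
                "auroc_snp": constituent_auroc["snp"],
                "auroc_cimp": constituent_auroc["cimp"],
                "auroc_combined": combined_auroc,
                "max_constituent": max(constituent_auroc.values()),
            }
        )
        logger.info(
            "combined seed %d: snp %.3f cimp %.3f combined %.3f",
            seed, constituent_auroc["snp"], constituent_auroc["cimp"], combined_auroc,
        )

    out["mean_combined"] = float(np.mean([r["auroc_combined"] for r in out["per_seed"]]))
    out["mean_max_constituent"] = float(
        np.mean([r["max_constituent"] for r in out["per_seed"]])
    )
    return out
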