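"""End-to-end synthetic replication experiment.

Generates a training cohort and a disjoint test cohort of pelvic phantoms,
trains the baseline segmentation networks (one per structure), fine-tunes a
patient-specific network per test patient, trains one deformation network,
runs the classical benchmarks (rigid contour copying, multi-stage B-spline
registration with contour propagation), evaluates every method on every test
fraction with the DSC/HD95/HDavg protocol, and writes the metrics table,
statistics report and a manifest.

The data split mirrors the clinical design: generic models never see test
patients; patient-specific fine-tuning uses only the test patient's own
planning scan; all methods share the same test fractions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmarks import (BsplineStage, bspline_register, default_stages,
                         propagate_contours, realistic_ddf_pool, rigid_copy)
from .evaluation import (aggregate, crop_to_slices, evaluate_structure,
                         EvalRecord, records_to_frame, rectum_eval_region,
                         render_report)
from .grid_ops import crop_around_centroid
from .losses import ConfigurationError, LossWeights
from .network import NetworkSpec, predict_ddf, predict_segmentation
from .phantom import (AnatomyParams, AnatomyPrior, PatientCase,
                      VariationParams, derive_ptv, make_cohort)
from .training import (AugmentParams, TrainingConfig, finetune_patient,
                       make_supervised_pairs, pairs_from_cases, train_baseline,
                       train_ddfm)

log = logging.getLogger("contourprop")

ALL_STAGES = ("phantom", "train", "benchmark", "predict", "evaluate", "stats")
METHODS = ("copy", "bspline", "bm", "ddfm", "psm")


class SplitError(ValueError):
    """A test patient leaks into generic-model training."""


@dataclass
class ExperimentConfig:
    out_dir: str = "experiment_out"
    seed: int = 0
    # cohorts
    n_train_patients: int = 5
    n_test_patients: int = 3
    n_fractions: int = 3
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: float = 3.0
    crop_shape: tuple[int, int, int] = (24, 24, 24)
    center_jitter_mm: float = 2.5
    axes_jitter_frac: float = 0.12
    train_variation: VariationParams = field(default_factory=VariationParams)
    test_variation: VariationParams = field(default_factory=VariationParams)
    structures: tuple[str, ...] = ("bladder", "rectum", "ctv")
    # networks & training
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        n_levels=4, base_channels=4))
    bm: TrainingConfig | None = None
    psm: TrainingConfig | None = None
    ddfm: TrainingConfig | None = None
    # benchmark
    stages: list[BsplineStage] | None = None
    # evaluation
    ptv_margin_mm: float = 5.0
    rectum_margin_mm: float = 15.0
    ddfm_rigid_ctv: bool = False
    bm_training_ids: list[str] | None = None
    save_volumes: bool = False

    def __post_init__(self):
        if self.bm is None:
            self.bm = TrainingConfig(regime="BM", epochs=40, batch_size=2,
                                     learning_rate=1e-3, network=self.network,
                                     seed=self.seed)
        if self.psm is None:
            self.psm = TrainingConfig(regime="PSM", epochs=40, batch_size=1,
                                      learning_rate=1e-4, network=self.network,
                                      seed=self.seed + 1,
                                      augmentation=AugmentParams())
        if self.ddfm is None:
            self.ddfm = TrainingConfig(regime="DDFM",
                                       ddfm_data_variant="true_pairs",
                                       schedule="at_once", epochs=40,
                                       batch_size=2, learning_rate=1e-3,
                                       weights=LossWeights(),
                                       network=self.network,
                                       seed=self.seed + 2)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("train_variation", "test_variation"):
            if key in d and isinstance(d[key], dict):
                d[key] = VariationParams(**_tupled(d[key]))
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkSpec(**d["network"])
        for key in ("bm", "psm", "ddfm"):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if "weights" in sub and isinstance(sub["weights"], dict):
                    sub["weights"] = LossWeights(**sub["weights"])
                if "augmentation" in sub and isinstance(sub["augmentation"], dict):
                    sub["augmentation"] = AugmentParams(**_tupled(sub["augmentation"]))
                if "network" in sub and isinstance(sub["network"], dict):
                    sub["network"] = NetworkSpec(**sub["network"])
                elif "network" not in sub and "network" in d:
                    sub["network"] = d["network"]
                d[key] = TrainingConfig(**_tupled(sub))
        if "stages" in d and d["stages"] is not None:
            d["stages"] = [BsplineStage(**s) if isinstance(s, dict) else s
                           for s in d["stages"]]
        return cls(**_tupled(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def manifest_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) and k.endswith(
        ("shape", "range", "scales", "structures")) else v
        for k, v in d.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class Finding:
    fatal: bool
    message: str


def validate_config(config: ExperimentConfig) -> list[Finding]:
    """Static checks: grid divisibility, weight sanity, split integrity."""
    findings: list[Finding] = []
    div = config.network.divisor
    if any(s % div for s in config.crop_shape):
        findings.append(Finding(True, f"crop shape {config.crop_shape} not "
                                f"divisible by 2^(n_levels-1)={div}"))
    for name, tc in (("bm", config.bm), ("psm", config.psm), ("ddfm", config.ddfm)):
        try:
            tc.validate()
        except Exception as exc:  # noqa: BLE001
            findings.append(Finding(True, f"{name} training config: {exc}"))
    for vname, var in (("train_variation", config.train_variation),
                       ("test_variation", config.test_variation)):
        try:
            var.validate()
        except Exception as exc:  # noqa: BLE001
            findings.append(Finding(True, f"{vname}: {exc}"))
    if config.bm_training_ids:
        test_ids = {f"te{i:03d}" for i in range(config.n_test_patients)}
        leaking = sorted(set(config.bm_training_ids) & test_ids)
        if leaking:
            findings.append(Finding(True, f"test patient(s) {leaking} appear "
                                    "in the generic-model training list"))
    if config.n_train_patients < 2:
        findings.append(Finding(True, "need at least 2 training patients"))
    return findings


def _crop_case(case: PatientCase, crop_shape) -> PatientCase:
    img, st = crop_around_centroid(case.planning_image, case.planning_structures,
                                   "ctv", crop_shape)
    fracs = []
    for fr in case.fractions:
        fi, fs = crop_around_centroid(fr.image, fr.structures, "ctv", crop_shape)
        fracs.append(dataclasses.replace(fr, image=fi, structures=fs))
    return dataclasses.replace(case, planning_image=img, planning_structures=st,
                               fractions=fracs)


def _make_cohorts(config: ExperimentConfig):
    base = AnatomyParams(grid_shape=tuple(config.grid_shape),
                         spacing_mm=(config.spacing_mm,) * 3)
    prior = AnatomyPrior(base=base, center_jitter_mm=config.center_jitter_mm,
                         axes_jitter_frac=config.axes_jitter_frac)
    train = make_cohort(config.n_train_patients, prior, config.train_variation,
                        seed=config.seed * 1000 + 11,
                        n_fractions=config.n_fractions)
    test = make_cohort(config.n_test_patients, prior, config.test_variation,
                       seed=config.seed * 1000 + 22,
                       n_fractions=config.n_fractions)
    for i, c in enumerate(train):
        c.patient_id = f"tr{i:03d}"
    for i, c in enumerate(test):
        c.patient_id = f"te{i:03d}"
    train = [_crop_case(c, config.crop_shape) for c in train]
    test = [_crop_case(c, config.crop_shape) for c in test]
    return train, test


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    report_md: str
    manifest: dict
    out_dir: Path


def run_experiment(config: ExperimentConfig,
                   stages: tuple[str, ...] = ALL_STAGES) -> ExperimentResult:
    """Run the full comparison; returns the metric records and report."""
    findings = validate_config(config)
    fatal = [f for f in findings if f.fatal]
    if fatal:
        if any("training list" in f.message for f in fatal):
            raise SplitError("; ".join(f.message for f in fatal))
        raise ConfigurationError("; ".join(f.message for f in fatal))

    out = Path(config.out_dir)
    for sub in ("cohorts", "checkpoints", "metrics", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for m in METHODS:
        (out / "predictions" / m).mkdir(parents=True, exist_ok=True)

    log.info("stage=phantom generating cohorts")
    train_cohort, test_cohort = _make_cohorts(config)
    bm_ids = config.bm_training_ids or [c.patient_id for c in train_cohort]
    test_ids = {c.patient_id for c in test_cohort}
    leak = sorted(set(bm_ids) & test_ids)
    if leak:
        raise SplitError(f"test patient(s) {leak} appear in generic-model training")
    bm_cases = [c for c in train_cohort if c.patient_id in bm_ids]

    models: dict = {}
    if "train" in stages:
        for s in config.structures:
            log.info("stage=train regime=BM structure=%s", s)
            models[("bm", s)] = train_baseline(bm_cases, s, config.bm)
            models[("bm", s)].save(out / "checkpoints" / f"bm_{s}.npz")
        for case in test_cohort:
            for s in config.structures:
                log.info("stage=train regime=PSM patient=%s structure=%s",
                         case.patient_id, s)
                models[("psm", case.patient_id, s)] = finetune_patient(
                    models[("bm", s)], case, s, config.psm)
        log.info("stage=train regime=DDFM variant=%s",
                 config.ddfm.ddfm_data_variant)
        if config.ddfm.ddfm_data_variant == "true_pairs":
            pairs = pairs_from_cases(train_cohort, config.structures)
        elif config.ddfm.ddfm_data_variant == "gt_synthetic_ddf":
            pairs = make_supervised_pairs(train_cohort, n_per_case=max(
                1, config.n_fractions), structures=config.structures,
                seed=config.seed + 7)
        else:  # gt_realistic_ddf
            pool = realistic_ddf_pool(train_cohort, config.stages)
            pairs = make_supervised_pairs(train_cohort, n_per_case=max(
                1, config.n_fractions), structures=config.structures,
                realistic_pool=pool, seed=config.seed + 7)
        models["ddfm"] = train_ddfm(pairs, config.ddfm)
        models["ddfm"].save(out / "checkpoints" / "ddfm.npz")
        _write_history(models, out / "checkpoints")

    records: list[EvalRecord] = []
    if "predict" in stages or "evaluate" in stages:
        for case in test_cohort:
            ptv = derive_ptv(case.planning_structures.masks["ctv"],
                             config.ptv_margin_mm, case.planning_structures.spacing_mm)
            z_range = rectum_eval_region(ptv, config.spacing_mm,
                                         config.rectum_margin_mm)
            for k, frac in enumerate(case.fractions):
                preds = {}
                preds["copy"] = rigid_copy(case.planning_structures,
                                           frac.image).masks
                if "benchmark" in stages:
                    ddf_b = bspline_register(frac.image, case.planning_image,
                                             config.stages)
                    preds["bspline"] = propagate_contours(
                        case.planning_structures, ddf_b).masks
                if "train" in stages:
                    ddf_n = predict_ddf(models["ddfm"], case.planning_image,
                                        frac.image)
                    preds["ddfm"] = propagate_contours(
                        case.planning_structures, ddf_n,
                        rigid_ctv=config.ddfm_rigid_ctv).masks
                    preds["bm"] = {s: (predict_segmentation(
                        models[("bm", s)], frac.image) > 0.5).astype(np.uint8)
                        for s in config.structures}
                    preds["psm"] = {s: (predict_segmentation(
                        models[("psm", case.patient_id, s)],
                        frac.image) > 0.5).astype(np.uint8)
                        for s in config.structures}
                for method, masks in preds.items():
                    for s in config.structures:
                        truth = frac.structures.masks[s]
                        pred = masks[s]
                        if s == "rectum":
                            pred = crop_to_slices(pred, z_range)
                            truth = crop_to_slices(truth, z_range)
                        d, h95, havg = evaluate_structure(
                            pred, truth, frac.structures.spacing_mm)
                        records.append(EvalRecord(case.patient_id, k, s,
                                                  method, d, h95, havg))
                        log.info("stage=evaluate patient=%s fraction=%d "
                                 "structure=%s method=%s dsc=%.3f",
                                 case.patient_id, k, s, method, d)
                if config.save_volumes:
                    from . import nifti
                    for method, masks in preds.items():
                        for s, m in masks.items():
                            nifti.save_mask(
                                m, frac.structures.spacing_mm,
                                frac.structures.origin_mm,
                                out / "predictions" / method /
                                f"{case.patient_id}_f{k:02d}_{s}.nii.gz")

    df = records_to_frame(records) if records else pd.DataFrame()
    report_md = ""
    if not df.empty:
        df.to_csv(out / "metrics" / "metrics.csv", index=False)
        if "stats" in stages:
            report_md = render_report(df, structures=config.structures)
            stats_rows = []
            for s in config.structures:
                for metric in ("dsc", "hd95_mm", "hdavg_mm"):
                    cs = aggregate(df, metric=metric, structure=s)
                    for _, row in cs.pairwise.iterrows():
                        stats_rows.append({"structure": s, "metric": metric,
                                           **row.to_dict()})
            pd.DataFrame(stats_rows).to_csv(out / "metrics" / "pairwise_tests.csv",
                                            index=False)
            (out / "report" / "report.md").write_text(report_md)

    manifest = {"config_hash": config.manifest_hash(), "seed": config.seed,
                "version": __version__,
                "stages": list(stages),
                "n_records": len(records),
                "config": _jsonable(dataclasses.asdict(config))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(df, report_md, manifest, out)


def _write_history(models: dict, directory: Path) -> None:
    rows = []
    for key, model in models.items():
        if not hasattr(model, "history"):
            continue
        name = key if isinstance(key, str) else "_".join(str(k) for k in key)
        for entry in model.history:
            rows.append({"model": name, **entry})
    if rows:
        pd.DataFrame(rows).to_csv(directory / "training_log.csv", index=False)
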