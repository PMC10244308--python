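"""End-to-end reproducible runs: generate -> preprocess -> train -> score -> evaluate.

A :class:`RunConfig` bundles the cohort design, preprocessing rules (patch
side, stride, the 50-pixel background limit, registration quality floor),
model settings and evaluation settings (128 patches per cohort per bootstrap
replicate, 10 replicates, T_exam grid, alpha = 0.05). ``run_pipeline``
executes all stages, records every subject exclusion with a reason code, and
returns a JSON-serializable report whose content hash is reproducible under a
fixed seed.

The single global seed fans out to per-stage and per-subject seeds (CRC-based,
so a subject's patches do not depend on cohort ordering).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import scoring
from .fanogan import (AnomalyModel, ModelConfig, anomaly_score, save_model,
                      train_encoder, train_wgan)
from .preprocess import (DifferenceVolume, compute_difference, compute_norm_stats,
                         consecutive_negative_pairs, extract_lesion_patches,
                         extract_random_patches, normalize_patch,
                         register_followup, segment_breast)
from .synthetic import CohortConfig, Cohort, ConfigError, generate_cohort

__all__ = ["RunConfig", "validate_config", "run_pipeline", "smoke_config",
           "report_hash"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    patch_side: int = 64
    stride: int = 16
    background_limit: int = 50
    registration_enabled: bool = True
    registration_floor: float = 0.85
    use_generator_masks: bool = True   # synthetic passthrough vs Otsu segmentation
    n_normal_patches_train: int = 200  # per training-subject difference exam
    n_normal_patches_eval: int = 200   # per evaluation-subject difference exam
    n_lesion_patches: int = 30         # per positive subject
    n_per_group: int = 128
    n_replicates: int = 10
    t_exam_grid: tuple = ev.DEFAULT_T_EXAM_GRID
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["model"] = self.model.to_dict()
        d["t_exam_grid"] = [float(t) for t in self.t_exam_grid]
        return d


def smoke_config(seed: int = 0) -> RunConfig:
    """Desk-scale configuration: small volumes, 8x8 patches, short training."""
    cohort = CohortConfig(
        n_negative=24, n_positive=16, n_visits=3,
        volume_shape=(6, 32, 32), tissue_corr_len=3.0, tissue_amp=0.25,
        drift_sigma=0.01, deform_amp=0.5, noise_sigma=0.02,
        lesion_contrast=0.7, precursor_contrast=0.2, lesion_radius_vox=2.5,
        scanner_shift_prob=0.3, seed=seed)
    model = ModelConfig(patch_side=8, latent_dim=8, width=64, batch_size=32,
                        critic_steps=5, gen_steps=150, encoder_steps=300,
                        seed=seed)
    return RunConfig(cohort=cohort, model=model, patch_side=8, stride=8,
                     n_normal_patches_train=250, n_normal_patches_eval=250,
                     n_lesion_patches=30, seed=seed)


def study_config(seed: int = 0) -> RunConfig:
    """Evaluation-scale conditions: ~70 examinations, stable exam-level fit.

    Same voxel scale and model as :func:`smoke_config` but with enough
    validation/test subjects for a powered logistic regression and bootstrap
    sampling without replacement at 128 patches per cohort per replicate.
    """
    config = smoke_config(seed)
    config.cohort.n_negative = 60
    config.cohort.n_positive = 40
    return config


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations across the nested configuration (empty = ok)."""
    v = list(config.cohort.violations())
    _, ny, nx = config.cohort.volume_shape if len(config.cohort.volume_shape) == 3 \
        else (1, 0, 0)
    if config.patch_side < 1:
        v.append(f"patch_side must be >= 1, got {config.patch_side}")
    elif config.patch_side > min(ny, nx):
        v.append(
            f"patch_side {config.patch_side} exceeds in-plane volume extent "
            f"({ny}, {nx})")
    if config.model.patch_side != config.patch_side:
        v.append(
            f"model.patch_side {config.model.patch_side} != pipeline patch_side "
            f"{config.patch_side}")
    if config.stride < 1:
        v.append(f"stride must be >= 1, got {config.stride}")
    if config.background_limit < 0:
        v.append(f"background_limit must be >= 0, got {config.background_limit}")
    if not 0 <= config.registration_floor <= 1:
        v.append(f"registration_floor must be in [0,1], got {config.registration_floor}")
    if config.n_per_group < 1 or config.n_replicates < 1:
        v.append("n_per_group and n_replicates must be >= 1")
    if not 0 < config.alpha < 1:
        v.append(f"alpha must be in (0,1), got {config.alpha}")
    for name in ("n_normal_patches_train", "n_normal_patches_eval",
                 "n_lesion_patches"):
        if getattr(config, name) < 1:
            v.append(f"{name} must be >= 1")
    return v


def _subject_seed(global_seed: int, subject_id: str, stage: int) -> int:
    return (zlib.crc32(subject_id.encode()) ^ (global_seed & 0x7FFFFFFF)
            ^ (stage * 0x9E3779B1)) & 0x7FFFFFFF


def _prepare_subject(subj, config: RunConfig, exclusions: list[dict]
                     ) -> list[DifferenceVolume] | None:
    """Segment/register a subject's visits and return its difference exams."""
    visits = subj.visits
    if not config.use_generator_masks:
        for v, visit in enumerate(visits):
            mask, reason = segment_breast(visit.volume)
            if reason is not None:
                exclusions.append({"subject_id": subj.subject_id,
                                   "reason": reason, "visit": v})
                return None
            visit.mask = mask
    if config.registration_enabled:
        ref = visits[0]
        for v in range(1, len(visits)):
            reg = register_followup(visits[v].volume, visits[v].mask,
                                    ref.volume, ref.mask,
                                    quality_floor=config.registration_floor)
            if reg.excluded:
                exclusions.append({"subject_id": subj.subject_id,
                                   "reason": reg.exclusion, "visit": v,
                                   "quality": reg.quality})
                return None
            visits[v].volume = reg.volume
            visits[v].mask = reg.mask & visits[v].mask
    diffs = []
    for (i, j) in consecutive_negative_pairs(subj):
        diffs.append(compute_difference(visits[i], visits[j], pair=(i, j),
                                        subject_id=subj.subject_id))
    return diffs


def run_pipeline(config: RunConfig, outdir: str | Path | None = None,
                 cohort: Cohort | None = None) -> dict:
    """Execute all stages and return the run report.

    ``cohort`` may be supplied to reuse an existing (e.g. loaded) cohort;
    otherwise it is generated from ``config.cohort``. With ``outdir`` set,
    artifacts (report JSON, exam-score CSV, model checkpoint) are written.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid run configuration: " + "; ".join(violations))
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    split_of = dict(cohort.manifest.groupby("subject_id")["split"].first())
    exclusions: list[dict] = []

    diffs_by_subject: dict[str, list[DifferenceVolume]] = {}
    for subj in cohort.subjects:
        diffs = _prepare_subject(subj, config, exclusions)
        if diffs is not None:
            diffs_by_subject[subj.subject_id] = diffs

    # --- patch extraction --------------------------------------------------
    train_patches = []
    eval_normal: dict[str, list] = {"validation": [], "test": []}
    lesion_by_subject: dict[str, list] = {}
    for subj in cohort.subjects:
        sid = subj.subject_id
        if sid not in diffs_by_subject:
            continue
        split = split_of[sid]
        diffs = diffs_by_subject[sid]
        if subj.cohort == "negative":
            n_want = (config.n_normal_patches_train if split == "train"
                      else config.n_normal_patches_eval)
            for diff in diffs:
                res = extract_random_patches(
                    diff, n_want, p=config.patch_side,
                    rng_seed=_subject_seed(config.seed, sid, diff.visit_pair[0]),
                    background_limit=config.background_limit)
                if res.exclusion:
                    exclusions.append({"subject_id": sid, "reason": res.exclusion,
                                       "visit_pair": list(diff.visit_pair)})
                    continue
                if split == "train":
                    train_patches.extend(res.patches)
                else:
                    eval_normal[split].extend(res.patches)
        else:
            diff = diffs[-1]  # last negative/negative difference: precursor exam
            res = extract_lesion_patches(
                diff, subj.lesion_mask, p=config.patch_side,
                n_per_lesion=config.n_lesion_patches,
                rng_seed=_subject_seed(config.seed, sid, 7),
                background_limit=config.background_limit)
            if res.exclusion:
                exclusions.append({"subject_id": sid, "reason": res.exclusion})
            else:
                lesion_by_subject[sid] = res.patches

    if not train_patches:
        raise RuntimeError("pipeline halted at patch extraction: "
                           "no training patches survived")

    # --- normalization + model training ------------------------------------
    norm_stats = compute_norm_stats(train_patches)
    xtrain = np.stack([normalize_patch(p, norm_stats) for p in train_patches])
    model_config = ModelConfig(**{**config.model.to_dict(), "seed": config.seed})
    G, D, gan_log = train_wgan(xtrain, model_config)
    E, enc_log = train_encoder(xtrain, G, D, model_config)
    model = AnomalyModel(G=G, D=D, E=E, config=model_config,
                         norm_stats=norm_stats, k=model_config.k)

    def _score(patches) -> np.ndarray:
        if not patches:
            return np.zeros(0)
        x = np.stack([normalize_patch(p, norm_stats) for p in patches])
        return np.atleast_1d(anomaly_score(x, model).L)

    pools = {}
    for split in ("validation", "test"):
        pools[f"{split}_normal"] = _score(eval_normal[split])
        lesions = [p for sid, ps in lesion_by_subject.items()
                   if split_of[sid] == split for p in ps]
        pools[f"{split}_lesion"] = _score(lesions)

    # --- patch-level evaluation --------------------------------------------
    def _boot(split: str):
        pos = pools[f"{split}_lesion"]
        neg = pools[f"{split}_normal"]
        if pos.size == 0 or neg.size == 0:
            return None
        return ev.bootstrap_roc(pos, neg, n_per_group=config.n_per_group,
                                n_replicates=config.n_replicates,
                                seed=_subject_seed(config.seed, split, 11))

    val_boot = _boot("validation")
    test_boot = _boot("test")
    if val_boot is not None:
        patch_threshold = float(np.mean(
            [r.youden_threshold for r in val_boot.replicates]))
    elif test_boot is not None:
        patch_threshold = float(np.mean(
            [r.youden_threshold for r in test_boot.replicates]))
    else:
        raise RuntimeError("pipeline halted at patch evaluation: "
                           "no evaluable patch pools")

    # --- examination-level evaluation --------------------------------------
    exam_rows = []
    final_grade = {s.subject_id: s.visits[-1].grade for s in cohort.subjects}
    for subj in cohort.subjects:
        sid = subj.subject_id
        if sid not in diffs_by_subject or split_of[sid] == "train":
            continue
        diffs = diffs_by_subject[sid]
        exam_diffs = diffs if subj.cohort == "negative" else [diffs[-1]]
        for diff in exam_diffs:
            amap = scoring.sliding_window_map(diff, model, stride=config.stride)
            if not np.isfinite(amap.values).any():
                exclusions.append({"subject_id": sid,
                                   "reason": "no evaluable tissue",
                                   "visit_pair": list(diff.visit_pair)})
                continue
            binary = scoring.classify_voxels(amap, patch_threshold)
            exam = scoring.exam_level_score(binary, amap, patch_threshold)
            exam_rows.append({
                "subject_id": sid,
                "visit_pair": list(diff.visit_pair),
                "split": split_of[sid],
                "score": exam.score,
                "n_voxels": exam.n_voxels,
                "label": 1 if subj.cohort == "positive" else 0,
                "scanner_pair": list(diff.scanner_pair),
                "scanner_indicator": 1 if 1 in diff.scanner_pair else 0,
                "final_grade": final_grade[sid],
            })
    exam_df = pd.DataFrame(exam_rows)

    logistic = None
    sweep = None
    stratified = None
    if len(exam_df) and exam_df.label.nunique() == 2:
        fit = ev.fit_exam_logistic(exam_df.score, exam_df.label,
                                   exam_df.scanner_indicator, alpha=config.alpha)
        logistic = {
            "coefficients": fit.coefficients,
            "standard_errors": fit.standard_errors,
            "wald_z": fit.wald_z,
            "p_values": fit.p_values,
            "conf_int": {k: list(v) for k, v in fit.conf_int.items()},
            "converged": fit.converged,
            "score_significant": fit.score_significant,
            "diagnostic": fit.diagnostic,
        }
        sweep = ev.threshold_sweep(exam_df.score, exam_df.label,
                                   config.t_exam_grid)
        grades = np.where(exam_df.label == 1,
                          exam_df.final_grade, 1)
        stratified = {k: v.to_dict(orient="records") for k, v in
                      ev.malignancy_stratified_eval(exam_df.score, grades,
                                                    config.t_exam_grid).items()}

    # --- lesion-level detection --------------------------------------------
    lesion_rows = []
    for sid, patches in lesion_by_subject.items():
        scores = _score(patches)
        detected, fraction = scoring.lesion_level_detection(scores, patch_threshold)
        lesion_rows.append({"subject_id": sid, "n_patches": len(patches),
                            "fraction_anomalous": fraction, "detected": detected})

    def _ci(b):
        return None if b is None else {k: list(v) for k, v in b.ci.items()}

    def _reps(b):
        if b is None:
            return None
        return [{"auc": r.auc, "youden_threshold": r.youden_threshold,
                 "sensitivity": r.sensitivity, "specificity": r.specificity,
                 "fpr": r.fpr_at_threshold} for r in b.replicates]

    report = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_subjects": len(cohort.subjects),
        "n_excluded": len({e["subject_id"] for e in exclusions}),
        "exclusions": exclusions,
        "pool_sizes": {k: int(v.size) for k, v in pools.items()},
        "patch_threshold": patch_threshold,
        "patch_eval": {
            "validation": {"ci": _ci(val_boot), "replicates": _reps(val_boot)},
            "test": {"ci": _ci(test_boot), "replicates": _reps(test_boot)},
        },
        "exam_eval": {
            "exams": exam_rows,
            "logistic": logistic,
            "threshold_sweep": None if sweep is None
                else sweep.to_dict(orient="records"),
            "stratified": stratified,
        },
        "lesion_detection": lesion_rows,
        "training": {"final_critic_loss": gan_log["critic_loss"][-1],
                     "final_encoder_loss": enc_log["encoder_loss"][-1]},
    }
    report["report_hash"] = report_hash(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(_sanitize(report), fh, indent=2)
        if len(exam_df):
            exam_df.to_csv(outdir / "exam_scores.csv", index=False)
        if sweep is not None:
            sweep.to_csv(outdir / "threshold_sweep.csv", index=False)
        save_model(model, outdir / "model.npz")
    # in-memory conveniences; underscore keys are never serialized or hashed
    report["_model"] = model
    report["_pools"] = pools
    return report


def _sanitize(obj):
    """NaN-free, JSON-ready copy (NaN -> None), excluding private keys."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_hash(report: dict) -> str:
    """Content hash of the report (excluding the hash field itself)."""
    core = {k: v for k, v in report.items() if k not in ("report_hash",)}
    return hashlib.sha256(
        json.dumps(_sanitize(core), sort_keys=True).encode()).hexdigest()
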