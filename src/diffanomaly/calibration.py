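"""Type-I-error calibration of the examination-level Wald test.

Under the null (zero lesion and precursor contrast) the positive and negative
cohorts are statistically identical, so the Wald test on the exam-score
coefficient should reject at close to its nominal level. This module
simulates many small null cohorts end to end — generate volumes, score the
final inter-visit difference exam with a *fixed* scoring model, aggregate to
examination level, fit the logistic model with the scanner covariate — and
reports the empirical rejection rate.

Because the labels are independent of the images under the null, any fixed
(label-blind) scoring function is valid here; an untrained network with fixed
weights is used so that hundreds of replicate cohorts stay cheap. The
per-cohort voxel-score median serves as the classification threshold — also
label-blind, and it keeps exam scores away from the degenerate 0/1 corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import fit_exam_logistic
from .fanogan import AnomalyModel, ModelConfig, build_networks
from .preprocess import NormStats, compute_difference, consecutive_negative_pairs
from .scoring import classify_voxels, exam_level_score, sliding_window_map
from .synthetic import CohortConfig, generate_subject

__all__ = ["NullCalibrationResult", "null_calibration", "null_cohort_config"]


@dataclass
class NullCalibrationResult:
    n_cohorts: int
    n_exams_per_cohort: int
    alpha: float
    rejections: int
    p_values: list = field(default_factory=list)
    n_nonconverged: int = 0

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.n_cohorts

    def binomial_interval(self, level: float = 0.99) -> tuple[float, float]:
        """Normal-approximation binomial band around the nominal alpha."""
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(self.alpha * (1 - self.alpha) / self.n_cohorts)
        return (self.alpha - half, self.alpha + half)


def null_cohort_config(seed: int, n_negative: int = 40, n_positive: int = 40
                       ) -> CohortConfig:
    """Zero-effect cohort: lesion and precursor contrast both zero."""
    return CohortConfig(
        n_negative=n_negative, n_positive=n_positive, n_visits=3,
        volume_shape=(4, 24, 24), tissue_corr_len=3.0, tissue_amp=0.25,
        drift_sigma=0.01, deform_amp=0.5, noise_sigma=0.02,
        lesion_contrast=0.0, precursor_contrast=0.0, lesion_radius_vox=1.5,
        scanner_shift_prob=0.3, seed=seed)


def _fixed_scorer(patch_side: int) -> AnomalyModel:
    """Untrained model with fixed weights: a deterministic, label-blind scorer."""
    config = ModelConfig(patch_side=patch_side, latent_dim=8, width=32, seed=777)
    G, D, E = build_networks(config)
    return AnomalyModel(G=G, D=D, E=E, config=config,
                        norm_stats=NormStats(lo=-0.1, hi=0.1), k=config.k)


def null_calibration(n_cohorts: int = 400, seed: int = 0,
                     n_negative: int = 40, n_positive: int = 40,
                     patch_side: int = 8, stride: int = 8,
                     alpha: float = 0.05) -> NullCalibrationResult:
    """Empirical rejection rate of the exam-level Wald test over null cohorts.

    Each replicate cohort contributes one examination per subject (the final
    consecutive negative/negative difference). Non-convergent fits (rare
    separation artifacts at this sample size) are counted as non-rejections.
    """
    model = _fixed_scorer(patch_side)
    rejections = 0
    nonconv = 0
    p_values: list[float] = []
    for c in range(n_cohorts):
        config = null_cohort_config(seed=(seed * 100_003 + c) & 0x7FFFFFFF,
                                    n_negative=n_negative, n_positive=n_positive)
        exam_fracs = []
        labels = []
        scanner = []
        voxel_pool = []
        maps = []
        for i in range(config.n_negative + config.n_positive):
            cohort_label = "negative" if i < config.n_negative else "positive"
            subj = generate_subject(config, cohort_label, i)
            # first inter-visit exam for every subject: both cohorts can then
            # carry the period-1 scanner flag (visit 0), keeping the covariate
            # free of structural separation
            pair = consecutive_negative_pairs(subj)[0]
            diff = compute_difference(subj.visits[pair[0]], subj.visits[pair[1]],
                                      pair, subj.subject_id)
            amap = sliding_window_map(diff, model, stride=stride)
            maps.append((amap, diff))
            labels.append(0 if cohort_label == "negative" else 1)
            scanner.append(1 if 1 in diff.scanner_pair else 0)
            voxel_pool.append(amap.values[np.isfinite(amap.values)])
        threshold = float(np.median(np.concatenate(voxel_pool)))
        for amap, diff in maps:
            binary = classify_voxels(amap, threshold)
            exam_fracs.append(exam_level_score(binary, amap, threshold).score)
        fit = fit_exam_logistic(exam_fracs, labels, scanner, alpha=alpha)
        if not fit.converged:
            nonconv += 1
            p_values.append(1.0)
            continue
        p = fit.p_values["exam_score"]
        p_values.append(p)
        if p < alpha:
            rejections += 1
    return NullCalibrationResult(
        n_cohorts=n_cohorts, n_exams_per_cohort=n_negative + n_positive,
        alpha=alpha, rejections=rejections, p_values=p_values,
        n_nonconverged=nonconv)
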