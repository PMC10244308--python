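"""From local patch scores to voxel maps, examination scores, lesion calls.

A trained anomaly model scores 64x64 (or configured-size) windows slid over
every axial slice of a difference volume; each voxel's anomaly value is the
mean score of all windows covering it. Thresholding the map with the
validation-derived patch threshold gives binary voxel calls, and the
examination-level score is the fraction of classified (covered) breast-tissue
voxels called anomalous — by construction in [0, 1]. A future lesion counts
as detected when at least half of the patches covering its location are
called anomalous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fanogan import anomaly_score
from .preprocess import DifferenceVolume, normalize_patch

__all__ = [
    "AnomalyMap",
    "ExamScore",
    "score_patches",
    "sliding_window_map",
    "classify_voxels",
    "exam_level_score",
    "lesion_level_detection",
]

DEFAULT_STRIDE = 16


@dataclass
class AnomalyMap:
    values: np.ndarray        # voxel anomaly scores; NaN where undefined
    coverage: np.ndarray      # count of windows contributing to each voxel
    mask: np.ndarray          # breast mask of the difference volume
    source: tuple[str, tuple[int, int]] = ("", (1, 0))  # (subject_id, visit_pair)


@dataclass
class ExamScore:
    score: float
    patch_threshold: float
    n_voxels: int
    source: tuple[str, tuple[int, int]] = ("", (1, 0))
    scanner_pair: tuple[int, int] = (2, 2)

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"examination score {self.score} outside [0, 1]")
        if self.n_voxels <= 0:
            raise ValueError("examination score aggregated over zero voxels")


def score_patches(model, patches: np.ndarray) -> np.ndarray:
    """Anomaly scores L for a batch of *normalized* patches.

    Dispatches to a model-provided ``score_batch`` when present (used by test
    stubs); otherwise computes the standard L = L_R + k * L_D.
    """
    if hasattr(model, "score_batch"):
        return np.asarray(model.score_batch(patches), dtype=np.float64)
    return np.atleast_1d(anomaly_score(patches, model).L)


def sliding_window_map(diff: DifferenceVolume, model, stride: int = DEFAULT_STRIDE,
                       ) -> AnomalyMap:
    """Slide the model over every axial slice and fuse window scores per voxel.

    Window top-left corners lie on the stride grid (multiples of ``stride``
    starting at 0) with the window fully inside the slice; a window is
    evaluated iff its center voxel is inside the mask. Raw patch values are
    normalized with the model's training statistics before scoring. Each
    voxel's value is the mean over all windows covering it; voxels without
    coverage, or outside the mask, are NaN.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    p = model.patch_side
    nz, ny, nx = diff.values.shape
    half = p // 2
    sums = np.zeros((nz, ny, nx))
    coverage = np.zeros((nz, ny, nx), dtype=np.int64)

    tops_y = range(0, ny - p + 1, stride)
    tops_x = range(0, nx - p + 1, stride)
    for z in range(nz):
        windows = []
        positions = []
        for ty in tops_y:
            for tx in tops_x:
                if not diff.mask[z, ty + half, tx + half]:
                    continue
                raw = diff.values[z, ty:ty + p, tx:tx + p]
                windows.append(raw)
                positions.append((ty, tx))
        if not windows:
            continue
        batch = np.stack(windows)
        if model.norm_stats is not None:
            batch = normalize_patch(batch, model.norm_stats)
        scores = score_patches(model, batch)
        for (ty, tx), s in zip(positions, scores):
            sums[z, ty:ty + p, tx:tx + p] += s
            coverage[z, ty:ty + p, tx:tx + p] += 1

    values = np.full((nz, ny, nx), np.nan)
    defined = (coverage > 0) & diff.mask.astype(bool)
    values[defined] = sums[defined] / coverage[defined]
    return AnomalyMap(values=values, coverage=coverage, mask=diff.mask,
                      source=(diff.subject_id, diff.visit_pair))


def classify_voxels(amap: AnomalyMap, patch_threshold: float) -> np.ndarray:
    """Binary anomaly field: defined voxels with value > patch_threshold."""
    if not np.isfinite(patch_threshold):
        raise ValueError(f"patch threshold must be finite, got {patch_threshold}")
    defined = np.isfinite(amap.values)
    out = np.zeros(amap.values.shape, dtype=bool)
    out[defined] = amap.values[defined] > patch_threshold
    return out


def exam_level_score(binary_field: np.ndarray, amap: AnomalyMap,
                     patch_threshold: float = np.nan) -> ExamScore:
    """Fraction of covered breast-tissue voxels called anomalous, in [0, 1]."""
    covered = (amap.coverage > 0) & amap.mask.astype(bool)
    n = int(covered.sum())
    if n == 0:
        raise ValueError("no evaluable tissue: zero covered breast voxels")
    score = float(binary_field[covered].sum() / n)
    return ExamScore(score=score, patch_threshold=float(patch_threshold),
                     n_voxels=n, source=amap.source)


def lesion_level_detection(lesion_scores: np.ndarray,
                           patch_threshold: float) -> tuple[bool, float]:
    """A future lesion is detected iff >= 50% of its patches score above threshold.

    ``lesion_scores`` are the anomaly scores L of the patches covering the
    future lesion location.
    """
    scores = np.asarray(lesion_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no lesion patches to evaluate")
    fraction = float((scores > patch_threshold).mean())
    return fraction >= 0.5, fraction
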