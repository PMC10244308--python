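"""Preprocessing: registration, segmentation, difference volumes, patches.

Turns one subject's visit series into registered, masked inter-visit
difference volumes ``I_diff = I_i - I_j`` (subtracted volume of visit *i*
minus registered visit *j*, i > j, both graded negative) and labeled 2-D
axial patches. The key extraction rule: a patch is kept only if at most
``background_limit`` (default 50) of its pixels fall outside the breast mask;
patch centers must lie inside the mask.

Registration and segmentation are deliberately simple desk-scale components:
rigid-then-affine intensity-based registration via SimpleITK with a
normalized-cross-correlation quality gate, and Otsu threshold + largest
connected component + morphological closing for breast segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing as morphological_closing

from .synthetic import SubjectSeries, Visit

__all__ = [
    "DifferenceVolume",
    "PatchSample",
    "ExtractionResult",
    "RegistrationResult",
    "NormStats",
    "register_followup",
    "segment_breast",
    "compute_difference",
    "consecutive_negative_pairs",
    "extract_random_patches",
    "extract_lesion_patches",
    "compute_norm_stats",
    "normalize_patch",
]

DEFAULT_BACKGROUND_LIMIT = 50
DEFAULT_REGISTRATION_FLOOR = 0.85


@dataclass
class DifferenceVolume:
    """Voxelwise difference of two registered visits (i > j, both grade 1)."""

    values: np.ndarray            # signed 3-D field
    mask: np.ndarray              # intersection of both visits' breast masks
    visit_pair: tuple[int, int]   # (i, j), 0-based visit indices, i > j
    scanner_pair: tuple[int, int]
    subject_id: str = ""

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class PatchSample:
    pixels: np.ndarray            # (p, p) axial patch from the difference volume
    center: tuple[int, int, int]  # (z, y, x) voxel coordinate
    label: str                    # "normal" | "future_lesion"
    n_background: int             # pixels outside the mask within the footprint
    subject_id: str = ""
    visit_pair: tuple[int, int] = (1, 0)


@dataclass
class ExtractionResult:
    patches: list[PatchSample]
    exclusion: str | None = None  # reason code if the subject/exam is excluded


@dataclass
class RegistrationResult:
    volume: np.ndarray
    mask: np.ndarray
    transform_parameters: dict
    quality: float                # NCC inside the mask after registration
    excluded: bool = False
    exclusion: str | None = None


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    if av.size < 2:
        return 0.0
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def register_followup(
    moving_volume: np.ndarray,
    moving_mask: np.ndarray,
    fixed_volume: np.ndarray,
    fixed_mask: np.ndarray,
    quality_floor: float = DEFAULT_REGISTRATION_FLOOR,
) -> RegistrationResult:
    """Rigid-then-affine registration of a follow-up visit onto a reference visit.

    Both volumes must share a voxel grid. Returns the resampled moving volume
    and mask plus the transform parameters; the attached quality score is the
    normalized cross-correlation between fixed and resampled-moving volume
    inside the joint mask. Quality below ``quality_floor`` flags the pair as
    "excluded: misregistration" (the result is still returned).
    """
    import SimpleITK as sitk

    if moving_volume.shape != fixed_volume.shape:
        raise ValueError(
            f"volumes must share a grid: {moving_volume.shape} vs {fixed_volume.shape}"
        )
    fixed = sitk.GetImageFromArray(np.ascontiguousarray(fixed_volume, dtype=np.float64))
    moving = sitk.GetImageFromArray(np.ascontiguousarray(moving_volume, dtype=np.float64))

    def _stage(transform):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=100,
            relaxationFactor=0.5)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(transform, inPlace=True)
        return reg.Execute(fixed, moving)

    rigid = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    rigid = _stage(sitk.Euler3DTransform(rigid))

    affine = sitk.AffineTransform(3)
    affine.SetMatrix(rigid.GetMatrix())
    affine.SetTranslation(rigid.GetTranslation())
    affine.SetCenter(rigid.GetCenter())
    affine = _stage(affine)

    resampled = sitk.GetArrayFromImage(
        sitk.Resample(moving, fixed, affine, sitk.sitkLinear, 0.0))
    moving_mask_img = sitk.GetImageFromArray(
        np.ascontiguousarray(moving_mask.astype(np.uint8)))
    resampled_mask = sitk.GetArrayFromImage(
        sitk.Resample(moving_mask_img, fixed, affine,
                      sitk.sitkNearestNeighbor, 0)) > 0

    joint = fixed_mask.astype(bool) & resampled_mask
    quality = _ncc(fixed_volume, resampled, joint) if joint.any() else 0.0

    # guard against optimizer divergence: registration must not align worse
    # than the untransformed input (the visits share a grid already)
    joint0 = fixed_mask.astype(bool) & moving_mask.astype(bool)
    identity_quality = _ncc(fixed_volume, moving_volume, joint0) \
        if joint0.any() else 0.0
    params = {
        "matrix": list(affine.GetMatrix()),
        "translation": list(affine.GetTranslation()),
        "center": list(affine.GetCenter()),
    }
    if identity_quality > quality:
        resampled = moving_volume.astype(np.float64).copy()
        resampled_mask = moving_mask.astype(bool).copy()
        quality = identity_quality
        params = {"matrix": list(np.eye(3).ravel()),
                  "translation": [0.0, 0.0, 0.0], "center": [0.0, 0.0, 0.0]}

    excluded = quality < quality_floor
    return RegistrationResult(
        volume=resampled,
        mask=resampled_mask,
        transform_parameters=params,
        quality=quality,
        excluded=excluded,
        exclusion="excluded: misregistration" if excluded else None,
    )


def segment_breast(volume: np.ndarray) -> tuple[np.ndarray, str | None]:
    """Otsu threshold + largest connected component + morphological closing.

    Returns ``(mask, exclusion)`` where exclusion is "excluded: segmentation"
    for a degenerate (empty) result. For synthetic cohorts the generator's
    mask may be passed through instead (pipeline config switch).
    """
    vol = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(vol).all() or vol.max() == vol.min():
        return np.zeros(vol.shape, dtype=bool), "excluded: segmentation"
    thr = threshold_otsu(vol)
    fg = vol > thr
    if not fg.any():
        return fg, "excluded: segmentation"
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros(vol.shape, dtype=bool), "excluded: segmentation"
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = morphological_closing(mask, footprint=np.ones((1, 3, 3), dtype=bool))
    if not mask.any():
        return mask, "excluded: segmentation"
    return mask, None


def compute_difference(visit_i: Visit, visit_j: Visit,
                       pair: tuple[int, int] = (1, 0),
                       subject_id: str = "") -> DifferenceVolume:
    """``I_diff = I_i - I_j`` on a common grid; mask = AND of both masks."""
    if visit_i.volume.shape != visit_j.volume.shape:
        raise ValueError(
            f"visit shapes differ: {visit_i.volume.shape} vs {visit_j.volume.shape}"
        )
    return DifferenceVolume(
        values=visit_i.volume - visit_j.volume,
        mask=visit_i.mask.astype(bool) & visit_j.mask.astype(bool),
        visit_pair=pair,
        scanner_pair=(visit_i.scanner_period, visit_j.scanner_period),
        subject_id=subject_id,
    )


def consecutive_negative_pairs(series: SubjectSeries) -> list[tuple[int, int]]:
    """(i, i-1) visit pairs where both visits are graded 1 (negative screens)."""
    pairs = []
    for i in range(1, len(series.visits)):
        if series.visits[i].grade == 1 and series.visits[i - 1].grade == 1:
            pairs.append((i, i - 1))
    return pairs


def _background_count_map(mask_plane: np.ndarray, p: int) -> np.ndarray:
    """Count of background (mask==0) pixels in each p x p window.

    Returned array is indexed by window top-left corner; computed with a
    2-D summed-area table.
    """
    bg = (~mask_plane.astype(bool)).astype(np.int64)
    ii = np.zeros((bg.shape[0] + 1, bg.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = bg.cumsum(0).cumsum(1)
    ny, nx = bg.shape
    h, w = ny - p + 1, nx - p + 1
    if h <= 0 or w <= 0:
        return np.zeros((0, 0), dtype=np.int64)
    return (ii[p:p + h, p:p + w] - ii[:h, p:p + w]
            - ii[p:p + h, :w] + ii[:h, :w])


def _cut_patch(diff: DifferenceVolume, z: int, cy: int, cx: int, p: int,
               label: str) -> PatchSample:
    top, left = cy - p // 2, cx - p // 2
    pixels = diff.values[z, top:top + p, left:left + p].copy()
    n_bg = int((~diff.mask[z, top:top + p, left:left + p]).sum())
    return PatchSample(pixels=pixels, center=(z, cy, cx), label=label,
                       n_background=n_bg, subject_id=diff.subject_id,
                       visit_pair=diff.visit_pair)


def _eligible_centers(diff: DifferenceVolume, p: int, background_limit: int,
                      candidate_mask: np.ndarray) -> np.ndarray:
    """(z, cy, cx) centers whose window fits in-plane, center in candidate_mask,
    and window background <= background_limit against the breast mask."""
    nz, ny, nx = diff.values.shape
    if p > ny or p > nx:
        raise ValueError(
            f"patch side {p} exceeds in-plane volume extent ({ny}, {nx})"
        )
    half = p // 2
    out = []
    for z in range(nz):
        plane = candidate_mask[z]
        if not plane.any():
            continue
        bgmap = _background_count_map(diff.mask[z], p)
        ok = np.zeros((ny, nx), dtype=bool)
        # center (cy,cx) has top-left (cy-half, cx-half); must index into bgmap
        ok[half:half + bgmap.shape[0], half:half + bgmap.shape[1]] = \
            bgmap <= background_limit
        cys, cxs = np.nonzero(plane & ok)
        if cys.size:
            out.append(np.column_stack([np.full(cys.size, z), cys, cxs]))
    if not out:
        return np.zeros((0, 3), dtype=np.int64)
    return np.concatenate(out, axis=0)


def extract_random_patches(
    diff: DifferenceVolume,
    n: int,
    p: int = 64,
    rng_seed: int | np.random.Generator = 0,
    background_limit: int = DEFAULT_BACKGROUND_LIMIT,
) -> ExtractionResult:
    """Sample up to ``n`` normal patches uniformly over eligible centers.

    Eligible centers lie in the mask, admit a full in-plane window, and have
    window background <= ``background_limit``. Sampling is without
    replacement; fewer than ``n`` eligible centers returns them all, zero
    flags "excluded: breast too small".
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    centers = _eligible_centers(diff, p, background_limit, diff.mask)
    if centers.shape[0] == 0:
        return ExtractionResult(patches=[], exclusion="excluded: breast too small")
    take = min(n, centers.shape[0])
    idx = rng.choice(centers.shape[0], size=take, replace=False)
    patches = [_cut_patch(diff, *centers[i], p, "normal") for i in sorted(idx)]
    return ExtractionResult(patches=patches)


def extract_lesion_patches(
    diff: DifferenceVolume,
    lesion_mask: np.ndarray,
    p: int = 64,
    n_per_lesion: int = 30,
    rng_seed: int | np.random.Generator = 0,
    background_limit: int = DEFAULT_BACKGROUND_LIMIT,
) -> ExtractionResult:
    """Patches centered on future-lesion voxels, subsampled to ``n_per_lesion``.

    Any patch with more than ``background_limit`` background pixels is
    excluded after subsampling; if every candidate is excluded the subject is
    flagged "excluded from patch-level evaluation".
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    nz, ny, nx = diff.values.shape
    half = p // 2
    cand = np.argwhere(lesion_mask.astype(bool))
    fits = ((cand[:, 1] >= half) & (cand[:, 1] - half + p <= ny)
            & (cand[:, 2] >= half) & (cand[:, 2] - half + p <= nx))
    cand = cand[fits]
    if cand.shape[0] == 0:
        return ExtractionResult(
            patches=[], exclusion="excluded from patch-level evaluation")
    take = min(n_per_lesion, cand.shape[0])
    idx = rng.choice(cand.shape[0], size=take, replace=False)
    patches = []
    for i in sorted(idx):
        patch = _cut_patch(diff, *cand[i], p, "future_lesion")
        if patch.n_background <= background_limit:
            patches.append(patch)
    if not patches:
        return ExtractionResult(
            patches=[], exclusion="excluded from patch-level evaluation")
    return ExtractionResult(patches=patches)


@dataclass
class NormStats:
    """Training-split intensity bounds mapped to the model range [-1, 1]."""

    lo: float
    hi: float
    percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self):
        if not np.isfinite([self.lo, self.hi]).all() or self.hi <= self.lo:
            raise ValueError(f"degenerate normalization bounds [{self.lo}, {self.hi}]")


def compute_norm_stats(patches: list[PatchSample] | np.ndarray,
                       percentiles: tuple[float, float] = (1.0, 99.0)) -> NormStats:
    """Global percentile bounds over training patches (training split only)."""
    if isinstance(patches, np.ndarray):
        values = patches.ravel()
    else:
        if not patches:
            raise ValueError("no patches to compute statistics from")
        values = np.concatenate([p.pixels.ravel() for p in patches])
    lo, hi = np.percentile(values, percentiles)
    return NormStats(lo=float(lo), hi=float(hi), percentiles=tuple(percentiles))


def normalize_patch(patch: PatchSample | np.ndarray, stats: NormStats) -> np.ndarray:
    """Affine map of pixel values to [-1, 1] with clipping outside the bounds."""
    pixels = patch.pixels if isinstance(patch, PatchSample) else patch
    scaled = 2.0 * (pixels - stats.lo) / (stats.hi - stats.lo) - 1.0
    return np.clip(scaled, -1.0, 1.0)
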