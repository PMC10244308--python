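"""Synthetic longitudinal screening cohorts.

The clinical cohorts this package targets (annual subtracted CE-MRI screens of
high-risk women) are not publicly distributable, so this module generates
volumes with the statistical structure the downstream analysis assumes:

* per subject, ``n_visits`` >= 3 volumetric visits with a breast mask;
* a *negative* cohort whose inter-visit change is normal variability only
  (smooth deformation, global multiplicative intensity drift, additive noise,
  and an optional scanner-era intensity shift on the first visit);
* a *positive* cohort in which a lesion (bright Gaussian blob) emerges at the
  final visit, with a subtler, spatially wider precursor bump added at the
  same location in the last *negative* visit — so the difference image of the
  two last negative visits carries a learnable precursor signature.

Nothing here claims anatomical realism: the background is a band-limited
Gaussian random field standing in for fibroglandular texture, and the breast
mask is a smooth squircle. The generator is deterministic given
``(config, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "CohortConfig",
    "Visit",
    "SubjectSeries",
    "Cohort",
    "ConfigError",
    "generate_subject",
    "generate_cohort",
    "assign_splits",
    "load_cohort",
]

# Global affine intensity shift applied to visits acquired in the shifted
# scanner era ("period 1"): v -> GAIN * v + OFFSET. Reproduces, qualitatively,
# the confound where difference images straddling a scanner switch carry a
# systematic intensity offset and inflate examination-level scores.
SCANNER_GAIN = 1.15
SCANNER_OFFSET = 0.08

# Baseline tissue intensity inside the breast mask (arbitrary unit scale).
TISSUE_BASE = 0.5

# Split fractions: negatives train/validation/test, positives validation/test.
NEGATIVE_SPLIT = (0.75, 0.07, 0.18)
POSITIVE_SPLIT = (0.15, 0.85)


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Intensities are on an arbitrary unit scale with breast tissue around
    ``TISSUE_BASE``; all spatial quantities are in voxels.
    """

    n_negative: int = 20
    n_positive: int = 10
    n_visits: int = 3
    volume_shape: tuple[int, int, int] = (8, 96, 96)  # (z, y, x)
    tissue_corr_len: float = 3.0     # correlation length of background texture
    tissue_amp: float = 0.25         # texture amplitude (std) around TISSUE_BASE
    drift_sigma: float = 0.02        # std of per-visit multiplicative drift
    deform_amp: float = 0.5          # max voxel displacement of inter-visit warp
    noise_sigma: float = 0.02        # additive Gaussian noise std
    lesion_contrast: float = 0.7     # peak added intensity of emerged lesion
    precursor_contrast: float = 0.35  # peak of precursor bump (< lesion_contrast)
    lesion_radius_vox: float = 4.0
    scanner_shift_prob: float = 0.3  # P(first visit uses shifted "period 1" scale)
    seed: int = 0

    def violations(self) -> list[str]:
        """All invariant violations (empty list means valid)."""
        v: list[str] = []
        if self.n_negative < 0 or self.n_positive < 0:
            v.append("cohort sizes must be non-negative")
        if self.n_visits < 3:
            v.append(f"n_visits must be >= 3, got {self.n_visits}")
        if not (0 <= self.precursor_contrast < self.lesion_contrast
                or (self.precursor_contrast == 0 and self.lesion_contrast == 0)):
            v.append(
                "precursor_contrast must satisfy 0 <= precursor < lesion "
                f"(got {self.precursor_contrast} vs {self.lesion_contrast})"
            )
        for name in ("tissue_amp", "drift_sigma", "deform_amp", "noise_sigma"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.scanner_shift_prob <= 1:
            v.append(f"scanner_shift_prob must be in [0,1], got {self.scanner_shift_prob}")
        if len(self.volume_shape) != 3 or any(s < 1 for s in self.volume_shape):
            v.append(f"volume_shape must be 3 positive ints, got {self.volume_shape}")
        else:
            need = int(np.ceil(2 * self.lesion_radius_vox))
            for axis, size in zip("zyx", self.volume_shape):
                if size < need:
                    v.append(
                        f"volume_shape {axis}-dimension {size} too small to "
                        f"contain a lesion of radius {self.lesion_radius_vox} "
                        f"(needs >= {need})"
                    )
        return v

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise ConfigError("; ".join(bad))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["volume_shape"] = tuple(d["volume_shape"])
        return cls(**d)


@dataclass
class Visit:
    volume: np.ndarray        # 3-D float64, (z, y, x)
    mask: np.ndarray          # 3-D bool breast mask
    grade: int                # BI-RADS-like ordinal 1-5
    scanner_period: int       # 1 = shifted era, 2 = reference era


@dataclass
class SubjectSeries:
    subject_id: str
    cohort: str                         # "negative" | "positive"
    visits: list[Visit]
    lesion_mask: np.ndarray | None = None   # bool, positives only
    lesion_center: tuple[int, int, int] | None = None


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectSeries]
    manifest: pd.DataFrame

    def save(self, outdir: str | Path, overwrite: bool = False) -> Path:
        return _save_cohort(self, Path(outdir), overwrite)


def _squircle_mask(shape: tuple[int, int, int], rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Breast-tissue stand-in: a superellipse (squircle) prism.

    Exponent 4 keeps corners filled, so a centered square patch comparable to
    the in-plane extent has little background inside the mask.
    """
    nz, ny, nx = shape
    ay = (0.46 + rng.uniform(-0.02, 0.02)) * ny
    ax = (0.46 + rng.uniform(-0.02, 0.02)) * nx
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    val = (np.abs(y[:, None]) / ay) ** 4 + (np.abs(x[None, :]) / ax) ** 4
    plane = val <= 1.0
    return np.broadcast_to(plane, (nz, ny, nx)).copy(), val


def _texture(shape, corr_len: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(size=shape)
    if corr_len > 0:
        smooth = gaussian_filter(noise, sigma=corr_len, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
    else:
        smooth = noise
    return amp * smooth


def _displacement_warp(vol: np.ndarray, amp: float, corr_len: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply a smooth random displacement field with max |d| = amp voxels."""
    if amp == 0:
        return vol
    shape = vol.shape
    disp = []
    for _ in range(3):
        d = gaussian_filter(rng.normal(size=shape), sigma=max(corr_len, 1.0) * 1.5,
                            mode="reflect")
        disp.append(d)
    peak = max(np.abs(d).max() for d in disp)
    if peak > 0:
        disp = [d * (amp / peak) for d in disp]
    grid = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    return map_coordinates(vol, coords, order=1, mode="nearest")


def _gaussian_bump(shape, center, sigma: float, peak: float) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                             indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return peak * np.exp(-d2 / (2.0 * sigma**2))


def generate_subject(config: CohortConfig, cohort: str, subject_seed: int) -> SubjectSeries:
    """Generate one subject's visit series, deterministic in (config, subject_seed)."""
    config.validate()
    if cohort not in ("negative", "positive"):
        raise ValueError(f"cohort must be 'negative' or 'positive', got {cohort!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF,
                                                        int(subject_seed)]))
    shape = config.volume_shape
    mask, squircle_val = _squircle_mask(shape, rng)

    base = mask * np.clip(
        TISSUE_BASE + _texture(shape, config.tissue_corr_len, config.tissue_amp, rng),
        0.0, None)

    # lesion geometry (positives): center well inside the mask, away from z edges
    lesion_mask = None
    lesion_center = None
    lesion_bump = precursor_bump = None
    if cohort == "positive":
        nz = shape[0]
        zmargin = min(int(np.ceil(config.lesion_radius_vox)), (nz - 1) // 2)
        interior2d = squircle_val <= 0.5
        zz, yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                 np.arange(shape[2]), indexing="ij")
        ok = interior2d[None, :, :] & (zz >= zmargin) & (zz <= nz - 1 - zmargin)
        cand = np.argwhere(ok)
        if len(cand) == 0:
            raise ConfigError(
                "volume too small to place a lesion inside the mask: "
                f"volume_shape={shape}, lesion_radius={config.lesion_radius_vox}"
            )
        lesion_center = tuple(int(c) for c in cand[rng.integers(len(cand))])
        zz = zz - lesion_center[0]
        yy = yy - lesion_center[1]
        xx = xx - lesion_center[2]
        d2 = zz**2 + yy**2 + xx**2
        lesion_mask = (d2 <= config.lesion_radius_vox**2) & mask
        lesion_bump = _gaussian_bump(shape, lesion_center,
                                     sigma=config.lesion_radius_vox / 1.6,
                                     peak=config.lesion_contrast)
        precursor_bump = _gaussian_bump(shape, lesion_center,
                                        sigma=1.5 * config.lesion_radius_vox,
                                        peak=config.precursor_contrast)

    shifted = bool(rng.uniform() < config.scanner_shift_prob) \
        if config.scanner_shift_prob > 0 else False

    final_grade = 1
    if cohort == "positive":
        final_grade = int(rng.choice([2, 3, 4, 5], p=[0.35, 0.30, 0.25, 0.10]))

    visits: list[Visit] = []
    n = config.n_visits
    for v in range(n):
        vol = _displacement_warp(base, config.deform_amp, config.tissue_corr_len, rng) \
            if config.deform_amp > 0 else base.copy()
        if config.drift_sigma > 0:
            vol = vol * (1.0 + rng.normal(0.0, config.drift_sigma))
        if cohort == "positive" and v == n - 2:
            vol = vol + precursor_bump
        if cohort == "positive" and v == n - 1:
            vol = vol + lesion_bump
        vol = vol * mask
        period = 1 if (v == 0 and shifted) else 2
        if period == 1:
            vol = vol * SCANNER_GAIN + SCANNER_OFFSET * mask
        if config.noise_sigma > 0:
            vol = vol + rng.normal(0.0, config.noise_sigma, size=shape)
        grade = final_grade if v == n - 1 else 1
        visits.append(Visit(volume=vol, mask=mask.copy(), grade=grade,
                            scanner_period=period))

    return SubjectSeries(
        subject_id=f"{cohort[:3]}{subject_seed:04d}",
        cohort=cohort,
        visits=visits,
        lesion_mask=lesion_mask,
        lesion_center=lesion_center,
    )


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def assign_splits(n_negative: int, n_positive: int,
                  rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Random split labels: negatives train/validation/test, positives validation/test.

    Fractions follow the screening-study design (negatives 75/7/18, positives
    15/85); every non-empty stratum keeps at least one validation and one test
    subject where the cohort size permits.
    """
    neg_counts = _largest_remainder(n_negative, NEGATIVE_SPLIT)
    if n_negative >= 3:
        for idx in (1, 2):  # ensure val and test non-empty, borrow from train
            if neg_counts[idx] == 0 and neg_counts[0] > 1:
                neg_counts[idx] += 1
                neg_counts[0] -= 1
    pos_counts = _largest_remainder(n_positive, POSITIVE_SPLIT)
    if n_positive >= 2:
        for idx in (0, 1):
            other = 1 - idx
            if pos_counts[idx] == 0 and pos_counts[other] > 1:
                pos_counts[idx] += 1
                pos_counts[other] -= 1

    neg_labels = (["train"] * neg_counts[0] + ["validation"] * neg_counts[1]
                  + ["test"] * neg_counts[2])
    pos_labels = ["validation"] * pos_counts[0] + ["test"] * pos_counts[1]
    neg_labels = [neg_labels[i] for i in rng.permutation(n_negative)]
    pos_labels = [pos_labels[i] for i in rng.permutation(n_positive)]
    return neg_labels, pos_labels


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort in memory, with a manifest and split labels."""
    config.validate()
    subjects: list[SubjectSeries] = []
    for i in range(config.n_negative):
        subjects.append(generate_subject(config, "negative", i))
    for i in range(config.n_positive):
        subjects.append(generate_subject(config, "positive", 10000 + i))

    split_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 999_999]))
    neg_labels, pos_labels = assign_splits(config.n_negative, config.n_positive,
                                           split_rng)
    split_of = {}
    for subj, lab in zip(subjects[:config.n_negative], neg_labels):
        split_of[subj.subject_id] = lab
    for subj, lab in zip(subjects[config.n_negative:], pos_labels):
        split_of[subj.subject_id] = lab

    rows = []
    for subj in subjects:
        for v, visit in enumerate(subj.visits):
            rows.append({
                "subject_id": subj.subject_id,
                "cohort": subj.cohort,
                "visit_index": v,
                "grade": visit.grade,
                "scanner_period": visit.scanner_period,
                "volume_path": "",
                "mask_path": "",
                "lesion_mask_path": "",
                "split": split_of[subj.subject_id],
            })
    manifest = pd.DataFrame(rows)
    return Cohort(config=config, subjects=subjects, manifest=manifest)


# ---------------------------------------------------------------------------
# serialization: NIfTI volumes + CSV manifest + YAML config mirror

def _save_cohort(cohort: Cohort, outdir: Path, overwrite: bool) -> Path:
    import nibabel as nib

    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {outdir} exists and is not empty; "
                "pass overwrite=True to replace it"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    manifest = cohort.manifest.copy()
    for subj in cohort.subjects:
        sdir = outdir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        lesion_path = ""
        if subj.lesion_mask is not None:
            lesion_path = str(Path(subj.subject_id) / "lesion_mask.nii")
            nib.save(nib.Nifti1Image(subj.lesion_mask.astype(np.uint8), affine),
                     sdir / "lesion_mask.nii")
        for v, visit in enumerate(subj.visits):
            vol_path = Path(subj.subject_id) / f"visit{v}_sub.nii"
            mask_path = Path(subj.subject_id) / f"visit{v}_mask.nii"
            nib.save(nib.Nifti1Image(visit.volume.astype(np.float32), affine),
                     outdir / vol_path)
            nib.save(nib.Nifti1Image(visit.mask.astype(np.uint8), affine),
                     outdir / mask_path)
            sel = (manifest.subject_id == subj.subject_id) & \
                  (manifest.visit_index == v)
            manifest.loc[sel, "volume_path"] = str(vol_path)
            manifest.loc[sel, "mask_path"] = str(mask_path)
            manifest.loc[sel, "lesion_mask_path"] = lesion_path
    manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh)
    cohort.manifest = manifest
    return outdir


def load_cohort(indir: str | Path) -> Cohort:
    """Read a cohort saved by :meth:`Cohort.save` (or real data with the same schema)."""
    import nibabel as nib

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv",
                           keep_default_na=False, dtype={"lesion_mask_path": str})
    with open(indir / "config.yaml") as fh:
        config = CohortConfig.from_dict(yaml.safe_load(fh))
    subjects = []
    for sid, grp in manifest.groupby("subject_id", sort=False):
        grp = grp.sort_values("visit_index")
        visits = []
        for _, row in grp.iterrows():
            vol = np.asarray(nib.load(indir / row.volume_path).dataobj,
                             dtype=np.float64)
            mask = np.asarray(nib.load(indir / row.mask_path).dataobj) > 0
            visits.append(Visit(volume=vol, mask=mask, grade=int(row.grade),
                                scanner_period=int(row.scanner_period)))
        lesion = None
        lp = grp.iloc[0].lesion_mask_path
        if lp:
            lesion = np.asarray(nib.load(indir / lp).dataobj) > 0
        subjects.append(SubjectSeries(subject_id=sid, cohort=grp.iloc[0].cohort,
                                      visits=visits, lesion_mask=lesion))
    return Cohort(config=config, subjects=subjects, manifest=manifest)
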