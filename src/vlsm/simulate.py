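"""Synthetic lesion-symptom cohorts with a planted epileptogenic region.

The generator emulates the statistical structure the mapping assumes:
each subject carries one connected blob-shaped lesion of realistic
volume (mean ~80 cm^3, SD ~60 cm^3, truncated at 1 cm^3 — the scale of
low-grade gliomas), a hidden spherical region of interest (ROI) acts as
the epileptogenic zone, and an ordinal seizure-frequency category (0-4
scale) arises from a latent score

    latent = gamma * involvement_fraction + beta . covariates + noise

discretized at fixed ascending cut points.  ``involvement_fraction`` is
the fraction of the ROI covered by the subject's lesion, so lesions that
miss the ROI draw their category from covariates and noise alone.
Categorical clinical covariates (seizure type, ASM use, resection,
pathology, lobes, Engel class) are sampled to match realistic cohort
marginals so the clinical summary tables exercise every code path.

With the default cut points a lesion clear of the ROI still has roughly
a two-in-three chance of some seizure history, mirroring the high
seizure prevalence of low-grade glioma cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .clinical import (
    ClinicalRecord,
    EngelClass,
    FrequencyCategory,
    Hemisphere,
    Lobe,
    Pathology,
    Resection,
    SeizureType,
)
from .imaging import DEFAULT_GRID, LesionVolume, TemplateGrid

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_lesion",
    "simulate_cohort",
    "recovery_metrics",
    "write_cohort",
]

_FREQ_BY_SCORE = [
    FrequencyCategory.NONE,
    FrequencyCategory.RARE_1_2,
    FrequencyCategory.MONTHLY,
    FrequencyCategory.WEEKLY,
    FrequencyCategory.DAILY,
]

# cohort marginals for the categorical covariates (typical LGG series)
_SEIZURE_TYPE_P = {  # conditional on any seizure history
    SeizureType.FOCAL_AWARE: 52 / 246,
    SeizureType.FOCAL_IMPAIRED_AWARENESS: 26 / 246,
    SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC: 168 / 246,
}
_ASM_P_SEIZURE = 239 / 246
_ASM_P_NOSEIZURE = 31 / 106
_GROSS_TOTAL_P = 110 / 352
_PATHOLOGY_P = {
    Pathology.OLIGODENDROGLIOMA: 66 / 352,
    Pathology.ASTROCYTOMA: 123 / 352,
    Pathology.OLIGOASTROCYTOMA: 163 / 352,
}
_LOBE_P = {
    Lobe.FRONTAL: 238 / 352,
    Lobe.TEMPORAL: 109 / 352,
    Lobe.INSULA: 60 / 352,
    Lobe.PARIETAL: 49 / 352,
    Lobe.OCCIPITAL: 6 / 352,
}
_ENGEL_AVAILABLE_P = 185 / 246


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; the seed is mandatory.

    ``effect_gamma`` is the latent-scale gain on ROI involvement fraction
    (0 = null cohort); ``covariate_betas`` are latent-scale gains on
    (sex, standardized age, standardized volume); ``cut_points`` map the
    latent score to the five frequency categories.
    """

    seed: int
    grid: TemplateGrid = DEFAULT_GRID
    n_subjects: int = 60
    roi_center: tuple[int, int, int] = (8, 14, 12)
    roi_radius: float = 3.0
    lesion_volume_mean: float = 80.8
    lesion_volume_sd: float = 60.0
    lesion_volume_min: float = 1.0
    effect_gamma: float = 6.0
    covariate_betas: tuple[float, float, float] = (0.2, 0.2, 0.2)
    noise_sd: float = 1.0
    cut_points: tuple[float, float, float, float] = (-0.5, 1.0, 2.0, 3.0)
    center_margin: int = 4

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if list(self.cut_points) != sorted(set(self.cut_points)):
            raise ValueError("cut_points must be strictly ascending")
        if not self.grid.contains(self.roi_center):
            raise ValueError("ROI center must lie inside the grid")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"dims": self.grid.dims, "voxel_size": self.grid.voxel_size}
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    roi_mask: np.ndarray
    involvement_fraction: np.ndarray
    latent: np.ndarray
    categories: list[FrequencyCategory]

    def to_dict(self) -> dict:
        return {
            "involvement_fraction": self.involvement_fraction.tolist(),
            "latent": self.latent.tolist(),
            "categories": [c.value for c in self.categories],
            "roi_n_voxels": int(self.roi_mask.sum()),
        }


def _sphere_mask(grid: TemplateGrid, center: Sequence[int], radius: float) -> np.ndarray:
    ix, iy, iz = np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij")
    d2 = (ix - center[0]) ** 2 + (iy - center[1]) ** 2 + (iz - center[2]) ** 2
    return d2 <= radius**2


def simulate_lesion(
    grid: TemplateGrid,
    center: Sequence[float],
    target_volume_cm3: float,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> LesionVolume:
    """One connected blob of (almost exactly) the requested volume.

    The blob is the sublevel set of a randomly stretched ellipsoidal
    Gaussian bump centred at ``center``: taking the ``k`` voxels of
    smallest elliptical distance, with ``k`` the target voxel count, is
    exactly thresholding the bump at the level that yields that count,
    and the sublevel set of a convex quadratic is connected.
    """
    target_count = int(round(target_volume_cm3 / grid.voxel_volume_cm3))
    if target_count < 1:
        target_count = 1
    if target_count > grid.n_voxels:
        raise ValueError(
            f"target volume {target_volume_cm3:.1f} cm^3 exceeds the grid volume"
        )
    # random per-axis stretches give ellipsoidal, non-spherical blobs
    scales = np.exp(rng.normal(0.0, 0.25, size=3))
    ix, iy, iz = np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij")
    d2 = (
        ((ix - center[0]) / scales[0]) ** 2
        + ((iy - center[1]) / scales[1]) ** 2
        + ((iz - center[2]) / scales[2]) ** 2
    )
    flat = d2.ravel()
    keep = np.argpartition(flat, target_count - 1)[:target_count]
    data = np.zeros(grid.n_voxels, dtype=np.uint8)
    data[keep] = 1
    return LesionVolume(subject_id, data.reshape(grid.dims), grid)


def _truncated_normal(rng, mean, sd, lower, upper):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lower <= v <= upper:
            return v
    return float(np.clip(rng.normal(mean, sd), lower, upper))


def _calibrate_truncated_mean(target, sd, lower, upper):
    """Pre-truncation location whose truncated-normal mean equals ``target``.

    Truncating at the lower bound inflates the realized mean, so drawing
    from Normal(target, sd) would overshoot the configured cohort mean by
    ~10 cm^3 at the default settings.
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def gap(mu):
        a, b = (lower - mu) / sd, (upper - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target

    return float(brentq(gap, target - 3 * sd, target + sd, xtol=1e-6))


def _categorical(rng, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[LesionVolume], list[ClinicalRecord], GroundTruth]:
    """Draw a full lesion-symptom cohort plus its ground truth.

    Identical configs (including the seed) yield bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    roi = _sphere_mask(grid, config.roi_center, config.roi_radius)
    roi_size = int(roi.sum())
    max_vol = 0.5 * grid.n_voxels * grid.voxel_volume_cm3
    vol_mu = _calibrate_truncated_mean(
        config.lesion_volume_mean, config.lesion_volume_sd,
        config.lesion_volume_min, max_vol,
    )
    lo = np.array([config.center_margin] * 3)
    hi = np.array(grid.dims) - config.center_margin

    masks: list[LesionVolume] = []
    records: list[ClinicalRecord] = []
    fracs = np.empty(config.n_subjects)
    latents = np.empty(config.n_subjects)
    cats: list[FrequencyCategory] = []
    b_sex, b_age, b_vol = config.covariate_betas

    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        center = rng.integers(lo, hi)
        vol = _truncated_normal(
            rng, vol_mu, config.lesion_volume_sd,
            config.lesion_volume_min, max_vol,
        )
        lesion = simulate_lesion(grid, center, vol, rng, subject_id=sid)
        realized_vol = lesion.n_voxels * grid.voxel_volume_cm3
        frac = float((lesion.data.astype(bool) & roi).sum()) / roi_size

        age = float(rng.uniform(16.0, 68.0))
        sex = int(rng.random() < 0.6)
        age_z = (age - 42.0) / 15.0
        vol_z = (realized_vol - 80.8) / 60.0
        latent = (
            config.effect_gamma * frac
            + b_sex * sex + b_age * age_z + b_vol * vol_z
            + rng.normal(0.0, config.noise_sd)
        )
        score = int(np.searchsorted(config.cut_points, latent, side="left"))
        cat = _FREQ_BY_SCORE[score]

        if cat == FrequencyCategory.NONE:
            stype = SeizureType.NONE
            asm = rng.random() < _ASM_P_NOSEIZURE
            engel = None
        else:
            stype = _categorical(rng, _SEIZURE_TYPE_P)
            asm = rng.random() < _ASM_P_SEIZURE
            if rng.random() < _ENGEL_AVAILABLE_P:
                # worse control when seizures were frequent preoperatively
                p_unc = 0.30 + 0.20 * (score >= 2)
                if rng.random() < p_unc:
                    engel = [EngelClass.II, EngelClass.III, EngelClass.IV][
                        rng.choice(3, p=[0.5, 0.3, 0.2])
                    ]
                else:
                    engel = EngelClass.I
            else:
                engel = None

        lobes = {lobe for lobe in Lobe if rng.random() < _LOBE_P[lobe]}
        if not lobes:
            lobes = {Lobe.FRONTAL}
        hemisphere = (
            Hemisphere.LEFT if center[0] < grid.dims[0] / 2 else Hemisphere.RIGHT
        )

        records.append(ClinicalRecord(
            subject_id=sid,
            age=age,
            sex=sex,
            tumor_volume=realized_vol,
            frequency_category=cat,
            seizure_type=stype,
            asm_use=bool(asm),
            resection=(
                Resection.GROSS_TOTAL if rng.random() < _GROSS_TOTAL_P
                else Resection.PARTIAL
            ),
            pathology=_categorical(rng, _PATHOLOGY_P),
            hemisphere=hemisphere,
            lobes=frozenset(lobes),
            engel_class=engel,
        ))
        masks.append(lesion)
        fracs[i] = frac
        latents[i] = latent
        cats.append(cat)

    truth = GroundTruth(
        roi_mask=roi, involvement_fraction=fracs, latent=latents, categories=cats
    )
    return masks, records, truth


def recovery_metrics(
    retained: np.ndarray, roi_mask: np.ndarray, eligible: np.ndarray
) -> dict[str, float]:
    """Voxel-level sensitivity, specificity and Dice versus the true ROI.

    Only voxels inside the eligibility (power) screen are scored: outside
    it the method never had a chance to detect anything.
    """
    ret = np.asarray(retained, bool)
    roi = np.asarray(roi_mask, bool)
    elig = np.asarray(eligible, bool)
    if ret.shape != roi.shape or roi.shape != elig.shape:
        raise ValueError("maps must share a grid")
    if not elig.any():
        raise ValueError("eligible set is empty")
    ret, roi = ret & elig, roi & elig
    tp = float((ret & roi).sum())
    fn = float((elig & ~ret & roi).sum())
    fp = float((ret & ~roi).sum())
    tn = float((elig & ~ret & ~roi).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return {"sensitivity": sens, "specificity": spec, "dice": dice}


def write_cohort(
    out_dir: str | Path,
    masks: Sequence[LesionVolume],
    records: Sequence[ClinicalRecord],
    truth: GroundTruth | None = None,
    config: SimulationConfig | None = None,
) -> Path:
    """Write the NIfTI + CSV + ground-truth layout the pipeline consumes."""
    from .clinical import records_to_dataframe
    from .imaging import write_map

    out = Path(out_dir)
    mask_dir = out / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    for m in masks:
        write_map(m.data, m.grid, mask_dir / f"{m.subject_id}.nii.gz")
    records_to_dataframe(records).to_csv(out / "clinical.csv", index=False)
    if truth is not None:
        grid = masks[0].grid
        write_map(truth.roi_mask.astype(np.uint8), grid, out / "roi_mask.nii.gz")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
    if config is not None:
        with open(out / "simulation_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)
    return out
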