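"""End-to-end orchestration: cohort -> maps -> clusters -> reports.

Ties the stages together in the order the method runs (overlap map,
power screen, per-voxel GLM, permutation threshold, clusters, peak
involvement) behind a single config object, and handles run manifests,
logging and the on-disk layout of results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import ClinicalRecord, RankTestResult
from .core import (
    ClusterResult,
    PermutationNull,
    PowerMap,
    StatMap,
    apply_threshold,
    build_design,
    eligible_mask,
    extract_clusters,
    involvement_vs_frequency,
    label_involvement,
    permutation_null,
    power_map,
    voxelwise_glm,
)
from .imaging import LesionVolume, OverlapMap, overlap_map, write_map

logger = logging.getLogger("vlsm")

__all__ = ["VlsmConfig", "VlsmResult", "run_vlsm", "write_results",
           "build_manifest", "write_manifest", "setup_logging"]


def setup_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> None:
    """Route pipeline progress to stderr and optionally a run log file."""
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class VlsmConfig:
    """Analysis parameters; stochastic stages require an explicit seed."""

    seed: int
    alpha: float = 0.05
    n_permutations: int = 1000
    connectivity: int = 26
    power_effect_size: float = 1.0
    power_threshold: float = 0.8
    scheme: str = "score"
    threshold_mode: str = "voxelwise"
    include_no_seizure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "VlsmConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw or raw["seed"] is None:
            raise ValueError("config must provide an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VlsmResult:
    overlap: OverlapMap
    power: PowerMap
    eligible: np.ndarray
    stat: StatMap
    null: PermutationNull
    retained: np.ndarray
    clusters: ClusterResult
    involvement: np.ndarray | None
    involvement_test: RankTestResult | None
    subject_ids: list[str]
    scores: np.ndarray
    config: VlsmConfig


def run_vlsm(
    masks: Sequence[LesionVolume],
    records: Sequence[ClinicalRecord],
    config: VlsmConfig,
) -> VlsmResult:
    """Run the full mapping on an in-memory cohort.

    Subjects without a seizure history enter with score 0 by default
    (``include_no_seizure``); the power screen is applied before the GLM
    and the permutation null, so only voxels with adequate lesion
    coverage are ever tested.
    """
    ids_m = [m.subject_id for m in masks]
    ids_r = [r.subject_id for r in records]
    if ids_m != ids_r:
        raise ValueError("mask order does not match record order")
    if not config.include_no_seizure:
        keep = [i for i, r in enumerate(records) if r.has_seizure]
        masks = [masks[i] for i in keep]
        records = [records[i] for i in keep]
    logger.info("cohort: %d subjects on grid %s", len(masks), masks[0].grid.dims)

    ov = overlap_map(list(masks))
    pw = power_map(ov, config.power_effect_size, config.alpha)
    elig = eligible_mask(pw, config.power_threshold)
    logger.info("power screen: %d of %d voxels eligible",
                int(elig.sum()), masks[0].grid.n_voxels)

    design = build_design(records)
    stat = voxelwise_glm(list(masks), design, elig)
    logger.info("GLM done: %d tested voxels, df=%d",
                int(stat.eligible.sum()), stat.df_residual)

    null = permutation_null(
        list(masks), design, stat.eligible,
        n_permutations=config.n_permutations, alpha=config.alpha,
        seed=config.seed, scheme=config.scheme, mode=config.threshold_mode,
    )
    retained = apply_threshold(stat, null)
    clusters = extract_clusters(retained, stat.t, config.connectivity)
    logger.info("threshold: %d voxels retained in %d clusters",
                int(retained.sum()), len(clusters.clusters))

    involvement = None
    inv_test = None
    scores = np.array([r.frequency_score for r in records])
    if clusters.clusters:
        peak = clusters.clusters[0].peak
        involvement = label_involvement(list(masks), peak)
        if involvement.any() and not involvement.all():
            inv_test = involvement_vs_frequency(involvement, scores)
            logger.info("peak %s involvement: %d subjects, Mann-Whitney p=%.4g",
                        peak, int(involvement.sum()), inv_test.p_value)
    return VlsmResult(
        overlap=ov, power=pw, eligible=elig, stat=stat, null=null,
        retained=retained, clusters=clusters, involvement=involvement,
        involvement_test=inv_test, subject_ids=[r.subject_id for r in records],
        scores=scores, config=config,
    )


def write_results(out_dir: str | Path, result: VlsmResult) -> Path:
    """Write all maps (NIfTI), the cluster table and involvement CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.stat.grid
    write_map(np.nan_to_num(result.stat.t), grid, out / "t_map.nii.gz")
    write_map(np.nan_to_num(result.stat.beta), grid, out / "beta_map.nii.gz")
    write_map(result.power.power, grid, out / "power_map.nii.gz")
    write_map(np.nan_to_num(result.null.threshold), grid, out / "threshold_map.nii.gz")
    write_map(result.retained.astype(np.uint8), grid, out / "retained_mask.nii.gz")
    write_map(result.overlap.counts.astype(np.int32), grid, out / "overlap_map.nii.gz")
    write_map(result.clusters.labels.astype(np.int32), grid, out / "cluster_labels.nii.gz")
    result.clusters.to_table().to_csv(out / "clusters.csv", index=False)
    inv = pd.DataFrame({
        "subject_id": result.subject_ids,
        "frequency_score": result.scores,
        "peak_involved": (
            result.involvement.astype(int)
            if result.involvement is not None
            else [""] * len(result.subject_ids)
        ),
    })
    inv.to_csv(out / "involvement.csv", index=False)
    if result.involvement_test is not None:
        with open(out / "involvement_test.json", "w") as fh:
            json.dump({
                "u_statistic": result.involvement_test.u_statistic,
                "p_value": result.involvement_test.p_value,
                "n_involved": result.involvement_test.n1,
                "n_not_involved": result.involvement_test.n2,
            }, fh, indent=1)
    return out


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    config: dict,
    seed: int | None,
    input_paths: Sequence[str | Path] = (),
) -> dict:
    return {
        "command": command,
        "version": __version__,
        "config": config,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(out_dir: str | Path, manifest: dict) -> Path:
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
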