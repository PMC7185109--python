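"""File formats: cohort CSV, NIfTI volumes, configs and run manifests.

Cohort tables are plain CSV with columns subject_id, label, age, sex,
education, mmse, then one column per in-mask voxel named by its linear
(flat, C-order) voxel index.  Volumes are NIfTI with an axis-aligned
RAS affine; masks carry a JSON sidecar noting the 0-based index
convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid, VoxelMask
from .simulate import CohortDataset

__all__ = [
    "PipelineConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_nifti_volume",
    "write_nifti_volume",
    "read_mask",
    "write_mask",
    "write_manifest",
]

COVARIATE_COLS = ["age", "sex", "education", "mmse"]
MANDATORY_COLS = ["subject_id", "label"] + COVARIATE_COLS


@dataclass
class PipelineConfig:
    """Full pipeline configuration; serializes losslessly to JSON and
    rejects unknown keys on load."""

    nu: float = 1.0
    kappa: float = 10.0
    rho: float = 1.0
    alpha: float | None = None
    t_max: float | None = None
    checkpoint_stride: int = 20
    patience: int = 5
    max_steps: int = 30000
    K: int = 10
    R: int = 10
    seed: int = 0
    plateau_eps: float = 0.0
    signed_ranking: bool = False
    signed_atlas: bool = False
    welch: bool = False
    yates: bool = False
    ci_method: str = "t"  # or "bootstrap"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hyper(self):
        from .lbi import ModelHyperparams

        return ModelHyperparams(
            nu=self.nu,
            kappa=self.kappa,
            alpha=self.alpha,
            rho=self.rho,
            t_max=self.t_max,
            checkpoint_stride=self.checkpoint_stride,
            patience=self.patience,
            max_steps=self.max_steps,
            seed=self.seed,
        )


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    """Write a cohort as CSV in the canonical column order."""
    feat_cols = [str(int(i)) for i in dataset.mask.flat_indices]
    df = pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "label": dataset.labels,
        }
    )
    for c in COVARIATE_COLS:
        df[c] = np.asarray(dataset.covariates[c])
    feat = pd.DataFrame(dataset.features, columns=feat_cols)
    # %.17g round-trips float64 exactly
    pd.concat([df, feat], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path, mask: VoxelMask) -> CohortDataset:
    """Read a cohort CSV; the mask supplies the expected voxel columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError("empty cohort table")
    missing = [c for c in MANDATORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    feat_cols = [str(int(i)) for i in mask.flat_indices]
    missing_feat = [c for c in feat_cols if c not in df.columns]
    if missing_feat:
        raise ValueError(
            f"{len(missing_feat)} voxel columns absent (mask/cohort mismatch)"
        )
    features = df[feat_cols].to_numpy(dtype=float)
    if not np.isfinite(features).all():
        raise ValueError("non-numeric or missing feature values")
    return CohortDataset(
        features,
        df["label"].to_numpy(dtype=int),
        df[COVARIATE_COLS].reset_index(drop=True),
        mask,
        subject_ids=df["subject_id"].astype(str).tolist(),
    )


def _check_affine(affine: np.ndarray) -> np.ndarray:
    lin = affine[:3, :3]
    if np.any(np.abs(lin - np.diag(np.diag(lin))) > 1e-6) or np.any(np.diag(lin) <= 0):
        raise ValueError(
            "only axis-aligned RAS affines (positive diagonal) are supported; "
            "resample oblique volumes first"
        )
    return np.diag(lin)


def read_nifti_volume(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    vs = _check_affine(img.affine)
    return VoxelGrid(np.asarray(img.dataobj), tuple(float(v) for v in vs))


def write_nifti_volume(grid: VoxelGrid, path: str | Path, dtype=None) -> None:
    data = np.asarray(grid.data)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    write_nifti_volume(
        VoxelGrid(mask.inside.astype(np.uint8), mask.voxel_size_mm), path
    )
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "index_origin": 0,
                "axis_order": "RAS",
                "voxel_size_mm": list(mask.voxel_size_mm),
                "n_in_mask": mask.n_features,
            },
            indent=2,
        )
    )


def read_mask(path: str | Path) -> VoxelMask:
    grid = read_nifti_volume(path)
    return VoxelMask(np.asarray(grid.data) > 0, grid.voxel_size_mm)


def write_manifest(path: str | Path, config: PipelineConfig, seed: int, extra=None):
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__

    cfg = json.dumps(asdict(config), sort_keys=True)
    manifest = {
        "config": json.loads(cfg),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
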