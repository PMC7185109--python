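"""Cross-cohort transfer: train on one cohort, test on another.

Verifies generalization of prediction and stability of feature
selection across cohorts sharing the same voxel grid and mask.  The
trained bundle carries its own standardization statistics; a target
cohort is standardized with the *source* statistics (a deployed model
cannot peek at target distributions), with target-refit standardization
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .crossval import binary_metrics, roc_auc
from .grid import VoxelMask
from .lbi import (
    ModelHyperparams,
    ModelState,
    Standardizer,
    fit_path,
    predict_label,
    predict_proba,
    select_checkpoint,
)
from .operator import build_difference_operator
from .simulate import CohortDataset

__all__ = ["ModelBundle", "train_full", "external_test", "support_overlap"]


@dataclass
class ModelBundle:
    """A fitted model plus everything needed to apply it elsewhere:
    selected state, standardization statistics, and the mask contract."""

    state: ModelState
    standardizer: Standardizer
    mask_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask_inside: np.ndarray
    hyper: ModelHyperparams = field(default_factory=ModelHyperparams)

    def check_mask(self, mask: VoxelMask) -> None:
        problems = []
        if tuple(mask.dims) != tuple(self.mask_dims):
            problems.append(f"dims {mask.dims} != {self.mask_dims}")
        if not np.allclose(mask.voxel_size_mm, self.voxel_size_mm):
            problems.append(
                f"voxel size {mask.voxel_size_mm} != {self.voxel_size_mm}"
            )
        elif mask.inside.shape == np.asarray(self.mask_inside).shape:
            diff = int(np.sum(mask.inside != self.mask_inside))
            if diff:
                problems.append(f"{diff} voxels differ between masks")
        if problems:
            raise ValueError("mask contract violated: " + "; ".join(problems))


def train_full(
    dataset: CohortDataset, hyper: ModelHyperparams, seed: int | None = None
) -> ModelBundle:
    """Fit on all subjects with an internal stratified 80/20 split for
    checkpoint selection; standardization on the full cohort."""
    seed = hyper.seed if seed is None else seed
    X, y = dataset.features, np.asarray(dataset.labels)
    D = build_difference_operator(dataset.mask, hyper.rho)
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=0.2, stratify=y, random_state=seed % (2**32)
    )
    path = fit_path(Xs[idx_tr], y[idx_tr], D, hyper, Xs[idx_val], y[idx_val])
    state = select_checkpoint(path, Xs[idx_val], y[idx_val], use_cached=True)
    return ModelBundle(
        state,
        std,
        tuple(dataset.mask.dims),
        tuple(dataset.mask.voxel_size_mm),
        dataset.mask.inside.copy(),
        hyper,
    )


def external_test(
    bundle: ModelBundle,
    target: CohortDataset,
    refit_standardization: bool = False,
) -> dict[str, float]:
    """Apply a trained bundle to an external cohort and score it."""
    bundle.check_mask(target.mask)
    std = (
        Standardizer.fit(target.features)
        if refit_standardization
        else bundle.standardizer
    )
    Xs = std.transform(target.features)
    y = np.asarray(target.labels)
    proba = predict_proba(bundle.state, Xs)
    pred = predict_label(bundle.state, Xs)
    acc, sens, spec = binary_metrics(y, pred)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "auc": roc_auc(y, proba),
    }


def support_overlap(bundle_a: ModelBundle, bundle_b: ModelBundle, n: int) -> float:
    """Jaccard overlap of the two models' top-n voxels by |beta|."""
    top_a = set(np.argsort(-np.abs(bundle_a.state.beta), kind="stable")[:n].tolist())
    top_b = set(np.argsort(-np.abs(bundle_b.state.beta), kind="stable")[:n].tolist())
    union = top_a | top_b
    return len(top_a & top_b) / len(union) if union else 1.0
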