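"""Reproducible benchmark experiments on synthetic cohorts.

These drivers bundle the package's main end-to-end computations at the
standard study conditions so that results can be regenerated from a
single seed: support recovery of planted lesion voxels, repeated
cross-validated classification, null calibration, key-voxel plateau
analysis, and cross-cohort transfer.  They are what the acceptance
script and the heavier integration tests run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .crossval import repeat_cv
from .interpret import rank_weights, topn_curve_from_cv
from .lbi import ModelHyperparams
from .model import SplitLBIModel
from .simulate import SMALL_CONFIG, SimulationConfig, null_config, simulate_cohort
from .transfer import external_test, support_overlap, train_full

__all__ = [
    "support_recovery_experiment",
    "null_calibration_experiment",
    "keyvoxel_experiment",
    "transfer_experiment",
]


def _seeded(base_seed: int, i: int) -> int:
    return (base_seed * 9973 + i) % (2**31)


def support_recovery_experiment(
    base_seed: int = 0,
    n_seeds: int = 5,
    R: int = 10,
    K: int = 10,
    config: SimulationConfig = SMALL_CONFIG,
    hyper: ModelHyperparams | None = None,
) -> dict:
    """Planted-lesion recovery and repeated CV at the strong-signal setting.

    Per seed: draw a cohort, fit the full-cohort model, count how many
    of the top-10 voxels by sparse-estimator magnitude are true lesion
    voxels, and run R x K-fold cross-validation.  Returns per-seed
    values and their medians.
    """
    hyper = hyper or ModelHyperparams()
    hits, accs, aucs, senss, specs = [], [], [], [], []
    for i in range(n_seeds):
        seed = _seeded(base_seed, i + 1)
        ds, truth = simulate_cohort(replace(config, seed=seed))
        res = SplitLBIModel.from_cohort(ds).fit(seed=seed)
        top10 = np.argsort(-np.abs(res.sparse_params), kind="stable")[:10]
        hits.append(
            len(set(top10.tolist()) & set(truth.lesion_voxel_indices.tolist()))
        )
        cv = repeat_cv(ds, hyper, R=R, K=K, seed=seed)
        accs.append(cv.mean["accuracy"])
        aucs.append(cv.mean["auc"])
        senss.append(cv.mean["sensitivity"])
        specs.append(cv.mean["specificity"])
    return {
        "hits_top10": hits,
        "cv_accuracy": accs,
        "cv_auc": aucs,
        "cv_sensitivity": senss,
        "cv_specificity": specs,
        "median_hits_top10": float(np.median(hits)),
        "median_cv_accuracy": float(np.median(accs)),
        "median_cv_auc": float(np.median(aucs)),
        "median_cv_sensitivity": float(np.median(senss)),
        "median_cv_specificity": float(np.median(specs)),
        "n_subjects": int(config.n_ad + config.n_nc),
    }


def null_calibration_experiment(
    base_seed: int = 0,
    n_seeds: int = 3,
    K: int = 10,
    config: SimulationConfig = SMALL_CONFIG,
    hyper: ModelHyperparams | None = None,
) -> dict:
    """Cross-validated performance on zero-effect cohorts.

    With no planted signal the pooled accuracy should sit inside the
    binomial band around the majority-class rate and the AUC near 1/2.
    """
    hyper = hyper or ModelHyperparams()
    accs, aucs = [], []
    for i in range(n_seeds):
        seed = _seeded(base_seed, 100 + i)
        ds, _ = simulate_cohort(null_config(config, seed=seed))
        cv = repeat_cv(ds, hyper, R=1, K=K, seed=seed)
        accs.append(cv.mean["accuracy"])
        aucs.append(cv.mean["auc"])
    n = config.n_ad + config.n_nc
    majority = max(config.n_ad, config.n_nc) / n
    return {
        "accuracy": accs,
        "auc": aucs,
        "median_accuracy": float(np.median(accs)),
        "median_auc": float(np.median(aucs)),
        "majority_rate": majority,
        "binomial_halfwidth": 1.96 * float(np.sqrt(majority * (1 - majority) / n)),
        "n_subjects": n,
    }


def keyvoxel_experiment(
    base_seed: int = 0,
    config: SimulationConfig = SMALL_CONFIG,
    K: int = 10,
    hyper: ModelHyperparams | None = None,
) -> dict:
    """Out-of-fold top-n accuracy curve and its plateau point n_key."""
    from .crossval import make_folds, run_cv

    hyper = hyper or ModelHyperparams()
    seed = _seeded(base_seed, 1)
    ds, truth = simulate_cohort(replace(config, seed=seed))
    res = SplitLBIModel.from_cohort(ds).fit(seed=seed)
    plan = make_folds(ds.labels, K, seed=seed)
    rep = run_cv(ds, hyper, plan, keep_models=True)
    curve = topn_curve_from_cv(rep, ds, rank_weights(res.selected.beta))
    n_key = int(curve.n_key)
    top = set(curve.ranking[:n_key].tolist())
    planted = set(truth.lesion_voxel_indices.tolist()) | set(
        truth.bias_voxel_indices.tolist()
    )
    return {
        "n_key": n_key,
        "n_voxels": int(ds.n_features),
        "accuracy_at_n_key": float(curve.accuracy[n_key - 1]),
        "max_accuracy": float(curve.accuracy.max()),
        "plateau_precision_planted": len(top & planted) / len(top),
    }


def transfer_experiment(
    base_seed: int = 0,
    config: SimulationConfig = SMALL_CONFIG,
    hyper: ModelHyperparams | None = None,
) -> dict:
    """Train on one cohort, test on a second cohort of the same disease
    process (shared ground truth, independent subjects)."""
    hyper = hyper or ModelHyperparams()
    s1, s2 = _seeded(base_seed, 201), _seeded(base_seed, 202)
    ds_a, truth = simulate_cohort(replace(config, seed=s1))
    ds_b, _ = simulate_cohort(replace(config, seed=s2), truth=truth)
    bundle_a = train_full(ds_a, hyper, seed=s1)
    bundle_b = train_full(ds_b, hyper, seed=s2)
    ab = external_test(bundle_a, ds_b)
    ba = external_test(bundle_b, ds_a)
    return {
        "accuracy_ab": ab["accuracy"],
        "accuracy_ba": ba["accuracy"],
        "auc_ab": ab["auc"],
        "auc_ba": ba["auc"],
        "top10_overlap": support_overlap(bundle_a, bundle_b, 10),
        "n_subjects": int(config.n_ad + config.n_nc),
    }
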