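"""Model interpretation: key voxels, atlas weight maps, cohort statistics.

Key-voxel analysis ranks the dense coefficients, re-evaluates the
classifier keeping only the top-n weights for n = 1..P, and finds the
plateau point n_key past which accuracy no longer improves — the
corresponding voxels are the "key voxels".  Weight maps are resampled
to atlas resolution by nearest-neighbour interpolation and aggregated
per labelled region into a table of absolute weight and relative weight
percentage.  Cohort statistics mirror the usual case-control summary
table (two-sample t from printed summaries, 2x2 chi-square) and the
partial-correlation analysis of regional gray matter against MMSE with
age/sex/education as nuisance covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import VoxelGrid
from .lbi import ModelState

__all__ = [
    "WeightCurve",
    "rank_weights",
    "topn_accuracy_curve",
    "topn_curve_from_cv",
    "find_plateau",
    "upsample_nearest",
    "aggregate_by_atlas",
    "partial_correlation",
    "ttest_from_summary",
    "chisq_2x2",
]


@dataclass
class WeightCurve:
    """Accuracy as a function of the number of top-ranked weights kept."""

    ns: np.ndarray
    accuracy: np.ndarray
    ranking: np.ndarray

    @property
    def n_key(self) -> int:
        return find_plateau(self.accuracy, ns=self.ns)


def rank_weights(beta: np.ndarray, signed: bool = False) -> np.ndarray:
    """Feature indices by decreasing |beta| (or signed beta); ties break
    to the lower index."""
    beta = np.asarray(beta, dtype=float)
    key = beta if signed else np.abs(beta)
    # stable sort on -key -> decreasing value, ascending index within ties
    return np.argsort(-key, kind="stable")


def topn_accuracy_curve(
    state: ModelState,
    X: np.ndarray,
    y: np.ndarray,
    ns: np.ndarray | None = None,
    signed: bool = False,
) -> WeightCurve:
    """Accuracy of the classifier restricted to its top-n weights.

    For each n the lower-ranked coefficients are zeroed (intercept
    kept) and the masked model is scored on (X, y).  Computed
    incrementally, O(N*P) overall.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ranking = rank_weights(state.beta, signed=signed)
    P = len(ranking)
    if ns is None:
        ns = np.arange(1, P + 1)
    ns = np.asarray(ns)
    eta = np.full(X.shape[0], state.intercept)
    acc = np.empty(P)
    running = np.empty(P)
    for pos, j in enumerate(ranking):
        eta = eta + X[:, j] * state.beta[j]
        running[pos] = np.mean((eta > 0).astype(int) == y)
    acc = running[ns - 1]
    return WeightCurve(ns, acc, ranking)


def topn_curve_from_cv(repeat, dataset, ranking: np.ndarray) -> WeightCurve:
    """Out-of-fold top-n accuracy curve from one CV repeat.

    Each fold's model is masked to the shared top-n ranking before
    predicting its held-out fold, so every accuracy value is computed
    on data unseen by the corresponding model.
    """
    X, y = dataset.features, np.asarray(dataset.labels)
    plan = repeat.plan
    if not repeat.fold_states:
        raise ValueError("CV repeat was run without keep_models=True")
    P = len(ranking)
    n_sub = len(y)
    etas = np.empty((P, n_sub))
    for fold in range(plan.K):
        te = plan.test_indices(fold)
        st = repeat.fold_states[fold]
        std = repeat.fold_standardizers[fold]
        Xs = std.transform(X[te])
        eta = np.full(len(te), st.intercept)
        for pos, j in enumerate(ranking):
            eta = eta + Xs[:, j] * st.beta[j]
            etas[pos, te] = eta
    acc = ((etas > 0).astype(int) == y[None, :]).mean(axis=1)
    return WeightCurve(np.arange(1, P + 1), acc, ranking)


def find_plateau(accuracy: np.ndarray, eps: float = 0.0, ns: np.ndarray | None = None) -> int:
    """Smallest n whose accuracy reaches the curve maximum and stays
    there (within eps) for every larger n."""
    acc = np.asarray(accuracy, dtype=float)
    if acc.size == 0:
        raise ValueError("empty curve")
    target = acc.max() - eps
    ok = acc >= target - 1e-15
    # suffix_all[i] == True iff every point from i on sits at the max
    suffix_all = np.flip(np.logical_and.accumulate(np.flip(ok)))
    if suffix_all.any():
        i = int(np.argmax(suffix_all))
    else:
        # no sustained plateau at this eps: fall back to the first maximizer
        i = int(np.argmax(acc))
    if ns is not None:
        return int(np.asarray(ns)[i])
    return i + 1


def upsample_nearest(
    coarse: VoxelGrid,
    target_dims: tuple[int, int, int],
    target_voxel_size_mm: tuple[float, float, float],
) -> VoxelGrid:
    """Nearest-neighbour resampling of a coarse volume to a finer grid.

    Both grids share the physical origin at the corner of voxel (0,0,0);
    each fine voxel takes the value of the coarse voxel whose center is
    nearest to its own center (a physical-extent mismatch beyond one
    coarse voxel per axis is rejected).
    """
    cs = np.asarray(coarse.voxel_size_mm)
    fs = np.asarray(target_voxel_size_mm, dtype=float)
    cd = np.asarray(coarse.dims)
    fd = np.asarray(target_dims)
    if np.any(np.abs(cd * cs - fd * fs) > cs):
        raise ValueError(
            f"incompatible physical extents: coarse {cd * cs} mm vs target {fd * fs} mm"
        )
    idx = []
    for ax in range(3):
        centers = (np.arange(fd[ax]) + 0.5) * fs[ax]
        j = np.floor(centers / cs[ax]).astype(int)  # nearest coarse center
        idx.append(np.clip(j, 0, cd[ax] - 1))
    fine = coarse.data[np.ix_(idx[0], idx[1], idx[2])]
    return VoxelGrid(fine, tuple(float(v) for v in fs))


def aggregate_by_atlas(
    weights: VoxelGrid,
    atlas: VoxelGrid,
    label_names: dict[int, str] | None = None,
    signed: bool = False,
) -> pd.DataFrame:
    """Aggregate a weight volume over atlas regions.

    Region weight is the sum of |w| (or signed w) across voxels carrying
    that label; percent is relative to the total over all regions;
    volume is label voxel count times voxel volume; centroid is the mean
    physical coordinate of the labelled voxels.  Returns a table sorted
    by decreasing weight percent.
    """
    if weights.dims != atlas.dims:
        raise ValueError("weight and atlas volumes must share dims")
    labels = np.asarray(atlas.data).astype(int)
    if labels.max() <= 0:
        raise ValueError("atlas contains no positive labels")
    w = np.asarray(weights.data, dtype=float)
    w = w if signed else np.abs(w)
    flat_lab = labels.ravel()
    flat_w = w.ravel()
    present = np.unique(flat_lab[flat_lab > 0])
    sums = np.bincount(flat_lab[flat_lab > 0], weights=flat_w[flat_lab > 0])
    counts = np.bincount(flat_lab[flat_lab > 0])
    vs = np.asarray(atlas.voxel_size_mm)
    voxel_vol = float(np.prod(vs))
    coords = np.indices(atlas.dims).reshape(3, -1)
    rows = []
    total = sums.sum()
    for lab in present:
        sel = flat_lab == lab
        centroid = ((coords[:, sel].mean(axis=1) + 0.5) * vs)
        rows.append(
            {
                "label": int(lab),
                "name": (label_names or {}).get(int(lab), f"region_{lab}"),
                "volume_mm3": counts[lab] * voxel_vol,
                "centroid_x_mm": centroid[0],
                "centroid_y_mm": centroid[1],
                "centroid_z_mm": centroid[2],
                "weight": sums[lab],
                "weight_percent": 100.0 * sums[lab] / total if total > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows).sort_values("weight_percent", ascending=False)
    return df.reset_index(drop=True)


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized by OLS on [1, covariates]; the
    p-value is the t-transform with df = n - n_covariates - 2.  With no
    covariates this is the plain Pearson correlation and its p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        C = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    # residuals that are numerically zero relative to the centered data
    # mean the variable is covariate-determined: correlation undefined -> 0
    ssx, ssy = float(rx @ rx), float(ry @ ry)
    sx0 = float(np.sum((x - x.mean()) ** 2))
    sy0 = float(np.sum((y - y.mean()) ** 2))
    if ssx <= 1e-24 * max(sx0, 1.0) or ssy <= 1e-24 * max(sy0, 1.0):
        return 0.0, 1.0
    denom = np.sqrt(ssx * ssy)
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return r, float(p)


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2, welch: bool = False):
    """Two-sample t-test from group summaries (pooled by default,
    Welch behind the flag); returns (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chisq_2x2(counts, yates: bool = False):
    """Pearson chi-square on a 2x2 table (df=1), continuity correction
    behind the Yates flag; returns (statistic, p)."""
    table = np.asarray(counts)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)
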