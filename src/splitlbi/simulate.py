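"""Synthetic case-control cohorts of coarse gray-matter voxel features.

Emulates the statistical structure the classifier assumes in real
voxel-based morphometry data: a smooth gray-matter template on an
ellipsoidal brain mask, spatially contiguous atrophy clusters in the
patient group ("lesion features"), a handful of boundary voxels with
mistakenly *enlarged* values in patients ("procedural bias", the
artefact registration/segmentation introduces near tissue boundaries),
Gaussian between-subject and per-voxel noise, group-matched covariates,
and an MMSE cognition score driven down by each subject's realized
lesion load.  Ground truth (which voxels carry effects) is retained so
support recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import deque

import numpy as np
import pandas as pd

from .grid import VoxelMask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortDataset",
    "make_ellipsoid_mask",
    "plant_lesions",
    "simulate_cohort",
    "STUDY_CONFIG",
    "SMALL_CONFIG",
]

#: mask fraction tuned so the 24x28x24 grid holds ~2,500 in-mask voxels
DEFAULT_SEMI_AXES_FRACTION = 0.67

MMSE_BASE = 27.0


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator.

    Gray-matter features are in [0, 1] tissue-volume units; effects are
    additive on that scale (negative lesion_effect = atrophy in the AD
    group, positive bias_effect = procedural enlargement).
    """

    grid_dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    semi_axes_fraction: float = DEFAULT_SEMI_AXES_FRACTION
    n_ad: int = 57
    n_nc: int = 47
    n_lesion_clusters: int = 5
    lesion_cluster_radius: int = 2
    lesion_cluster_size: int | None = None  # exact voxels per cluster, overrides radius
    lesion_effect: float = -0.2
    n_bias_voxels: int = 10
    bias_effect: float = 0.1
    subject_sd: float = 0.02
    voxel_sd: float = 0.05
    mmse_slope: float = 65.0
    mmse_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ad", "n_nc", "n_lesion_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_bias_voxels < 0:
            raise ValueError("n_bias_voxels must be >= 0")
        if any(s < 0 for s in (self.subject_sd, self.voxel_sd, self.mmse_sd)):
            raise ValueError("noise standard deviations must be >= 0")


#: the default, study-scale conditions
STUDY_CONFIG = SimulationConfig()

#: support-recovery scale: ~300 voxels, 10 lesion voxels in 2 compact clusters
SMALL_CONFIG = SimulationConfig(
    grid_dims=(10, 10, 10),
    semi_axes_fraction=0.85,
    n_lesion_clusters=2,
    lesion_cluster_size=5,
    n_bias_voxels=10,
)


@dataclass
class GroundTruth:
    """Planted effect layout: lesion/bias feature indices and the
    per-voxel AD-group effect (nonzero exactly on their union)."""

    lesion_voxel_indices: np.ndarray
    bias_voxel_indices: np.ndarray
    effect: np.ndarray  # length P, GM units

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.lesion_voxel_indices, self.bias_voxel_indices)
        if overlap.size:
            raise ValueError("lesion and bias voxel sets must be disjoint")


@dataclass
class CohortDataset:
    """Subject x voxel feature matrix with labels and covariates."""

    features: np.ndarray  # (n, P) in [0, 1]
    labels: np.ndarray  # 1 = AD, 0 = NC
    covariates: pd.DataFrame  # age, sex, education, mmse
    mask: VoxelMask
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(len(self.labels))]

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def make_ellipsoid_mask(
    grid_dims: tuple[int, int, int],
    semi_axes_fraction: float | tuple[float, float, float] = DEFAULT_SEMI_AXES_FRACTION,
    voxel_size_mm: tuple[float, float, float] = (8.0, 8.0, 8.0),
) -> VoxelMask:
    """Centered ellipsoid stand-in for a template-derived brain mask.

    Semi-axis i is ``fraction_i * dims_i / 2``; a voxel is inside when
    its center satisfies the ellipsoid inequality.
    """
    dims = tuple(int(d) for d in grid_dims)
    if any(d <= 2 for d in dims):
        raise ValueError(f"degenerate grid dims {dims}: every axis must exceed 2")
    frac = np.broadcast_to(np.asarray(semi_axes_fraction, dtype=float), (3,))
    if np.any(frac <= 0) or np.any(frac > 1):
        raise ValueError("semi-axes fractions must lie in (0, 1]")
    center = (np.array(dims) - 1) / 2.0
    semi = frac * np.array(dims) / 2.0
    g = np.indices(dims).reshape(3, -1).T
    inside = ((((g - center) / semi) ** 2).sum(axis=1) <= 1.0).reshape(dims)
    return VoxelMask(inside, voxel_size_mm)


def _radial2(mask: VoxelMask, frac: float | tuple) -> np.ndarray:
    """Squared ellipsoidal radius (0 center, 1 surface) per feature."""
    dims = np.array(mask.dims)
    frac = np.broadcast_to(np.asarray(frac, dtype=float), (3,))
    center = (dims - 1) / 2.0
    semi = frac * dims / 2.0
    coords = mask.coords()
    return (((coords - center) / semi) ** 2).sum(axis=1)


def _neighbors(mask: VoxelMask) -> list[np.ndarray]:
    """6-connected in-mask neighbour lists in feature-index space."""
    dims = mask.dims
    lut = np.full(mask.inside.size, -1, dtype=np.int64)
    lut[mask.flat_indices] = np.arange(mask.n_features)
    coords = mask.coords()
    nbrs: list[list[int]] = [[] for _ in range(mask.n_features)]
    for ax in range(3):
        for step in (-1, 1):
            shifted = coords.copy()
            shifted[:, ax] += step
            ok = (shifted[:, ax] >= 0) & (shifted[:, ax] < dims[ax])
            flat = np.ravel_multi_index(shifted[ok].T, dims)
            feat = lut[flat]
            src = np.flatnonzero(ok)[feat >= 0]
            for s, f in zip(src, feat[feat >= 0]):
                nbrs[s].append(int(f))
    return [np.array(sorted(n), dtype=np.int64) for n in nbrs]


def plant_lesions(
    mask: VoxelMask,
    n_clusters: int,
    radius: int = 1,
    rng: np.random.Generator | None = None,
    size: int | None = None,
    candidate_features: np.ndarray | None = None,
    allowed_features: np.ndarray | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    """Grow pairwise-disjoint 6-connected lesion blobs inside the mask.

    Each cluster is grown by breadth-first search from a seeded center:
    in radius mode it is the BFS ball of the given graph radius (radius
    0 -> 1 voxel, radius 1 in open space -> center + 6 face neighbours);
    with ``size`` set it is the first ``size`` voxels in BFS order, a
    compact connected blob of exact size.  Returns sorted feature
    indices of all lesion voxels.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nbrs = _neighbors(mask)
    candidates = (
        np.arange(mask.n_features) if candidate_features is None else np.asarray(candidate_features)
    )
    if candidates.size == 0:
        raise ValueError("no candidate voxels to seed lesions")
    # growth never leaves the allowed region (defaults to the whole mask)
    taken: set[int] = set()
    if allowed_features is not None:
        allowed = set(int(v) for v in np.asarray(allowed_features))
        taken.update(j for j in range(mask.n_features) if j not in allowed)
    clusters: list[np.ndarray] = []
    for _ in range(n_clusters):
        for attempt in range(max_retries):
            center = int(rng.choice(candidates))
            if center in taken:
                continue
            blob = _grow_blob(center, nbrs, taken, radius=radius, size=size)
            if blob is not None:
                clusters.append(blob)
                taken.update(int(v) for v in blob)
                break
        else:
            raise RuntimeError(
                f"could not place {n_clusters} disjoint lesion clusters after "
                f"{max_retries} retries; mask too small"
            )
    return np.sort(np.concatenate(clusters))


def _grow_blob(center, nbrs, taken, radius, size):
    """BFS growth avoiding voxels already taken; None if target unreachable."""
    visited = {center}
    dist = {center: 0}
    order = [center]
    q = deque([center])
    while q:
        v = q.popleft()
        for w in nbrs[v]:
            w = int(w)
            if w in visited or w in taken:
                continue
            if size is None and dist[v] + 1 > radius:
                continue
            visited.add(w)
            dist[w] = dist[v] + 1
            order.append(w)
            q.append(w)
            if size is not None and len(order) >= size:
                q.clear()
                break
    if size is not None:
        if len(order) < size:
            return None
        return np.array(order[:size], dtype=np.int64)
    return np.array(order, dtype=np.int64)


def _template(mask: VoxelMask, frac) -> np.ndarray:
    """Baseline GM value per voxel: 0.7 at the center falling to 0.3 at
    the mask surface, mimicking higher GM density deep in the brain."""
    r2 = np.clip(_radial2(mask, frac), 0.0, 1.0)
    return 0.3 + 0.4 * (1.0 - r2)


def simulate_cohort(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[CohortDataset, GroundTruth]:
    """Draw one cohort under the configured conditions.

    Feature model per subject i, voxel j:
        x_ij = clip( template_j + g_i * effect_j + u_i + eps_ij , 0, 1)
    with g_i = 1 for AD, u_i ~ N(0, subject_sd^2), eps_ij ~ N(0,
    voxel_sd^2).  MMSE_i = clip(27 - mmse_slope * load_i + eta_i, 0, 30)
    where load_i is subject i's realized mean atrophy over lesion
    voxels.  Deterministic given the config (seed included).

    Passing an existing ``truth`` reuses its lesion/bias layout — the
    way to draw several cohorts of the same underlying disease process
    (e.g. for cross-cohort transfer experiments).
    """
    rng = np.random.default_rng(config.seed)
    mask = make_ellipsoid_mask(
        config.grid_dims, config.semi_axes_fraction, config.voxel_size_mm
    )
    P = mask.n_features
    template = _template(mask, config.semi_axes_fraction)

    if truth is None:
        # interior = strictly inside the boundary shell; lesions live
        # there, procedural-bias voxels on the outermost shell
        shell = mask.boundary_shell()
        interior = np.setdiff1d(np.arange(P), shell)
        lesion = plant_lesions(
            mask,
            config.n_lesion_clusters,
            radius=config.lesion_cluster_radius,
            rng=rng,
            size=config.lesion_cluster_size,
            candidate_features=interior,
            allowed_features=interior,
        )
        shell_free = np.setdiff1d(shell, lesion)
        if config.n_bias_voxels > shell_free.size:
            raise ValueError("not enough boundary voxels for the requested bias set")
        bias = np.sort(rng.choice(shell_free, size=config.n_bias_voxels, replace=False))

        effect = np.zeros(P)
        effect[lesion] = config.lesion_effect
        effect[bias] = config.bias_effect
        truth = GroundTruth(lesion, bias, effect)
    else:
        if truth.effect.shape != (P,):
            raise ValueError("ground truth does not match the configured grid")
        lesion = truth.lesion_voxel_indices
        effect = truth.effect

    tol = 0.05
    planted_mean = template + effect
    if planted_mean.min() < -tol or planted_mean.max() > 1 + tol:
        raise ValueError(
            "configured effects push mean GM values outside [0, 1] beyond "
            f"the truncation tolerance {tol}"
        )

    n = config.n_ad + config.n_nc
    g = np.concatenate([np.ones(config.n_ad), np.zeros(config.n_nc)])
    u = rng.normal(0.0, config.subject_sd, size=n)
    eps = rng.normal(0.0, config.voxel_sd, size=(n, P))
    X = template[None, :] + g[:, None] * effect[None, :] + u[:, None] + eps
    X = np.clip(X, 0.0, 1.0)

    # realized atrophy load: mean template-shortfall over lesion voxels
    load = (template[None, lesion] - X[:, lesion]).mean(axis=1)
    mmse = np.clip(
        MMSE_BASE - config.mmse_slope * load + rng.normal(0, config.mmse_sd, n), 0, 30
    )
    age = rng.normal(65.0, 9.0, n)
    sex = rng.binomial(1, 0.5, n)
    education = np.clip(rng.normal(11.0, 5.0, n), 0, None)
    cov = pd.DataFrame(
        {"age": age, "sex": sex, "education": education, "mmse": mmse}
    )
    dataset = CohortDataset(X, g.astype(int), cov, mask)
    return dataset, truth


def null_config(config: SimulationConfig = STUDY_CONFIG, seed: int = 0) -> SimulationConfig:
    """Same conditions with all planted effects switched off."""
    return replace(config, lesion_effect=0.0, bias_effect=0.0, seed=seed)
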