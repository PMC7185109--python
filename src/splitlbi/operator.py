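"""Structured difference operator D on the in-mask voxel graph.

D stacks an identity block (voxel-level sparsity) on top of a
rho-weighted incidence block of the 6-neighbourhood graph restricted to
the mask (spatially fused sparsity).  Penalising ``||D beta - gamma||^2``
with a sparse gamma therefore selects voxels while encouraging spatially
contiguous supports; rho=0 recovers pure L1-style voxel sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .grid import VoxelMask

__all__ = ["DifferenceOperator", "build_difference_operator", "spectral_norm_sq"]


@dataclass
class DifferenceOperator:
    """Sparse map from feature space R^P to penalty space R^(P+E)."""

    matrix: sparse.csr_matrix
    n_features: int
    n_edges: int
    rho: float
    edges: np.ndarray  # (E, 2) feature-index pairs, a < b, lexicographic

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def identity_block(self, v: np.ndarray) -> np.ndarray:
        """First-P-rows slice of a penalty-space vector."""
        return np.asarray(v)[: self.n_features]

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(path, self.matrix)


def mask_edges(mask: VoxelMask) -> np.ndarray:
    """Unordered face-adjacent in-mask voxel pairs as feature indices.

    Pairs are (a, b) with a < b, sorted lexicographically.
    """
    dims = mask.dims
    lut = np.full(mask.inside.size, -1, dtype=np.int64)
    lut[mask.flat_indices] = np.arange(mask.n_features)
    inside = mask.inside
    pairs = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, dims[ax] - 1)
        sl_hi[ax] = slice(1, dims[ax])
        both = inside[tuple(sl_lo)] & inside[tuple(sl_hi)]
        lo = np.zeros(dims, dtype=bool)
        lo[tuple(sl_lo)] = both
        a_flat = np.flatnonzero(lo.ravel())
        stride = int(np.prod(dims[ax + 1 :]))
        b_flat = a_flat + stride
        pairs.append(np.stack([lut[a_flat], lut[b_flat]], axis=1))
    edges = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
    if edges.size:
        edges = np.sort(edges, axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
    return edges


def build_difference_operator(mask: VoxelMask, rho: float = 1.0) -> DifferenceOperator:
    """Assemble D for a mask.  Rows 0..P-1 are the identity on features;
    with rho > 0, row P+e is rho*(beta_a - beta_b) for edge e=(a,b)."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    P = mask.n_features
    if P < 1:
        raise ValueError("mask selects no voxels")
    eye = sparse.identity(P, format="csr")
    if rho == 0:
        edges = np.empty((0, 2), dtype=np.int64)
        mat = eye
    else:
        edges = mask_edges(mask)
        E = edges.shape[0]
        if E:
            rows = np.repeat(np.arange(E), 2)
            cols = edges.ravel()
            vals = np.tile([rho, -rho], E)
            inc = sparse.csr_matrix((vals, (rows, cols)), shape=(E, P))
            mat = sparse.vstack([eye, inc], format="csr")
        else:
            mat = eye
    return DifferenceOperator(mat, P, edges.shape[0], float(rho), edges)


def spectral_norm_sq(
    A, tol: float = 1e-11, max_iter: int = 20000, rng_seed: int = 0
) -> float:
    """Largest eigenvalue of A^T A by power iteration.

    Deterministic given the seed; iterates until the Rayleigh quotient
    changes by less than ``tol`` relatively.
    """
    A = sparse.csr_matrix(A) if sparse.issparse(A) else np.asarray(A, dtype=float)
    n = A.shape[1]
    rng = np.random.default_rng(rng_seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = A.T @ (A @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        lam_new = float(v @ w)
        v = w / nw
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            lam = lam_new
            break
        lam = lam_new
    return float(lam)
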