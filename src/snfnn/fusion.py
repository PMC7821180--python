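"""Similarity network fusion (SNF) by KNN-sparsified cross-diffusion.

SNF merges several similarity matrices over the same entities into one
comprehensive matrix.  Each view is turned into a row-stochastic "status"
matrix P (full kernel, carrying the global structure) and a sparse "local"
matrix L that keeps only each entity's K nearest neighbours (carrying the
reliable local structure).  The views then exchange information iteratively:

    P_v  <-  L_v @ mean_{w != v}(P_w) @ L_v.T

so each view diffuses the other views' status through its own most trusted
edges.  After T iterations the fused network is the average of the status
matrices.  Every iterate is re-symmetrized and row-renormalized (diagonal
pinned at 1/2, off-diagonal mass at 1/2) so the output invariants —
symmetry, non-negativity, unit row sums — hold regardless of floating-point
drift.  Inputs are already similarities in [0, 1], so no scaled-exponential
affinity transform is applied beforehand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import SimilarityMatrix

__all__ = ["FusionConfig", "FusedNetwork", "full_kernel", "knn_kernel", "snf_fuse"]


@dataclass
class FusionConfig:
    """K: neighbourhood size (clipped to p-1); T: number of diffusion steps."""

    K: int = 20
    T: int = 20

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class FusedNetwork:
    """Fused similarity matrix with provenance of the views that built it."""

    entity_ids: list[str]
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)
    config: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = len(self.entity_ids)
        if v.shape != (p, p):
            raise ValueError(f"fused matrix shape {v.shape} does not match {p} ids")
        if not np.isfinite(v).all():
            raise ValueError("fused matrix has non-finite entries")
        if v.min() < 0:
            raise ValueError("fused matrix has negative entries")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValueError("fused matrix is asymmetric")
        self.values = v

    def to_similarity(self, rescale: bool = False) -> SimilarityMatrix:
        """View as a SimilarityMatrix; min-max rescaled into [0,1] on request."""
        v = self.values.copy()
        if rescale:
            off = ~np.eye(len(self.entity_ids), dtype=bool)
            lo, hi = v[off].min(), v[off].max()
            if hi > lo:
                v[off] = (v[off] - lo) / (hi - lo)
        np.fill_diagonal(v, 1.0)
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        return SimilarityMatrix(self.entity_ids, v, view_name="fused")

    def write(self, path: str | Path) -> None:
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)
        frame.to_csv(path, sep="\t", float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"views": self.provenance, "K": self.config.K, "T": self.config.T})
        )


def full_kernel(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic status matrix: P(i,i) = 1/2, off-diagonal mass = 1/2.

    ``P(i, j) = S(i, j) / (2 * sum_{t != i} S(i, t))`` for ``j != i``.  A row
    with zero off-diagonal mass gets a uniform off-diagonal distribution.
    """
    s = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    p = s.shape[0]
    off = s.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    degenerate = row_sums <= 0
    if degenerate.any():
        off[degenerate] = 1.0
        np.fill_diagonal(off, 0.0)
        row_sums = off.sum(axis=1)
    kernel = off / (2.0 * row_sums[:, None])
    np.fill_diagonal(kernel, 0.5)
    return kernel


def knn_kernel(sim: SimilarityMatrix | np.ndarray, K: int) -> np.ndarray:
    """Sparse local matrix: each row keeps its K strongest neighbours.

    Neighbour ties are broken by lower column index.  Rows are normalized to
    sum 1 over the neighbourhood; an all-zero neighbourhood becomes uniform.
    """
    s = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    p = s.shape[0]
    if not 1 <= K <= p - 1:
        raise ValueError(f"K must be in [1, {p - 1}], got {K}")
    local = np.zeros_like(s)
    for i in range(p):
        row = s[i].copy()
        row[i] = -np.inf
        # stable argsort on -row: descending value, ties -> lower column index
        neighbours = np.argsort(-row, kind="stable")[:K]
        mass = s[i, neighbours].sum()
        if mass > 0:
            local[i, neighbours] = s[i, neighbours] / mass
        else:
            local[i, neighbours] = 1.0 / K
    return local


def _renormalize(p_mat: np.ndarray) -> np.ndarray:
    """Symmetrize, pin diagonal at 1/2 and rescale off-diagonal mass to 1/2."""
    p_mat = (p_mat + p_mat.T) / 2.0
    n = p_mat.shape[0]
    off = np.clip(p_mat, 0.0, None)
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    degenerate = row_sums <= 0
    if degenerate.any():
        off[degenerate] = 1.0
        np.fill_diagonal(off, 0.0)
        row_sums = off.sum(axis=1)
    out = off / (2.0 * row_sums[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def _symmetric_stochastic(p_mat: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Project to (near-)symmetric row-stochastic form by Sinkhorn-style alternation."""
    for _ in range(max_iter):
        p_mat = _renormalize(p_mat)
        p_mat = (p_mat + p_mat.T) / 2.0
        if np.abs(p_mat.sum(axis=1) - 1.0).max() < tol:
            break
    return p_mat


def snf_fuse(
    views: list[SimilarityMatrix], config: FusionConfig | None = None
) -> FusedNetwork:
    """Fuse one or more similarity views into a single network.

    A single view short-circuits to its (symmetrized) full kernel.  With
    several views the KNN-sparsified cross-diffusion above runs for
    ``config.T`` iterations before averaging.

    Views whose matrices are exactly equal are collapsed to one copy first:
    a duplicate view adds no information, and the cross-diffusion iteration
    would otherwise double-count it, so fusion is defined to depend only on
    the distinct input matrices (fusing ``{A, A}`` equals fusing ``{A}``).
    """
    if not views:
        raise ValueError("snf_fuse needs at least one view")
    config = config or FusionConfig()
    axis = views[0].entity_ids
    for v in views:
        if v.entity_ids != axis:
            raise ValueError(f"view {v.view_name!r} is on a different entity axis")
    p = len(axis)
    provenance = [v.view_name for v in views]

    distinct: list[SimilarityMatrix] = []
    for v in views:
        if not any(np.array_equal(v.values, d.values) for d in distinct):
            distinct.append(v)
    views = distinct

    if len(views) == 1:
        fused = full_kernel(views[0])
        fused = (fused + fused.T) / 2.0
        return FusedNetwork(list(axis), fused, provenance, config)

    K = min(config.K, p - 1)
    status = [_renormalize(full_kernel(v)) for v in views]
    local = [knn_kernel(v, K) for v in views]
    n_views = len(views)
    for _ in range(config.T):
        total = np.sum(status, axis=0)
        updated = []
        for v in range(n_views):
            others = (total - status[v]) / (n_views - 1)
            updated.append(_renormalize(local[v] @ others @ local[v].T))
        status = updated
    fused = np.mean(status, axis=0)
    fused = _symmetric_stochastic(fused)
    return FusedNetwork(list(axis), fused, provenance, config)
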