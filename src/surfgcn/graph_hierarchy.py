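"""Graph Laplacians and the multi-level coarsening hierarchy behind pooling.

The network halves the number of graph nodes after every residual block, so a
hierarchy of coarsened graphs is computed once per template and shared by all
subjects.  Coarsening is greedy heavy-edge matching (Graclus-style): matched
vertex pairs become one supernode, unmatched vertices are paired with inserted
*fake* nodes so every level halves exactly, and nodes are reordered so that the
two children of supernode ``p`` sit at positions ``2p`` and ``2p+1``.  Max
pooling is then a plain stride-2 reduction, and fake nodes (which carry no
edges) are excluded via a neutral element so they can never win a max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_io import TemplateGraph

__all__ = [
    "Laplacian",
    "GraphHierarchy",
    "build_laplacian",
    "coarsen",
    "pool_features",
    "upsample_map",
]


@dataclass
class Laplacian:
    """A (combinatorial or symmetric-normalized) graph Laplacian."""

    matrix: sp.csr_matrix
    kind: str  # {combinatorial, normalized}
    degree: np.ndarray
    lambda_max: float


@dataclass
class _Level:
    adjacency: sp.csr_matrix  # padded + reordered
    laplacian: Laplacian
    n_padded: int
    n_real: int
    fake_mask: np.ndarray  # bool, True where the node is padding


@dataclass
class GraphHierarchy:
    """Coarsened graph levels plus the bookkeeping for pooling and upsampling.

    ``perm0`` maps original template vertex ``i`` to its padded level-0
    position; ``interp_weights`` is a row-stochastic sparse smoothing operator
    on the original template used as the final step of upsampling.
    """

    levels: list[_Level]
    perm0: np.ndarray  # (n_original,) original index -> padded level-0 position
    n_original: int
    interp_weights: sp.csr_matrix
    seed: int

    @property
    def num_levels(self) -> int:
        return len(self.levels) - 1

    def pad_features(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter (n_original, F) features into padded level-0 order."""
        values = np.asarray(values)
        out = np.full((self.levels[0].n_padded,) + values.shape[1:], fill,
                      dtype=values.dtype)
        out[self.perm0] = values
        return out

    def unpad_values(self, padded: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`pad_features` (level 0 only)."""
        return np.asarray(padded)[self.perm0]

    def parent_map(self, level: int) -> np.ndarray:
        """Child position at `level` -> parent position at `level + 1`."""
        n = self.levels[level].n_padded
        return np.arange(n) // 2


class LaplacianKindError(ValueError):
    pass


def _largest_eigenvalue(matrix: sp.spmatrix) -> float:
    """Largest eigenvalue of a symmetric PSD matrix.

    Dense eigensolve below a small size, Lanczos (ARPACK) above; both give the
    eigenvalue to near machine precision, so the scaled Laplacian's spectrum
    stays inside [-1, 1] rather than slightly overshooting it.
    """
    n = matrix.shape[0]
    if n == 0:
        return 0.0
    if n <= 64:
        return float(np.linalg.eigvalsh(matrix.toarray()).max())
    from scipy.sparse.linalg import eigsh

    val = eigsh(matrix.astype(np.float64), k=1, which="LA",
                return_eigenvectors=False, tol=1e-9)
    return float(val[0])


def build_laplacian(
    graph: TemplateGraph | sp.spmatrix,
    kind: str = "normalized",
    fixed_lambda_max: float | None = None,
) -> Laplacian:
    """Build L = D - A (combinatorial) or L = I - D^{-1/2} A D^{-1/2} (normalized).

    Zero-degree vertices get an all-zero row/column in the normalized form
    (their eigenvalue is 0).  ``lambda_max`` is computed to near machine
    precision (capped at 2 for the normalized kind, whose spectrum lies in
    [0, 2]); ``fixed_lambda_max`` skips the computation.
    """
    adjacency = graph.adjacency if isinstance(graph, TemplateGraph) else graph
    adjacency = sp.csr_matrix(adjacency)
    if (abs(adjacency - adjacency.T) > 1e-10).nnz:
        raise ValueError("adjacency must be symmetric")
    if adjacency.nnz and adjacency.data.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    n = adjacency.shape[0]
    if kind == "combinatorial":
        lap = sp.diags(deg) - adjacency
    elif kind == "normalized":
        with np.errstate(divide="ignore"):
            dinv = 1.0 / np.sqrt(deg)
        dinv[deg == 0] = 0.0
        dhalf = sp.diags(dinv)
        eye = sp.diags((deg > 0).astype(float))  # zero row for isolated vertices
        lap = eye - dhalf @ adjacency @ dhalf
    else:
        raise LaplacianKindError(f"unknown Laplacian kind {kind!r}")
    lap = sp.csr_matrix((lap + lap.T) * 0.5)  # enforce exact symmetry

    if fixed_lambda_max is not None:
        lmax = float(fixed_lambda_max)
    elif adjacency.nnz == 0:
        lmax = 2.0 if kind == "normalized" else 0.0
    else:
        lmax = _largest_eigenvalue(lap)
        if kind == "normalized":
            lmax = min(lmax, 2.0)
    return Laplacian(matrix=lap, kind=kind, degree=deg, lambda_max=lmax)


# ---------------------------------------------------------------------------
# Heavy-edge matching coarsening
# ---------------------------------------------------------------------------


def _heavy_edge_matching(
    adjacency: sp.csr_matrix, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Greedy matching maximizing the normalized-cut weight w_ij (1/d_i + 1/d_j).

    Returns clusters as 1- or 2-tuples of vertex ids covering every vertex.
    """
    n = adjacency.shape[0]
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    matched = np.zeros(n, dtype=bool)
    clusters: list[tuple[int, ...]] = []
    order = rng.permutation(n)
    indptr, indices, data = adjacency.indptr, adjacency.indices, adjacency.data
    inv_deg = np.zeros(n)
    nz = deg > 0
    inv_deg[nz] = 1.0 / deg[nz]
    for v in order:
        if matched[v]:
            continue
        best, best_w = -1, -1.0
        for p in range(indptr[v], indptr[v + 1]):
            u = indices[p]
            if matched[u] or u == v:
                continue
            w = data[p] * (inv_deg[v] + inv_deg[u])
            if w > best_w:
                best_w, best = w, u
        matched[v] = True
        if best >= 0:
            matched[best] = True
            clusters.append((int(v), int(best)))
        else:
            clusters.append((int(v),))
    return clusters


def _coarse_adjacency(adjacency: sp.csr_matrix,
                      clusters: list[tuple[int, ...]]) -> sp.csr_matrix:
    n = adjacency.shape[0]
    m = len(clusters)
    assign = np.empty(n, dtype=np.int64)
    for c, members in enumerate(clusters):
        for v in members:
            assign[v] = c
    rows = np.arange(n)
    p = sp.coo_matrix((np.ones(n), (assign[rows], rows)), shape=(m, n)).tocsr()
    coarse = p @ adjacency @ p.T
    coarse = sp.csr_matrix(coarse)
    coarse.setdiag(0.0)
    coarse.eliminate_zeros()
    return coarse


def _build_interp_weights(graph: TemplateGraph) -> sp.csr_matrix:
    """Row-stochastic one-ring smoothing operator on the original template.

    Each vertex keeps half of its own value and distributes the other half
    over its triangulation neighbors with inverse-distance weights — a convex
    combination, so upsampled maps stay within the coarse map's value range.
    """
    a = graph.adjacency.tocoo()
    if a.nnz == 0:
        return sp.identity(graph.n, format="csr")
    d = np.linalg.norm(graph.coordinates[a.row] - graph.coordinates[a.col], axis=1)
    w = 1.0 / np.maximum(d, 1e-9)
    neigh = sp.coo_matrix((w, (a.row, a.col)), shape=a.shape).tocsr()
    row_sum = np.asarray(neigh.sum(axis=1)).ravel()
    scale = np.zeros_like(row_sum)
    nz = row_sum > 0
    scale[nz] = 0.5 / row_sum[nz]
    smooth = sp.diags(scale) @ neigh
    self_w = np.where(nz, 0.5, 1.0)  # isolated vertices keep their value
    return sp.csr_matrix(sp.diags(self_w) + smooth)


def coarsen(graph: TemplateGraph, num_levels: int, seed: int = 0) -> GraphHierarchy:
    """Coarsen ``num_levels`` times; every level halves the padded node count.

    Deterministic for a fixed seed.  The hierarchy is computed once per
    template and reused for every subject.
    """
    if num_levels < 0:
        raise ValueError("num_levels must be >= 0")
    rng = np.random.default_rng(seed)

    adjacencies = [sp.csr_matrix(graph.adjacency)]
    cluster_lists: list[list[tuple[int, ...]]] = []
    for _ in range(num_levels):
        clusters = _heavy_edge_matching(adjacencies[-1], rng)
        cluster_lists.append(clusters)
        adjacencies.append(_coarse_adjacency(adjacencies[-1], clusters))

    # Sibling-contiguous ordering with fake-node padding, coarsest level first.
    n_coarsest = adjacencies[-1].shape[0]
    order = list(range(n_coarsest))  # padded positions -> real ids (or >= n_real)
    orders = [order]
    for lvl in range(num_levels - 1, -1, -1):
        clusters = cluster_lists[lvl]
        n_real = adjacencies[lvl].shape[0]
        fake_counter = n_real
        child_order: list[int] = []
        for parent in orders[0]:
            if parent < len(clusters):
                members = clusters[parent]
                if len(members) == 2:
                    child_order.extend(members)
                else:
                    child_order.append(members[0])
                    child_order.append(fake_counter)
                    fake_counter += 1
            else:  # fake parent -> two fake children
                child_order.append(fake_counter)
                child_order.append(fake_counter + 1)
                fake_counter += 2
        orders.insert(0, child_order)

    levels: list[_Level] = []
    for lvl in range(num_levels + 1):
        ids = np.asarray(orders[lvl], dtype=np.int64)
        n_real = adjacencies[lvl].shape[0]
        n_padded = ids.shape[0]
        fake = ids >= n_real
        # Reindex: padded adjacency with fake nodes isolated.
        pos_of = np.full(n_real, -1, dtype=np.int64)
        pos_of[ids[~fake]] = np.nonzero(~fake)[0]
        a = adjacencies[lvl].tocoo()
        padded = sp.coo_matrix(
            (a.data, (pos_of[a.row], pos_of[a.col])), shape=(n_padded, n_padded)
        ).tocsr()
        lap = build_laplacian(padded, kind="normalized")
        levels.append(
            _Level(adjacency=padded, laplacian=lap, n_padded=n_padded,
                   n_real=n_real, fake_mask=fake)
        )

    perm0 = np.empty(graph.n, dtype=np.int64)
    ids0 = np.asarray(orders[0], dtype=np.int64)
    real0 = ids0 < graph.n
    perm0[ids0[real0]] = np.nonzero(real0)[0]

    return GraphHierarchy(
        levels=levels,
        perm0=perm0,
        n_original=graph.n,
        interp_weights=_build_interp_weights(graph),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pooling and upsampling
# ---------------------------------------------------------------------------


def pool_features(
    values: np.ndarray, hierarchy: GraphHierarchy, level: int
) -> np.ndarray:
    """Stride-2 max pooling from ``level`` to ``level + 1``.

    ``values`` has the padded vertex count of ``level`` along its second-to-last
    axis (leading batch axes allowed).  Fake children take the neutral element
    -inf so a real sibling always wins; pairs of two fakes yield 0.
    """
    if level < 0 or level >= hierarchy.num_levels:
        raise ValueError(f"level {level} out of range")
    lv = hierarchy.levels[level]
    values = np.asarray(values)
    axis = values.ndim - 2 if values.ndim >= 2 else 0
    if values.shape[axis] != lv.n_padded:
        raise ValueError(
            f"expected {lv.n_padded} rows at level {level}, got {values.shape[axis]}"
        )
    work = np.moveaxis(values, axis, 0).astype(float, copy=True)
    work[lv.fake_mask] = -np.inf
    paired = work.reshape(work.shape[0] // 2, 2, *work.shape[1:])
    pooled = paired.max(axis=1)
    pooled[~np.isfinite(pooled)] = 0.0  # both children fake
    return np.moveaxis(pooled, 0, axis)


def upsample_map(
    coarse_values: np.ndarray, hierarchy: GraphHierarchy, level: int | None = None
) -> np.ndarray:
    """Interpolate a coarse per-node map back to the full template resolution.

    Accepts either the padded or the real vertex count of the source level.
    Each child first inherits its parent's value down to level 0, then one
    smoothing pass over the template's one-ring (inverse-distance weighted,
    row-stochastic) approximates spherical linear interpolation on the
    structure surfaces.  Output length is the original template vertex count.
    """
    if level is None:
        level = hierarchy.num_levels
    if level < 0 or level > hierarchy.num_levels:
        raise ValueError(f"level {level} out of range")
    lv = hierarchy.levels[level]
    coarse_values = np.asarray(coarse_values, dtype=float).ravel()
    if coarse_values.shape[0] == lv.n_padded:
        padded = coarse_values.copy()
    elif coarse_values.shape[0] == lv.n_real:
        # scatter real values into padded positions
        padded = np.zeros(lv.n_padded)
        padded[~lv.fake_mask] = coarse_values
    else:
        raise ValueError(
            f"coarse map length {coarse_values.shape[0]} matches neither the "
            f"padded ({lv.n_padded}) nor real ({lv.n_real}) count of level {level}"
        )
    for _ in range(level):
        padded = np.repeat(padded, 2)
    full = padded[hierarchy.perm0]
    return hierarchy.interp_weights @ full
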