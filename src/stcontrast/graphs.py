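"""Spatial and expression-similarity graphs.

Three constructions feed the model:

* the spatial k-NN graph ``G`` over pixel coordinates, used by the gene
  encoder's neighborhood sampler and by the adjacency-reconstruction loss;
* the similarity adjacency ``A``: among each spot's k nearest spatial
  neighbors, the single one with the most similar expression profile, used to
  smooth positive views;
* for multiple slices, the global similarity matrix ``A*`` adding, per spot,
  symmetric links to its k most expression-similar spots in every other
  slice — the alignment-free device that lets contrastive positives span
  slices and corrects batch effects.

Similarity defaults to cosine on the preprocessed expression; Pearson and
(negative) Euclidean are available since the choice is a convention, not part
of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp

from .st_io import SpotDataset

DEFAULT_K = 6


# ---------------------------------------------------------------------------
# similarity kernels
# ---------------------------------------------------------------------------


def _similarity_matrix(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise similarity (higher = more similar), rows of X vs rows of Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if metric == "cosine":
        xn = np.linalg.norm(X, axis=1, keepdims=True)
        yn = np.linalg.norm(Y, axis=1, keepdims=True)
        xn[xn == 0] = 1.0
        yn[yn == 0] = 1.0
        return (X / xn) @ (Y / yn).T
    if metric == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        return _similarity_matrix(Xc, Yc, "cosine")
    if metric == "euclidean":
        d2 = (
            (X**2).sum(axis=1, keepdims=True)
            - 2 * X @ Y.T
            + (Y**2).sum(axis=1, keepdims=True).T
        )
        return -np.sqrt(np.maximum(d2, 0.0))
    raise ValueError(f"unknown similarity metric {metric!r}")


# ---------------------------------------------------------------------------
# spatial k-NN graph G
# ---------------------------------------------------------------------------


@dataclass
class SpatialGraph:
    """Undirected spatial k-NN graph (edges symmetrized by union)."""

    n_spots: int
    k: int
    edges: np.ndarray  # (n_edges, 2) with i < j
    distances: np.ndarray  # per-edge Euclidean pixel distance
    neighbors: List[np.ndarray] = field(default_factory=list)  # adjacency lists

    def adjacency(self, fmt: str = "csr"):
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        A = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_spots, self.n_spots),
        )
        return A.asformat(fmt)

    def to_edge_list(self, spot_ids=None):
        ids = spot_ids if spot_ids is not None else list(range(self.n_spots))
        return [
            (ids[int(a)], ids[int(b)], float(d))
            for (a, b), d in zip(self.edges, self.distances)
        ]


def spatial_knn(coords: np.ndarray, k: int = DEFAULT_K) -> SpatialGraph:
    """Connect each spot to its k nearest spots (Euclidean, self excluded).

    Distance ties break toward the lower spot index, making the edge set
    deterministic for duplicated coordinates.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} spots, got {n}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")

    d2 = (
        (coords**2).sum(axis=1, keepdims=True)
        - 2 * coords @ coords.T
        + (coords**2).sum(axis=1)
    )
    np.fill_diagonal(d2, np.inf)
    # lexsort: secondary key = index (ascending) resolves ties deterministically
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), d2), axis=1)
    knn = order[:, :k]

    pairs = set()
    for i in range(n):
        for j in knn[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=np.intp).reshape(-1, 2)
    dist = np.sqrt(np.maximum(d2[edges[:, 0], edges[:, 1]], 0.0))

    nbrs = [[] for _ in range(n)]
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    neighbors = [np.array(sorted(x), dtype=np.intp) for x in nbrs]
    return SpatialGraph(n_spots=n, k=k, edges=edges, distances=dist, neighbors=neighbors)


def spatial_distance(a, b) -> float:
    """Euclidean pixel distance between two spot coordinates."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# similarity adjacency A
# ---------------------------------------------------------------------------


@dataclass
class SimilarityGraph:
    A: sp.csr_matrix  # N x N binary symmetric, zero diagonal
    k_spatial: int

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]


def similarity_adjacency(
    coords: np.ndarray,
    X: np.ndarray,
    k_spatial: int = DEFAULT_K,
    metric: str = "cosine",
) -> SimilarityGraph:
    """For each spot, link it to the most expression-similar of its
    ``k_spatial`` nearest spatial neighbors (symmetric, ties to lower index)."""
    coords = np.asarray(coords, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != coords.shape[0]:
        raise ValueError("X rows must match coords rows")
    g = spatial_knn(coords, k=k_spatial)
    n = coords.shape[0]

    d2 = (
        (coords**2).sum(axis=1, keepdims=True)
        - 2 * coords @ coords.T
        + (coords**2).sum(axis=1)
    )
    np.fill_diagonal(d2, np.inf)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), d2), axis=1)
    cand = order[:, :k_spatial]

    S = _similarity_matrix(X, X, metric)
    rows, cols = [], []
    for i in range(n):
        sims = S[i, cand[i]]
        tied = cand[i][sims >= sims.max() - 1e-12]
        best = int(tied.min())  # similarity ties break to the lower spot index
        rows.extend([i, best])
        cols.extend([best, i])
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0
    A.setdiag(0)
    A.eliminate_zeros()
    return SimilarityGraph(A=A, k_spatial=k_spatial)


# ---------------------------------------------------------------------------
# multi-slice layout and cross-slice similarity A*
# ---------------------------------------------------------------------------


@dataclass
class MultiSliceLayout:
    """Slices placed side by side in a common pixel frame.

    ``merged`` concatenates expression (intersected gene set) and translated
    coordinates; ``slice_index`` maps each merged spot to its slice of
    origin; ``A_star`` (filled by :func:`cross_slice_similarity`) is the
    global T × T similarity matrix.
    """

    slices: List[SpotDataset]
    x_offsets: List[float]
    merged: SpotDataset
    slice_index: np.ndarray
    A_star: Optional[sp.csr_matrix] = None

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def translate_and_concat(slices: List[SpotDataset], gap_px: int = 50) -> MultiSliceLayout:
    """Place slices left-to-right with a ``gap_px`` horizontal separation.

    Images are horizontally concatenated (zero-padded to the max height),
    coordinates translated by the cumulative offsets, and expression matrices
    row-concatenated on the intersection of gene sets (order taken from the
    first slice). Raises on an empty gene intersection.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices")
    common = set(slices[0].gene_ids)
    for s in slices[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValueError("slices share no genes")
    genes = [g for g in slices[0].gene_ids if g in common]

    has_image = all(s.image is not None for s in slices)
    widths = []
    for s in slices:
        if s.image is not None:
            widths.append(s.image.shape[1])
        else:
            widths.append(float(np.ceil(s.coords[:, 0].max())) + 1)

    x_offsets, off = [], 0.0
    for w in widths:
        x_offsets.append(off)
        off += w + gap_px

    expr_blocks, coord_blocks, ids, labels, slice_index = [], [], [], [], []
    any_labels = any(s.labels is not None for s in slices)
    for si, s in enumerate(slices):
        gidx = [s.gene_ids.index(g) for g in genes]
        expr_blocks.append(s.expression[:, gidx])
        c = s.coords.copy()
        c[:, 0] += x_offsets[si]
        coord_blocks.append(c)
        ids.extend(f"{s.slice_id}:{sid}" for sid in s.spot_ids)
        slice_index.extend([si] * s.n_spots)
        if any_labels:
            labels.extend(
                s.labels if s.labels is not None else [None] * s.n_spots
            )

    image = None
    if has_image:
        Hmax = max(s.image.shape[0] for s in slices)
        total_w = int(sum(widths) + gap_px * (len(slices) - 1))
        image = np.zeros((Hmax, total_w, 3), dtype=np.uint8)
        for s, off_x in zip(slices, x_offsets):
            h, w = s.image.shape[:2]
            image[:h, int(off_x) : int(off_x) + w] = s.image

    merged = SpotDataset(
        expression=np.vstack(expr_blocks),
        coords=np.vstack(coord_blocks),
        spot_ids=ids,
        gene_ids=genes,
        image=image,
        labels=np.asarray(labels) if any_labels else None,
        slice_id="+".join(s.slice_id for s in slices),
        platform=slices[0].platform,
        is_preprocessed=all(s.is_preprocessed for s in slices),
    )
    return MultiSliceLayout(
        slices=slices,
        x_offsets=[float(x) for x in x_offsets],
        merged=merged,
        slice_index=np.asarray(slice_index, dtype=np.intp),
    )


def _matching_features(
    X: np.ndarray, coords: np.ndarray, slice_index: np.ndarray,
    smoothing_rounds: int, standardize: bool, k_spatial: int,
) -> np.ndarray:
    """Noise-robust profiles for cross-slice matching.

    Individual spot profiles are noisy (counting noise, dropout), so each
    slice's expression is averaged over its spatial k-NN neighborhood
    ``smoothing_rounds`` times and then per-gene standardized within the
    slice, which also cancels additive per-gene batch offsets before
    similarities are compared across slices.
    """
    Z = np.asarray(X, dtype=np.float64).copy()
    for s in np.unique(slice_index):
        rows = np.where(slice_index == s)[0]
        Xs = Z[rows]
        if smoothing_rounds > 0 and len(rows) > k_spatial:
            g = spatial_knn(coords[rows], k=k_spatial)
            M = np.zeros((len(rows), len(rows)))
            for i in range(len(rows)):
                mem = np.concatenate([[i], g.neighbors[i]])
                M[i, mem] = 1.0 / len(mem)
            for _ in range(smoothing_rounds):
                Xs = M @ Xs
        if standardize:
            sd = Xs.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (Xs - Xs.mean(axis=0)) / sd
        Z[rows] = Xs
    return Z


def cross_slice_similarity(
    layout: MultiSliceLayout,
    k: int = DEFAULT_K,
    k_spatial: int = DEFAULT_K,
    metric: str = "cosine",
    match_smoothing: int = 2,
    match_standardize: bool = True,
) -> MultiSliceLayout:
    """Fill ``layout.A_star``: within-slice blocks reuse each slice's own
    similarity adjacency; across slices, every spot links symmetrically to
    its ``k`` most expression-similar spots in each other slice (all spots if
    a slice has fewer than ``k``). Cross-slice similarities are computed on
    spatially smoothed, per-slice standardized profiles (see
    :func:`_matching_features`)."""
    X = layout.merged.expression
    coords = layout.merged.coords
    idx = layout.slice_index
    T = X.shape[0]
    A = sp.lil_matrix((T, T))
    Xm = _matching_features(
        X, coords, idx, smoothing_rounds=match_smoothing,
        standardize=match_standardize, k_spatial=k_spatial,
    )

    for si in range(layout.n_slices):
        sel = np.where(idx == si)[0]
        Asl = similarity_adjacency(coords[sel], X[sel], k_spatial=k_spatial, metric=metric).A
        coo = Asl.tocoo()
        A[sel[coo.row], sel[coo.col]] = 1.0

    for si in range(layout.n_slices):
        rows = np.where(idx == si)[0]
        for sj in range(layout.n_slices):
            if sj == si:
                continue
            cols = np.where(idx == sj)[0]
            kk = min(k, len(cols))
            S = _similarity_matrix(Xm[rows], Xm[cols], metric)
            # top-k per row; argsort on (-sim, index) for deterministic ties
            order = np.lexsort(
                (np.tile(np.arange(len(cols)), (len(rows), 1)), -S), axis=1
            )[:, :kk]
            for r, top in zip(rows, order):
                cc = cols[top]
                A[r, cc] = 1.0
                A[cc, r] = 1.0

    A = A.tocsr()
    A.setdiag(0)
    A.eliminate_zeros()
    layout.A_star = A
    return layout


def graph_from_adjacency(A: sp.spmatrix, coords: np.ndarray, k: int) -> SpatialGraph:
    """Wrap an arbitrary symmetric adjacency as a SpatialGraph (edge
    distances from coords); used to hand the encoder a combined graph."""
    A = sp.csr_matrix(A)
    coo = sp.triu(A, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col]).astype(np.intp)
    dist = np.sqrt(((coords[edges[:, 0]] - coords[edges[:, 1]]) ** 2).sum(axis=1))
    n = A.shape[0]
    nbrs = [[] for _ in range(n)]
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    neighbors = [np.array(sorted(x), dtype=np.intp) for x in nbrs]
    return SpatialGraph(n_spots=n, k=k, edges=edges, distances=dist, neighbors=neighbors)


def integration_graph(layout: MultiSliceLayout, k: int = DEFAULT_K) -> SpatialGraph:
    """Encoder graph for alignment-free integration: the union of the
    within-slice spatial k-NN edges and the cross-slice similarity edges of
    ``A_star``, so feature extraction itself mixes matched spots across
    slices (this is what corrects batch effects during training)."""
    if layout.A_star is None:
        raise ValueError("run cross_slice_similarity first")
    merged = layout.merged
    G = spatial_knn(merged.coords, k=k)
    A = ((G.adjacency("csr") + layout.A_star) > 0).astype(np.float64)
    return graph_from_adjacency(A, merged.coords, k)


def export_edge_list(A: sp.spmatrix, spot_ids, path) -> None:
    """Write a symmetric adjacency as a TSV edge list (i < j once)."""
    coo = sp.triu(A, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("spot_id_a\tspot_id_b\tweight\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{spot_ids[i]}\t{spot_ids[j]}\t{v:g}\n")
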