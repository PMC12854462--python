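"""Graph constructions vs exhaustive brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from stcontrast.graphs import (
    cross_slice_similarity,
    graph_from_adjacency,
    integration_graph,
    similarity_adjacency,
    spatial_distance,
    spatial_knn,
    translate_and_concat,
)
from stcontrast.st_io import SpotDataset


def knn_edges_oracle(coords, k):
    """Exhaustive O(n^2) k-NN with lower-index tie-breaks, symmetrized."""
    n = len(coords)
    edges = set()
    for i in range(n):
        d = [(np.hypot(*(coords[i] - coords[j])), j) for j in range(n) if j != i]
        d.sort()
        for _, j in d[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


def _ds(coords, X, slice_id="s", image=None):
    n, g = X.shape
    return SpotDataset(
        X, coords, [f"{slice_id}{i}" for i in range(n)], [f"g{j}" for j in range(g)],
        image=image, slice_id=slice_id,
    )


class TestSpatialKnn:
    def test_three_four_five_distance(self):
        assert spatial_distance((0, 0), (3, 4)) == 5.0

    def test_default_k_is_six(self):
        import inspect

        assert inspect.signature(spatial_knn).parameters["k"].default == 6

    @pytest.mark.parametrize("n,k,seed", [(8, 2, 0), (50, 6, 1), (200, 6, 2)])
    def test_matches_exhaustive_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 100, size=(n, 2))
        g = spatial_knn(coords, k=k)
        assert {tuple(e) for e in g.edges} == knn_edges_oracle(coords, k)

    def test_collinear_spots_small_k(self):
        coords = np.column_stack([np.arange(8.0), np.zeros(8)])
        g = spatial_knn(coords, k=2)
        assert {tuple(e) for e in g.edges} == knn_edges_oracle(coords, 2)

    def test_adjacency_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        g = spatial_knn(rng.uniform(0, 10, (30, 2)), k=4)
        A = g.adjacency("csr")
        assert (A != A.T).nnz == 0
        assert A.diagonal().sum() == 0


def similarity_oracle(coords, X, k_spatial):
    """Literal double loop: cosine-best among k spatial neighbors."""
    n = len(coords)
    A = np.zeros((n, n))
    norm = np.linalg.norm(X, axis=1)
    for i in range(n):
        d = [(np.hypot(*(coords[i] - coords[j])), j) for j in range(n) if j != i]
        d.sort()
        cand = [j for _, j in d[:k_spatial]]
        sims = [X[i] @ X[j] / (norm[i] * norm[j]) for j in cand]
        best = cand[int(np.argmax(sims))]
        A[i, best] = A[best, i] = 1
    return A


class TestSimilarityAdjacency:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, size=(20, 2))
        X = rng.uniform(0.1, 5, size=(20, 8))
        g = similarity_adjacency(coords, X, k_spatial=6)
        assert np.array_equal(np.asarray(g.A.todense()), similarity_oracle(coords, X, 6))

    def test_forced_neighbor_choice(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        X = np.array([[1.0, 0], [1, 0.01], [0, 1]])
        g = similarity_adjacency(coords, X, k_spatial=2)
        A = np.asarray(g.A.todense())
        assert A[0, 1] == 1 and A[1, 0] == 1

    def test_identical_expression_ties_to_lower_index(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        X = np.ones((4, 3))
        g = similarity_adjacency(coords, X, k_spatial=3)
        A = np.asarray(g.A.todense())
        assert A[3, 0] == 1  # spot 3's candidates all tie -> lowest index 0

    def test_symmetric_zero_diag(self):
        rng = np.random.default_rng(8)
        g = similarity_adjacency(rng.uniform(0, 9, (15, 2)), rng.uniform(0, 1, (15, 5)))
        assert (g.A != g.A.T).nnz == 0
        assert g.A.diagonal().sum() == 0


class TestMultiSlice:
    def _slices(self, widths=(100, 100), n=12, g=6, seed=0, image=True):
        rng = np.random.default_rng(seed)
        out = []
        for si, w in enumerate(widths):
            img = rng.integers(0, 255, size=(60, w, 3)).astype(np.uint8) if image else None
            out.append(
                _ds(
                    rng.uniform(5, min(w, 55), size=(n, 2)),
                    rng.uniform(0, 4, size=(n, g)),
                    slice_id=f"sl{si}",
                    image=img,
                )
            )
        return out

    def test_offsets_are_cumulative_widths_plus_gap(self):
        layout = translate_and_concat(self._slices((100, 100)), gap_px=10)
        assert layout.x_offsets == [0.0, 110.0]

    def test_total_spot_count(self):
        layout = translate_and_concat(self._slices((80, 90, 100)), gap_px=5)
        assert layout.merged.n_spots == 3 * 12

    def test_translation_preserves_within_slice_distances(self):
        slices = self._slices()
        layout = translate_and_concat(slices, gap_px=50)
        c = layout.merged.coords[:12]
        orig = slices[0].coords
        d_new = np.linalg.norm(c[:, None] - c[None], axis=2)
        d_old = np.linalg.norm(orig[:, None] - orig[None], axis=2)
        assert np.allclose(d_new, d_old)

    def test_duplicated_slice_coordinates_disjoint(self):
        s = self._slices((100,))[0]
        import copy

        layout = translate_and_concat([s, copy.deepcopy(s)], gap_px=50)
        x1 = layout.merged.coords[:12, 0]
        x2 = layout.merged.coords[12:, 0]
        assert x2.min() - x1.max() >= 50

    def test_empty_gene_intersection_raises(self):
        a, b = self._slices(image=False)
        b.gene_ids = [f"other{j}" for j in range(b.n_genes)]
        with pytest.raises(ValueError, match="share no genes"):
            translate_and_concat([a, b])

    def test_cross_slice_matches_bruteforce_topk(self):
        slices = self._slices(n=10)
        layout = translate_and_concat(slices, gap_px=20)
        # raw-cosine semantics for the oracle comparison
        layout = cross_slice_similarity(
            layout, k=3, k_spatial=3, match_smoothing=0, match_standardize=False
        )
        A = np.asarray(layout.A_star.todense())
        X = layout.merged.expression
        norm = np.linalg.norm(X, axis=1)
        expected = np.zeros_like(A)
        for i in range(10):
            sims = [(X[i] @ X[j] / (norm[i] * norm[j]), j) for j in range(10, 20)]
            sims.sort(key=lambda t: (-t[0], t[1]))
            for _, j in sims[:3]:
                expected[i, j] = expected[j, i] = 1
        for j in range(10, 20):
            sims = [(X[j] @ X[i] / (norm[j] * norm[i]), i) for i in range(10)]
            sims.sort(key=lambda t: (-t[0], t[1]))
            for _, i in sims[:3]:
                expected[j, i] = expected[i, j] = 1
        cross = A.copy()
        cross[:10, :10] = 0
        cross[10:, 10:] = 0
        assert np.array_equal(cross, expected)

    def test_cross_slice_out_degree_at_least_k(self):
        layout = translate_and_concat(self._slices(n=10), gap_px=20)
        layout = cross_slice_similarity(layout, k=3, k_spatial=3)
        A = layout.A_star
        cross = A[:10, 10:]
        assert np.all(np.asarray(cross.sum(axis=1)).ravel() >= 3)

    def test_a_star_symmetric_zero_diag(self):
        layout = translate_and_concat(self._slices(), gap_px=20)
        layout = cross_slice_similarity(layout, k=3, k_spatial=4)
        assert (layout.A_star != layout.A_star.T).nnz == 0
        assert layout.A_star.diagonal().sum() == 0

    def test_integration_graph_contains_both_edge_sets(self):
        layout = translate_and_concat(self._slices(), gap_px=20)
        layout = cross_slice_similarity(layout, k=3, k_spatial=4)
        G = integration_graph(layout, k=4)
        A = G.adjacency("csr")
        G_sp = spatial_knn(layout.merged.coords, k=4).adjacency("csr")
        assert ((A - G_sp) < 0).nnz == 0  # superset of spatial edges
        assert ((A - layout.A_star) < 0).nnz == 0  # superset of A*
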