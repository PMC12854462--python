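"""Encoder, fusion and decoder contracts against hand-unrolled oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from stcontrast.autodiff import Tensor
from stcontrast.backbone import FrozenConvBackbone
from stcontrast.graphs import spatial_knn
from stcontrast.model_core import (
    EncoderParams,
    ModelConfig,
    decode_expression,
    edge_probability,
    encode_genes,
    encode_genes_full,
    encode_images,
    fuse,
    normalized_adjacency,
    sample_batch_subgraph,
)


def elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _params(n_genes, d, backbone=None, seed=0):
    cfg = ModelConfig(d=d)
    return EncoderParams.create(
        n_genes, backbone or FrozenConvBackbone(), cfg, np.random.default_rng(seed)
    )


def _line_graph(n=8, k=2):
    coords = np.column_stack([np.arange(float(n)), np.zeros(n)])
    return spatial_knn(coords, k=k), coords


class TestSubgraphSampling:
    def test_large_fanout_takes_full_neighborhoods(self):
        G, _ = _line_graph()
        sg = sample_batch_subgraph(G, B=4, fanout=(10, 10), rng=np.random.default_rng(0))
        for s, f in zip(sg.seed_spots, sg.first_order):
            assert set(f) == set(G.neighbors[s])

    def test_all_spots_as_seeds(self):
        G, _ = _line_graph()
        sg = sample_batch_subgraph(G, B=8, fanout=(2, 2), rng=np.random.default_rng(0))
        assert np.array_equal(np.sort(sg.seed_spots), np.arange(8))

    def test_fixed_seed_reproducible(self):
        G, _ = _line_graph()
        a = sample_batch_subgraph(G, 4, (1, 1), np.random.default_rng(5))
        b = sample_batch_subgraph(G, 4, (1, 1), np.random.default_rng(5))
        assert np.array_equal(a.seed_spots, b.seed_spots)
        assert all(np.array_equal(x, y) for x, y in zip(a.first_order, b.first_order))
        assert np.array_equal(a.nodes, b.nodes)

    def test_sampled_neighbors_are_graph_neighbors(self):
        G, _ = _line_graph()
        sg = sample_batch_subgraph(G, 5, (2, 2), np.random.default_rng(1))
        for s, f in zip(sg.seed_spots, sg.first_order):
            assert set(f) <= set(G.neighbors[s])


class TestGeneEncoder:
    def test_constant_features_fixed_point(self):
        # identity weights, positive constant input: ELU acts as identity
        G, _ = _line_graph()
        d = 3
        p = _params(d, d)
        p.W0.data = np.eye(d)
        p.W1.data = np.eye(d)
        p.b0.data[:] = 0
        p.b1.data[:] = 0
        X = np.tile([1.0, 2.0, 0.5], (8, 1))
        sg = sample_batch_subgraph(G, 8, (10, 10), np.random.default_rng(0))
        out = encode_genes(X[sg.nodes], sg, p)
        assert np.allclose(out.data, X)

    def test_zero_input_zero_output(self):
        G, _ = _line_graph()
        p = _params(4, 2)
        p.b0.data[:] = 0
        p.b1.data[:] = 0
        sg = sample_batch_subgraph(G, 4, (2, 2), np.random.default_rng(0))
        out = encode_genes(np.zeros((len(sg.nodes), 4)), sg, p)
        assert np.allclose(out.data, 0.0)

    def test_star_graph_hand_unroll(self):
        # star: center 0 connected to 1..4
        coords = np.array([[0.0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        G = spatial_knn(coords, k=1)
        p = _params(2, 2)
        W0, b0 = p.W0.data, p.b0.data
        W1, b1 = p.W1.data, p.b1.data
        X = np.arange(10.0).reshape(5, 2)
        sg = sample_batch_subgraph(G, 5, (10, 10), np.random.default_rng(0))
        out = encode_genes(X[sg.nodes], sg, p)
        # oracle: literal per-node loop over the two stated layers
        h1 = {}
        for u in range(5):
            mem = [u] + sorted(sg.children.get(u, []))
            h1[u] = elu(X[mem].mean(axis=0) @ W0 + b0)
        expected = []
        for s, f in zip(sg.seed_spots, sg.first_order):
            stack = np.vstack([h1[int(s)]] + [h1[int(j)] for j in f])
            expected.append(elu(stack.mean(axis=0) @ W1 + b1))
        assert np.allclose(out.data, np.vstack(expected))

    def test_full_fanout_matches_full_graph_encoder(self):
        G, _ = _line_graph()
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 4))
        p = _params(4, 3)
        sg = sample_batch_subgraph(G, 8, (10, 10), rng)
        batched = encode_genes(X[sg.nodes], sg, p)
        full = encode_genes_full(X, G, p)
        assert np.allclose(batched.data, full.data[sg.seed_spots])

    def test_invariant_under_neighbor_order(self):
        # mean aggregation cannot depend on the order neighbors are listed
        G, _ = _line_graph()
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 4))
        p = _params(4, 3)
        sg = sample_batch_subgraph(G, 8, (10, 10), rng)
        out1 = encode_genes(X[sg.nodes], sg, p).data
        sg.first_order = [f[::-1].copy() for f in sg.first_order]
        out2 = encode_genes(X[sg.nodes], sg, p).data
        assert np.allclose(out1, out2)


class TestImageEncoder:
    def test_identical_patches_identical_rows(self):
        bb = FrozenConvBackbone()
        p = _params(4, 8, backbone=bb)
        patch = np.full((16, 16, 3), 120.0)
        feats = bb.encode(np.stack([patch, patch]))
        out = encode_images(feats, p)
        assert np.allclose(out.data[0], out.data[1])

    def test_two_calls_bit_identical(self):
        bb = FrozenConvBackbone()
        p = _params(4, 8, backbone=bb)
        patches = np.random.default_rng(0).uniform(0, 255, (3, 16, 16, 3))
        a = encode_images(bb.encode(patches), p).data
        b = encode_images(bb.encode(patches), p).data
        assert np.array_equal(a, b)

    def test_zero_patch_fixed_finite_vector(self):
        bb = FrozenConvBackbone()
        f1 = bb.encode(np.zeros((1, 112, 112, 3)))
        f2 = FrozenConvBackbone().encode(np.zeros((1, 112, 112, 3)))
        assert np.all(np.isfinite(f1))
        assert np.array_equal(f1, f2)

    def test_backbone_frozen_checksum_stable(self):
        bb = FrozenConvBackbone()
        before = bb.checksum()
        bb.encode(np.random.default_rng(1).uniform(0, 255, (4, 16, 16, 3)))
        assert bb.checksum() == before

    def test_feature_dim_mismatch_raises(self):
        p = _params(4, 8)
        with pytest.raises(ValueError, match="does not match"):
            encode_images(np.zeros((2, 5)), p)

    def test_tiny_patch_rejected(self):
        with pytest.raises(ValueError, match="side"):
            FrozenConvBackbone().encode(np.zeros((1, 3, 3, 3)))


class TestFusion:
    def test_symmetric_weights_identity(self):
        d = 3
        p = _params(4, d)
        p.Wf.data = np.vstack([np.eye(d), np.eye(d)])
        v = np.array([[1.0, 2.0, 3.0]])
        _, h_f = fuse(Tensor(v), Tensor(v), 0.5, p)
        assert np.allclose(h_f.data, v)

    def test_gene_dominance_limit(self):
        d = 2
        p = _params(4, d)
        p.Wf.data = np.vstack([np.eye(d), np.zeros((d, d))])
        hs = Tensor(np.array([[2.0, -1.0]]))
        hi = Tensor(np.array([[7.0, 7.0]]))
        _, h_f = fuse(hs, hi, 1 - 1e-9, p)
        assert np.allclose(h_f.data, hs.data, atol=1e-6)

    def test_matches_matrix_arithmetic(self, rng):
        d = 4
        p = _params(4, d)
        hs, hi = rng.standard_normal((3, d)), rng.standard_normal((3, d))
        k = 0.3
        h_c, h_f = fuse(Tensor(hs), Tensor(hi), k, p)
        expected_c = np.concatenate([k * hs, (1 - k) * hi], axis=1)
        assert np.allclose(h_c.data, expected_c)
        assert np.allclose(h_f.data, expected_c @ p.Wf.data)

    def test_block_homogeneity(self, rng):
        d = 3
        p = _params(4, d)
        hs, hi = rng.standard_normal((2, d)), rng.standard_normal((2, d))
        h_c, _ = fuse(Tensor(3.0 * hs), Tensor(hi), 0.4, p)
        base, _ = fuse(Tensor(hs), Tensor(hi), 0.4, p)
        assert np.allclose(h_c.data[:, :d], 3.0 * base.data[:, :d])
        assert np.allclose(h_c.data[:, d:], base.data[:, d:])

    def test_k_out_of_range_rejected(self):
        p = _params(4, 2)
        with pytest.raises(ValueError):
            fuse(Tensor(np.ones((1, 2))), Tensor(np.ones((1, 2))), 1.5, p)


class TestEdgeProbability:
    def test_orthogonal_is_half(self):
        assert edge_probability([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_norm_ln3_gives_three_quarters(self):
        v = np.sqrt(np.log(3.0) / 2.0) * np.ones(2)
        assert edge_probability(v, v) == pytest.approx(0.75)

    def test_random_pair_matches_scalar_oracle(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert edge_probability(a, b) == pytest.approx(1 / (1 + np.exp(-a @ b)))


class TestDecoder:
    def test_isolated_spot_dense_map(self, rng):
        p = _params(6, 4)
        h = rng.standard_normal((1, 4))
        A = sp.csr_matrix((1, 1))
        out = decode_expression(Tensor(h), A, p)
        expected = elu(h @ p.dec_W1.data + p.dec_b1.data) @ p.dec_W2.data + p.dec_b2.data
        assert np.allclose(out.data, expected)

    def test_identical_embeddings_symmetric_rows(self, rng):
        p = _params(5, 3)
        h = np.tile(rng.standard_normal(3), (2, 1))
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]]))
        out = decode_expression(Tensor(h), A, p).data
        assert np.allclose(out[0], out[1])

    def test_four_node_toy_matches_dense_oracle(self, rng):
        p = _params(6, 4)
        h = rng.standard_normal((4, 4))
        A_raw = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float
        )
        out = decode_expression(Tensor(h), sp.csr_matrix(A_raw), p).data
        Ah = A_raw + np.eye(4)
        dinv = 1 / np.sqrt(Ah.sum(axis=1))
        Ahat = Ah * dinv[:, None] * dinv[None, :]
        expected = (
            Ahat @ (elu(Ahat @ h @ p.dec_W1.data + p.dec_b1.data) @ p.dec_W2.data)
            + p.dec_b2.data
        )
        assert np.allclose(out, expected)

    def test_normalized_adjacency_rowsum_regular_graph(self):
        # on a k-regular graph with self-loops every row sums to 1
        A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        An = normalized_adjacency(sp.csr_matrix(A))
        assert np.allclose(An.sum(axis=1), 1.0)
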