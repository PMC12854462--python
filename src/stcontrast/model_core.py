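"""Multimodal encoder-decoder core.

Gene expression is encoded with a two-layer mean-aggregation graph encoder
(GraphSAGE-style) over the spatial k-NN graph, with hierarchical neighborhood
sampling per minibatch. Image patches pass through a frozen backbone and a
trainable MLP head. The two modality embeddings are fused by scalar-weighted
concatenation (weight ``k_emb`` on the gene block, ``1 - k_emb`` on the image
block) followed by a trainable linear projection. A sigmoid inner-product
head scores spot-pair connectivity, and a two-layer graph-convolution decoder
maps fused embeddings back to expression space.

All trainable pieces live on the in-package autodiff engine; aggregation
matrices are constants, so every forward pass is a short chain of dense
matmuls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor, concat
from .backbone import FrozenConvBackbone, ImageBackbone
from .graphs import SpatialGraph


@dataclass
class ModelConfig:
    """Architecture and optimization knobs.

    ``d`` is the shared embedding dimension of both modalities;
    ``fanout`` the (first-order, second-order) neighbor sample sizes —
    with the spatial graph built at k = 6 the default keeps full
    neighborhoods affordable.
    """

    d: int = 64
    decoder_hidden: int = 256
    fanout: Tuple[int, int] = (6, 6)
    batch_size: int = 256
    lr: float = 1e-3
    tau: float = 0.5
    n_neg: int = 16
    k_emb_init: float = 0.5


@dataclass
class BatchSubgraph:
    """Seeds plus sampled 1st/2nd-order neighborhoods and their adjacencies."""

    seed_spots: np.ndarray  # (B,) global indices
    first_order: List[np.ndarray]  # per-seed sampled neighbors (global)
    second_order: List[np.ndarray]  # per-seed union of 2nd-order samples
    children: Dict[int, np.ndarray]  # layer-0 aggregation children per node
    nodes: np.ndarray  # all subgraph nodes (global, sorted)
    A_S: sp.csr_matrix  # induced adjacency over `nodes`
    A_seed: sp.csr_matrix  # induced adjacency over the seeds only
    A_batch_sim: Optional[sp.csr_matrix] = None  # similarity A restricted to seeds

    @property
    def n_seeds(self) -> int:
        return len(self.seed_spots)


def sample_batch_subgraph(
    G: SpatialGraph,
    B: int,
    fanout: Tuple[int, int] = (6, 6),
    rng: Optional[np.random.Generator] = None,
    seeds: Optional[np.ndarray] = None,
    A_sim: Optional[sp.spmatrix] = None,
) -> BatchSubgraph:
    """Draw B seed spots and uniform without-replacement neighbor samples.

    ``seeds`` overrides the random seed draw (used at inference where every
    spot is a seed). When ``A_sim`` is given, its seed-restricted block is
    attached for positive-view smoothing.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = G.n_spots
    if seeds is None:
        if B > n:
            raise ValueError("batch size exceeds spot count")
        seeds = np.sort(rng.choice(n, size=B, replace=False))
    else:
        seeds = np.asarray(seeds, dtype=np.intp)

    def _sample(pool: np.ndarray, size: int) -> np.ndarray:
        if len(pool) <= size:
            return pool.copy()
        return rng.choice(pool, size=size, replace=False)

    children: Dict[int, np.ndarray] = {}
    first_order, second_order = [], []
    for s in seeds:
        f = _sample(G.neighbors[s], fanout[0])
        children[int(s)] = f
        first_order.append(f)
        sec = []
        for j in f:
            sj = _sample(G.neighbors[j], fanout[1])
            prev = children.get(int(j))
            children[int(j)] = (
                sj if prev is None else np.unique(np.concatenate([prev, sj]))
            )
            sec.append(sj)
        second_order.append(
            np.unique(np.concatenate(sec)) if sec else np.array([], dtype=np.intp)
        )

    nodes = np.unique(
        np.concatenate(
            [seeds]
            + first_order
            + second_order
        )
    ).astype(np.intp)
    Afull = G.adjacency("csr")
    A_S = Afull[np.ix_(nodes, nodes)].tocsr()
    A_seed = Afull[np.ix_(seeds, seeds)].tocsr()
    A_batch_sim = None
    if A_sim is not None:
        A_batch_sim = sp.csr_matrix(A_sim)[np.ix_(seeds, seeds)]
    return BatchSubgraph(
        seed_spots=np.asarray(seeds, dtype=np.intp),
        first_order=first_order,
        second_order=second_order,
        children=children,
        nodes=nodes,
        A_S=A_S,
        A_seed=A_seed,
        A_batch_sim=A_batch_sim,
    )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class EncoderParams:
    """All trainable weights plus the frozen backbone handle."""

    W0: Tensor
    b0: Tensor
    W1: Tensor
    b1: Tensor
    head_W1: Tensor
    head_b1: Tensor
    head_W2: Tensor
    head_b2: Tensor
    Wf: Tensor
    W_ST: Tensor
    W_img: Tensor
    dec_W1: Tensor
    dec_b1: Tensor
    dec_W2: Tensor
    dec_b2: Tensor
    backbone: ImageBackbone = field(default_factory=FrozenConvBackbone)

    @classmethod
    def create(
        cls,
        n_genes: int,
        backbone: ImageBackbone,
        cfg: ModelConfig,
        rng: np.random.Generator,
    ) -> "EncoderParams":
        d, h = cfg.d, cfg.decoder_hidden
        F = backbone.n_features
        return cls(
            W0=_glorot(rng, n_genes, d),
            b0=_zeros(d),
            W1=_glorot(rng, d, d),
            b1=_zeros(d),
            head_W1=_glorot(rng, F, d),
            head_b1=_zeros(d),
            head_W2=_glorot(rng, d, d),
            head_b2=_zeros(d),
            Wf=_glorot(rng, 2 * d, d),
            W_ST=_glorot(rng, d, d),
            W_img=_glorot(rng, d, d),
            dec_W1=_glorot(rng, d, h),
            dec_b1=_zeros(h),
            dec_W2=_glorot(rng, h, n_genes),
            dec_b2=_zeros(n_genes),
            backbone=backbone,
        )

    def trainable(self) -> List[Tensor]:
        return [
            self.W0, self.b0, self.W1, self.b1,
            self.head_W1, self.head_b1, self.head_W2, self.head_b2,
            self.Wf, self.W_ST, self.W_img,
            self.dec_W1, self.dec_b1, self.dec_W2, self.dec_b2,
        ]

    def snapshot(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.trainable()]

    def restore(self, snap: List[np.ndarray]) -> None:
        for p, w in zip(self.trainable(), snap):
            p.data = w.copy()


# ---------------------------------------------------------------------------
# encoder / fusion / decoder forward passes
# ---------------------------------------------------------------------------


def _mean_agg_matrix(members: List[np.ndarray], index: Dict[int, int], n_cols: int) -> np.ndarray:
    """Dense row-normalized aggregation matrix: row r averages member columns."""
    M = np.zeros((len(members), n_cols))
    for r, mem in enumerate(members):
        cols = [index[int(u)] for u in mem]
        M[r, cols] = 1.0 / len(cols)
    return M


def encode_genes(X_S: np.ndarray, sg: BatchSubgraph, params: EncoderParams) -> Tensor:
    """Two-layer mean-aggregation encoding of the sampled subgraph's seeds.

    Layer 0 updates every seed and sampled first-order node by averaging its
    own input feature with its sampled children's; layer 1 updates each seed
    from its own layer-0 output and its sampled neighbors'. Returns a
    (B, d) embedding for the seeds. A node with no sampled children
    aggregates over itself alone.
    """
    nodes = sg.nodes
    node_pos = {int(u): i for i, u in enumerate(nodes)}
    l0_nodes = sorted({int(s) for s in sg.seed_spots} | {int(j) for f in sg.first_order for j in f})
    l0_pos = {u: i for i, u in enumerate(l0_nodes)}

    members0 = [
        np.concatenate([[u], sg.children.get(u, np.array([], dtype=np.intp))]).astype(np.intp)
        for u in l0_nodes
    ]
    M0 = _mean_agg_matrix(members0, node_pos, len(nodes))

    members1 = [
        np.concatenate([[int(s)], f]).astype(np.intp)
        for s, f in zip(sg.seed_spots, sg.first_order)
    ]
    M1 = np.zeros((sg.n_seeds, len(l0_nodes)))
    for r, mem in enumerate(members1):
        cols = [l0_pos[int(u)] for u in mem]
        M1[r, cols] = 1.0 / len(cols)

    X_nodes = np.asarray(X_S, dtype=np.float64)
    h1 = (Tensor(M0 @ X_nodes) @ params.W0 + params.b0).elu()
    h2 = ((Tensor(M1) @ h1) @ params.W1 + params.b1).elu()
    return h2


def encode_genes_full(X: np.ndarray, G: SpatialGraph, params: EncoderParams) -> Tensor:
    """Full-graph two-layer encoding (no sampling): every spot is a seed and
    aggregates over its complete spatial neighborhood at both layers."""
    n = G.n_spots
    M = np.zeros((n, n))
    for i in range(n):
        mem = np.concatenate([[i], G.neighbors[i]])
        M[i, mem] = 1.0 / len(mem)
    h1 = (Tensor(M @ np.asarray(X, dtype=np.float64)) @ params.W0 + params.b0).elu()
    h2 = ((Tensor(M) @ h1) @ params.W1 + params.b1).elu()
    return h2


def encode_images(
    features: np.ndarray, params: EncoderParams, batch: Optional[np.ndarray] = None
) -> Tensor:
    """Trainable MLP head over frozen backbone features.

    ``features`` may be precomputed backbone output (B, F) or raw patches,
    in which case the frozen backbone is applied first.
    """
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim == 4:  # raw patches
        if feats.shape[1] != feats.shape[2]:
            raise ValueError("patches must be square")
        feats = params.backbone.encode(feats)
    if feats.ndim != 2 or feats.shape[1] != params.head_W1.shape[0]:
        raise ValueError(
            f"backbone feature dim {feats.shape[-1]} does not match head input "
            f"{params.head_W1.shape[0]}"
        )
    if batch is not None:
        feats = feats[np.asarray(batch, dtype=np.intp)]
    h = (Tensor(feats) @ params.head_W1 + params.head_b1).elu()
    return h @ params.head_W2 + params.head_b2


def fuse(h_ST: Tensor, h_img: Tensor, k_emb: float, params: EncoderParams) -> Tuple[Tensor, Tensor]:
    """Weighted concatenation and projection: returns (h_c, h_f)."""
    if not 0.0 < k_emb < 1.0:
        raise ValueError("k_emb must lie strictly inside (0, 1)")
    h_c = concat([h_ST * k_emb, h_img * (1.0 - k_emb)], axis=1)
    h_f = h_c @ params.Wf
    return h_c, h_f


def edge_probability(h_i, h_j) -> float:
    """Sigmoid inner-product connection probability for one spot pair."""
    a = h_i.data if isinstance(h_i, Tensor) else np.asarray(h_i, dtype=np.float64)
    b = h_j.data if isinstance(h_j, Tensor) else np.asarray(h_j, dtype=np.float64)
    return float(1.0 / (1.0 + np.exp(-float(a @ b))))


def normalized_adjacency(A: sp.spmatrix) -> np.ndarray:
    """Symmetric degree-normalized adjacency with self-loops,
    D^{-1/2} (A + I) D^{-1/2}, densified."""
    A = np.asarray(sp.csr_matrix(A).todense(), dtype=np.float64)
    A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    return A * dinv[:, None] * dinv[None, :]


def decode_expression(h_f: Tensor, A: sp.spmatrix, params: EncoderParams) -> Tensor:
    """Two-layer graph convolution from fused embeddings back to expression.

    Hidden layer uses ELU; the output layer is linear. ``A`` is the raw
    (seed-induced) adjacency; normalization with self-loops happens here.
    """
    Ahat = Tensor(normalized_adjacency(A))
    h = (Ahat @ (h_f @ params.dec_W1) + params.dec_b1).elu()
    return Ahat @ (h @ params.dec_W2) + params.dec_b2


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(params: EncoderParams, path, extra: Optional[dict] = None) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(params.snapshot())}
    if extra:
        import json

        arrays["meta_json"] = np.frombuffer(
            json.dumps(extra).encode(), dtype=np.uint8
        )
    np.savez(path, **arrays)


def load_checkpoint(params: EncoderParams, path) -> Optional[dict]:
    data = np.load(path)
    snap = [data[f"w{i}"] for i in range(len(params.trainable()))]
    params.restore(snap)
    if "meta_json" in data:
        import json

        return json.loads(bytes(data["meta_json"]).decode())
    return None


def make_optimizer(params: EncoderParams, cfg: ModelConfig) -> Adam:
    return Adam(params.trainable(), lr=cfg.lr)
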