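"""Minibatch trainer binding graphs, augmentation, model and losses.

One :class:`ContrastiveTrainer` owns a (preprocessed) dataset, its spatial
and similarity graphs, precomputed frozen backbone features, pseudo-labels
and the trainable parameters. ``train_epoch`` runs the joint objective —
contrastive + adjacency + expression reconstruction — over a random batch
partition; the RL loop snapshots/restores the full trainer state to train
candidate models per hyper-parameter sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp

from .augment import AugmentConfig, augment_patches, mask_noise
from .autodiff import Tensor, concat
from .backbone import ImageBackbone
from .graphs import SimilarityGraph, SpatialGraph
from .model_core import (
    EncoderParams,
    ModelConfig,
    decode_expression,
    encode_genes,
    encode_genes_full,
    encode_images,
    fuse,
    make_optimizer,
    sample_batch_subgraph,
)
from .objectives import LossWeights, adjacency_loss, expression_loss_mean, total_loss
from .tuple_contrast import (
    DISTURB_V2,
    FULL,
    AlphaMixture,
    assign_pseudo_labels,
    info_nce_fused,
    sample_negative_indices,
)

logger = logging.getLogger(__name__)


@dataclass
class AblationFlags:
    """Switches mirroring the ablation study; all off by default."""

    drop_contrastive: bool = False
    drop_adjacency_loss: bool = False
    drop_expression_loss: bool = False
    fixed_alpha: bool = False
    fixed_kemb: bool = False
    no_neighbor_smoothing: bool = False

    def as_dict(self) -> Dict[str, bool]:
        return {k: bool(v) for k, v in self.__dict__.items()}


class ContrastiveTrainer:
    """Joint-objective trainer for one (possibly multi-slice) dataset.

    Parameters
    ----------
    X : preprocessed spot × gene matrix
    G : spatial k-NN graph over (translated) pixel coordinates
    A_sim : similarity adjacency (per-slice A, or the global A* when
        integrating slices)
    patches : per-spot image patches, or None for expression-only mode
    """

    def __init__(
        self,
        X: np.ndarray,
        G: SpatialGraph,
        A_sim: sp.spmatrix,
        patches: Optional[np.ndarray],
        backbone: ImageBackbone,
        cfg: ModelConfig,
        aug_cfg: Optional[AugmentConfig] = None,
        weights: Optional[LossWeights] = None,
        ablations: Optional[AblationFlags] = None,
        K_pseudo: int = 4,
        seed: int = 0,
    ):
        self.X = np.asarray(X, dtype=np.float64)
        self.G = G
        self.A_sim = sp.csr_matrix(A_sim)
        self.cfg = cfg
        self.aug_cfg = aug_cfg or AugmentConfig()
        self.weights = weights or LossWeights()
        self.ablations = ablations or AblationFlags()
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.n_spots, self.n_genes = self.X.shape
        self.image_mode = patches is not None

        self.patches = patches
        self.backbone = backbone
        if self.image_mode:
            self.backbone_features = backbone.encode(patches)
        else:
            # expression-only mode: a zero image feature keeps shapes intact
            self.backbone_features = np.zeros((self.n_spots, backbone.n_features))

        self.params = EncoderParams.create(
            self.n_genes, backbone, cfg, np.random.default_rng(seed)
        )
        self.optimizer = make_optimizer(self.params, cfg)

        h_img0 = self._head(self.backbone_features)
        if self.image_mode:
            self.pseudo_labels = assign_pseudo_labels(h_img0, K_pseudo, seed=seed)
        else:
            # no image signal: pseudo-labels from gene embeddings instead
            hst0 = encode_genes_full(self.X, G, self.params).data
            self.pseudo_labels = assign_pseudo_labels(hst0, K_pseudo, seed=seed)
        self.loss_log: List[Dict[str, float]] = []

    # -- low-level helpers ----------------------------------------------------
    def _head(self, feats: np.ndarray) -> np.ndarray:
        return encode_images(feats, self.params).data

    def snapshot(self) -> dict:
        return {
            "weights": self.params.snapshot(),
            "opt": self.optimizer.state_dict(),
            "rng": self.rng.bit_generator.state,
        }

    def restore(self, snap: dict) -> None:
        self.params.restore(snap["weights"])
        self.optimizer.load_state_dict(snap["opt"])
        self.rng.bit_generator.state = snap["rng"]

    # -- training -------------------------------------------------------------
    def _smoothing_matrix(self, seeds: np.ndarray, A_batch: sp.spmatrix) -> np.ndarray:
        """Constant matrix realizing (h_i + neighbor-mean)/2 on the batch."""
        B = len(seeds)
        A = np.asarray(sp.csr_matrix(A_batch).todense(), dtype=np.float64)
        S = np.eye(B)
        if self.ablations.no_neighbor_smoothing:
            return S
        m = A.sum(axis=1)
        nz = m > 0
        S[nz] = 0.5 * (np.eye(B)[nz] + A[nz] / m[nz, None])
        return S

    def train_step(self, sg, alpha: AlphaMixture, k_emb: float) -> Dict[str, float]:
        seeds = sg.seed_spots
        h_ST = encode_genes(self.X[sg.nodes], sg, self.params)
        h_img = encode_images(self.backbone_features, self.params, batch=seeds)
        _, h_f = fuse(h_ST, h_img, k_emb, self.params)

        zero = Tensor(0.0)
        l_a = zero if self.ablations.drop_adjacency_loss else adjacency_loss(sg.A_seed, h_f)
        if self.ablations.drop_expression_loss:
            l_b = zero
        else:
            X_hat = decode_expression(h_f, sg.A_seed, self.params)
            l_b = expression_loss_mean(X_hat, self.X[seeds])

        if self.ablations.drop_contrastive:
            l_con = zero
        else:
            l_con = self._contrastive_loss(sg, h_ST, h_img, alpha, k_emb)

        loss = total_loss(l_con, l_a, l_b, self.weights)
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.step()
        return {
            "loss": float(loss.data),
            "contrastive": float(l_con.data),
            "adjacency": float(l_a.data),
            "expression": float(l_b.data),
        }

    def _contrastive_loss(self, sg, h_ST: Tensor, h_img: Tensor, alpha, k_emb):
        seeds = sg.seed_spots
        B = len(seeds)
        p = self.params

        # anchor views
        v1 = (h_ST * k_emb) @ p.W_ST
        v2 = (h_img * (1.0 - k_emb)) @ p.W_img

        # positive gene view: neighbor smoothing (constant matrix) + mask noise
        S = self._smoothing_matrix(seeds, sg.A_batch_sim)
        noise = mask_noise(np.zeros((B, self.cfg.d)), self.aug_cfg, self.rng)
        h_ST_pos = Tensor(S) @ h_ST + Tensor(noise)

        # positive image view: augmented patches through frozen backbone + head
        if self.image_mode:
            aug = augment_patches(self.patches[seeds], self.aug_cfg, self.rng)
            feats_pos = self.backbone.encode(aug)
        else:
            feats_pos = self.backbone_features[seeds]
        h_img_pos = encode_images(feats_pos, p)

        v1p = (h_ST_pos * k_emb) @ p.W_ST
        v2p = (h_img_pos * (1.0 - k_emb)) @ p.W_img

        a_f = concat([v1, v2], axis=1) @ p.Wf
        p_f = concat([v1p, v2p], axis=1) @ p.Wf

        src, kinds = sample_negative_indices(
            self.pseudo_labels[seeds], self.cfg.n_neg, alpha, self.rng
        )
        anchor_idx = np.repeat(np.arange(B), self.cfg.n_neg)
        src_f, kinds_f = src.ravel(), kinds.ravel()
        idx_v1 = np.where(kinds_f != DISTURB_V2, src_f, anchor_idx)
        idx_v2 = np.where((kinds_f == FULL) | (kinds_f == DISTURB_V2), src_f, anchor_idx)
        n_f = concat([v1.gather_rows(idx_v1), v2.gather_rows(idx_v2)], axis=1) @ p.Wf
        return info_nce_fused(a_f, p_f, n_f, anchor_idx, self.cfg.tau)

    def train_epoch(self, alpha: AlphaMixture, k_emb: float) -> Dict[str, float]:
        order = self.rng.permutation(self.n_spots)
        B = min(self.cfg.batch_size, self.n_spots)
        totals: Dict[str, float] = {}
        n_batches = 0
        for start in range(0, self.n_spots, B):
            seeds = np.sort(order[start : start + B])
            if len(seeds) < max(2, B // 8):  # skip degenerate trailing batches
                continue
            sg = sample_batch_subgraph(
                self.G, len(seeds), self.cfg.fanout, self.rng, seeds=seeds,
                A_sim=self.A_sim,
            )
            stats = self.train_step(sg, alpha, k_emb)
            for k, v in stats.items():
                totals[k] = totals.get(k, 0.0) + v
            n_batches += 1
        means = {k: v / max(n_batches, 1) for k, v in totals.items()}
        self.loss_log.append(means)
        return means

    # -- inference ------------------------------------------------------------
    def unimodal_embeddings(self) -> tuple:
        """Full-data (h_ST, h_img) with complete neighborhoods, as numpy."""
        h_ST = encode_genes_full(self.X, self.G, self.params).data
        h_img = self._head(self.backbone_features)
        return h_ST, h_img

    def fused_embedding(self, k_emb: float) -> np.ndarray:
        h_ST, h_img = self.unimodal_embeddings()
        h_c = np.concatenate([k_emb * h_ST, (1.0 - k_emb) * h_img], axis=1)
        return h_c @ self.params.Wf.data

    def denoise(self, k_emb: float) -> np.ndarray:
        """Decode the full-data fused embedding back to expression space."""
        h_f = Tensor(self.fused_embedding(k_emb))
        return decode_expression(h_f, self.G.adjacency(), self.params).data
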