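"""Tuple-disturbing contrastive learning.

Each spot is represented as a two-view tuple: a projected, ``k_emb``-weighted
gene view and a projected, ``(1 - k_emb)``-weighted image view. Image-feature
clustering assigns every spot a pseudo-label once, before training. Negatives
for an anchor are built from a pseudo-label-mismatched sample ``h_j`` drawn
uniformly, disturbed according to the (α0, α1, α2) mixture: with probability
α0 the whole tuple is replaced, with probability αk only view k is. The
contrastive objective is a temperature-scaled InfoNCE over (anchor, positive,
negative) triplets in the shared fused space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat

logger = logging.getLogger(__name__)

FULL, DISTURB_V1, DISTURB_V2 = 0, 1, 2


@dataclass
class AlphaMixture:
    """Simplex point (α0, α1, α2): full / gene-view / image-view disturbance."""

    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.alpha.shape != (3,):
            raise ValueError("alpha must have 3 components")
        if np.any(self.alpha < -1e-9) or abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError(f"alpha must lie on the probability simplex: {self.alpha}")

    @classmethod
    def uniform(cls) -> "AlphaMixture":
        return cls(np.full(3, 1.0 / 3.0))


@dataclass
class TupleSample:
    """Per-spot two-view tuple with its pseudo-label."""

    v1: np.ndarray
    v2: np.ndarray
    pseudo_label: int
    spot_index: int


def assign_pseudo_labels(
    h_img_all: np.ndarray, K_pseudo: int, seed: int = 0
) -> np.ndarray:
    """Seeded centroid clustering of image embeddings into ≤ K_pseudo labels."""
    from sklearn.cluster import KMeans

    h = np.asarray(h_img_all, dtype=np.float64)
    if K_pseudo < 2:
        raise ValueError("K_pseudo must be >= 2")
    if h.shape[0] < K_pseudo:
        raise ValueError("fewer spots than pseudo-label clusters")
    if np.allclose(h, h[0]):
        logger.warning("identical image embeddings; assigning a single pseudo-label")
        return np.zeros(h.shape[0], dtype=np.intp)
    km = KMeans(n_clusters=K_pseudo, n_init=4, random_state=seed)
    return km.fit_predict(h).astype(np.intp)


def draw_negative(
    anchor: TupleSample,
    pool: Sequence[TupleSample],
    mix: AlphaMixture,
    rng: np.random.Generator,
) -> TupleSample:
    """One disturbed negative for ``anchor`` from the batch pool.

    The source ``h_j`` is uniform among pool members with a mismatched
    pseudo-label (falling back to any j ≠ i when none exists); the
    disturbance type is multinomial over (α0, α1, α2).
    """
    cand = [
        s for s in pool
        if s.spot_index != anchor.spot_index and s.pseudo_label != anchor.pseudo_label
    ]
    if not cand:
        logger.warning(
            "no pseudo-label-mismatched candidate for spot %d; using any other spot",
            anchor.spot_index,
        )
        cand = [s for s in pool if s.spot_index != anchor.spot_index]
        if not cand:
            raise ValueError("pool holds no sample other than the anchor")
    hj = cand[int(rng.integers(len(cand)))]
    kind = int(rng.choice(3, p=mix.alpha))
    if kind == FULL:
        return TupleSample(hj.v1.copy(), hj.v2.copy(), hj.pseudo_label, hj.spot_index)
    if kind == DISTURB_V1:
        return TupleSample(hj.v1.copy(), anchor.v2.copy(), anchor.pseudo_label, hj.spot_index)
    return TupleSample(anchor.v1.copy(), hj.v2.copy(), anchor.pseudo_label, hj.spot_index)


@dataclass
class ContrastBatch:
    """Anchors, aligned positives, and per-anchor negative lists."""

    anchors: List[TupleSample]
    positives: List[TupleSample]
    negatives: List[List[TupleSample]]
    tau: float = 0.5

    def __post_init__(self):
        if len(self.positives) != len(self.anchors):
            raise ValueError("one positive per anchor required")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


def info_nce_scores(pos_scores: Tensor, neg_scores: Tensor, tau: float) -> Tensor:
    """Mean pairwise InfoNCE from raw similarity scores.

    Each (anchor, negative) pair contributes
    ``-log[ e^{s+/τ} / (e^{s+/τ} + e^{s-/τ}) ] = softplus((s- - s+)/τ)``,
    averaged over pairs. ``pos_scores`` broadcasts against ``neg_scores``.
    """
    diff = (neg_scores - pos_scores) * (1.0 / tau)
    return diff.softplus().mean()


def info_nce(batch: ContrastBatch, Wf: Tensor) -> Tensor:
    """InfoNCE over a contrast batch, fusing tuples with the shared ``Wf``.

    Every tuple (anchor, positive, negative) is fused by concatenating its
    two views and applying the model's fusion projection, so the contrastive
    space coincides with the clustering space. The score is the dot product
    of fused vectors.
    """

    def fuse_tuples(samples: Sequence[TupleSample]) -> Tensor:
        V = np.stack([np.concatenate([s.v1, s.v2]) for s in samples])
        return Tensor(V) @ Wf

    a = fuse_tuples(batch.anchors)  # (B, d)
    p = fuse_tuples(batch.positives)
    pos = (a * p).sum(axis=1, keepdims=True)  # (B, 1)

    n_neg = len(batch.negatives[0])
    if any(len(n) != n_neg for n in batch.negatives):
        raise ValueError("all anchors must carry the same number of negatives")
    flat = [s for negs in batch.negatives for s in negs]
    nf = fuse_tuples(flat)  # (B*n_neg, d)
    B = len(batch.anchors)
    idx = np.repeat(np.arange(B), n_neg)
    neg = (a.gather_rows(idx) * nf).sum(axis=1, keepdims=True)  # (B*n_neg, 1)
    pos_rep = pos.gather_rows(idx)
    return info_nce_scores(pos_rep, neg, batch.tau)


def info_nce_fused(
    a_f: Tensor, p_f: Tensor, n_f: Tensor, anchor_of_negative: np.ndarray, tau: float
) -> Tensor:
    """InfoNCE on already-fused vectors (vectorized trainer path).

    ``n_f`` stacks all negatives; ``anchor_of_negative[r]`` names the anchor
    row of negative r.
    """
    idx = np.asarray(anchor_of_negative, dtype=np.intp)
    pos = (a_f * p_f).sum(axis=1, keepdims=True)
    neg = (a_f.gather_rows(idx) * n_f).sum(axis=1, keepdims=True)
    return info_nce_scores(pos.gather_rows(idx), neg, tau)


def sample_negative_indices(
    pseudo_labels: np.ndarray,
    n_neg: int,
    mix: AlphaMixture,
    rng: np.random.Generator,
) -> tuple:
    """Vectorized negative plan for a batch: (source index, disturbance kind).

    Matches :func:`draw_negative` semantics — per anchor, ``n_neg`` sources
    are drawn uniformly among label-mismatched batch members (any other spot
    when none exists) and each gets a multinomial disturbance kind. Returns
    arrays of shape (B, n_neg).
    """
    labels = np.asarray(pseudo_labels)
    B = labels.shape[0]
    src = np.empty((B, n_neg), dtype=np.intp)
    warned = False
    for i in range(B):
        cand = np.where(labels != labels[i])[0]
        cand = cand[cand != i]
        if cand.size == 0:
            if not warned:
                logger.warning("batch has no pseudo-label-mismatched candidates")
                warned = True
            cand = np.setdiff1d(np.arange(B), [i])
        src[i] = cand[rng.integers(cand.size, size=n_neg)]
    kinds = rng.choice(3, p=mix.alpha, size=(B, n_neg)).astype(np.intp)
    return src, kinds


def build_tuples(
    h_ST: np.ndarray,
    h_img: np.ndarray,
    k_emb: float,
    W_ST: np.ndarray,
    W_img: np.ndarray,
    pseudo_labels: np.ndarray,
    spot_indices: np.ndarray,
) -> List[TupleSample]:
    """Project weighted modality embeddings into per-spot tuples (numpy view)."""
    v1 = (k_emb * np.asarray(h_ST)) @ np.asarray(W_ST)
    v2 = ((1.0 - k_emb) * np.asarray(h_img)) @ np.asarray(W_img)
    return [
        TupleSample(v1[i], v2[i], int(pseudo_labels[i]), int(spot_indices[i]))
        for i in range(v1.shape[0])
    ]
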