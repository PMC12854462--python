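"""Reconstruction losses and the joint training objective.

The adjacency term penalizes low predicted connection probability on the
(positively connected) spot pairs of the sampled subgraph; the expression
term is the squared reconstruction error of the decoder; the total combines
them with the contrastive loss under weights γ1 (adjacency inside the
reconstruction loss) and γ2 (reconstruction inside the total), both 1 by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

Scalar = Union[float, Tensor]


@dataclass
class LossWeights:
    gamma1: float = 1.0
    gamma2: float = 1.0

    def __post_init__(self):
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("loss weights must be non-negative")


def adjacency_loss(A_S: sp.spmatrix, h_f: Tensor) -> Tensor:
    """Mean squared shortfall of edge probability over the subgraph's edges.

    For every connected pair (i, j), the predicted probability is
    sigmoid(h_i · h_j); the loss averages (1 - p)^2 over edges. An edgeless
    subgraph contributes 0 with a warning.
    """
    A = sp.csr_matrix(A_S)
    coo = sp.triu(A, k=1).tocoo()
    if coo.nnz == 0:
        logger.warning("subgraph has no edges; adjacency loss is 0")
        return Tensor(0.0)
    hi = h_f.gather_rows(coo.row)
    hj = h_f.gather_rows(coo.col)
    p = (hi * hj).sum(axis=1).sigmoid()
    return ((1.0 - p) ** 2).mean()


def expression_loss(X_hat: Tensor, X_batch: np.ndarray) -> Tensor:
    """Sum of squared element-wise reconstruction errors over the batch."""
    X_hat = as_tensor(X_hat)
    X_batch = np.asarray(X_batch, dtype=np.float64)
    if X_hat.shape != X_batch.shape:
        raise ValueError(f"shape mismatch: {X_hat.shape} vs {X_batch.shape}")
    return ((X_hat - Tensor(X_batch)) ** 2).sum()


def expression_loss_mean(X_hat: Tensor, X_batch: np.ndarray) -> Tensor:
    """Per-entry mean of :func:`expression_loss` (used for optimization and
    logging so loss components share a scale)."""
    n = float(np.asarray(X_batch).size)
    return expression_loss(X_hat, X_batch) * (1.0 / n)


def total_loss(l_con: Scalar, l_a: Scalar, l_b: Scalar, w: LossWeights) -> Scalar:
    """Joint objective: L = L_con + γ2 · (L_recon_b + γ1 · L_recon_a)."""
    if not any(isinstance(x, Tensor) for x in (l_con, l_a, l_b)):
        return float(l_con) + w.gamma2 * (float(l_b) + w.gamma1 * float(l_a))
    l_recon = as_tensor(l_b) + w.gamma1 * as_tensor(l_a)
    return as_tensor(l_con) + w.gamma2 * l_recon
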