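"""Positive-view augmentation for both modalities.

The gene view is augmented at the embedding level: each spot's feature vector
is averaged with the mean of its similarity-graph neighbors present in the
batch, a masked subset of feature dimensions receives unit Gaussian noise,
and missing values are imputed by row means. The image view is augmented at
the patch level with conservative geometric transforms (flips, blur,
rotation) that leave tissue semantics intact — pixel-value jitter is
deliberately avoided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import scipy.ndimage as ndi

logger = logging.getLogger(__name__)


@dataclass
class AugmentConfig:
    """Knobs for positive-view construction.

    ``mask_frac`` is the fraction of embedding dimensions perturbed with
    N(0, 1) noise; flips and blur each fire with probability 0.3 by default,
    mirroring the 30% convention; rotation angles are drawn uniformly from
    ``rotation_degrees``.
    """

    mask_frac: float = 0.3
    flip_prob: float = 0.3
    blur_prob: float = 0.3
    blur_sigma: float = 1.0
    rotation_degrees: Tuple[float, float] = (0.0, 360.0)
    per_spot_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("mask_frac", "flip_prob", "blur_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def smooth_with_neighbors(h: np.ndarray, A_batch) -> np.ndarray:
    """Average each spot's features with its batch-neighbor mean.

    For spot i with m_i > 0 neighbors in ``A_batch`` the output is
    ``(h_i + mean_k h_k) / 2``; isolated spots pass through unchanged.
    Linear in ``h``.
    """
    h = np.asarray(h, dtype=np.float64)
    A = np.asarray(
        A_batch.todense() if hasattr(A_batch, "todense") else A_batch, dtype=np.float64
    )
    if A.shape != (h.shape[0], h.shape[0]):
        raise ValueError("A_batch must be square over the batch")
    m = A.sum(axis=1)
    neigh_mean = np.zeros_like(h)
    nz = m > 0
    if np.any(nz):
        neigh_mean[nz] = (A[nz] @ h) / m[nz, None]
    out = h.copy()
    out[nz] = 0.5 * (h[nz] + neigh_mean[nz])
    return out


def mask_noise(h: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Add N(0, 1) noise to ``round(d * mask_frac)`` feature dimensions.

    The masked dimensions are drawn once per call and shared across the
    batch (``per_spot_mask=True`` draws an independent mask per spot).
    """
    h = np.asarray(h, dtype=np.float64)
    d = h.shape[1]
    n_mask = int(round(d * cfg.mask_frac))
    out = h.copy()
    if n_mask == 0:
        return out
    if cfg.per_spot_mask:
        for i in range(h.shape[0]):
            dims = rng.choice(d, size=n_mask, replace=False)
            out[i, dims] += rng.standard_normal(n_mask)
    else:
        dims = rng.choice(d, size=n_mask, replace=False)
        out[:, dims] += rng.standard_normal((h.shape[0], n_mask))
    return out


def impute_row_mean(X: np.ndarray) -> np.ndarray:
    """Replace NaN entries by their row's observed mean (all-NaN rows → 0)."""
    X = np.asarray(X, dtype=np.float64)
    out = X.copy()
    missing = np.isnan(out)
    if not missing.any():
        return out
    all_missing = missing.all(axis=1)
    if all_missing.any():
        logger.warning("%d fully-missing rows imputed to zero", int(all_missing.sum()))
        out[all_missing] = 0.0
        missing[all_missing] = False
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(np.where(missing, np.nan, out), axis=1)
    rows, cols = np.where(missing)
    out[rows, cols] = row_means[rows]
    return out


def augment_gene_view(
    h: np.ndarray, A_batch, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Full gene-modality positive view: smooth, mask-noise, impute."""
    out = smooth_with_neighbors(h, A_batch)
    out = mask_noise(out, cfg, rng)
    return impute_row_mean(out)


def augment_image_patch(
    patch: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Flips → optional Gaussian blur → rotation (reflect-padded, center pivot).

    Output shape equals input shape; fully deterministic given ``rng``.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be a square (s, s, 3) array")
    out = patch
    if rng.random() < cfg.flip_prob:
        out = out[:, ::-1]  # horizontal
    if rng.random() < cfg.flip_prob:
        out = out[::-1]  # vertical
    if rng.random() < cfg.blur_prob:
        out = ndi.gaussian_filter(out, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    lo, hi = cfg.rotation_degrees
    angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if angle % 360.0 != 0.0:
        out = ndi.rotate(
            out, angle, axes=(0, 1), reshape=False, order=1, mode="reflect", prefilter=False
        )
    return np.ascontiguousarray(out)


def augment_patches(
    patches: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply :func:`augment_image_patch` to every patch in a stack."""
    return np.stack([augment_image_patch(p, cfg, rng) for p in patches])
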