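"""Frozen image backbones.

The histology branch follows a pretrained-backbone + trainable-head design:
the backbone maps a square RGB patch to a fixed feature vector and never
receives gradients. Production users can plug any extractor satisfying
:class:`ImageBackbone`; the shipped default is :class:`FrozenConvBackbone`, a
small randomly initialized (fixed-seed) two-layer convolutional network over
an adaptively pooled patch, concatenated with per-channel color statistics.
Random convolutional features preserve color and coarse texture contrasts,
which is what spot-level histology patches mostly carry at this scale.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class ImageBackbone(Protocol):
    n_features: int

    def encode(self, patches: np.ndarray) -> np.ndarray:  # (B, s, s, 3) -> (B, F)
        ...


def _adaptive_avg_pool(batch: np.ndarray, out_side: int) -> np.ndarray:
    """Average-pool (B, s, s, C) to (B, out_side, out_side, C) for any s."""
    B, s, _, C = batch.shape
    if s == out_side:
        return batch
    edges = np.linspace(0, s, out_side + 1).astype(int)
    pooled = np.add.reduceat(batch, edges[:-1], axis=1)
    pooled = np.add.reduceat(pooled, edges[:-1], axis=2)
    counts = np.diff(edges)
    return pooled / (counts[None, :, None, None] * counts[None, None, :, None])


def _conv2d(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid 2-D convolution: (B,H,W,Cin) * (kh,kw,Cin,Cout) -> (B,H',W',Cout)."""
    kh, kw = W.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # win: (B, H', W', Cin, kh, kw)
    return np.einsum("bhwcij,ijco->bhwo", win, W)


class FrozenConvBackbone:
    """Fixed-seed random convolutional feature extractor (never trained).

    Patches are pooled to ``pool_side`` x ``pool_side``, passed through two
    ReLU convolution layers with fixed He-initialized filters, then global
    mean- and max-pooled; per-channel color mean/std of the raw patch are
    appended. Output is deterministic for identical inputs, which is the
    frozen contract the rest of the model relies on.
    """

    def __init__(self, seed: int = 0, pool_side: int = 8, c1: int = 16, c2: int = 32):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.pool_side = pool_side
        self.W1 = rng.standard_normal((3, 3, 3, c1)) * np.sqrt(2.0 / (9 * 3))
        self.W2 = rng.standard_normal((3, 3, c1, c2)) * np.sqrt(2.0 / (9 * c1))
        self.n_features = 2 * c2 + 6

    def encode(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 3:
            patches = patches[None]
        if patches.shape[1] < 5:
            raise ValueError(
                f"backbone expects patch side >= 5 pixels, got {patches.shape[1]}"
            )
        x = patches / 255.0 if patches.max() > 1.5 else patches
        color_mean = x.mean(axis=(1, 2))
        color_std = x.std(axis=(1, 2))
        h = _adaptive_avg_pool(x - 0.5, self.pool_side)
        h = np.maximum(_conv2d(h, self.W1), 0.0)
        h = np.maximum(_conv2d(h, self.W2), 0.0)
        feats = np.concatenate(
            [h.mean(axis=(1, 2)), h.max(axis=(1, 2)), color_mean, color_std], axis=1
        )
        return feats

    def checksum(self) -> str:
        """Digest of the frozen filters; must not change across training."""
        m = hashlib.sha256()
        m.update(self.W1.tobytes())
        m.update(self.W2.tobytes())
        return m.hexdigest()


def get_backbone(name: str = "frozen-conv", **kwargs) -> ImageBackbone:
    if name in ("frozen-conv", "fallback"):
        return FrozenConvBackbone(**kwargs)
    raise ValueError(f"unknown backbone {name!r}")
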