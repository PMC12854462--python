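"""Synthetic spatial-transcriptomics tissue generator.

Emulates layered cortical-style tissue: spots on a regular grid partitioned
into K contiguous horizontal bands (domains), each with its own gene
program. Counts are negative-binomial (Poisson-Gamma) with dropout-style
zero inflation; the pseudo-histology image gives each spot's neighborhood a
domain-specific base color mixed with uniform pixel noise. Multi-slice
replicates add per-gene multiplicative batch shifts (additive on the log
scale) and can crop the shared spatial footprint to model partial overlap.

Everything is deterministic under ``seed``, and the defaults define the
conditions the test-bed is built around (a 30 x 30 grid, four bands, 200
genes, a 2-unit log-fold program elevation, 30% dropout, strong but not
perfect image signal).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import numpy as np

from .st_io import SpotDataset


@dataclass
class TissueSpec:
    """Generator parameters; see module docstring for the emulated features."""

    n_side: int = 30
    K: int = 4
    n_genes: int = 200
    n_program_genes: int = 10
    effect: float = 2.0  # log-fold elevation of program genes in their domain
    dropout: float = 0.3
    noise_sd: float = 0.3  # lognormal spot-level jitter on NB means
    dispersion: float = 2.0  # NB shape (lower = more overdispersed)
    base_mean: float = 2.0
    image_signal: float = 0.7  # 1 = flat domain color, 0 = pure pixel noise
    pitch_px: int = 16  # grid spacing in pixels (also patch side)
    batch_shift_sd: float = 1.0
    overlap_frac: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.K > self.n_side:
            raise ValueError("more domains than grid rows")
        if self.n_program_genes * self.K > self.n_genes:
            raise ValueError("program genes exceed gene count")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.image_signal <= 1.0:
            raise ValueError("image_signal must lie in [0, 1]")


# domain base colors (RGB in 0..255), cycled when K > 6
_PALETTE = np.array(
    [
        [200, 120, 150],
        [120, 160, 210],
        [170, 200, 120],
        [220, 190, 110],
        [160, 120, 200],
        [120, 200, 190],
    ],
    dtype=np.float64,
)


def _band_labels(n_side: int, K: int) -> np.ndarray:
    """K contiguous horizontal bands in row-major spot order.

    Banding by spot index keeps band sizes equal (N/K each when K divides
    N) even when K does not divide the number of grid rows; boundaries then
    run mid-row but domains stay spatially connected stripes.
    """
    n = n_side * n_side
    return (np.arange(n) * K) // n


def program_gene_indices(spec: TissueSpec, domain: int) -> np.ndarray:
    """Indices of the genes elevated in ``domain``'s program."""
    start = domain * spec.n_program_genes
    return np.arange(start, start + spec.n_program_genes)


def _expression(
    spec: TissueSpec, labels: np.ndarray, rng: np.random.Generator,
    batch_shift: np.ndarray = None,
) -> np.ndarray:
    n = labels.size
    base = spec.base_mean * np.exp(
        0.25 * rng.standard_normal(spec.n_genes)
    )  # gene-level baseline heterogeneity
    mu = np.tile(base, (n, 1))
    for k in range(spec.K):
        idx = program_gene_indices(spec, k)
        mu[np.ix_(labels == k, idx)] *= np.exp(spec.effect)
    if batch_shift is not None:
        mu *= np.exp(batch_shift)[None, :]
    if spec.noise_sd > 0:
        mu *= np.exp(spec.noise_sd * rng.standard_normal((n, spec.n_genes)))
    # Poisson-Gamma mixture = negative binomial with shape `dispersion`
    lam = rng.gamma(spec.dispersion, mu / spec.dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout > 0:
        counts *= rng.random((n, spec.n_genes)) >= spec.dropout
    return counts


def _image(
    spec: TissueSpec, labels: np.ndarray, coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h = w = spec.n_side * spec.pitch_px
    img = rng.uniform(0, 255, size=(h, w, 3))
    if spec.image_signal > 0:
        color_field = np.zeros((h, w, 3))
        half = spec.pitch_px // 2
        for (x, y), lab in zip(coords.astype(int), labels):
            color = _PALETTE[lab % len(_PALETTE)]
            color_field[
                max(y - half, 0) : y + half + 1, max(x - half, 0) : x + half + 1
            ] = color
        img = spec.image_signal * color_field + (1.0 - spec.image_signal) * img
    return np.clip(img, 0, 255).astype(np.uint8)


def make_tissue(spec: TissueSpec, slice_id: str = "slice0") -> SpotDataset:
    """Generate one slice with ground-truth band labels attached."""
    rng = np.random.default_rng(spec.seed)
    labels = _band_labels(spec.n_side, spec.K)
    grid = np.arange(spec.n_side) * spec.pitch_px + spec.pitch_px // 2
    xs, ys = np.meshgrid(grid, grid)  # row-major: y = band axis
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    counts = _expression(spec, labels, rng)
    image = _image(spec, labels, coords, rng)
    n = labels.size
    return SpotDataset(
        expression=counts,
        coords=coords,
        spot_ids=[f"{slice_id}_s{i:04d}" for i in range(n)],
        gene_ids=[f"gene{j:04d}" for j in range(spec.n_genes)],
        image=image,
        labels=labels.copy(),
        slice_id=slice_id,
        platform="other",
    )


def make_multislice(spec: TissueSpec, n_slices: int = 2) -> List[SpotDataset]:
    """Replicate slices sharing the domain layout, with per-slice batch shifts.

    Each slice draws an independent per-gene shift ~ N(0, batch_shift_sd^2)
    applied on the log scale of the NB means, plus independent count noise.
    ``overlap_frac`` < 1 crops complementary row ranges so footprints only
    partially overlap.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    root = np.random.default_rng(spec.seed)
    labels_full = _band_labels(spec.n_side, spec.K)
    grid = np.arange(spec.n_side) * spec.pitch_px + spec.pitch_px // 2
    xs, ys = np.meshgrid(grid, grid)
    coords_full = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)

    n_keep = max(int(round(spec.overlap_frac * spec.n_side)), spec.K)
    max_start = spec.n_side - n_keep
    slices = []
    for s in range(n_slices):
        rng = np.random.default_rng(root.integers(2**31))
        shift = (
            spec.batch_shift_sd * rng.standard_normal(spec.n_genes)
            if spec.batch_shift_sd > 0
            else None
        )
        # complementary row windows create the partial-overlap geometry
        start = 0 if max_start == 0 else int(round(s * max_start / (n_slices - 1)))
        rows = np.arange(start, start + n_keep)
        keep = np.repeat(np.isin(np.arange(spec.n_side), rows), spec.n_side)
        labels = labels_full[keep]
        coords = coords_full[keep]
        counts = _expression(spec, labels, rng, batch_shift=shift)
        image = _image(spec, labels_full, coords_full, rng)
        slices.append(
            SpotDataset(
                expression=counts,
                coords=coords.copy(),
                spot_ids=[f"sl{s}_s{i:04d}" for i in range(labels.size)],
                gene_ids=[f"gene{j:04d}" for j in range(spec.n_genes)],
                image=image,
                labels=labels.copy(),
                slice_id=f"slice{s}",
                platform="other",
            )
        )
    return slices
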