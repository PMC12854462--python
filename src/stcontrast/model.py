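"""Model / Results facade over the training and clustering pipeline.

Follows the familiar two-object pattern: :class:`SpatialDomainModel` is
built from data plus a :class:`~stcontrast.config.RunConfig`, ``fit()``
runs the seeded training loop and returns a
:class:`SpatialDomainResults` carrying embeddings, the learned
hyper-parameters, domain labels, metrics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from . import train_cluster as tc
from .config import RunConfig
from .graphs import MultiSliceLayout, translate_and_concat
from .st_io import SpotDataset, load_spot_dataset


class SpatialDomainModel:
    """Multimodal contrastive spatial-domain model for one or more slices."""

    def __init__(self, data: Union[SpotDataset, MultiSliceLayout], config: Optional[RunConfig] = None):
        self.data = data
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        expr_path,
        coords_path,
        image_path=None,
        platform: str = "other",
        labels_path=None,
        config: Optional[RunConfig] = None,
    ) -> "SpatialDomainModel":
        ds = load_spot_dataset(
            expr_path, coords_path, image_path=image_path, platform=platform,
            labels_path=labels_path,
        )
        return cls(ds, config)

    @classmethod
    def from_slices(cls, slices, config: Optional[RunConfig] = None) -> "SpatialDomainModel":
        """Alignment-free multi-slice integration entry point."""
        cfg = config or RunConfig()
        layout = translate_and_concat(list(slices), gap_px=cfg.gap_px)
        return cls(layout, cfg)

    def fit(self, seed: Optional[int] = None) -> "SpatialDomainResults":
        cfg = self.config
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        out = tc.train(self.data, cfg)
        return SpatialDomainResults(self, out, cfg)


class SpatialDomainResults:
    """Fitted embeddings, learned hyper-parameters and domain assignments."""

    def __init__(self, model: SpatialDomainModel, output: tc.TrainOutput, config: RunConfig):
        self.model = model
        self.output = output
        self.config = config
        self._domains: Optional[tc.DomainResult] = None

    # -- fitted quantities ----------------------------------------------------
    @property
    def embedding(self) -> np.ndarray:
        """Fused per-spot representation h_f (N × d)."""
        return self.output.h_f

    @property
    def gene_embedding(self) -> np.ndarray:
        return self.output.h_ST

    @property
    def image_embedding(self) -> np.ndarray:
        return self.output.h_img

    @property
    def k_emb(self) -> float:
        """Learned gene-vs-image fusion weight (RL policy mean)."""
        return self.output.k_emb

    @property
    def alpha(self) -> np.ndarray:
        """Learned negative-mixture probabilities (α0, α1, α2)."""
        return self.output.alpha

    @property
    def manifest(self) -> dict:
        return self.output.manifest

    @property
    def loss_history(self):
        return self.output.trainer.loss_log

    # -- domain assignment ----------------------------------------------------
    def domains(self, refresh: bool = False) -> tc.DomainResult:
        if self._domains is None or refresh:
            self._domains = tc.assign_domains(self.output, self.config)
        return self._domains

    @property
    def labels_(self) -> np.ndarray:
        return self.domains().labels

    def evaluate(self, truth: Optional[np.ndarray] = None) -> dict:
        truth = truth if truth is not None else self.output.dataset.labels
        return tc.evaluate(self.labels_, truth=truth, embedding=self.embedding)

    def predict_expression(self) -> np.ndarray:
        """Denoised expression X̂ from the decoder (N × genes)."""
        return tc.denoise(self.output)

    def to_anndata(self):
        return tc.to_anndata(self.output, labels=self.labels_)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        dom = self.domains()
        ds = self.output.dataset
        lines = [
            "Spatial domain identification results",
            "=" * 45,
            f"{'spots':<28}{ds.n_spots}",
            f"{'genes (post-HVG)':<28}{ds.n_genes}",
            f"{'epochs':<28}{self.config.epochs}",
            f"{'embedding dim':<28}{self.config.model.d}",
            f"{'fusion weight k_emb':<28}{self.k_emb:.4f}",
            f"{'negative mixture alpha':<28}"
            + "(" + ", ".join(f"{a:.3f}" for a in self.alpha) + ")",
            f"{'domains found':<28}{len(np.unique(dom.labels))}",
            f"{'Leiden resolution':<28}{dom.resolution_used:.4f}",
        ]
        for name, val in dom.metrics.items():
            lines.append(f"{name:<28}{val:.4f}")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<SpatialDomainResults: {self.output.dataset.n_spots} spots, "
            f"k_emb={self.k_emb:.3f}>"
        )
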