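"""Run configuration: nested dataclasses, strict dict/YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .augment import AugmentConfig
from .model_core import ModelConfig
from .objectives import LossWeights
from .trainer import AblationFlags


@dataclass
class PolicyConfig:
    sigma_alpha: float = 0.3
    sigma_k: float = 0.3
    eta: float = 0.05
    n_candidates: int = 4


@dataclass
class RunConfig:
    """Top-level configuration for a full run.

    ``n_domains`` doubles as the Leiden target cluster count and the
    pseudo-label count; when absent, clustering falls back to the
    resolution sweep scored by silhouette.
    """

    n_domains: Optional[int] = None
    epochs: int = 30
    seed: int = 0
    n_hvg: int = 3000
    library_size: float = 1e4
    k_spatial: int = 6
    similarity_metric: str = "cosine"
    gap_px: int = 50
    cross_slice_k: int = 6
    patch_px: Optional[int] = None
    backbone_seed: int = 0
    refine: bool = False
    refine_radius: Optional[float] = None  # None -> 1.5 x median NN distance
    resolution_range: Tuple[float, float] = (0.1, 3.0)
    resolution_step: float = 0.05
    max_bisect: int = 50
    leiden_knn: int = 15
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    ablations: AblationFlags = field(default_factory=AblationFlags)
    policy: PolicyConfig = field(default_factory=PolicyConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.resolution_step <= 0:
            raise ValueError("resolution step must be positive")

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d, path="")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def apply_overrides(self, overrides: dict) -> "RunConfig":
        """Dotted-key overrides (e.g. ``model.lr=0.01``) win over the file."""
        d = self.to_dict()
        for key, value in overrides.items():
            node = d
            parts = key.split(".")
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config section {p!r} in {key!r}")
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = value
        return RunConfig.from_dict(d)


def _build(cls, d: dict, path: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise TypeError(f"expected mapping for {cls.__name__} at {path or 'root'}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise KeyError(f"unknown config key {sorted(unknown)[0]!r} at {path or 'root'}")
    kwargs = {}
    for k, v in d.items():
        f = names[k]
        sub = f.type if isinstance(f.type, type) else None
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default):
            kwargs[k] = _build(type(default), v, path=f"{path}{k}.")
        elif isinstance(v, list) and isinstance(default, tuple):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)
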