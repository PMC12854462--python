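"""Training orchestration, spatial-domain assignment and downstream hooks.

``train`` wires preprocessing, graphs, the trainer and the RL loop into one
seeded run; domains are then assigned by Leiden clustering of the fused
embedding — binary-searching the resolution when a target cluster count is
known, otherwise sweeping a fixed resolution grid and keeping the
silhouette-optimal labeling — with an optional majority-vote spatial
refinement pass. Metrics (ARI, NMI, Davies-Bouldin) and the decoder-based
expression denoising round out the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import scipy.sparse as sp

from .config import RunConfig
from .backbone import FrozenConvBackbone
from .graphs import (
    MultiSliceLayout,
    SimilarityGraph,
    cross_slice_similarity,
    similarity_adjacency,
    spatial_knn,
)
from .rl_policy import PolicyState, alternating_train, project_k
from .st_io import SpotDataset, extract_patches, preprocess
from .trainer import ContrastiveTrainer

logger = logging.getLogger(__name__)


@dataclass
class TrainOutput:
    """Everything a fitted run produces."""

    trainer: ContrastiveTrainer
    policy: PolicyState
    audits: list
    h_f: np.ndarray
    h_ST: np.ndarray
    h_img: np.ndarray
    k_emb: float
    alpha: np.ndarray
    dataset: SpotDataset
    graph: object
    manifest: Dict[str, object]


@dataclass
class DomainResult:
    labels: np.ndarray
    embedding: np.ndarray
    resolution_used: float
    metrics: Dict[str, float] = field(default_factory=dict)
    denoised: Optional[np.ndarray] = None


def _prepare(ds_or_layout, cfg: RunConfig):
    """Resolve dataset, similarity adjacency and spatial graph for training."""
    if isinstance(ds_or_layout, MultiSliceLayout):
        layout = ds_or_layout
        ds = layout.merged
        if not ds.is_preprocessed:
            ds = preprocess(ds, n_hvg=cfg.n_hvg, library_size=cfg.library_size)
            layout.merged = ds
            layout.A_star = None
        if layout.A_star is None:
            layout = cross_slice_similarity(
                layout, k=cfg.cross_slice_k, k_spatial=cfg.k_spatial,
                metric=cfg.similarity_metric,
            )
        A_sim = layout.A_star
        from .graphs import integration_graph

        return ds, A_sim, integration_graph(layout, k=cfg.k_spatial)
    else:
        ds = ds_or_layout
        if not ds.is_preprocessed:
            ds = preprocess(ds, n_hvg=cfg.n_hvg, library_size=cfg.library_size)
        A_sim = similarity_adjacency(
            ds.coords, ds.expression, k_spatial=cfg.k_spatial,
            metric=cfg.similarity_metric,
        ).A
    G = spatial_knn(ds.coords, k=cfg.k_spatial)
    return ds, A_sim, G


def train(ds_or_layout: Union[SpotDataset, MultiSliceLayout], cfg: RunConfig) -> TrainOutput:
    """Run the full seeded training loop and return embeddings + model.

    Without an image the run degrades to gene-only mode: the fusion weight
    is pinned near 1 and the image branch sees zero features.
    """
    ds, A_sim, G = _prepare(ds_or_layout, cfg)
    rng = np.random.default_rng(cfg.seed)

    patches = None
    if ds.image is not None:
        patches = extract_patches(ds, side_px=cfg.patch_px).patches
    else:
        logger.warning("no image available; training in gene-only mode (k_emb -> 1)")

    backbone = FrozenConvBackbone(seed=cfg.backbone_seed)
    ablations = cfg.ablations
    K_pseudo = cfg.n_domains if cfg.n_domains is not None else 8

    trainer = ContrastiveTrainer(
        X=ds.expression,
        G=G,
        A_sim=A_sim,
        patches=patches,
        backbone=backbone,
        cfg=cfg.model,
        aug_cfg=cfg.augment,
        weights=cfg.weights,
        ablations=ablations,
        K_pseudo=K_pseudo,
        seed=cfg.seed,
    )
    ps = PolicyState(
        sigma_alpha=cfg.policy.sigma_alpha,
        sigma_k=cfg.policy.sigma_k,
        eta=cfg.policy.eta,
        n_candidates=cfg.policy.n_candidates,
    )
    if patches is None:
        # gene-only: pin k_emb at ~1 so the (zero) image block is ignored
        from dataclasses import replace

        ps.mu_k = 13.8
        trainer.ablations = replace(ablations, fixed_kemb=True)

    trainer, ps, audits = alternating_train(
        trainer, ps, T=cfg.epochs, rng=rng, K=K_pseudo, cluster_seed=cfg.seed
    )
    k_emb = ps.k_mean
    h_ST, h_img = trainer.unimodal_embeddings()
    h_f = trainer.fused_embedding(k_emb)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "k_emb": float(k_emb),
        "alpha": ps.alpha_mean.alpha.tolist(),
        "ablations": trainer.ablations.as_dict(),
        "image_mode": patches is not None,
        "n_spots": ds.n_spots,
        "n_genes": ds.n_genes,
    }
    return TrainOutput(
        trainer=trainer,
        policy=ps,
        audits=audits,
        h_f=h_f,
        h_ST=h_ST,
        h_img=h_img,
        k_emb=float(k_emb),
        alpha=ps.alpha_mean.alpha,
        dataset=ds,
        graph=G,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Leiden clustering
# ---------------------------------------------------------------------------


def _leiden_once(embedding: np.ndarray, resolution: float, knn: int, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    k = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, int(j)), max(i, int(j))) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=np.intp)


def leiden_target_k(
    embedding: np.ndarray, K: int, cfg: Optional[RunConfig] = None
) -> tuple:
    """Binary-search the Leiden resolution for exactly K clusters.

    The bracket starts at [0.01, upper] and doubles the upper bound until K
    is bracketed; terminates on an exact hit or after ``max_bisect``
    evaluations, returning the closest-count labeling (ties prefer the lower
    resolution). Returns (labels, resolution).
    """
    cfg = cfg or RunConfig()
    if K < 2:
        raise ValueError("K must be >= 2")
    seed, knn, max_iter = cfg.seed, cfg.leiden_knn, cfg.max_bisect
    lo, hi = 0.01, cfg.resolution_range[1]
    evals = 0
    best = None  # (|count-K|, resolution, labels)

    def record(res, labels):
        nonlocal best
        key = (abs(len(np.unique(labels)) - K), res)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], labels)

    labels = _leiden_once(embedding, hi, knn, seed)
    evals += 1
    record(hi, labels)
    while len(np.unique(labels)) < K and evals < max_iter and hi < 1e4:
        hi *= 2.0
        labels = _leiden_once(embedding, hi, knn, seed)
        evals += 1
        record(hi, labels)
    if best[0] == 0:
        return best[2], best[1]

    while evals < max_iter:
        mid = 0.5 * (lo + hi)
        labels = _leiden_once(embedding, mid, knn, seed)
        evals += 1
        record(mid, labels)
        count = len(np.unique(labels))
        if count == K:
            return labels, mid
        if count < K:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "binary search hit %d iterations; closest cluster count differs from "
        "target %d by %d", evals, K, best[0],
    )
    return best[2], best[1]


def leiden_sweep_sc(embedding: np.ndarray, cfg: Optional[RunConfig] = None) -> tuple:
    """Sweep the resolution grid and keep the silhouette-optimal labeling.

    The grid spans ``resolution_range`` at ``resolution_step`` (59 points by
    default); degenerate labelings (single cluster or all singletons) are
    skipped; score ties prefer the lower resolution. Returns
    (labels, resolution).
    """
    from sklearn.metrics import silhouette_score

    cfg = cfg or RunConfig()
    lo, hi = cfg.resolution_range
    grid = np.round(np.arange(lo, hi + 1e-9, cfg.resolution_step), 10)
    best = None  # (score, resolution, labels)
    for res in grid:
        labels = _leiden_once(embedding, float(res), cfg.leiden_knn, cfg.seed)
        k = len(np.unique(labels))
        if k < 2 or k >= embedding.shape[0]:
            continue
        score = float(silhouette_score(embedding, labels))
        if best is None or score > best[0]:
            best = (score, float(res), labels)
    if best is None:
        raise ValueError("no resolution produced a scoreable labeling")
    return best[2], best[1]


def resolution_grid(cfg: Optional[RunConfig] = None) -> np.ndarray:
    cfg = cfg or RunConfig()
    lo, hi = cfg.resolution_range
    return np.round(np.arange(lo, hi + 1e-9, cfg.resolution_step), 10)


# ---------------------------------------------------------------------------
# refinement, metrics, denoising
# ---------------------------------------------------------------------------


def default_refine_radius(coords: np.ndarray) -> float:
    """1.5 x median nearest-neighbor distance (covers the first hex shell)."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    d, _ = nn.kneighbors(coords)
    return 1.5 * float(np.median(d[:, 1]))


def refine_labels(labels: np.ndarray, coords: np.ndarray, r: float) -> np.ndarray:
    """One synchronous majority-vote pass within spatial radius ``r``.

    Each spot takes the modal label among all spots within distance r (self
    included); ties keep the current label. Never introduces a new label.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=np.float64)
    n = len(labels)
    d2 = (
        (coords**2).sum(axis=1, keepdims=True)
        - 2 * coords @ coords.T
        + (coords**2).sum(axis=1)
    )
    out = labels.copy()
    uniq = np.unique(labels)
    for i in range(n):
        nbr = np.where(d2[i] <= r * r + 1e-12)[0]
        counts = {lab: 0 for lab in uniq}
        for j in nbr:
            counts[labels[j]] += 1
        mx = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == mx]
        if len(winners) == 1:
            out[i] = winners[0]
    return out


def evaluate(
    labels: np.ndarray,
    truth: Optional[np.ndarray] = None,
    embedding: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """ARI/NMI against ground truth plus Davies-Bouldin on the embedding."""
    from sklearn import metrics as skm

    out: Dict[str, float] = {}
    if truth is not None:
        if len(truth) != len(labels):
            raise ValueError("truth must align with labels")
        out["ARI"] = float(skm.adjusted_rand_score(truth, labels))
        out["NMI"] = float(skm.normalized_mutual_info_score(truth, labels))
    if embedding is not None and len(np.unique(labels)) >= 2:
        out["DB"] = float(skm.davies_bouldin_score(embedding, labels))
    return out


def morans_i(X: np.ndarray, W: sp.spmatrix) -> np.ndarray:
    """Column-wise Moran's I spatial autocorrelation under binary weights W."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == W.shape[0]:
        pass
    elif X.shape[1] == W.shape[0]:
        X = X.T
    else:
        raise ValueError("X rows must match W")
    W = sp.csr_matrix(W)
    n = X.shape[0]
    z = X - X.mean(axis=0)
    num = (z * (W @ z)).sum(axis=0)
    den = (z**2).sum(axis=0)
    den[den == 0] = np.inf
    return (n / W.sum()) * num / den


def denoise(out: TrainOutput) -> np.ndarray:
    """Full-dataset decoder pass: denoised expression aligned to gene order."""
    return out.trainer.denoise(out.k_emb)


def assign_domains(out: TrainOutput, cfg: RunConfig) -> DomainResult:
    """Cluster the fused embedding into spatial domains and score them."""
    if cfg.n_domains is not None:
        labels, res = leiden_target_k(out.h_f, cfg.n_domains, cfg)
    else:
        labels, res = leiden_sweep_sc(out.h_f, cfg)
    if cfg.refine:
        r = cfg.refine_radius or default_refine_radius(out.dataset.coords)
        labels = refine_labels(labels, out.dataset.coords, r)
    truth = out.dataset.labels
    metrics = evaluate(labels, truth=truth, embedding=out.h_f)
    return DomainResult(
        labels=labels, embedding=out.h_f, resolution_used=res, metrics=metrics
    )


# ---------------------------------------------------------------------------
# optional scanpy-based downstream conveniences (thin wrappers, no bespoke logic)
# ---------------------------------------------------------------------------


def to_anndata(out: TrainOutput, labels: Optional[np.ndarray] = None):
    """Package results as an AnnData for scanpy downstream use (UMAP/PAGA/DEG)."""
    import pandas as pd
    from anndata import AnnData

    ds = out.dataset
    ad = AnnData(
        ds.expression,
        obs=pd.DataFrame(index=[str(s) for s in ds.spot_ids]),
        var=pd.DataFrame(index=[str(g) for g in ds.gene_ids]),
    )
    ad.obsm["spatial"] = ds.coords.copy()
    ad.obsm["X_stcontrast"] = out.h_f.copy()
    if labels is not None:
        ad.obs["domain"] = pd.Categorical([str(l) for l in labels])
    return ad


def run_umap(ad, seed: int = 0):
    import scanpy as sc

    sc.pp.neighbors(ad, use_rep="X_stcontrast", random_state=seed)
    sc.tl.umap(ad, random_state=seed)
    return ad


def run_paga(ad, groups: str = "domain"):
    import scanpy as sc

    if "neighbors" not in ad.uns:
        sc.pp.neighbors(ad, use_rep="X_stcontrast")
    sc.tl.paga(ad, groups=groups)
    return ad


def rank_marker_genes(ad, groupby: str = "domain"):
    import scanpy as sc

    sc.tl.rank_genes_groups(ad, groupby=groupby, method="wilcoxon")
    return ad
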