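"""Spot-level dataset container, file I/O and expression preprocessing.

A :class:`SpotDataset` bundles the spot × gene expression matrix, pixel-space
spot coordinates, an optional H&E-style RGB image, and optional ground-truth
domain labels for one tissue slice. Loaders accept a dense CSV/TSV dialect
(header row = gene ids, first column = spot ids) or the 10x-style sparse
triplet layout (matrix-market with spots as columns, plus barcodes/features
lists). Preprocessing follows the standard spatial-transcriptomics recipe:
highly-variable-gene selection, per-spot library-size normalization and a
log(1 + x) transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("ST", "Visium", "Xenium", "other")

#: default square patch side (pixels) per platform, matched to spot diameter
PLATFORM_PATCH_PX = {"ST": 112, "Visium": 112, "Xenium": 30}


@dataclass
class SpotDataset:
    """One tissue slice: expression, coordinates, image, optional labels.

    ``expression`` is spot × gene and non-negative (raw counts or processed
    values). ``coords`` holds continuous 0-based pixel positions with
    x = image column and y = image row.
    """

    expression: np.ndarray
    coords: np.ndarray
    spot_ids: list
    gene_ids: list
    image: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    slice_id: str = "slice0"
    platform: str = "other"
    is_preprocessed: bool = False

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.expression.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"expression has {self.expression.shape[0]} spots but coords has "
                f"{self.coords.shape[0]}"
            )
        if len(self.spot_ids) != self.expression.shape[0]:
            raise ValueError("spot_ids length mismatch")
        if len(self.gene_ids) != self.expression.shape[1]:
            raise ValueError("gene_ids length mismatch")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; one of {PLATFORMS}")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def copy(self) -> "SpotDataset":
        return replace(
            self,
            expression=self.expression.copy(),
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            gene_ids=list(self.gene_ids),
            image=None if self.image is None else self.image.copy(),
            labels=None if self.labels is None else np.asarray(self.labels).copy(),
        )


@dataclass
class PatchSet:
    """Per-spot square RGB patches extracted from the slice image."""

    patches: np.ndarray  # (n_spots, side_px, side_px, 3)
    side_px: int
    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 4 or self.patches.shape[3] != 3:
            raise ValueError("patches must be (n, side, side, 3)")
        if self.patches.shape[1] != self.side_px or self.patches.shape[2] != self.side_px:
            raise ValueError("patch side mismatch")

    def __len__(self):
        return self.patches.shape[0]


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------


def _read_dense_expression(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_sparse_expression(mtx_path: Path) -> pd.DataFrame:
    """10x dialect: matrix-market with genes as rows and spots as columns,
    alongside ``barcodes.tsv`` and ``features.tsv`` (or genes.tsv)."""
    from scipy.io import mmread

    d = mtx_path.parent
    mat = np.asarray(mmread(str(mtx_path)).todense(), dtype=np.float64)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    feat_path = d / "features.tsv"
    if not feat_path.exists():
        feat_path = d / "genes.tsv"
    genes = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes imply {(len(genes), len(barcodes))}"
        )
    return pd.DataFrame(mat.T, index=barcodes, columns=genes)


def load_image(path) -> Optional[np.ndarray]:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 array; None on failure."""
    from PIL import Image

    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # unreadable image degrades to expression-only
        logger.warning("could not read image %s (%s); continuing without image", path, exc)
        return None


def load_spot_dataset(
    expr_path,
    coords_path,
    image_path=None,
    platform: str = "other",
    labels_path=None,
    slice_id: str = "slice0",
) -> SpotDataset:
    """Load a slice from disk, aligning expression and coordinate rows by spot id.

    Raises ``KeyError`` naming the first spot id missing from the coordinate
    table. An unreadable image yields a dataset without image plus a logged
    warning.
    """
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        expr = _read_sparse_expression(expr_path)
    else:
        expr = _read_dense_expression(expr_path)
    expr.index = expr.index.astype(str)

    coords = pd.read_csv(coords_path)
    if "spot_id" not in coords.columns:
        raise ValueError("coords file must have columns spot_id, x, y")
    coords = coords.set_index(coords["spot_id"].astype(str))

    missing = [s for s in expr.index if s not in coords.index]
    if missing:
        raise KeyError(f"spot id {missing[0]!r} present in expression but missing from coords")
    coords = coords.loc[expr.index]

    image = load_image(image_path) if image_path is not None else None

    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        lab = lab.set_index(lab["spot_id"].astype(str))
        labels = lab.loc[expr.index, "label"].to_numpy()

    return SpotDataset(
        expression=expr.to_numpy(dtype=np.float64),
        coords=coords[["x", "y"]].to_numpy(dtype=np.float64),
        spot_ids=expr.index.tolist(),
        gene_ids=[str(g) for g in expr.columns],
        image=image,
        labels=labels,
        slice_id=slice_id,
        platform=platform,
    )


def save_spot_dataset(ds: SpotDataset, outdir, image_format: str = "png") -> dict:
    """Write a dataset in the dense dialect; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    expr = pd.DataFrame(ds.expression, index=ds.spot_ids, columns=ds.gene_ids)
    paths["expression"] = outdir / "expression.csv"
    expr.to_csv(paths["expression"], index_label="spot_id")
    coords = pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    )
    paths["coords"] = outdir / "coords.csv"
    coords.to_csv(paths["coords"], index=False)
    if ds.image is not None:
        from PIL import Image

        paths["image"] = outdir / f"image.{image_format}"
        Image.fromarray(np.asarray(ds.image, dtype=np.uint8)).save(paths["image"])
    if ds.labels is not None:
        paths["labels"] = outdir / "labels.csv"
        pd.DataFrame({"spot_id": ds.spot_ids, "label": ds.labels}).to_csv(
            paths["labels"], index=False
        )
    return paths


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    ds: SpotDataset,
    n_hvg: int = 3000,
    library_size: float = 1e4,
    hvg_flavor: str = "seurat",
) -> SpotDataset:
    """HVG selection, library-size normalization and log(1 + x) transform.

    Gene selection ranks genes by normalized dispersion (Seurat flavor, as in
    scanpy) computed on a log-normalized copy; the retained raw counts are
    then scaled so each spot's row sum equals ``library_size`` (all-zero rows
    stay zero) and log-transformed. Spot order is unchanged.
    """
    import scanpy as sc
    from anndata import AnnData

    if np.any(ds.expression < 0):
        raise ValueError("expression must be non-negative before preprocessing")

    X = ds.expression
    gene_ids = list(ds.gene_ids)
    if n_hvg < X.shape[1]:
        ad = AnnData(
            X.copy(), obs=pd.DataFrame(index=[str(s) for s in ds.spot_ids]),
            var=pd.DataFrame(index=pd.Index([str(g) for g in gene_ids]).astype(str)),
        )
        sc.pp.normalize_total(ad, target_sum=library_size)
        sc.pp.log1p(ad)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(ad, n_top_genes=n_hvg, flavor=hvg_flavor)
        keep = np.where(ad.var["highly_variable"].to_numpy())[0]
        # scanpy may return slightly more/fewer at dispersion ties; enforce n_hvg
        if keep.size > n_hvg:
            order = np.argsort(-ad.var["dispersions_norm"].to_numpy()[keep], kind="stable")
            keep = np.sort(keep[order[:n_hvg]])
        X = X[:, keep]
        gene_ids = [gene_ids[i] for i in keep]
    elif n_hvg > X.shape[1]:
        logger.warning(
            "n_hvg=%d exceeds gene count %d; keeping all genes", n_hvg, X.shape[1]
        )

    row_sums = X.sum(axis=1, keepdims=True)
    scale = np.divide(library_size, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    X = np.log1p(X * scale)

    out = ds.copy()
    out.expression = X
    out.gene_ids = gene_ids
    out.is_preprocessed = True
    return out


def hvg_indices(X: np.ndarray, n_hvg: int, library_size: float = 1e4) -> np.ndarray:
    """Indices of the top-``n_hvg`` genes by normalized dispersion (sorted)."""
    import scanpy as sc
    from anndata import AnnData

    ad = AnnData(np.asarray(X, dtype=np.float64).copy())
    sc.pp.normalize_total(ad, target_sum=library_size)
    sc.pp.log1p(ad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(ad, n_top_genes=n_hvg, flavor="seurat")
    return np.where(ad.var["highly_variable"].to_numpy())[0]


# ---------------------------------------------------------------------------
# image patches
# ---------------------------------------------------------------------------


def default_patch_size(platform: str) -> int:
    """Platform-standard patch side in pixels (spot-diameter match)."""
    return PLATFORM_PATCH_PX.get(platform, 32)


def extract_patches(ds: SpotDataset, side_px: Optional[int] = None) -> PatchSet:
    """Axis-aligned square patches centered on each spot's pixel position.

    Centers round half-up; patches overhanging the image border are
    zero-padded to full size so modalities stay synchronized.
    """
    if ds.image is None:
        raise ValueError(
            "dataset has no image; run in expression-only mode or provide an image"
        )
    if side_px is None:
        side_px = default_patch_size(ds.platform)
    if side_px < 1:
        raise ValueError("side_px must be >= 1")

    img = np.asarray(ds.image, dtype=np.float64)
    H, W = img.shape[:2]
    half = side_px // 2
    n = ds.n_spots
    patches = np.zeros((n, side_px, side_px, 3), dtype=np.float64)
    for i in range(n):
        cx = int(np.floor(ds.coords[i, 0] + 0.5))
        cy = int(np.floor(ds.coords[i, 1] + 0.5))
        y0, x0 = cy - half, cx - half
        y1, x1 = y0 + side_px, x0 + side_px
        sy0, sx0 = max(y0, 0), max(x0, 0)
        sy1, sx1 = min(y1, H), min(x1, W)
        if sy1 > sy0 and sx1 > sx0:
            patches[i, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    return PatchSet(patches=patches, side_px=side_px, centers=ds.coords.copy())


def load_dataset_dir(path, platform: str = "other", slice_id: Optional[str] = None) -> SpotDataset:
    """Load a dataset directory written by :func:`save_spot_dataset` (or the
    equivalent layout: expression.csv|matrix.mtx, coords.csv, optional
    image.png/tif and labels.csv)."""
    d = Path(path)
    expr = d / "expression.csv"
    if not expr.exists():
        expr = d / "matrix.mtx"
    if not expr.exists():
        raise FileNotFoundError(f"no expression.csv or matrix.mtx under {d}")
    image = None
    for name in ("image.png", "image.tif", "image.tiff"):
        if (d / name).exists():
            image = d / name
            break
    labels = (d / "labels.csv") if (d / "labels.csv").exists() else None
    return load_spot_dataset(
        expr,
        d / "coords.csv",
        image_path=image,
        platform=platform,
        labels_path=labels,
        slice_id=slice_id or d.name,
    )


def impute_nan_rows(X: np.ndarray) -> np.ndarray:
    """Replace NaN entries with their row mean (zeros for all-NaN rows)."""
    from .augment import impute_row_mean

    return impute_row_mean(X)
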