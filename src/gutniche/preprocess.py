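"""QC filtering, normalization, HVG selection, PCA and density clustering.

The clustering path mirrors the standard droplet scRNA-seq workflow:
keep genes detected in >= 3 cells and cells with enough detected genes
(100 for stomach, 150 for intestine), CPM-normalize and log-transform,
select ~2000 highly variable genes by binned dispersion, project onto
principal components chosen by an elbow (plateau) rule on the component
standard deviations, embed in 2-D with t-SNE and cluster the embedding
by density (DBSCAN), assigning residual noise points to their nearest
clustered neighbour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .io import CellLabels, CountMatrix, ExprMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "FilterError",
    "filter_counts",
    "normalize_cpm_log",
    "select_hvg",
    "pca_elbow",
    "embed_and_cluster",
]


class FilterError(ValueError):
    """Raised when QC filtering leaves an empty matrix."""


class ClusteringError(RuntimeError):
    """Raised when density clustering marks every point as noise."""


@dataclass
class QCParams:
    """Quality-control and clustering parameters.

    ``min_genes_per_cell`` defaults to 100; use 150 for intestinal data
    (`for_tissue` builds tissue defaults). ``elbow_tol`` is the relative
    drop in component standard deviation below which the PC curve is
    considered to have reached its plateau.
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 100
    n_hvg: int = 2000
    pca_max: int = 50
    elbow_tol: float = 0.005
    cluster_eps: float = 2.5
    cluster_min_pts: int = 10
    tsne_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.elbow_tol < 1):
            raise ValidationError("elbow_tol must lie in (0, 1)")
        for name in (
            "min_cells_per_gene",
            "min_genes_per_cell",
            "n_hvg",
            "pca_max",
            "cluster_min_pts",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def for_tissue(cls, tissue: str, **overrides) -> "QCParams":
        defaults = {"intestine": 150, "stomach": 100}
        overrides.setdefault("min_genes_per_cell", defaults.get(tissue, 100))
        return cls(**overrides)


def filter_counts(counts: CountMatrix, params: QCParams) -> CountMatrix:
    """Single-pass QC: genes detected in >= min_cells_per_gene cells first,
    then cells detecting >= min_genes_per_cell of the retained genes."""
    X = sp.csr_matrix(counts.counts)
    detected = (X > 0).astype(np.int64)
    gene_keep = np.asarray(detected.sum(axis=1)).ravel() >= params.min_cells_per_gene
    X2 = X[gene_keep]
    cell_keep = (
        np.asarray((X2 > 0).sum(axis=0)).ravel() >= params.min_genes_per_cell
    )
    if not gene_keep.any() or not cell_keep.any():
        raise FilterError(
            f"all filtered: {int(gene_keep.sum())} genes and "
            f"{int(cell_keep.sum())} cells survive "
            f"(thresholds {params.min_cells_per_gene} cells/gene, "
            f"{params.min_genes_per_cell} genes/cell)"
        )
    return CountMatrix(
        gene_ids=[g for g, k in zip(counts.gene_ids, gene_keep) if k],
        cell_ids=[c for c, k in zip(counts.cell_ids, cell_keep) if k],
        counts=X2[:, cell_keep],
        tissue=[t for t, k in zip(counts.tissue, cell_keep) if k],
    )


def normalize_cpm_log(counts: CountMatrix) -> dict[str, ExprMatrix]:
    """CPM and ln(1 + CPM) layers from filtered counts.

    Returns ``{"cpm": ..., "log_cpm": ...}``; the z-scored layer is
    produced later, on the HVG subset, by :func:`scale_genes`.
    """
    X = counts.dense().astype(float)
    totals = X.sum(axis=0)
    if np.any(totals == 0):
        raise ValidationError("cell with zero total counts; run filter_counts first")
    cpm = X / totals * 1e6
    log_cpm = np.log1p(cpm)
    mk = lambda v, layer: ExprMatrix(
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        values=v,
        layer=layer,
    )
    return {"cpm": mk(cpm, "cpm"), "log_cpm": mk(log_cpm, "log_cpm")}


def scale_genes(expr_log: ExprMatrix, genes: list[str]) -> ExprMatrix:
    """Per-gene z-score of the log layer restricted to *genes*."""
    idx = [expr_log.gene_ids.index(g) for g in genes]
    V = expr_log.values[idx]
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return ExprMatrix(
        gene_ids=list(genes),
        cell_ids=list(expr_log.cell_ids),
        values=(V - mu) / sd,
        layer="scaled",
    )


def select_hvg(expr_log: ExprMatrix, n_hvg: int = 2000, n_bins: int = 20) -> list[str]:
    """Highly variable genes by binned dispersion.

    Genes are split into ``n_bins`` equal-count bins of mean log
    expression; within each bin the dispersion (variance/mean) is
    z-scored, and the top ``n_hvg`` genes by that z are returned (ties
    broken by gene id).
    """
    V = expr_log.values
    mean = V.mean(axis=1)
    var = V.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum((np.arange(len(mean)) * n_bins) // len(mean), n_bins - 1)
    z = np.zeros(len(mean))
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        d = disp[m]
        sd = d.std(ddof=0)
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    if n_hvg >= len(expr_log.gene_ids):
        warnings.warn(
            f"n_hvg={n_hvg} >= {len(expr_log.gene_ids)} genes; returning all genes"
        )
        return list(expr_log.gene_ids)
    # sort by z descending, ties by gene id ascending
    keyed = sorted(zip(-z, expr_log.gene_ids))
    return [g for _, g in keyed[:n_hvg]]


def pca_elbow(
    scaled: ExprMatrix, pca_max: int = 50, elbow_tol: float = 0.005, seed: int = 0
) -> tuple[np.ndarray, int]:
    """PCA over cells with an elbow rule on component standard deviations.

    Components are kept up to the onset of the plateau: the smallest
    ``i`` (1-based) such that every later drop ``(sd_j - sd_{j+1}) /
    sd_1`` for ``j >= i`` stays below ``elbow_tol``. A curve that keeps
    falling by more than ``elbow_tol`` yields ``pca_max`` components;
    isotropic noise (flat curve) yields 1. Returns (cells x n_pcs
    scores, n_pcs).
    """
    X = scaled.values.T  # cells x genes
    limit = min(pca_max, min(X.shape) - 1) if min(X.shape) > 1 else 1
    if limit < pca_max:
        warnings.warn(f"pca_max={pca_max} clipped to {limit} by data dimensions")
    pca = PCA(n_components=limit, svd_solver="auto", random_state=seed)
    scores = pca.fit_transform(X)
    sd = np.sqrt(pca.explained_variance_)
    drops = (sd[:-1] - sd[1:]) / sd[0]
    n_pcs = limit
    for i in range(1, limit):
        if np.all(drops[i - 1 :] < elbow_tol):
            n_pcs = i
            break
    return scores[:, :n_pcs], n_pcs


def embed_and_cluster(
    pc_scores: np.ndarray,
    cell_ids: list[str],
    params: QCParams,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, CellLabels]:
    """t-SNE embedding (library-backed, seeded) + DBSCAN density clustering.

    Noise points are assigned the cluster of their nearest non-noise
    neighbour; cluster ids are relabeled by decreasing size.
    """
    n = pc_scores.shape[0]
    perplexity = min(perplexity, max(2.0, (n - 1) / 3.0))
    if np.ptp(pc_scores, axis=0).max() == 0:
        # all cells identical: a single cluster at the origin
        emb = np.zeros((n, 2))
        return emb, CellLabels(cell_ids=list(cell_ids), cluster=np.zeros(n, dtype=int))
    if n > 3:
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=params.tsne_seed,
            init="pca",
        ).fit_transform(pc_scores)
    else:  # too few points for t-SNE; fall back to the first two PCs
        emb = pc_scores[:, :2].copy()
        if emb.shape[1] < 2:
            emb = np.column_stack([emb, np.zeros(n)])
    labels = DBSCAN(eps=params.cluster_eps, min_samples=params.cluster_min_pts).fit(
        emb
    ).labels_
    if (labels == -1).all():
        raise ClusteringError(
            "density clustering marked every cell as noise; try a larger cluster_eps"
        )
    noise = labels == -1
    if noise.any():
        nn = NearestNeighbors(n_neighbors=1).fit(emb[~noise])
        _, idx = nn.kneighbors(emb[noise])
        labels[noise] = labels[~noise][idx.ravel()]
        log.info("assigned %d noise cells to nearest clusters", int(noise.sum()))
    # relabel by decreasing size, stable in old label for ties
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(zip(-counts, uniq))
    remap = {old: new for new, (_, old) in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    return emb, CellLabels(cell_ids=list(cell_ids), cluster=labels)
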