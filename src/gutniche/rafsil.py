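"""Random-forest cell similarity on pooled expression profiles.

Two modifications of the RAFSIL1 scheme adapt it to sparse droplet
data: cells are pooled in seeded groups of 20 within each (type,
tissue), and the forest's input features are the union of each
cluster's top-20 marker genes rather than RAFSIL's internal feature
construction. Per repeat, a synthetic background is built by permuting
each feature column independently, a forest learns to separate real
from synthetic profiles, and similarity is the fraction of trees in
which two real samples share a terminal leaf; dissimilarity = 1 - mean
proximity over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import CellLabels, ExprMatrix

__all__ = ["PoolingParams", "SimilarityMatrix", "pool_cells", "rafsil_similarity"]


@dataclass
class PoolingParams:
    pool_size: int = 20
    min_remainder: int | None = None  # default pool_size // 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.min_remainder is None:
            self.min_remainder = self.pool_size // 2


@dataclass
class SimilarityMatrix:
    dissimilarity: np.ndarray  # samples x samples in [0, 1]
    metadata: pd.DataFrame  # sample_id, type, tissue, n_cells, cell_ids


def pool_cells(
    expr_log: ExprMatrix,
    labels: CellLabels,
    tissue: str,
    params: PoolingParams,
) -> tuple[ExprMatrix, pd.DataFrame]:
    """Average log expression over seeded pools of cells per (type, tissue).

    Cells of each type are randomly partitioned into groups of
    ``pool_size``; a remainder of at least ``min_remainder`` cells keeps
    its own pool, a smaller one is merged into the last full pool. A
    type smaller than ``min_remainder`` becomes a single pool with a
    warning.
    """
    if expr_log.cell_ids != labels.cell_ids:
        raise ValueError("expression and labels cover different cells")
    rng = np.random.default_rng(params.seed)
    profiles = []
    meta = []
    for t in labels.cluster_ids():
        idx = np.flatnonzero(labels.cluster == t)
        idx = rng.permutation(idx)
        n_full = len(idx) // params.pool_size
        groups: list[np.ndarray]
        if n_full == 0:
            if len(idx) < params.min_remainder:
                warnings.warn(
                    f"type {t} has {len(idx)} cells (< min_remainder="
                    f"{params.min_remainder}); pooled as a single group"
                )
            groups = [idx]
        else:
            groups = [
                idx[i * params.pool_size : (i + 1) * params.pool_size]
                for i in range(n_full)
            ]
            rem = idx[n_full * params.pool_size :]
            if len(rem) >= params.min_remainder:
                groups.append(rem)
            elif len(rem):
                groups[-1] = np.concatenate([groups[-1], rem])
        for gi, g in enumerate(groups):
            profiles.append(expr_log.values[:, g].mean(axis=1))
            meta.append(
                {
                    "sample_id": f"{tissue}_t{t}_p{gi}",
                    "type": t,
                    "tissue": tissue,
                    "n_cells": len(g),
                    "cell_ids": ",".join(expr_log.cell_ids[i] for i in g),
                }
            )
    meta_df = pd.DataFrame(meta)
    pooled = ExprMatrix(
        gene_ids=list(expr_log.gene_ids),
        cell_ids=meta_df["sample_id"].tolist(),
        values=np.column_stack(profiles),
        layer="log_cpm",
    )
    return pooled, meta_df


def rafsil_similarity(
    pooled: ExprMatrix,
    metadata: pd.DataFrame,
    feature_genes: list[str],
    n_repeats: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> SimilarityMatrix:
    """Unsupervised-forest dissimilarity between pooled samples.

    ``feature_genes`` is typically the union of every cluster's top-20
    markers from both tissues.
    """
    feats = [g for g in feature_genes if g in set(pooled.gene_ids)]
    if len(feats) < 5:
        raise ValueError(f"need >= 5 features present, got {len(feats)}")
    if pooled.n_cells < 10:
        raise ValueError("need >= 10 pooled samples")
    idx = [pooled.gene_ids.index(g) for g in feats]
    X = pooled.values[idx].T  # samples x features
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features constant; forest cannot split")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    prox_sum = np.zeros((n, n))
    for rep in range(n_repeats):
        synth = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(X.shape[1])]
        )
        Xy = np.vstack([X, synth])
        y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(Xy, y)
        leaves = forest.apply(X)  # samples x trees
        prox = np.zeros((n, n))
        for tcol in range(leaves.shape[1]):
            col = leaves[:, tcol]
            prox += (col[:, None] == col[None, :]).astype(float)
        prox_sum += prox / leaves.shape[1]
    dis = 1.0 - prox_sum / n_repeats
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(dissimilarity=dis, metadata=metadata.reset_index(drop=True))
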