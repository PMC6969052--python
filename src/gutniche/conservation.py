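"""Cross-tissue cell-type matching and replicability.

Each cluster is summarized by its mean log-CPM over a shared feature
space built from the union of every cluster's top-30 markers in both
tissues. Stomach x intestine cluster pairs are compared by Spearman
correlation; pairs with rho >= 0.7 are called conserved. All clusters
of both tissues are also joined into a dendrogram (distance 1 - rho,
average linkage), and matches are validated by supervised
neighbor-voting (MetaNeighbor-style) AUROC on a Spearman cell-cell
network over highly variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import CellLabels, ExprMatrix
from .markers import top_markers

__all__ = [
    "ConservationResult",
    "AurocResult",
    "build_profiles",
    "spearman_match",
    "hcluster_profiles",
    "neighbor_voting_auroc",
    "dendrogram_newick",
]


@dataclass
class ConservationResult:
    feature_genes: list[str]
    profiles: dict[str, pd.DataFrame]  # tissue -> cluster x feature
    rho: pd.DataFrame  # stomach clusters x intestine clusters
    threshold: float
    matches: list[tuple[int, int, float]]
    linkage: np.ndarray | None = None
    leaf_names: list[str] = field(default_factory=list)


@dataclass
class AurocResult:
    """Direction-averaged neighbor-voting AUROC per cell type."""

    per_type: dict[int, float]
    one_direction_only: set[int] = field(default_factory=set)

    def mean(self) -> float:
        return float(np.mean(list(self.per_type.values())))


def build_profiles(
    expr_a: ExprMatrix,
    labels_a: CellLabels,
    expr_b: ExprMatrix,
    labels_b: CellLabels,
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    k: int = 30,
) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Cluster profiles over the union of both tissues' top-k marker genes.

    The feature space is the union of every cluster's top-k markers from
    both tissues, intersected with the genes present in both matrices,
    sorted; a profile is the mean log-CPM of a cluster's cells at each
    feature gene.
    """
    shared = set(expr_a.gene_ids) & set(expr_b.gene_ids)
    if not shared:
        raise ValueError("tissues share no gene ids")
    feats: set[str] = set()
    for table, labels in ((markers_a, labels_a), (markers_b, labels_b)):
        for c in sorted(set(table["cluster"])):
            feats.update(top_markers(table, c, k))
    feature_genes = sorted(feats & shared)
    if not feature_genes:
        raise ValueError("empty feature intersection between tissues")

    def tissue_profiles(expr: ExprMatrix, labels: CellLabels) -> pd.DataFrame:
        idx = [expr.gene_ids.index(g) for g in feature_genes]
        V = expr.values[idx]
        out = {}
        for c in labels.cluster_ids():
            out[c] = V[:, labels.cluster == c].mean(axis=1)
        return pd.DataFrame(out, index=feature_genes).T  # cluster x feature

    return feature_genes, {
        "a": tissue_profiles(expr_a, labels_a),
        "b": tissue_profiles(expr_b, labels_b),
    }


def spearman_match(
    feature_genes: list[str],
    profiles: dict[str, pd.DataFrame],
    threshold: float = 0.7,
) -> ConservationResult:
    """Spearman rho between every cross-tissue cluster pair; rho >= threshold
    is a conserved match. Constant profiles give undefined rho (NaN) and
    never match."""
    pa, pb = profiles["a"], profiles["b"]
    if len(feature_genes) < 3:
        raise ValueError("need >= 3 feature genes for rank correlation")
    rho = pd.DataFrame(index=pa.index, columns=pb.index, dtype=float)
    for ca in pa.index:
        x = pa.loc[ca].to_numpy()
        for cb in pb.index:
            y = pb.loc[cb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[ca, cb] = np.nan
                continue
            rho.loc[ca, cb] = stats.spearmanr(x, y).statistic
    matches = [
        (int(ca), int(cb), float(rho.loc[ca, cb]))
        for ca in pa.index
        for cb in pb.index
        if np.isfinite(rho.loc[ca, cb]) and rho.loc[ca, cb] >= threshold
    ]
    return ConservationResult(
        feature_genes=list(feature_genes),
        profiles=profiles,
        rho=rho,
        threshold=threshold,
        matches=matches,
    )


def hcluster_profiles(result: ConservationResult) -> ConservationResult:
    """Average-linkage dendrogram over all clusters of both tissues with
    distance 1 - Spearman rho. Leaves are named ``stomach_<c>`` /
    ``intestine_<c>``; ties break deterministically by label order."""
    pa, pb = result.profiles["a"], result.profiles["b"]
    names = [f"stomach_{c}" for c in pa.index] + [f"intestine_{c}" for c in pb.index]
    M = np.vstack([pa.to_numpy(), pb.to_numpy()])
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(M[i]) == 0 or np.ptp(M[j]) == 0:
                d = 1.0
            else:
                d = 1.0 - stats.spearmanr(M[i], M[j]).statistic
            D[i, j] = D[j, i] = max(d, 0.0)
    cond = D[np.triu_indices(n, k=1)]
    result.linkage = hierarchy.linkage(cond, method="average")
    result.leaf_names = names
    return result


def dendrogram_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def _rank_standardize_rows(net: np.ndarray) -> np.ndarray:
    """Rank each row and scale to [0, 1] (average ranks for ties)."""
    out = np.empty_like(net)
    n = net.shape[1]
    for i in range(net.shape[0]):
        out[i] = stats.rankdata(net[i]) / n
    return out


def build_voting_network(
    expr_a: ExprMatrix, expr_b: ExprMatrix, hvg_genes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Combined-cell Spearman network over HVGs, rows rank-scaled to [0,1].

    Returns (network, side) where ``side`` is False for tissue-A cells
    and True for tissue-B cells. The network is label-free, so the same
    matrix scores any labelling (including permutation nulls).
    """
    genes = [g for g in hvg_genes if g in set(expr_a.gene_ids) & set(expr_b.gene_ids)]
    if len(genes) < 2:
        raise ValueError("need >= 2 shared HVGs")
    ia = [expr_a.gene_ids.index(g) for g in genes]
    ib = [expr_b.gene_ids.index(g) for g in genes]
    X = np.hstack([expr_a.values[ia], expr_b.values[ib]])  # genes x cells
    side = np.concatenate(
        [np.zeros(expr_a.n_cells, dtype=bool), np.ones(expr_b.n_cells, dtype=bool)]
    )
    # Spearman between cells = Pearson of per-cell gene ranks
    R = np.apply_along_axis(stats.rankdata, 0, X)
    R -= R.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(R, axis=0)
    norms[norms == 0] = 1.0
    R /= norms
    net = (R.T @ R).astype(np.float64)
    return _rank_standardize_rows(net), side


def auroc_from_network(
    net: np.ndarray, side: np.ndarray, labels: np.ndarray
) -> AurocResult:
    """Score a labelling on a prebuilt voting network.

    For each type, one tissue's labels are hidden; hidden cells receive
    votes from the visible cells of that type, normalized by their total
    connectivity to visible cells, and the AUROC of the votes for the
    truly positive hidden cells is recorded. The two hide-directions are
    averaged; a type present in only one tissue is reported for the
    computable direction and flagged.
    """
    labels = np.asarray(labels)
    types = sorted(set(labels.tolist()))
    per_type: dict[int, list[float]] = {}
    flagged: set[int] = set()
    for hidden_side in (False, True):
        hidden = side == hidden_side
        visible = ~hidden
        block = net[np.ix_(hidden, visible)]
        degree = block.sum(axis=1)
        indicator = np.column_stack(
            [(labels[visible] == t).astype(float) for t in types]
        )
        votes = (block @ indicator) / degree[:, None]
        for k, t in enumerate(types):
            if indicator[:, k].sum() == 0:
                continue
            truth = labels[hidden] == t
            if not truth.any():
                continue
            per_type.setdefault(t, []).append(_auroc(votes[:, k], truth))
    for t, v in per_type.items():
        if len(v) == 1:
            flagged.add(t)
    return AurocResult(
        per_type={t: float(np.mean(v)) for t, v in per_type.items()},
        one_direction_only=flagged,
    )


def neighbor_voting_auroc(
    expr_a: ExprMatrix,
    labels_a: np.ndarray,
    expr_b: ExprMatrix,
    labels_b: np.ndarray,
    hvg_genes: list[str],
) -> AurocResult:
    """Supervised neighbor-voting replicability AUROC per cell type.

    Cells of both tissues are combined; the network is the cell x cell
    Spearman correlation over the HVGs, each row rank-standardized to
    [0, 1]; labels are then scored by :func:`auroc_from_network`.
    """
    net, side = build_voting_network(expr_a, expr_b, hvg_genes)
    labels = np.concatenate([np.asarray(labels_a), np.asarray(labels_b)])
    return auroc_from_network(net, side, labels)


def _auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney form, ties by average rank)."""
    r = stats.rankdata(scores)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((r[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
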