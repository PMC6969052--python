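"""Gene-set enrichment, over-representation and disease-gene z-scores.

Three procedures feed the cross-tissue biology:

* GSEA-style enrichment contrasting conserved vs distinct cluster
  groups, ranking genes by signal-to-noise over cluster-average
  profiles and scoring sets with the classic weighted running-sum
  statistic; significance by gene-set permutation (the sample axis
  here is a handful of cluster averages, too few to permute).
* Hypergeometric over-representation (KEGG-style) with BH correction.
* The disease-gene procedure: z-score each gene across all cells,
  average z within clusters, keep genes with any cluster mean z above
  1.65 (one-sided 5% of a standard normal), and cluster the retained
  genes' cluster-z rows (Euclidean, complete linkage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import CellLabels, DiseaseGeneTable, ExprMatrix, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "DiseaseZResult",
    "rank_genes_s2n",
    "gsea_es",
    "gsea_significance",
    "ora_hypergeometric",
    "disease_z",
]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: es, nes, p_perm, fdr_q
    n_perm: int


@dataclass
class DiseaseZResult:
    cluster_z: pd.DataFrame  # analyzed genes x clusters, mean z per cluster
    retained: pd.DataFrame  # subset with max cluster z > threshold
    threshold: float
    linkage: np.ndarray | None = None  # dendrogram over the retained genes
    excluded: list[str] = field(default_factory=list)

    def trait_view(self, table: DiseaseGeneTable, trait: str,
                   retained_only: bool = False) -> pd.DataFrame:
        source = self.retained if retained_only else self.cluster_z
        genes = [g for g in table.genes_for(trait) if g in source.index]
        return source.loc[genes]

    def rank_clusters(self, table: DiseaseGeneTable, trait: str) -> pd.Series:
        """Clusters ordered by mean z over the trait's genes, best first."""
        view = self.trait_view(table, trait)
        return view.mean(axis=0).sort_values(ascending=False)


def rank_genes_s2n(
    cluster_profiles: pd.DataFrame, group_labels: dict[int | str, str]
) -> pd.Series:
    """Signal-to-noise ranking of genes, conserved vs distinct clusters.

    ``cluster_profiles`` is cluster x gene (cluster averages as the
    "samples"); ``group_labels`` maps each cluster to "conserved" or
    "distinct". Score = (mu_c - mu_d) / (s_c + s_d) with each group sd
    floored at max(0.2 * |mu|, 1e-6). Returned sorted decreasing.
    """
    groups = {g: [c for c, lab in group_labels.items() if lab == g] for g in
              ("conserved", "distinct")}
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(
                f"group {g!r} has {len(members)} cluster(s); signal-to-noise "
                "needs >= 2 per group — use gene-set permutation mode only"
            )
    Pc = cluster_profiles.loc[groups["conserved"]].to_numpy()
    Pd = cluster_profiles.loc[groups["distinct"]].to_numpy()

    def floored_sd(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = P.mean(axis=0)
        sd = P.std(axis=0, ddof=1)
        return mu, np.maximum(sd, np.maximum(0.2 * np.abs(mu), 1e-6))

    mu_c, s_c = floored_sd(Pc)
    mu_d, s_d = floored_sd(Pd)
    score = (mu_c - mu_d) / (s_c + s_d)
    out = pd.Series(score, index=cluster_profiles.columns)
    return out.sort_values(ascending=False, kind="stable")


def gsea_es(ranked_scores: pd.Series, gene_set: list[str] | set[str], p: float = 1.0) -> float:
    """Classic weighted Kolmogorov-Smirnov enrichment score.

    ``ranked_scores`` must be sorted decreasing. Hits advance the
    running sum by |score|^p / sum_hits |score|^p; misses retreat by
    1/(N - n_hits); ES is the extremum of the running sum.
    """
    genes = ranked_scores.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranking")
    N = len(genes)
    if k == N:
        return 1.0
    w = np.abs(ranked_scores.to_numpy()) ** p
    hw = np.where(in_set, w, 0.0)
    nr = hw.sum()
    if nr == 0:  # all hit scores zero: fall back to equal hit weights
        hw = in_set.astype(float)
        nr = float(k)
    run = np.cumsum(np.where(in_set, hw / nr, -1.0 / (N - k)))
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea_significance(
    ranked_scores: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Gene-set-permutation significance and NES-based FDR.

    For every set the null is the ES of size-matched random gene sets
    drawn from the ranking; NES divides ES by the mean |null ES| of the
    same sign, p = (1 + #{null at least as extreme, same sign}) /
    (n_perm + 1), and FDR follows the GSEA NES-ratio procedure.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    rng = np.random.default_rng(seed)
    genes = ranked_scores.index.to_numpy()
    rows = []
    null_nes_all: list[np.ndarray] = []
    for name, members in sets.sets.items():
        inter = set(members) & set(genes)
        if not inter:
            log.warning("set %s skipped: no overlap with ranking", name)
            continue
        es = gsea_es(ranked_scores, inter, p=weight_p)
        k = len(inter)
        null = np.empty(n_perm)
        for i in range(n_perm):
            rand = rng.choice(genes, size=k, replace=False)
            null[i] = gsea_es(ranked_scores, rand, p=weight_p)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        null_nes = np.zeros_like(null)
        pos, neg = null > 0, null < 0
        if pos.any():
            null_nes[pos] = null[pos] / np.abs(null[pos]).mean()
        if neg.any():
            null_nes[neg] = null[neg] / np.abs(null[neg]).mean()
        p_perm = (1 + int((np.abs(null) >= abs(es)).sum())) / (n_perm + 1)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p_perm": p_perm})
        null_nes_all.append(null_nes)
    table = pd.DataFrame(rows)
    if not table.empty:
        pooled = np.concatenate(null_nes_all)
        qs = []
        for nes in table["nes"]:
            if nes >= 0:
                num = (pooled >= nes).mean() / max((pooled >= 0).mean(), 1e-12)
                den = (table["nes"] >= nes).mean() / max(
                    (table["nes"] >= 0).mean(), 1e-12
                )
            else:
                num = (pooled <= nes).mean() / max((pooled <= 0).mean(), 1e-12)
                den = (table["nes"] <= nes).mean() / max(
                    (table["nes"] <= 0).mean(), 1e-12
                )
            qs.append(min(1.0, num / max(den, 1e-12)))
        table["fdr_q"] = qs
    return EnrichmentResult(table=table, n_perm=n_perm)


def ora_hypergeometric(
    query_genes: list[str] | set[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH correction.

    p = P(X >= overlap) drawing |query| genes from a universe of N genes
    of which |set & universe| are in the set.
    """
    uni = set(universe)
    query = set(query_genes)
    off = sorted(query - uni)
    if off:
        raise ValueError(f"query genes outside universe: {off}")
    N, n = len(uni), len(query)
    rows = []
    for name, members in sets.sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def disease_z(
    expr_log: ExprMatrix,
    labels: CellLabels,
    disease_table: DiseaseGeneTable | None = None,
    z_threshold: float = 1.65,
) -> DiseaseZResult:
    """Cluster-mean z-scores of gene expression, thresholded at z > 1.65.

    Each gene's log-CPM is z-scored across all cells; cluster means of
    those z-scores form the gene x cluster matrix (restricted to the
    disease table's genes when one is given). Genes whose maximum
    cluster mean z exceeds the threshold form the ``retained`` subset —
    the cluster-enriched genes kept for plotting — and are clustered by
    Euclidean complete linkage over their cluster-z rows. Trait-level
    cluster ranking uses the full matrix via ``rank_clusters``.
    Zero-variance genes are excluded with a log entry.
    """
    if expr_log.cell_ids != labels.cell_ids:
        raise ValueError("expression and labels cover different cells")
    genes = list(expr_log.gene_ids)
    if disease_table is not None:
        wanted = set(disease_table.rows["gene"])
        genes = [g for g in genes if g in wanted]
    idx = [expr_log.gene_ids.index(g) for g in genes]
    V = expr_log.values[idx]
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=0, keepdims=True)
    constant = sd.ravel() == 0
    excluded = [g for g, c in zip(genes, constant) if c]
    for g in excluded:
        log.info("disease_z: gene %s has zero variance; excluded", g)
    keep = ~constant
    Z = (V[keep] - mu[keep]) / sd[keep]
    kept_genes = [g for g, k in zip(genes, keep) if k]
    clusters = labels.cluster_ids()
    cz = pd.DataFrame(
        {c: Z[:, labels.cluster == c].mean(axis=1) for c in clusters},
        index=kept_genes,
    )
    retained = cz[cz.max(axis=1) > z_threshold]
    linkage = None
    if len(retained) >= 2:
        linkage = hierarchy.linkage(retained.to_numpy(), method="complete",
                                    metric="euclidean")
    return DiseaseZResult(
        cluster_z=cz, retained=retained, threshold=z_threshold,
        linkage=linkage, excluded=excluded,
    )
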