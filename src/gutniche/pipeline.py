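"""End-to-end orchestration of the cross-tissue stromal analysis.

``run_pipeline`` executes the stages in dependency order on synthetic
two-tissue data — simulate, QC + clustering per tissue, markers,
cross-tissue conservation, imputation + co-expression, disease-gene
z-scores, forest similarity, and the region comparison — writing each
stage's outputs and a manifest (parameters, seed, input hashes) under
the run directory. Reruns with an identical config are bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import conservation as cons
from . import enrichment, imputation, markers, preprocess, rafsil, regions
from .io import write_counts, write_expr
from .simulate import (
    SimConfig,
    simulate_disease_table,
    simulate_region_signals,
    simulate_two_tissue,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed by stable name hashing."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Unknown keys passed to :meth:`from_dict` are rejected so that typos
    in a config file fail loudly.
    """

    seed: int = 1
    out_dir: str = "run"
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    conservation_threshold: float = 0.7
    top_k_conservation: int = 30
    top_k_similarity: int = 20
    imputation: dict = field(default_factory=dict)
    pool: dict = field(default_factory=dict)
    region_sim: dict = field(
        default_factory=lambda: {"n_common": 500, "n_specific_per_tissue": (8, 8)}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _manifest(path: Path, stage: str, seed: int, params: dict, inputs: dict[str, Path]) -> None:
    doc = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for name, p in inputs.items()
            if Path(p).is_file()
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data; returns the summary metrics dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- simulate -----------------------------------------------------
    sim_cfg = SimConfig(**{"seed": stage_seed(config.seed, "simulate"), **config.sim})
    cm_a, cm_b, truth = simulate_two_tissue(sim_cfg)
    for cm, name in ((cm_a, "stomach"), (cm_b, "intestine")):
        write_counts(cm, out / f"counts_{name}", format="mtx_triplet")
    _manifest(out / "manifest_simulate.yaml", "simulate", sim_cfg.seed,
              asdict(sim_cfg), {})

    # --- per-tissue preprocess + clustering ---------------------------
    expr = {}
    labels_pred = {}
    truth_labels = {}
    for cm, tissue in ((cm_a, "stomach"), (cm_b, "intestine")):
        params = preprocess.QCParams.for_tissue(
            tissue, tsne_seed=stage_seed(config.seed, f"tsne_{tissue}"), **config.qc
        )
        filt = preprocess.filter_counts(cm, params)
        layers = preprocess.normalize_cpm_log(filt)
        hvg = preprocess.select_hvg(layers["log_cpm"], params.n_hvg)
        scaled = preprocess.scale_genes(layers["log_cpm"], hvg)
        scores, n_pcs = preprocess.pca_elbow(scaled, params.pca_max, params.elbow_tol)
        emb, lab = preprocess.embed_and_cluster(scores, filt.cell_ids, params)
        keep = [cm.cell_ids.index(c) for c in filt.cell_ids]
        truth_labels[tissue] = truth.cell_type[tissue][keep]
        expr[tissue] = layers["log_cpm"]
        labels_pred[tissue] = lab
        write_expr(layers["log_cpm"], out / f"logcpm_{tissue}.tsv")
        pd.DataFrame(
            {"cell_id": lab.cell_ids, "cluster": lab.cluster,
             "truth": truth_labels[tissue]}
        ).to_csv(out / f"labels_{tissue}.tsv", sep="\t", index=False)
        summary[f"ari_{tissue}"] = float(
            adjusted_rand_score(truth_labels[tissue], lab.cluster)
        )
        summary[f"n_pcs_{tissue}"] = n_pcs
        _manifest(
            out / f"manifest_preprocess_{tissue}.yaml", f"preprocess_{tissue}",
            params.tsne_seed, asdict(params),
            {"counts": out / f"counts_{tissue}" / "matrix.mtx"},
        )

    # --- markers + conservation on true type labels -------------------
    from .io import CellLabels

    lab_true = {
        t: CellLabels(cell_ids=expr[t].cell_ids, cluster=truth_labels[t])
        for t in ("stomach", "intestine")
    }
    mk = {t: markers.marker_table(expr[t], lab_true[t]) for t in expr}
    feature_genes, profiles = cons.build_profiles(
        expr["stomach"], lab_true["stomach"], expr["intestine"], lab_true["intestine"],
        mk["stomach"], mk["intestine"], k=config.top_k_conservation,
    )
    result = cons.spearman_match(feature_genes, profiles,
                                 threshold=config.conservation_threshold)
    result = cons.hcluster_profiles(result)
    result.rho.to_csv(out / "rho.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(
        cons.dendrogram_newick(result.linkage, result.leaf_names)
    )
    found = {(a, b) for a, b, _ in result.matches}
    true_pairs = set(truth.conserved_pairs)
    summary["conservation_precision"] = (
        len(found & true_pairs) / len(found) if found else 0.0
    )
    summary["conservation_recall"] = (
        len(found & true_pairs) / len(true_pairs) if true_pairs else 1.0
    )
    _manifest(out / "manifest_conserve.yaml", "conserve", config.seed,
              {"threshold": config.conservation_threshold,
               "k": config.top_k_conservation},
              {"rho": out / "rho.tsv"})

    # --- imputation + planted co-expression (stomach) -----------------
    ip = imputation.ImputationParams(**config.imputation)
    hvg = preprocess.select_hvg(expr["stomach"], 2000)
    scaled = preprocess.scale_genes(expr["stomach"], hvg)
    scores, _ = preprocess.pca_elbow(scaled)
    M = imputation.build_markov(scores, ip)
    imp = imputation.impute(expr["stomach"], M, ip.t_diffusion)
    target = truth.conserved_pairs[0][0]
    gx, gy = truth.markers[target][:2]
    mask, n_co = imputation.coexpression_call(imp, gx, gy)
    is_target = truth_labels["stomach"] == target
    summary["coexpression_precision"] = (
        float(is_target[mask].mean()) if mask.any() else 0.0
    )
    _manifest(out / "manifest_impute.yaml", "impute", config.seed, asdict(ip), {})

    # --- disease-gene z-scores ----------------------------------------
    dt = simulate_disease_table(
        truth, target_type=target,
        n_genes_from_markers=min(15, len(truth.markers[target])),
        n_background=5, all_genes=expr["stomach"].gene_ids,
        seed=stage_seed(config.seed, "disease"),
    )
    dz = enrichment.disease_z(expr["stomach"], lab_true["stomach"], dt)
    view = dz.trait_view(dt, "planted_trait")
    summary["disease_top_cluster"] = (
        int(view.mean(axis=0).idxmax()) if not view.empty else -1
    )
    summary["disease_target_cluster"] = int(target)

    # --- forest similarity --------------------------------------------
    pool_params = rafsil.PoolingParams(
        seed=stage_seed(config.seed, "pool"), **config.pool
    )
    pooled_parts = [
        rafsil.pool_cells(expr[t], lab_true[t], t, pool_params)
        for t in ("stomach", "intestine")
    ]
    feats = sorted(
        {
            g
            for t in expr
            for c in lab_true[t].cluster_ids()
            for g in markers.top_markers(mk[t], c, config.top_k_similarity)
        }
    )
    from .io import ExprMatrix

    pooled = ExprMatrix(
        gene_ids=list(expr["stomach"].gene_ids),
        cell_ids=[cid for p, _ in pooled_parts for cid in p.cell_ids],
        values=np.hstack([p.values for p, _ in pooled_parts]),
        layer="log_cpm",
    )
    meta = pd.concat([m for _, m in pooled_parts], ignore_index=True)
    sim_mat = rafsil.rafsil_similarity(
        pooled, meta, feats, seed=stage_seed(config.seed, "rafsil")
    )
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(sim_mat.dissimilarity, checks=False),
                          method="average")
    n_types = meta["type"].nunique()
    pred = hierarchy.fcluster(Z, t=n_types, criterion="maxclust")
    summary["rafsil_ari"] = float(adjusted_rand_score(meta["type"], pred))

    # --- region comparison --------------------------------------------
    rs, st, rtruth = simulate_region_signals(
        seed=stage_seed(config.seed, "regions"), **config.region_sim
    )
    comp = regions.ma_classify(rs, st)
    merged = comp.join(rtruth.region_class.set_index("region_id"))
    summary["region_errors"] = int((merged["class"] != merged["true_class"]).sum())
    comp.to_csv(out / "region_comparison.tsv", sep="\t")

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
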