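"""Synthetic two-tissue single-cell data with known ground truth.

The generator emulates the statistical structure of droplet scRNA-seq
DGE matrices from two tissues (stomach and intestine) that share a core
of conserved stromal cell types alongside tissue-specific ones:

* baseline gene abundances are log-normal across genes;
* each cell type is a *global expression program*: a mean-one log-normal
  modulation of every gene's abundance, as distinct cell lineages differ
  transcriptome-wide rather than at a handful of genes;
* on top of its program, each type carries a planted marker block — a
  disjoint set of genes whose expected expression is further multiplied
  by ``marker_fold``, the guaranteed-fold genes that marker selection
  should find;
* shared types use the *same* program, marker block and fold in both
  tissues, which is exactly the conserved transcriptome signature that
  downstream cross-tissue matching must recover;
* per-cell library sizes are log-normal (heavy-tailed droplet depth);
* counts are negative-binomial (Gamma-Poisson) with a fixed dispersion,
  optionally thinned by a logistic-in-log-mean Bernoulli dropout.

Companion generators produce paired-tissue genomic region signal tables
with planted common/tissue-specific regions, and a trait->gene table
whose trait genes are drawn from a chosen type's markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix, DiseaseGeneTable, RegionSet, SignalTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_two_tissue",
    "simulate_region_signals",
    "simulate_disease_table",
    "write_manifest",
]


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the two-tissue count simulation.

    Defaults define the package's reference study conditions: 8 shared
    types plus 3 stomach- and 2 intestine-specific types, 300 cells per
    type, 30 markers per type at 8-fold enrichment, 2000 genes, mean
    depth 2000 UMIs, NB dispersion 0.3.
    """

    n_genes: int = 2000
    shared_types: int = 8
    specific_types_per_tissue: tuple[int, int] = (3, 2)
    cells_per_type: int = 300
    markers_per_type: int = 30
    marker_fold: float = 8.0
    baseline_sigma: float = 0.5
    type_effect_sigma: float = 0.5
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.35
    nb_dispersion: float = 0.3
    coexpr_pair_background: float = 0.05  # expected UMI/cell outside the type
    coexpr_pair_expressed: float = 4.0  # expected UMI/cell in the type
    dropout_midpoint: float | None = None  # None disables dropout
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_programs = self.shared_types + sum(self.specific_types_per_tissue)
        # marker blocks plus the two dedicated co-expression pair genes
        if self.markers_per_type * n_programs + 2 > self.n_genes:
            raise ConfigError(
                f"{n_programs} marker programs x {self.markers_per_type} markers "
                f"(+2 pair genes) exceed {self.n_genes} genes"
            )
        for name in ("n_genes", "cells_per_type", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.marker_fold <= 1:
            raise ConfigError("marker_fold must exceed 1")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ConfigError("library_size_mean and nb_dispersion must be positive")


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``cell_type`` maps tissue -> per-cell global program id. Shared
    programs are numbered 0..shared_types-1 in both tissues, so the
    conserved pairs are ``(i, i)`` for shared program ids; specific
    programs get ids beyond that range, distinct between tissues.
    """

    cell_type: dict[str, np.ndarray] = field(default_factory=dict)
    conserved_pairs: list[tuple[int, int]] = field(default_factory=list)
    markers: dict[int, list[str]] = field(default_factory=dict)
    coexpr_pair: tuple[str, str] | None = None  # co-expressed only in coexpr_type
    coexpr_type: int | None = None
    region_class: pd.DataFrame | None = None  # region_id, true_class

    def types_in(self, tissue: str) -> list[int]:
        return sorted(set(self.cell_type[tissue].tolist()))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _simulate_tissue(
    rng: np.random.Generator,
    cfg: SimConfig,
    baseline: np.ndarray,
    program_ids: list[int],
    marker_idx: dict[int, np.ndarray],
    modulation: dict[int, np.ndarray],
    tissue: str,
    gene_ids: list[str],
) -> tuple[CountMatrix, np.ndarray]:
    n_cells = cfg.cells_per_type * len(program_ids)
    counts = np.empty((cfg.n_genes, n_cells), dtype=np.int64)
    cell_type = np.empty(n_cells, dtype=int)
    # mean depth library_size_mean with log-normal spread
    mu_log = np.log(cfg.library_size_mean) - cfg.library_size_sigma**2 / 2
    col = 0
    for t in program_ids:
        p = baseline * modulation[t]
        p[marker_idx[t]] *= cfg.marker_fold
        for _ in range(cfg.cells_per_type):
            lib = rng.lognormal(mu_log, cfg.library_size_sigma)
            mean = lib * p
            c = _nb_counts(rng, mean, cfg.nb_dispersion)
            if cfg.dropout_midpoint is not None:
                # logistic keep-probability in log gene mean
                keep_p = 1.0 / (
                    1.0
                    + np.exp(
                        -cfg.dropout_slope
                        * (np.log(mean + 1e-12) - cfg.dropout_midpoint)
                    )
                )
                c = np.where(rng.random(cfg.n_genes) < keep_p, c, 0)
            counts[:, col] = c
            cell_type[col] = t
            col += 1
    cell_ids = [f"{tissue}_c{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(
        gene_ids=list(gene_ids),
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts),
        tissue=[tissue] * n_cells,
    )
    return cm, cell_type


def simulate_two_tissue(cfg: SimConfig) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Draw stomach and intestine count matrices with planted cell types.

    Shared types (programs ``0..shared_types-1``) use identical
    expression programs, marker blocks and folds in both tissues;
    tissue-specific programs follow. Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    # baseline relative abundance: log-normal across genes, scaled so a cell
    # of mean depth has expected total library_size_mean
    base = rng.lognormal(0.0, cfg.baseline_sigma, size=cfg.n_genes)
    baseline = base / base.sum()

    n_spec_a, n_spec_b = cfg.specific_types_per_tissue
    n_programs = cfg.shared_types + n_spec_a + n_spec_b
    # disjoint marker blocks, chosen over a permuted gene order
    perm = rng.permutation(cfg.n_genes)
    marker_idx: dict[int, np.ndarray] = {}
    for t in range(n_programs):
        blk = perm[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]
        marker_idx[t] = np.sort(blk)
    # each program is a mean-one log-normal modulation of every gene; a
    # shared program reuses the same vector in both tissues. The program's
    # own marker block is exempt so planted markers carry exactly
    # marker_fold over a mean-one background.
    modulation = {}
    for t in range(n_programs):
        m = rng.lognormal(
            -cfg.type_effect_sigma**2 / 2, cfg.type_effect_sigma, cfg.n_genes
        )
        m[marker_idx[t]] = 1.0
        modulation[t] = m
    # planted co-expression pair: two dedicated population-restricted
    # genes (outside the marker blocks) with near-zero expression in
    # every type except shared program 0, where both are strongly
    # expressed — the structure of genuinely co-expressed population
    # markers such as pericyte/telocyte genes
    pair_idx = np.sort(perm[n_programs * cfg.markers_per_type :
                            n_programs * cfg.markers_per_type + 2])
    baseline[pair_idx] = cfg.coexpr_pair_background / cfg.library_size_mean
    baseline = baseline / baseline.sum()
    pair_fold = cfg.coexpr_pair_expressed / cfg.coexpr_pair_background
    for t in range(n_programs):
        modulation[t][pair_idx] = 1.0
    modulation[0][pair_idx] = pair_fold  # expressed only in shared program 0

    shared = list(range(cfg.shared_types))
    prog_a = shared + list(range(cfg.shared_types, cfg.shared_types + n_spec_a))
    prog_b = shared + list(
        range(cfg.shared_types + n_spec_a, cfg.shared_types + n_spec_a + n_spec_b)
    )

    cm_a, types_a = _simulate_tissue(
        rng, cfg, baseline, prog_a, marker_idx, modulation, "stomach", gene_ids
    )
    cm_b, types_b = _simulate_tissue(
        rng, cfg, baseline, prog_b, marker_idx, modulation, "intestine", gene_ids
    )
    truth = SimTruth(
        cell_type={"stomach": types_a, "intestine": types_b},
        conserved_pairs=[(t, t) for t in shared],
        markers={t: [gene_ids[i] for i in marker_idx[t]] for t in range(n_programs)},
        coexpr_pair=(gene_ids[pair_idx[0]], gene_ids[pair_idx[1]]),
        coexpr_type=0,
    )
    return cm_a, cm_b, truth


def simulate_region_signals(
    n_common: int,
    n_specific_per_tissue: tuple[int, int],
    signal_mean: float = 100.0,
    noise_cv: float = 0.1,
    specific_fold: float = 4.0,
    seed: int = 0,
) -> tuple[RegionSet, SignalTable, SimTruth]:
    """Paired-tissue region signal tables with planted common/specific regions.

    Common regions have equal expected signal in both tissues; specific
    regions differ by ``specific_fold`` (>= 4 by default) in expectation.
    Two replicate samples per tissue carry log-normal noise of
    coefficient of variation ``noise_cv``.
    """
    if n_common < 0 or min(n_specific_per_tissue) < 0:
        raise ConfigError("region counts must be non-negative")
    if specific_fold < 4:
        raise ConfigError("specific regions must differ by >= 4-fold in expectation")
    rng = np.random.default_rng(seed)
    n_a, n_b = n_specific_per_tissue
    n = n_common + n_a + n_b
    width = 2000
    gap = 10000
    rows = []
    classes = []
    base = rng.lognormal(np.log(signal_mean), 0.5, size=n)
    mean_a = np.empty(n)
    mean_b = np.empty(n)
    for i in range(n):
        start = 1000 + i * gap
        rows.append(("chr1", start, start + width, f"r{i:05d}"))
        if i < n_common:
            classes.append("common")
            mean_a[i] = mean_b[i] = base[i]
        elif i < n_common + n_a:
            classes.append("specific_stomach")
            mean_a[i] = base[i] * specific_fold
            mean_b[i] = base[i]
        else:
            classes.append("specific_intestine")
            mean_a[i] = base[i]
            mean_b[i] = base[i] * specific_fold
    rs = RegionSet(rows=pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))
    sigma = np.sqrt(np.log(1 + noise_cv**2))
    cols = {}
    sample_tissue = {}
    for tissue, mean in (("stomach", mean_a), ("intestine", mean_b)):
        for rep in (1, 2):
            name = f"{tissue}_rep{rep}"
            noise = rng.lognormal(-sigma**2 / 2, sigma, size=n) if sigma > 0 else 1.0
            cols[name] = mean * noise
            sample_tissue[name] = tissue
    st = SignalTable(
        signal=pd.DataFrame(cols, index=[r[3] for r in rows]),
        sample_tissue=sample_tissue,
    )
    truth = SimTruth(
        region_class=pd.DataFrame(
            {"region_id": [r[3] for r in rows], "true_class": classes}
        )
    )
    return rs, st, truth


def simulate_disease_table(
    truth: SimTruth,
    target_type: int,
    n_genes_from_markers: int = 15,
    n_background: int = 5,
    all_genes: list[str] | None = None,
    trait: str = "planted_trait",
    seed: int = 0,
) -> DiseaseGeneTable:
    """A one-trait table whose genes are sampled from a type's markers.

    ``n_background`` extra genes are drawn uniformly from ``all_genes``
    (excluding the chosen markers) to mimic unrelated associations.
    """
    if target_type not in truth.markers:
        raise ConfigError(f"type {target_type} not present in simulation truth")
    rng = np.random.default_rng(seed)
    markers = truth.markers[target_type]
    if n_genes_from_markers > len(markers):
        raise ConfigError("requested more marker genes than the type has")
    chosen = list(rng.choice(markers, size=n_genes_from_markers, replace=False))
    if n_background > 0:
        if all_genes is None:
            raise ConfigError("n_background > 0 requires all_genes")
        pool = [g for g in all_genes if g not in set(chosen)]
        chosen += list(rng.choice(pool, size=n_background, replace=False))
    return DiseaseGeneTable(
        rows=pd.DataFrame({"trait": trait, "gene": chosen}), source="synthetic"
    )


def write_manifest(path: str | Path, config: object, seed: int | None = None, **extra) -> None:
    """Record the generating config and seed beside simulation outputs."""
    doc = {"config": asdict(config) if hasattr(config, "__dataclass_fields__") else config}
    if seed is not None:
        doc["seed"] = seed
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
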