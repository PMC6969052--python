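"""Domain containers and plain-text readers/writers.

All pipeline stages exchange a small set of typed containers: sparse
genes x cells count matrices with per-cell tissue labels, real-valued
expression layers on the same axes, per-cell cluster assignments, gene
set collections (GMT), trait->gene association tables, and genomic
region sets (BED, 0-based half-open) with per-sample signal tables.

Every format round-trips: ``read(write(x)) == x`` exactly for integers
and strings and to machine precision for reals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExprMatrix",
    "CellLabels",
    "GeneSetCollection",
    "DiseaseGeneTable",
    "RegionSet",
    "SignalTable",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "write_expr",
    "read_expr",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_signal",
    "write_signal",
    "read_disease_table",
    "write_disease_table",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not parse as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountMatrix:
    """Sparse genes x cells non-negative integer UMI counts.

    ``tissue`` is a per-cell categorical label, typically ``"stomach"``
    or ``"intestine"``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix  # genes x cells
    tissue: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.tissue) != len(self.cell_ids):
            raise ValidationError("tissue label length != number of cells")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValidationError("counts contain non-finite entries")
            if np.any(data < 0):
                raise ValidationError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts contain non-integer entries")
        self.counts.data = self.counts.data.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ExprMatrix:
    """Real-valued genes x cells matrix sharing axes with its source counts.

    ``layer`` tags the transform: cpm, log_cpm, scaled or imputed.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # genes x cells, dense
    layer: str

    LAYERS = ("cpm", "log_cpm", "scaled", "imputed")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("values shape does not match axes")
        if self.layer not in self.LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None
        return self.values[i]


@dataclass
class CellLabels:
    """Per-cell cluster assignment, optionally with simulation ground truth."""

    cell_ids: list[str]
    cluster: np.ndarray  # int per cell
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=int)
        if len(self.cluster) != len(self.cell_ids):
            raise ValidationError("cluster length != number of cells")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=int)
            if len(self.truth) != len(self.cell_ids):
                raise ValidationError("truth length != number of cells")
        _check_unique(self.cell_ids, "cell")

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.cluster.tolist()))


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally with an explicit gene universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DiseaseGeneTable:
    """Rows of (trait, gene) associations, GWAS-catalog style."""

    rows: pd.DataFrame  # columns: trait, gene
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.rows = pd.DataFrame(self.rows)[["trait", "gene"]].astype(str)
        if self.rows.duplicated().any():
            raise ValidationError("duplicate (trait, gene) pairs")

    def genes_for(self, trait: str) -> list[str]:
        return self.rows.loc[self.rows["trait"] == trait, "gene"].tolist()

    def traits(self) -> list[str]:
        return sorted(self.rows["trait"].unique().tolist())


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open, sorted by (chrom, start)."""

    rows: pd.DataFrame  # columns: chrom, start, end, region_id

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).copy()
        required = ["chrom", "start", "end", "region_id"]
        extras = [c for c in df.columns if c not in required]
        df = df[required + extras]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            r = df.loc[bad[0]]
            raise ValidationError(
                f"region {r['region_id']!r}: start {r['start']} >= end {r['end']}"
            )
        _check_unique(df["region_id"].tolist(), "region")
        self.rows = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SignalTable:
    """region_id x sample matrix of non-negative signal plus sample->tissue map."""

    signal: pd.DataFrame  # index region_id, columns sample names
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        self.signal = pd.DataFrame(self.signal).astype(float)
        vals = self.signal.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("signal must be finite")
        if np.any(vals < 0):
            raise ValidationError("signal must be non-negative")
        missing = set(self.signal.columns) - set(self.sample_tissue)
        if missing:
            raise ValidationError(f"samples without tissue assignment: {sorted(missing)}")

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.signal.columns if self.sample_tissue[s] == tissue]

    def tissues(self) -> list[str]:
        return sorted(set(self.sample_tissue[s] for s in self.signal.columns))


# ---------------------------------------------------------------------------
# counts


def _collapse_duplicate_genes(
    gene_ids: list[str], mat: sp.spmatrix
) -> tuple[list[str], sp.csr_matrix]:
    """Sum rows that share a gene id, preserving first-occurrence order."""
    seen: dict[str, int] = {}
    order: list[str] = []
    for g in gene_ids:
        if g not in seen:
            seen[g] = len(order)
            order.append(g)
    if len(order) == len(gene_ids):
        return gene_ids, sp.csr_matrix(mat)
    n_dup = len(gene_ids) - len(order)
    warnings.warn(f"collapsed {n_dup} duplicate gene id rows by summation")
    log.warning("collapsed %d duplicate gene id rows by summation", n_dup)
    idx = np.array([seen[g] for g in gene_ids])
    coll = sp.csr_matrix(
        (np.ones(len(gene_ids)), (idx, np.arange(len(gene_ids)))),
        shape=(len(order), len(gene_ids)),
    )
    return order, sp.csr_matrix(coll @ sp.csr_matrix(mat))


def read_counts(path: str | Path, format: str, tissue_label: str) -> CountMatrix:
    """Read a DGE count matrix.

    ``format="mtx_triplet"``: *path* is a directory holding ``matrix.mtx``
    (genes x cells, MatrixMarket coordinate), ``genes.tsv`` and
    ``barcodes.tsv``. ``format="dense_tsv"``: *path* is a TSV with a header
    row of cell ids and gene ids in the first column.

    Duplicate gene ids are collapsed by summation with a warning.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(str(f))
        try:
            mat = scipy.io.mmread(str(mtx))
        except Exception as e:  # malformed header etc.
            raise FormatError(f"cannot parse MatrixMarket file {mtx}: {e}") from e
        gene_ids = [
            ln.split("\t")[0].strip()
            for ln in genes_f.read_text().splitlines()
            if ln.strip()
        ]
        cell_ids = [ln.strip() for ln in barcodes_f.read_text().splitlines() if ln.strip()]
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match {len(gene_ids)} genes "
                f"x {len(cell_ids)} barcodes"
            )
    elif format == "dense_tsv":
        if not path.exists():
            raise FileNotFoundError(str(path))
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as e:
            raise FormatError(f"cannot parse dense TSV {path}: {e}") from e
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        mat = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown counts format {format!r}")
    gene_ids, mat = _collapse_duplicate_genes(gene_ids, mat)
    return CountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=mat,
        tissue=[tissue_label] * len(cell_ids),
    )


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write counts as an MTX triplet directory or a dense TSV file."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
        (path / "genes.tsv").write_text("".join(g + "\n" for g in cm.gene_ids))
        (path / "barcodes.tsv").write_text("".join(c + "\n" for c in cm.cell_ids))
        (path / "tissue.tsv").write_text(
            "".join(f"{c}\t{t}\n" for c, t in zip(cm.cell_ids, cm.tissue))
        )
    elif format == "dense_tsv":
        df = pd.DataFrame(cm.dense(), index=cm.gene_ids, columns=cm.cell_ids)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def write_expr(em: ExprMatrix, path: str | Path) -> None:
    """Write an expression layer as a dense TSV (genes x cells)."""
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.cell_ids)
    with open(path, "w") as fh:
        fh.write(f"# layer={em.layer}\n")
        df.to_csv(fh, sep="\t")


def read_expr(path: str | Path) -> ExprMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# layer="):
            raise FormatError(f"{path}: missing '# layer=' header line")
        layer = header.strip().split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    return ExprMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=df.to_numpy(),
        layer=layer,
    )


# ---------------------------------------------------------------------------
# gene sets / disease tables


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse GMT: one set per line, ``name TAB description TAB member...``."""
    sets: dict[str, list[str]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs name, description, members")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"{path}:{i}: duplicate gene set name {name!r}")
        members = [g for g in parts[2:] if g]
        sets[name] = list(dict.fromkeys(members))
    return GeneSetCollection(sets=sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_disease_table(path: str | Path, source: str = "file") -> DiseaseGeneTable:
    """Read a trait-gene TSV with columns ``trait`` and ``gene``."""
    df = pd.read_csv(path, sep="\t")
    if not {"trait", "gene"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns 'trait' and 'gene'")
    return DiseaseGeneTable(rows=df[["trait", "gene"]], source=source)


def write_disease_table(dt: DiseaseGeneTable, path: str | Path) -> None:
    dt.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions / signal


def read_bed(path: str | Path) -> RegionSet:
    """Read BED3+ (half-open). Column 4, when present, is the region id."""
    rows = []
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: BED line needs chrom, start, end")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise FormatError(f"{path}:{i}: non-integer coordinate") from e
        if start >= end:
            raise ValidationError(f"{path}:{i}: start {start} >= end {end}")
        rid = parts[3] if len(parts) >= 4 and parts[3] else f"region_{i}"
        rows.append((parts[0], start, end, rid))
    return RegionSet(
        rows=pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    )


def write_bed(rs: RegionSet, path: str | Path) -> None:
    rs.rows[["chrom", "start", "end", "region_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_signal(path: str | Path, sample_tissue: dict[str, str]) -> SignalTable:
    """Read a region_id x sample signal TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SignalTable(signal=df, sample_tissue=dict(sample_tissue))


def write_signal(st: SignalTable, path: str | Path) -> None:
    st.signal.to_csv(path, sep="\t", float_format="%.17g")


def read_bed_signal(
    bed_path: str | Path, signal_path: str | Path, sample_tissue: dict[str, str]
) -> tuple[RegionSet, SignalTable]:
    """Read paired region set + signal table and check their ids agree."""
    rs = read_bed(bed_path)
    st = read_signal(signal_path, sample_tissue)
    if set(st.signal.index) != set(rs.rows["region_id"]):
        raise ValidationError("signal table region ids do not match BED region ids")
    return rs, st
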