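"""Cross-tissue enhancer/peak comparison.

Given super-enhancer (or peak) region sets with per-sample H3K27ac /
ChIP signal from two tissues, this module merges the region sets,
correlates samples on log2 signal, classifies each region as common
(fold < 1.5 between tissues), tissue-specific (fold > 2) or ambiguous
on library-size-scaled means, counts overlapping peaks by sweep-line,
and assigns each region its nearest TSS gene for downstream
over-representation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RegionSet, SignalTable, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "RegionParams",
    "merge_regions",
    "correlate_samples",
    "ma_classify",
    "count_overlaps",
    "nearest_gene",
]


@dataclass
class RegionParams:
    """Fold thresholds of the common/specific calls and signal pseudocount."""

    common_max_fold: float = 1.5
    specific_min_fold: float = 2.0
    pseudocount: float = 1.0
    overlap_min_bp: int = 1

    def __post_init__(self) -> None:
        if not (self.specific_min_fold >= self.common_max_fold > 1):
            raise ValidationError(
                "need specific_min_fold >= common_max_fold > 1"
            )


def _check_chrom_conventions(a: RegionSet, b: RegionSet) -> None:
    pa = {c.startswith("chr") for c in a.rows["chrom"].unique()}
    pb = {c.startswith("chr") for c in b.rows["chrom"].unique()}
    if pa and pb and pa != pb:
        raise ValidationError(
            "chromosome naming conventions differ between the two region sets "
            "(mixed 'chr' prefixes); harmonize before merging"
        )


def merge_regions(
    set_a: RegionSet, set_b: RegionSet, overlap_min_bp: int = 1
) -> RegionSet:
    """Union of two interval sets, merging intervals that overlap by
    >= overlap_min_bp; provenance (A, B or both) is recorded per merged
    region in a ``source`` column."""
    _check_chrom_conventions(set_a, set_b)
    rows = []
    for src, rs in (("A", set_a), ("B", set_b)):
        for r in rs.rows.itertuples():
            rows.append((r.chrom, r.start, r.end, src))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    merged: list[list] = []
    for chrom, start, end, src in rows:
        if (
            merged
            and merged[-1][0] == chrom
            and min(merged[-1][2], end) - max(merged[-1][1], start) >= overlap_min_bp
        ):
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3].add(src)
        else:
            merged.append([chrom, start, end, {src}])
    out = pd.DataFrame(
        [
            (
                chrom,
                start,
                end,
                f"m{i:05d}",
                "both" if len(src) == 2 else next(iter(src)),
            )
            for i, (chrom, start, end, src) in enumerate(merged)
        ],
        columns=["chrom", "start", "end", "region_id", "source"],
    )
    rs = RegionSet(rows=out)
    # self-check: no overlapping intervals survive the merge
    df = rs.rows
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    if np.any(same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])):
        raise AssertionError("merge produced overlapping intervals")
    return rs


def correlate_samples(
    signal: SignalTable, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pearson correlation of log2(signal + pseudocount) across regions.

    Returns the sample x sample matrix plus the mean within-tissue and
    between-tissue off-diagonal correlations. Constant samples get NaN
    correlations and are flagged in the log.
    """
    if len(signal.signal) < 3:
        raise ValueError("need >= 3 regions to correlate samples")
    L = np.log2(signal.signal.to_numpy() + pseudocount)
    samples = list(signal.signal.columns)
    const = L.std(axis=0) == 0
    for s, c in zip(samples, const):
        if c:
            log.warning("sample %s has constant signal; correlation undefined", s)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(L.T)
    C[const, :] = np.nan
    C[:, const] = np.nan
    np.fill_diagonal(C, np.where(const, np.nan, 1.0))
    corr = pd.DataFrame(C, index=samples, columns=samples)
    within, between = [], []
    for i, si in enumerate(samples):
        for j in range(i + 1, len(samples)):
            v = C[i, j]
            if not np.isfinite(v):
                continue
            same = signal.sample_tissue[si] == signal.sample_tissue[samples[j]]
            (within if same else between).append(v)
    summary = {
        "within_tissue_mean": float(np.mean(within)) if within else float("nan"),
        "between_tissue_mean": float(np.mean(between)) if between else float("nan"),
    }
    return corr, summary


def ma_classify(
    regions: RegionSet,
    signal: SignalTable,
    params: RegionParams = RegionParams(),
) -> pd.DataFrame:
    """MA comparison of per-tissue mean signal with the 1.5/2 fold rules.

    Samples are scaled to equal total signal; per-tissue means feed the
    orientation-free fold (higher + pc)/(lower + pc). Regions with fold
    below ``common_max_fold`` are common, above ``specific_min_fold``
    specific to the higher tissue, otherwise ambiguous. A = mean of
    log2 signals, M = signed log2 fold (second tissue over first).
    """
    tissues = signal.tissues()
    if len(tissues) != 2:
        raise ValueError(f"exactly two tissues required, got {tissues}")
    for t in tissues:
        if not signal.samples_of(t):
            raise ValueError(f"tissue {t} has no samples")
    S = signal.signal.copy()
    totals = S.sum(axis=0)
    S = S / totals * totals.mean()  # equal-total library scaling
    pc = params.pseudocount
    t1, t2 = tissues
    m1 = S[signal.samples_of(t1)].mean(axis=1)
    m2 = S[signal.samples_of(t2)].mean(axis=1)
    hi = np.maximum(m1, m2)
    lo = np.minimum(m1, m2)
    fold = (hi + pc) / (lo + pc)
    A = (np.log2(m1 + pc) + np.log2(m2 + pc)) / 2.0
    M = np.log2(m2 + pc) - np.log2(m1 + pc)
    cls = np.where(
        fold < params.common_max_fold,
        "common",
        np.where(
            fold > params.specific_min_fold,
            np.where(m1 >= m2, f"specific_{t1}", f"specific_{t2}"),
            "ambiguous",
        ),
    )
    zero = (S.to_numpy().sum(axis=1) == 0)
    if zero.any():
        log.warning("%d regions have zero signal in all samples", int(zero.sum()))
        cls = np.where(zero, "common", cls)
    out = pd.DataFrame(
        {
            "region_id": S.index,
            f"mean_{t1}": m1.to_numpy(),
            f"mean_{t2}": m2.to_numpy(),
            "A": A.to_numpy(),
            "M": M.to_numpy(),
            "fold": fold.to_numpy(),
            "class": cls,
        }
    ).set_index("region_id")
    order = {r: i for i, r in enumerate(regions.rows["region_id"])}
    missing = set(out.index) - set(order)
    if missing:
        raise ValidationError(f"signal regions absent from region set: {sorted(missing)[:5]}")
    return out.loc[sorted(out.index, key=order.__getitem__)]


def count_overlaps(
    peaks_a: RegionSet, peaks_b: RegionSet, overlap_min_bp: int = 1
) -> tuple[int, RegionSet]:
    """Number of A regions overlapping >= 1 B region by >= overlap_min_bp.

    Sweep-line over the concatenated sorted endpoints; returns the count
    plus the overlapping A regions as a RegionSet.
    """
    _check_chrom_conventions(peaks_a, peaks_b)
    hits = []
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in peaks_b.rows.itertuples():
        b_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()
    for r in peaks_a.rows.itertuples():
        ivals = b_by_chrom.get(r.chrom, [])
        # sweep over b intervals sorted by start; stop once b.start >= r.end
        hit = False
        for bs, be in ivals:
            if bs >= r.end:
                break
            if min(r.end, be) - max(r.start, bs) >= overlap_min_bp:
                hit = True
                break
        if hit:
            hits.append((r.chrom, r.start, r.end, r.region_id))
    rs = RegionSet(
        rows=pd.DataFrame(hits, columns=["chrom", "start", "end", "region_id"])
        if hits
        else pd.DataFrame(columns=["chrom", "start", "end", "region_id"])
    )
    return len(hits), rs


def nearest_gene(regions: RegionSet, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS gene per region (midpoint distance, 0 if TSS inside).

    ``tss_table`` needs columns gene, chrom, position, strand. Ties are
    broken alphabetically; regions on chromosomes absent from the table
    are left unassigned and flagged.
    """
    req = {"gene", "chrom", "position", "strand"}
    if not req.issubset(tss_table.columns):
        raise ValueError(f"TSS table needs columns {sorted(req)}")
    by_chrom = {c: g.sort_values(["position", "gene"]) for c, g in tss_table.groupby("chrom")}
    rows = []
    for r in regions.rows.itertuples():
        sub = by_chrom.get(r.chrom)
        if sub is None:
            log.warning("region %s: chromosome %s absent from TSS table", r.region_id, r.chrom)
            rows.append((r.region_id, None, np.nan))
            continue
        mid = (r.start + r.end) // 2
        pos = sub["position"].to_numpy()
        inside = (pos >= r.start) & (pos < r.end)
        if inside.any():
            cand = sub.loc[inside]
            gene = sorted(cand["gene"])[0]
            rows.append((r.region_id, gene, 0))
            continue
        dist = np.abs(pos - mid)
        best = dist.min()
        cand = sub.loc[dist == best, "gene"]
        rows.append((r.region_id, sorted(cand)[0], int(best)))
    return pd.DataFrame(rows, columns=["region_id", "gene", "distance"]).set_index(
        "region_id"
    )
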