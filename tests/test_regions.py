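"""Interval merging, signal correlation, MA classification, nearest gene."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutniche import regions as rg
from gutniche.io import RegionSet, SignalTable, ValidationError
from gutniche.simulate import simulate_region_signals


def _regions(intervals, chrom="chr1"):
    return RegionSet(rows=pd.DataFrame(
        [(chrom, s, e, f"r{i}") for i, (s, e) in enumerate(intervals)],
        columns=["chrom", "start", "end", "region_id"],
    ))


def brute_force_overlap_count(a, b, min_bp=1):
    """Oracle: quadratic all-pairs overlap count (A side)."""
    n = 0
    for r in a.rows.itertuples():
        for q in b.rows.itertuples():
            if r.chrom == q.chrom and min(r.end, q.end) - max(r.start, q.start) >= min_bp:
                n += 1
                break
    return n


class TestMergeRegions:
    def test_identical_sets_idempotent(self):
        a = _regions([(0, 10), (20, 30)])
        merged = rg.merge_regions(a, a)
        assert merged.rows[["start", "end"]].values.tolist() == [[0, 10], [20, 30]]
        assert set(merged.rows["source"]) == {"both"}

    def test_disjoint_concatenated_sorted(self):
        a = _regions([(50, 60)])
        b = _regions([(0, 10)])
        merged = rg.merge_regions(a, b)
        assert merged.rows[["start", "end"]].values.tolist() == [[0, 10], [50, 60]]

    def test_interval_arithmetic(self):
        merged = rg.merge_regions(_regions([(10, 20)]), _regions([(15, 30)]))
        assert merged.rows[["start", "end"]].values.tolist() == [[10, 30]]

    def test_chrom_convention_mismatch(self):
        a = _regions([(0, 10)], chrom="chr1")
        b = _regions([(0, 10)], chrom="1")
        with pytest.raises(ValidationError, match="convention"):
            rg.merge_regions(a, b)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=20))
    def test_merge_output_never_overlaps(self, raw):
        ivals = [(s, s + w) for s, w in raw]
        merged = rg.merge_regions(_regions(ivals), _regions(ivals)).rows
        for i in range(1, len(merged)):
            assert merged.loc[i, "start"] >= merged.loc[i - 1, "end"]


class TestCorrelateSamples:
    def _signal(self, cols):
        tissue = {c: ("stomach" if c.startswith("s") else "intestine") for c in cols}
        return SignalTable(signal=pd.DataFrame(cols, index=[f"r{i}" for i in
                                                            range(len(next(iter(cols.values()))))]),
                           sample_tissue=tissue)

    def test_duplicated_columns_unit_correlation(self):
        st_ = self._signal({"s1": [1.0, 5.0, 9.0], "s2": [1.0, 5.0, 9.0]})
        corr, _ = rg.correlate_samples(st_)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        st_ = self._signal({"s1": list(rng.random(5) * 10),
                            "i1": list(rng.random(5) * 10)})
        corr, _ = rg.correlate_samples(st_)
        assert corr.loc["s1", "s1"] == pytest.approx(1.0)
        assert corr.loc["s1", "i1"] == pytest.approx(corr.loc["i1", "s1"])

    def test_replicates_correlate_within_tissue(self):
        _, st_, _ = simulate_region_signals(200, (5, 5), noise_cv=0.1, seed=2)
        _, summary = rg.correlate_samples(st_)
        assert summary["within_tissue_mean"] > summary["between_tissue_mean"]


class TestMaClassify:
    def _inputs(self, sig_a, sig_b):
        n = len(sig_a)
        regions = _regions([(i * 1000, i * 1000 + 100) for i in range(n)])
        regions.rows["region_id"] = [f"r{i}" for i in range(n)]
        st_ = SignalTable(
            signal=pd.DataFrame({"a1": sig_a, "b1": sig_b},
                                index=[f"r{i}" for i in range(n)]),
            sample_tissue={"a1": "stomach", "b1": "intestine"},
        )
        return regions, st_

    def test_threshold_application(self):
        # near-equal totals so library scaling barely moves; folds ~1, ~3, ~1.7
        regions, st_ = self._inputs([4000.0, 3000.0, 2857.1],
                                    [4000.0, 1000.0, 4857.1])
        out = rg.ma_classify(regions, st_)
        assert out.loc["r0", "class"] == "common"
        assert out.loc["r1", "class"] == "specific_stomach"
        assert out.loc["r2", "class"] == "ambiguous"

    def test_specific_label_names_higher_tissue(self):
        regions, st_ = self._inputs([3000.0, 1000.0], [1000.0, 3000.0])
        out = rg.ma_classify(regions, st_)
        assert out.loc["r0", "class"] == "specific_stomach"
        assert out.loc["r1", "class"] == "specific_intestine"

    def test_sample_order_invariance(self):
        _, st_, _ = simulate_region_signals(50, (3, 3), noise_cv=0.05, seed=4)
        rs = _regions([(i * 1000, i * 1000 + 100) for i in range(56)])
        rs.rows["region_id"] = list(st_.signal.index)
        rs = RegionSet(rows=rs.rows)
        out1 = rg.ma_classify(rs, st_)
        shuffled = SignalTable(signal=st_.signal[list(st_.signal.columns)[::-1]],
                               sample_tissue=st_.sample_tissue)
        out2 = rg.ma_classify(rs, shuffled)
        assert (out1["class"] == out2["class"]).all()

    def test_planted_regions_recovered(self):
        rs, st_, truth = simulate_region_signals(500, (8, 8), noise_cv=0.1, seed=1)
        out = rg.ma_classify(rs, st_)
        merged = out.join(truth.region_class.set_index("region_id"))
        # intestine is the second tissue alphabetically -> label mapping direct
        assert (merged["class"] == merged["true_class"]).all()


class TestCountOverlaps:
    def test_identical_sets(self):
        a = _regions([(0, 10), (20, 30), (40, 50)])
        n, hits = rg.count_overlaps(a, a)
        assert n == 3 and len(hits) == 3

    def test_disjoint_sets(self):
        n, hits = rg.count_overlaps(_regions([(0, 10)]), _regions([(10, 20)]))
        assert n == 0 and len(hits) == 0

    def test_toy_against_quadratic_oracle(self):
        a = _regions([(0, 5), (10, 30), (28, 40), (50, 60), (70, 80)])
        b = _regions([(4, 12), (35, 55), (61, 69), (81, 90)])
        n, _ = rg.count_overlaps(a, b)
        assert n == brute_force_overlap_count(a, b)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 300), st.integers(1, 40)), min_size=1,
                 max_size=15),
        st.lists(st.tuples(st.integers(0, 300), st.integers(1, 40)), min_size=1,
                 max_size=15),
    )
    def test_random_against_quadratic_oracle(self, ra, rb):
        a = _regions([(s, s + w) for s, w in ra])
        b = _regions([(s, s + w) for s, w in rb])
        n, _ = rg.count_overlaps(a, b)
        assert n == brute_force_overlap_count(a, b)


class TestNearestGene:
    def _tss(self):
        return pd.DataFrame(
            {
                "gene": ["Wnt2b", "Gli2", "Hoxc8", "Nr2f1"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "position": [100, 5000, 5200, 300],
                "strand": ["+", "-", "+", "+"],
            }
        )

    def test_tss_inside_region(self):
        out = rg.nearest_gene(_regions([(90, 150)]), self._tss())
        assert out.loc["r0", "gene"] == "Wnt2b" and out.loc["r0", "distance"] == 0

    def test_equidistant_tie_alphabetical(self):
        # midpoint 5100: Gli2 at 5000 and Hoxc8 at 5200 both 100 away
        out = rg.nearest_gene(_regions([(5090, 5110)]), self._tss())
        assert out.loc["r0", "gene"] == "Gli2"

    def test_hand_enumerated_layout(self):
        regions = _regions([(0, 10), (4000, 4100), (5150, 5250), (9000, 9010)])
        out = rg.nearest_gene(regions, self._tss())
        assert list(out["gene"]) == ["Wnt2b", "Gli2", "Hoxc8", "Hoxc8"]

    def test_unknown_chromosome_flagged(self):
        out = rg.nearest_gene(_regions([(0, 10)], chrom="chrX"), self._tss())
        assert out.loc["r0", "gene"] is None
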