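"""Cross-tissue profile matching, dendrogram, neighbor-voting AUROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutniche import conservation as cons
from gutniche import preprocess as pp
from gutniche.io import ExprMatrix


def rank_formula_spearman(x, y):
    """Oracle: Pearson correlation of average ranks (tie-corrected)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _result(profiles_a, profiles_b, threshold=0.7):
    pa = pd.DataFrame(profiles_a).T
    pb = pd.DataFrame(profiles_b).T
    feats = [f"g{i}" for i in range(pa.shape[1])]
    pa.columns = pb.columns = feats
    return cons.spearman_match(feats, {"a": pa, "b": pb}, threshold=threshold)


class TestSpearmanMatch:
    def test_identical_profiles_match(self):
        v = [1.0, 3.0, 2.0, 5.0]
        res = _result({0: v}, {0: v})
        assert res.rho.loc[0, 0] == pytest.approx(1.0)
        assert res.matches == [(0, 0, pytest.approx(1.0))]

    def test_rank_reversed_unmatched(self):
        res = _result({0: [1.0, 2.0, 3.0, 4.0]}, {0: [4.0, 3.0, 2.0, 1.0]})
        assert res.rho.loc[0, 0] == pytest.approx(-1.0)
        assert res.matches == []

    def test_tie_corrected_oracle(self):
        x, y = [1.0, 2.0, 2.0, 3.0], [1.0, 3.0, 3.0, 4.0]
        res = _result({0: x}, {0: y})
        assert res.rho.loc[0, 0] == pytest.approx(rank_formula_spearman(x, y),
                                                  abs=1e-12)

    def test_threshold_is_inclusive_cut_at_070(self, rng):
        """Profiles correlating just below 0.7 are excluded, just above kept."""
        n = 40
        x = np.arange(n, dtype=float)
        below = above = None
        for _ in range(2000):
            y = x + rng.normal(scale=14, size=n)
            r = rank_formula_spearman(x, y)
            if 0.60 < r < 0.695:
                below = y
            elif 0.705 < r < 0.80:
                above = y
            if below is not None and above is not None:
                break
        res = _result({0: list(x)}, {0: list(below), 1: list(above)})
        assert [(a, b) for a, b, _ in res.matches] == [(0, 1)]

    def test_constant_profile_never_matches(self):
        res = _result({0: [2.0, 2.0, 2.0, 2.0]}, {0: [1.0, 2.0, 3.0, 4.0]})
        assert np.isnan(res.rho.loc[0, 0]) and res.matches == []

    def test_feature_order_permutation_invariant(self, rng):
        pa = {0: list(rng.normal(size=12)), 1: list(rng.normal(size=12))}
        pb = {0: list(rng.normal(size=12))}
        res = _result(pa, pb)
        perm = rng.permutation(12)
        pa2 = {k: list(np.array(v)[perm]) for k, v in pa.items()}
        pb2 = {k: list(np.array(v)[perm]) for k, v in pb.items()}
        res2 = _result(pa2, pb2)
        np.testing.assert_allclose(res.rho, res2.rho, atol=1e-12)

    def test_match_set_monotone_in_threshold(self, rng):
        pa = {i: list(rng.normal(size=15)) for i in range(4)}
        pb = {i: list(rng.normal(size=15)) for i in range(4)}
        prev = None
        for thr in (0.2, 0.5, 0.7, 0.9):
            got = {(a, b) for a, b, _ in _result(pa, pb, threshold=thr).matches}
            if prev is not None:
                assert got <= prev
            prev = got


class TestHcluster:
    def test_identical_clusters_merge_first_at_zero(self):
        v = [1.0, 4.0, 2.0, 8.0, 3.0]
        res = _result({0: v, 1: [5.0, 1.0, 2.0, 0.0, 9.0]}, {0: v})
        res = cons.hcluster_profiles(res)
        first = res.linkage[0]
        merged = {res.leaf_names[int(first[0])], res.leaf_names[int(first[1])]}
        assert merged == {"stomach_0", "intestine_0"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_tree_arity(self, rng):
        pa = {i: list(rng.normal(size=10)) for i in range(3)}
        pb = {i: list(rng.normal(size=10)) for i in range(2)}
        res = cons.hcluster_profiles(_result(pa, pb))
        assert res.linkage.shape[0] == 5 - 1

    def test_newick_serialization(self, rng):
        pa = {i: list(rng.normal(size=10)) for i in range(2)}
        res = cons.hcluster_profiles(_result(pa, pa))
        nwk = cons.dendrogram_newick(res.linkage, res.leaf_names)
        assert nwk.endswith(";") and "stomach_0" in nwk and "intestine_1" in nwk


class TestBuildProfiles:
    def test_cluster_of_identical_cells(self, rng):
        V = np.tile(rng.normal(size=(6, 1)), (1, 4))
        em = ExprMatrix([f"g{i}" for i in range(6)], [f"c{i}" for i in range(4)],
                        V, "log_cpm")
        from gutniche.io import CellLabels

        lab = CellLabels(cell_ids=em.cell_ids, cluster=np.zeros(4, dtype=int))
        table = pd.DataFrame(
            {"cluster": 0, "gene": em.gene_ids, "lr_stat": 1.0, "p": 0.01,
             "p_adj": 0.06, "log_fc": 1.0, "rank": range(1, 7)}
        )
        feats, prof = cons.build_profiles(em, lab, em, lab, table, table, k=6)
        expected = V[[em.gene_ids.index(g) for g in feats], 0]
        np.testing.assert_allclose(prof["a"].loc[0].to_numpy(), expected)

    def test_disjoint_gene_namespaces_error(self, rng):
        em1 = ExprMatrix(["a1"], ["c1", "c2", "c3"], rng.normal(size=(1, 3)), "log_cpm")
        em2 = ExprMatrix(["b1"], ["d1", "d2", "d3"], rng.normal(size=(1, 3)), "log_cpm")
        from gutniche.io import CellLabels

        lab1 = CellLabels(cell_ids=em1.cell_ids, cluster=np.zeros(3, dtype=int))
        lab2 = CellLabels(cell_ids=em2.cell_ids, cluster=np.zeros(3, dtype=int))
        t1 = pd.DataFrame({"cluster": 0, "gene": ["a1"], "lr_stat": 1.0, "p": 0.01,
                           "p_adj": 0.01, "log_fc": 1.0, "rank": [1]})
        t2 = t1.assign(gene=["b1"])
        with pytest.raises(ValueError, match="share no gene"):
            cons.build_profiles(em1, lab1, em2, lab2, t1, t2, k=1)


class TestNeighborVoting:
    def _tissue_copy_auroc(self, small_processed):
        expr = small_processed["stomach"]["expr"]
        tl = small_processed["stomach"]["truth"]
        hvg = pp.select_hvg(expr, 150)
        expr_b = ExprMatrix(expr.gene_ids, [c + "_copy" for c in expr.cell_ids],
                            expr.values.copy(), "log_cpm")
        return cons.neighbor_voting_auroc(expr, tl, expr_b, tl, hvg)

    def test_duplicated_data_perfect_replicability(self, small_processed):
        res = self._tissue_copy_auroc(small_processed)
        assert res.per_type and all(v == pytest.approx(1.0) for v in res.per_type.values())

    def test_bounded_in_unit_interval(self, small_processed):
        expr_a = small_processed["stomach"]["expr"]
        expr_b = small_processed["intestine"]["expr"]
        hvg = pp.select_hvg(expr_a, 150)
        res = cons.neighbor_voting_auroc(
            expr_a, small_processed["stomach"]["truth"],
            expr_b, small_processed["intestine"]["truth"], hvg,
        )
        assert all(0.0 <= v <= 1.0 for v in res.per_type.values())

    def test_shuffled_labels_chance_level(self, small_processed, rng):
        expr_a = small_processed["stomach"]["expr"]
        expr_b = small_processed["intestine"]["expr"]
        ta = small_processed["stomach"]["truth"].copy()
        tb = small_processed["intestine"]["truth"].copy()
        hvg = pp.select_hvg(expr_a, 150)
        means = []
        for _ in range(20):
            rng.shuffle(ta)
            rng.shuffle(tb)
            res = cons.neighbor_voting_auroc(expr_a, ta, expr_b, tb, hvg)
            means.append(res.mean())
        assert 0.45 <= float(np.mean(means)) <= 0.55
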