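"""GSEA running sum, permutation significance, ORA and disease z-scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gutniche import enrichment as en
from gutniche.io import CellLabels, DiseaseGeneTable, ExprMatrix, GeneSetCollection


def brute_force_es(ranked_scores, gene_set, p=1.0):
    """Oracle: explicit running-sum loop."""
    genes = list(ranked_scores.index)
    scores = ranked_scores.to_numpy()
    inset = [g in set(gene_set) for g in genes]
    nr = sum(abs(s) ** p for s, h in zip(scores, inset) if h)
    n_miss = len(genes) - sum(inset)
    run, best = 0.0, 0.0
    for s, h in zip(scores, inset):
        if h:
            run += abs(s) ** p / nr
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def exhaustive_ora_p(n_universe, set_size, query_size, overlap):
    """Oracle: exact tail probability by enumeration over all draws."""
    total = math.comb(n_universe, query_size)
    hits = 0
    for k in range(overlap, min(set_size, query_size) + 1):
        hits += math.comb(set_size, k) * math.comb(n_universe - set_size,
                                                   query_size - k)
    return hits / total


class TestSignalToNoise:
    def _profiles(self, rows):
        return pd.DataFrame(rows, index=[0, 1, 2, 3],
                            columns=[f"g{i}" for i in range(len(rows[0]))])

    def test_flat_gene_scores_zero(self):
        prof = self._profiles([[1.0, 5.0]] * 4)
        s = en.rank_genes_s2n(prof, {0: "conserved", 1: "conserved",
                                     2: "distinct", 3: "distinct"})
        np.testing.assert_allclose(s.to_numpy(), 0.0)

    def test_sign_ordering(self):
        prof = self._profiles([[3.0, 0.0], [3.2, 0.0], [0.0, 3.0], [0.0, 2.8]])
        s = en.rank_genes_s2n(prof, {0: "conserved", 1: "conserved",
                                     2: "distinct", 3: "distinct"})
        assert list(s.index) == ["g0", "g1"] and s["g0"] > 0 > s["g1"]

    def test_hand_formula(self):
        prof = self._profiles([[2.0], [4.0], [1.0], [2.0]])
        s = en.rank_genes_s2n(prof, {0: "conserved", 1: "conserved",
                                     2: "distinct", 3: "distinct"})
        mu_c, mu_d = 3.0, 1.5
        s_c = max(np.std([2, 4], ddof=1), 0.2 * mu_c)
        s_d = max(np.std([1, 2], ddof=1), 0.2 * mu_d)
        assert s["g0"] == pytest.approx((mu_c - mu_d) / (s_c + s_d))

    def test_single_cluster_group_rejected(self):
        prof = self._profiles([[1.0], [2.0], [3.0], [4.0]])
        with pytest.raises(ValueError, match="permutation"):
            en.rank_genes_s2n(prof, {0: "conserved", 1: "distinct",
                                     2: "distinct", 3: "distinct"})


class TestGseaEs:
    def _ranking(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_single_member_at_top(self):
        r = self._ranking()
        assert en.gsea_es(r, ["g0"]) == pytest.approx(1.0)

    def test_single_member_at_bottom(self):
        r = self._ranking()
        assert en.gsea_es(r, ["g9"]) == pytest.approx(brute_force_es(r, ["g9"]))
        assert en.gsea_es(r, ["g9"]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(100 + seed)
        r = self._ranking(seed=seed)
        gene_set = list(rng.choice(r.index, size=rng.integers(1, 6), replace=False))
        assert en.gsea_es(r, gene_set) == pytest.approx(
            brute_force_es(r, gene_set), abs=1e-12
        )

    def test_reversal_antisymmetry_with_equal_weights(self):
        """With all |scores| equal, reversing the ranking negates ES."""
        r = pd.Series([1.0] * 8, index=[f"g{i}" for i in range(8)])
        rev = r.iloc[::-1]
        s = ["g1", "g2"]
        assert en.gsea_es(r, s) == pytest.approx(-en.gsea_es(rev, s), abs=1e-12)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            en.gsea_es(self._ranking(), ["nope"])


class TestGseaSignificance:
    def test_planted_top_set_significant(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(1000)]
        r = pd.Series(np.sort(rng.normal(size=1000))[::-1], index=genes)
        res = en.gsea_significance(
            r, GeneSetCollection(sets={"top": genes[:20]}), n_perm=1000, seed=1
        )
        assert float(res.table["p_perm"].iloc[0]) <= 0.01
        assert float(res.table["nes"].iloc[0]) > 1.5

    def test_p_floor(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        r = pd.Series(np.sort(rng.normal(size=50))[::-1], index=genes)
        res = en.gsea_significance(
            r, GeneSetCollection(sets={"s": genes[:5]}), n_perm=199, seed=0
        )
        assert float(res.table["p_perm"].iloc[0]) >= 1 / 200


class TestOra:
    def test_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        query = universe[2:7]  # overlap 3
        out = en.ora_hypergeometric(query, GeneSetCollection(sets={"s": gene_set}),
                                    universe)
        assert out.loc[0, "overlap"] == 3
        assert out.loc[0, "p"] == pytest.approx(exhaustive_ora_p(20, 5, 5, 3),
                                                abs=1e-12)

    def test_zero_overlap_vacuous(self):
        universe = [f"g{i}" for i in range(10)]
        out = en.ora_hypergeometric(universe[5:], GeneSetCollection(
            sets={"s": universe[:3]}), universe)
        assert out.loc[0, "overlap"] == 0 and out.loc[0, "p"] == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(8)]
        out = en.ora_hypergeometric(universe, GeneSetCollection(
            sets={"s": universe[:4]}), universe)
        assert out.loc[0, "overlap"] == 4 and out.loc[0, "p"] == pytest.approx(1.0)

    def test_query_outside_universe_listed(self):
        with pytest.raises(ValueError, match="outside"):
            en.ora_hypergeometric(["zzz"], GeneSetCollection(sets={"s": ["g1"]}),
                                  ["g1", "g2"])


class TestDiseaseZ:
    def _toy(self):
        # 2 genes x 6 cells, clusters 0 = first 3 cells
        V = np.array(
            [
                [5.0, 5.0, 5.0, 1.0, 1.0, 1.0],  # enriched in cluster 0
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # constant
            ]
        )
        em = ExprMatrix(["hi", "flat"], [f"c{i}" for i in range(6)], V, "log_cpm")
        lab = CellLabels(cell_ids=em.cell_ids,
                         cluster=np.array([0, 0, 0, 1, 1, 1]))
        return em, lab

    def test_hand_z_computation(self):
        em, lab = self._toy()
        res = en.disease_z(em, lab)
        # gene "hi": values +/-2 around mean 3, sd 2 -> cluster-0 mean z = 1
        assert res.cluster_z.loc["hi", 0] == pytest.approx(1.0)
        assert res.cluster_z.loc["hi", 1] == pytest.approx(-1.0)
        # 1 < 1.65, so nothing passes the cluster-enrichment cut...
        assert list(res.retained.index) == []
        # ...until the threshold drops below the gene's best cluster z
        res2 = en.disease_z(em, lab, z_threshold=0.9)
        assert list(res2.retained.index) == ["hi"]

    def test_constant_gene_excluded(self):
        em, lab = self._toy()
        res = en.disease_z(em, lab, z_threshold=0.5)
        assert "flat" in res.excluded

    def test_default_threshold(self):
        em, lab = self._toy()
        assert en.disease_z(em, lab).threshold == 1.65

    def test_restricts_to_disease_genes(self):
        em, lab = self._toy()
        dt = DiseaseGeneTable(rows=pd.DataFrame({"trait": ["t"], "gene": ["hi"]}))
        res = en.disease_z(em, lab, dt, z_threshold=0.9)
        assert list(res.cluster_z.index) == ["hi"]
        assert res.trait_view(dt, "t").shape[0] == 1
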