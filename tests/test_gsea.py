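"""Running-sum enrichment scores, permutation NES/FDR and NES clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from budnet.core_io import ExperimentTable, GeneSet, GeneSetCollection, RankedList
from budnet.gsea import (
    GseaParams,
    enrichment_score,
    make_ranked_list,
    nes_and_fdr,
    nes_matrix_cluster,
)


@pytest.fixture()
def four_gene_list():
    return RankedList([("g1", 2.0), ("g2", 1.0), ("g3", -1.0), ("g4", -2.0)])


class TestMakeRankedList:
    def test_ties_break_lexicographically(self):
        frame = pd.DataFrame({"gene": ["b", "a", "c"], "log_ratio": [0.0, 0.0, 1.0]})
        ranked = make_ranked_list(ExperimentTable("e", frame))
        assert ranked.genes == ["c", "a", "b"]

    def test_order_by_score(self):
        frame = pd.DataFrame({"gene": ["g1", "g2", "g3"], "log_ratio": [2.0, -1.0, 1.0]})
        ranked = make_ranked_list(ExperimentTable("e", frame))
        assert ranked.genes == ["g1", "g3", "g2"]


class TestEnrichmentScore:
    def test_single_top_hit_reaches_one(self, four_gene_list):
        es, _, edge = enrichment_score(four_gene_list, GeneSet("s", ["g1"]))
        assert es == pytest.approx(1.0)
        assert edge.keys == {"g1"}

    def test_bottom_hit_running_sum(self, four_gene_list):
        es, running, _ = enrichment_score(four_gene_list, GeneSet("s", ["g4"]))
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)
        assert es == pytest.approx(-1.0)

    def test_middle_hit_running_sum(self, four_gene_list):
        es, running, _ = enrichment_score(four_gene_list, GeneSet("s", ["g2"]))
        np.testing.assert_allclose(running, [-1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert es == pytest.approx(2 / 3)

    def test_disjoint_set_rejected(self, four_gene_list):
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(four_gene_list, GeneSet("s", ["zz"]))

    @pytest.mark.parametrize("seed", range(4))
    def test_unweighted_es_equals_ks_statistic(self, seed):
        """With weight 0 the |ES| is the two-sample KS statistic on hit ranks."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        genes = [f"g{i:02d}" for i in range(n)]
        ranked = RankedList(zip(genes, rng.normal(size=n)))
        m = int(rng.integers(2, n - 1))
        members = rng.choice(genes, size=m, replace=False)
        es, _, _ = enrichment_score(ranked, GeneSet("s", members), weight_exponent=0.0)
        member_keys = {g.casefold() for g in members}
        positions = np.arange(n)
        hit_pos = positions[[k in member_keys for k in ranked.keys]]
        miss_pos = positions[[k not in member_keys for k in ranked.keys]]
        ks = ks_2samp(hit_pos, miss_pos, method="exact").statistic
        assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_running_sum_ends_at_zero_when_unweighted(self, four_gene_list):
        _, running, _ = enrichment_score(four_gene_list, GeneSet("s", ["g1", "g3"]), 0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        ranked = RankedList(zip(genes, rng.normal(size=50)))
        for m in (2, 10, 25):
            es, _, _ = enrichment_score(ranked, GeneSet("s", genes[:m]))
            assert abs(es) <= 1.0 + 1e-12


class TestNesAndFdr:
    def test_exhaustive_singleton_null(self, four_gene_list):
        """All C(4,1) sets are enumerated; observed {g1} sits at p = 1/2."""
        coll = GeneSetCollection([GeneSet("top", ["g1"])])
        res = nes_and_fdr(four_gene_list, coll,
                          GseaParams(min_set_size=1, n_permutations=10, rng_seed=0))
        assert res[0].perm_p == pytest.approx(0.5)

    def test_uncorrelated_set_is_null_like(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(500)]
        ranked = RankedList(zip(genes, rng.normal(size=500)))
        members = rng.choice(genes, size=30, replace=False)
        coll = GeneSetCollection([GeneSet("random", members)])
        res = nes_and_fdr(ranked, coll, GseaParams(n_permutations=500, rng_seed=3))[0]
        assert abs(res.nes) < 2.0
        assert res.fdr > 0.05

    def test_planted_set_attains_top_nes(self, bundle):
        from budnet.gsea import make_ranked_list as mk

        ranked = mk(bundle["experiments"][0])
        res = nes_and_fdr(ranked, bundle["genesets"],
                          GseaParams(n_permutations=500, rng_seed=1))
        by_nes = sorted(res, key=lambda r: -r.nes)
        assert by_nes[0].set_name.startswith("planted")
        assert by_nes[0].fdr < 0.05

    def test_invariant_to_relabeling_outside_sets(self, four_gene_list):
        coll = GeneSetCollection([GeneSet("s", ["g1", "g2"])])
        params = GseaParams(min_set_size=1, n_permutations=50, rng_seed=4)
        res_a = nes_and_fdr(four_gene_list, coll, params)[0]
        renamed = RankedList([("g1", 2.0), ("g2", 1.0), ("zz", -1.0), ("qq", -2.0)])
        res_b = nes_and_fdr(renamed, coll, params)[0]
        assert res_a.es == pytest.approx(res_b.es)
        assert res_a.perm_p == pytest.approx(res_b.perm_p)
        assert res_a.nes == pytest.approx(res_b.nes)

    def test_empty_after_filter_returns_empty(self, four_gene_list):
        coll = GeneSetCollection([GeneSet("tiny", ["g1"])])
        assert nes_and_fdr(four_gene_list, coll, GseaParams(min_set_size=2)) == []

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:03d}" for i in range(200)]
        ranked = RankedList(zip(genes, rng.normal(size=200)))
        coll = GeneSetCollection([GeneSet("s", genes[:20])])
        params = GseaParams(n_permutations=200, rng_seed=11)
        a = nes_and_fdr(ranked, coll, params)[0]
        b = nes_and_fdr(ranked, coll, params)[0]
        assert (a.nes, a.perm_p, a.fdr) == (b.nes, b.perm_p, b.fdr)


class TestNesMatrixCluster:
    def test_identical_rows_adjacent(self):
        frame = pd.DataFrame(
            {"s1": [1.0, 5.0, 1.0], "s2": [2.0, 6.0, 2.0]},
            index=["a", "far", "twin"],
        )
        clustered, row_nwk, _ = nes_matrix_cluster(frame)
        order = list(clustered.index)
        assert abs(order.index("a") - order.index("twin")) == 1

    def test_row_permutation_does_not_change_leaf_order(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(6, 4)),
                             index=[f"r{i}" for i in range(6)],
                             columns=[f"c{j}" for j in range(4)])
        a, nwk_a, _ = nes_matrix_cluster(frame)
        shuffled = frame.sample(frac=1, random_state=1)
        b, nwk_b, _ = nes_matrix_cluster(shuffled)
        assert list(a.index) == list(b.index)
        assert nwk_a == nwk_b

    def test_two_block_matrix_orders_blocks(self):
        block = pd.DataFrame(
            [[5.0, 5.0, 0.0, 0.0], [5.1, 4.9, 0.0, 0.1],
             [0.0, 0.1, 5.0, 5.0], [0.1, 0.0, 4.9, 5.1]],
            index=["a1", "a2", "b1", "b2"], columns=list("wxyz"),
        )
        clustered, _, _ = nes_matrix_cluster(block)
        order = list(clustered.index)
        assert {order[0], order[1]} in ({"a1", "a2"}, {"b1", "b2"})

    def test_single_row_identity(self):
        frame = pd.DataFrame({"x": [1.0], "y": [2.0]}, index=["only"])
        clustered, row_nwk, _ = nes_matrix_cluster(frame)
        assert list(clustered.index) == ["only"]
        assert row_nwk == "only;"


class TestTypeOneError:
    def test_perm_p_calibrated_under_null_ranking(self):
        """At a 0.05 threshold the rejection rate sits in the 99% MC band."""
        n, m, reps = 300, 20, 1000
        genes = [f"g{i:03d}" for i in range(n)]
        members = genes[:m]
        coll = GeneSetCollection([GeneSet("s", members)])
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(reps):
            ranked = RankedList(zip(genes, rng.normal(size=n)))
            res = nes_and_fdr(ranked, coll,
                              GseaParams(n_permutations=199, rng_seed=rep))[0]
            if res.perm_p <= 0.05:
                hits += 1
        rate = hits / reps
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half_width <= rate <= 0.05 + half_width
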