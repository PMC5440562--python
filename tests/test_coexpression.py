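"""Coexpression similarity, seed clustering, expansion and validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from budnet.coexpression import (
    coexpr_matrix,
    expand_cluster,
    grn_overlap,
    hcluster_seed,
    validate_induction,
)
from budnet.core_io import CoexpressionCompendium, ExperimentTable, GeneSet
from budnet.synthetic import ModuleSpec, SyntheticSpec, gen_compendium


def _compendium(rows: dict[str, list[float]]) -> CoexpressionCompendium:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    return CoexpressionCompendium(frame)


class TestCoexprMatrix:
    def test_hand_computed_pearson(self):
        comp = _compendium({"x": [1, 2, 3], "y": [3, 2, 1], "z": [1, 2, 2]})
        sim = coexpr_matrix(comp, "pearson")
        assert sim.matrix[sim.loc("x"), sim.loc("y")] == pytest.approx(-1.0)
        assert sim.matrix[sim.loc("x"), sim.loc("z")] == pytest.approx(0.866, abs=5e-4)

    def test_identical_vectors_have_mutual_rank_one(self):
        comp = _compendium(
            {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [4, 1, 3, 2], "d": [2, 2, 1, 4]}
        )
        sim = coexpr_matrix(comp, "mutual_rank")
        assert sim.matrix[sim.loc("a"), sim.loc("b")] == pytest.approx(1.0)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(6, 10)),
                             index=[f"g{i}" for i in range(6)])
        perm = rng.permutation(10)
        a = coexpr_matrix(CoexpressionCompendium(frame), "pearson")
        b = coexpr_matrix(CoexpressionCompendium(frame.iloc[:, perm]), "pearson")
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_constant_gene_excluded(self):
        comp = _compendium({"flat": [1, 1, 1, 1], "a": [1, 2, 3, 4], "b": [2, 1, 4, 3]})
        sim = coexpr_matrix(comp, "pearson")
        assert "flat" not in sim
        assert "a" in sim

    def test_requires_three_samples(self):
        comp = _compendium({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError, match="3 samples"):
            coexpr_matrix(comp)


class TestHclusterSeed:
    @pytest.fixture()
    def two_block_sim(self):
        spec = SyntheticSpec(
            n_genes=60, n_samples=100, seed=13,
            modules=[ModuleSpec(size=10, rho=0.9), ModuleSpec(size=10, rho=0.9)],
        )
        comp, truth = gen_compendium(spec)
        return coexpr_matrix(comp, "pearson"), truth

    def test_two_planted_blocks_recovered_exactly(self, two_block_sim):
        sim, truth = two_block_sim
        seed = GeneSet("seed", truth.module_genes(0) + truth.module_genes(1))
        clusters = hcluster_seed(seed, sim, k=2)
        got = {c.keys for c in clusters}
        want = {truth.module_geneset(0).keys, truth.module_geneset(1).keys}
        assert got == want

    def test_k_equals_n_gives_singletons(self, two_block_sim):
        sim, truth = two_block_sim
        seed = GeneSet("seed", truth.module_genes(0))
        clusters = hcluster_seed(seed, sim, k=10)
        assert sorted(len(c) for c in clusters) == [1] * 10

    def test_clusters_partition_seed(self, similarity, seed_list):
        clusters = hcluster_seed(seed_list, similarity, k=4)
        union = set()
        for c in clusters:
            assert not (union & c.keys)
            union |= c.keys
        assert union == seed_list.keys

    def test_k_too_large_rejected(self, two_block_sim):
        sim, truth = two_block_sim
        seed = GeneSet("seed", truth.module_genes(0))
        with pytest.raises(ValueError, match="exceeds"):
            hcluster_seed(seed, sim, k=11)


class TestExpandCluster:
    def test_identical_gene_ranks_first(self):
        comp = _compendium(
            {"m1": [1, 2, 3, 4], "twin": [2, 4, 6, 8],
             "noise": [4, 1, 2, 2], "anti": [4, 3, 2, 1]}
        )
        sim = coexpr_matrix(comp, "pearson")
        ranked = expand_cluster(GeneSet("c", ["m1"]), sim, top_n=3)
        assert ranked[0][0] == "twin"

    def test_planted_module_recovered_from_partial_cluster(self):
        spec = SyntheticSpec(
            n_genes=500, n_samples=200, seed=17,
            modules=[ModuleSpec(size=30, rho=0.8)],
        )
        comp, truth = gen_compendium(spec)
        sim = coexpr_matrix(comp, "mutual_rank")
        module = truth.module_genes(0)
        cluster = GeneSet("c", module[:10])
        top = {g for g, _ in expand_cluster(cluster, sim, top_n=25)}
        missing = set(module[10:]) - top
        assert not missing

    def test_top_n_zero_rejected(self, similarity):
        with pytest.raises(ValueError, match="top_n"):
            expand_cluster(GeneSet("c", ["G00000"]), similarity, top_n=0)

    def test_oversized_top_n_returns_all(self):
        comp = _compendium({"a": [1, 2, 3], "b": [3, 2, 1], "c": [1, 3, 2]})
        sim = coexpr_matrix(comp, "pearson")
        assert len(expand_cluster(GeneSet("c", ["a"]), sim, top_n=99)) == 2


class TestValidateInduction:
    def _experiments(self):
        frame = pd.DataFrame(
            {"gene": ["kept", "dropped"], "log_ratio": [np.log2(1.2), 0.1]}
        )
        return [ExperimentTable("e1", frame)]

    def test_boundary_candidate_kept_with_provenance(self):
        grn = validate_induction([("kept", 1.0), ("dropped", 0.9)], self._experiments())
        assert "kept" in grn.members and "dropped" not in grn.members
        assert grn.provenance["kept"] == ["e1"]

    def test_seed_cluster_always_included(self):
        seed = GeneSet("seed", ["dropped"])
        grn = validate_induction([], self._experiments(), seed_cluster=seed)
        assert "dropped" in grn.members
        assert grn.seed_cluster.keys <= grn.members.keys


class TestGrnOverlap:
    def _grn(self, label, genes):
        from budnet.coexpression import GRN

        return GRN(label=label, seed_cluster=GeneSet("s", []), members=GeneSet(label, genes))

    def test_hand_counts(self):
        a = self._grn("A", ["a", "b", "c"])
        b = self._grn("B", ["b", "c", "d", "e"])
        table = grn_overlap([a, b]).iloc[0]
        assert table["overlap"] == 2
        assert table["pct_of_smaller"] == pytest.approx(66.7, abs=0.05)
        assert table["jaccard"] == pytest.approx(2 / 5)

    def test_disjoint_and_identical(self):
        a = self._grn("A", ["a"])
        b = self._grn("B", ["b"])
        assert grn_overlap([a, b])["overlap"].iloc[0] == 0
        c = self._grn("C", ["x", "y"])
        d = self._grn("D", ["x", "y"])
        assert grn_overlap([c, d])["pct_of_smaller"].iloc[0] == 100.0
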