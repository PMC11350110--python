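import math

import dendropy
import numpy as np
import pytest

from bgcsurvey.io import read_newick
from bgcsurvey.phylo import (DistanceMatrix, PhyloError, bipartitions,
                             bootstrap_support, build_msa, congruence_report,
                             is_monophyletic, max_rf, nj_tree,
                             pairwise_distance, rf_distance)
from bgcsurvey.simulate import SimulationConfig, simulate_panel
from oracles import brute_rf, newick_splits


def _random_tree_newick(labels, seed):
    """Random binary topology by repeatedly joining two random subtrees."""
    rng = np.random.default_rng(seed)
    nodes = [f"{x}:0.1" for x in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):0.1")
    return f"({nodes[0]},{nodes[1]});"


class TestBuildMsa:
    def test_identical_sequences_no_gaps(self):
        msa = build_msa({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert msa == {"a": "ACGTACGT", "b": "ACGTACGT"}

    def test_single_deletion_adds_one_gap_column(self):
        msa = build_msa({"a": "ACGT", "b": "ACT"})
        assert len(msa["a"]) == len(msa["b"]) == 4
        assert msa["b"].count("-") == 1

    def test_column_count_at_least_max_input_length(self):
        seqs = {"a": "ACGTACGTAA", "b": "ACGTATTACGTAA", "c": "ACGTACG"}
        msa = build_msa(seqs)
        width = {len(s) for s in msa.values()}
        assert len(width) == 1
        assert width.pop() >= max(len(s) for s in seqs.values())
        for name, s in seqs.items():
            assert msa[name].replace("-", "") == s

    def test_fewer_than_two_rejected(self):
        with pytest.raises(PhyloError):
            build_msa({"a": "ACGT"})


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        d = pairwise_distance({"a": "ACGTAC", "b": "ACGTAC"}, "p")
        assert d.value("a", "b") == 0.0

    def test_quarter_p_distance(self):
        d = pairwise_distance({"a": "ACGT", "b": "ACGA"}, "p")
        assert d.value("a", "b") == 0.25

    def test_jc69_closed_form(self):
        """p = 0.3 -> d = -0.75 ln(1 - 0.4) = 0.38312 (5 dp)."""
        a = "A" * 100
        b = "C" * 30 + "A" * 70
        d = pairwise_distance({"a": a, "b": b}, "jc69")
        assert d.value("a", "b") == pytest.approx(-0.75 * math.log(0.6),
                                                  abs=1e-9)
        assert round(d.value("a", "b"), 5) == 0.38312

    def test_jc69_approaches_p_at_small_divergence(self):
        a = "A" * 100
        b = "C" + "A" * 99
        p = pairwise_distance({"a": a, "b": b}, "p").value("a", "b")
        j = pairwise_distance({"a": a, "b": b}, "jc69").value("a", "b")
        assert abs(j - p) / p < 0.01

    def test_saturated_pairs_capped_and_reported(self):
        d = pairwise_distance({"a": "ACGT" * 5, "b": "CATG" * 5}, "jc69")
        assert d.value("a", "b") == 5.0
        assert ("a", "b") in d.saturated

    def test_gap_columns_pairwise_deleted(self):
        d = pairwise_distance({"a": "AC-TAC", "b": "ACGTAC"}, "p")
        assert d.value("a", "b") == 0.0

    def test_k2p_distinguishes_transitions(self):
        # one transition (A->G) in 100 bases
        a = "A" * 100
        b = "G" + "A" * 99
        k = pairwise_distance({"a": a, "b": b}, "k2p").value("a", "b")
        j = pairwise_distance({"a": a, "b": b}, "jc69").value("a", "b")
        assert k == pytest.approx(j, rel=0.05)


class TestNjTree:
    def test_exact_recovery_of_additive_matrix(self):
        """NJ inverts the additive matrix of ((a:1,b:2):1,(c:3,d:4):1)."""
        labels = ["a", "b", "c", "d"]
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels, m))
        pdm = t.phylogenetic_distance_matrix()
        for i in range(4):
            for j in range(i + 1, 4):
                ti = t.taxon_namespace.get_taxon(labels[i])
                tj = t.taxon_namespace.get_taxon(labels[j])
                assert pdm.distance(ti, tj) == pytest.approx(m[i, j], abs=1e-9)

    def test_taxon_order_invariance(self):
        labels = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 2, size=(5, 5))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        t1 = nj_tree(DistanceMatrix(labels, m))
        perm = [3, 1, 4, 0, 2]
        m2 = m[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix([labels[i] for i in perm], m2))
        s1 = {frozenset(b) for b in bipartitions(t1)}
        s2 = {frozenset(b) for b in bipartitions(t2)}
        assert s1 == s2

    def test_three_taxa_star_with_exact_lengths(self):
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        pdm = t.phylogenetic_distance_matrix()
        ta = t.taxon_namespace.get_taxon("a")
        tb = t.taxon_namespace.get_taxon("b")
        assert pdm.distance(ta, tb) == pytest.approx(2.0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestBootstrap:
    def test_identical_sequences_degenerate(self):
        msa = {c: "ACGTACGTAC" for c in "abcd"}
        support = bootstrap_support(msa, n_reps=10, seed=1)
        assert support.supports == {}

    def test_separated_clades_strong_support(self):
        """Two 4-taxon clades at divergence ~0.2 between / ~0.01 within:
        the central split gets >= 95% support at 200 replicates."""
        res = simulate_panel(SimulationConfig(
            species_tree="(((GenA_s1:0.01,GenA_s2:0.01):0.005,"
                         "(GenA_s3:0.01,GenA_s4:0.01):0.005):0.1,"
                         "((GenB_s1:0.01,GenB_s2:0.01):0.005,"
                         "(GenB_s3:0.01,GenB_s4:0.01):0.005):0.1);",
            n_lineages=8, seed=17))
        msa = build_msa(res.markers)
        support = bootstrap_support(msa, n_reps=200, seed=4)
        central = frozenset({"GenA_s1", "GenA_s2", "GenA_s3", "GenA_s4"})
        assert support.supports[central] >= 95.0

    def test_deterministic_under_seed(self, small_panel):
        msa = build_msa(small_panel.markers)
        s1 = bootstrap_support(msa, n_reps=30, seed=9)
        s2 = bootstrap_support(msa, n_reps=30, seed=9)
        assert s1.supports == s2.supports


class TestRfDistance:
    def test_identical_trees_zero(self):
        t1 = read_newick("((a,b),(c,d),(e,f));")
        t2 = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick",
                               taxon_namespace=t1.taxon_namespace)
        assert rf_distance(t1, t2) == 0

    def test_two_quartet_resolutions_differ_by_two(self):
        """Distinct 4-taxon resolutions each have one non-trivial split;
        the splits differ, so RF = 2 (verified by enumeration)."""
        n1, n2 = "((a,b),(c,d));", "((a,c),(b,d));"
        t1 = read_newick(n1)
        t2 = dendropy.Tree.get(data=n2, schema="newick",
                               taxon_namespace=t1.taxon_namespace)
        assert rf_distance(t1, t2) == brute_rf(n1, n2) == 2

    def test_star_vs_resolved(self):
        star = read_newick("(a,b,c,d,e);")
        resolved = dendropy.Tree.get(data="(((a,b),c),(d,e));",
                                     schema="newick",
                                     taxon_namespace=star.taxon_namespace)
        assert rf_distance(star, resolved) == len(
            newick_splits("(((a,b),c),(d,e));"))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_bipartition_enumeration(self, seed):
        """Random pairs of trees on <= 8 taxa vs the brute-force oracle."""
        labels = [f"t{i}" for i in range(8)]
        n1 = _random_tree_newick(labels, seed)
        n2 = _random_tree_newick(labels, seed + 100)
        t1 = read_newick(n1)
        t2 = dendropy.Tree.get(data=n2, schema="newick",
                               taxon_namespace=t1.taxon_namespace)
        assert rf_distance(t1, t2) == brute_rf(n1, n2)

    def test_different_leaf_sets_rejected_unless_pruned(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,b),(c,e));")
        with pytest.raises(PhyloError):
            rf_distance(t1, t2)


class TestCongruence:
    def test_identical_trees_fully_congruent(self):
        t1 = read_newick("(((a1,a2),a3),((b1,b2),b3));")
        t2 = read_newick("(((a1,a2),a3),((b1,b2),b3));")
        genus = {x: x[0] for x in ("a1", "a2", "a3", "b1", "b2", "b3")}
        rep = congruence_report(t1, t2, genus)
        assert rep.rf == 0 and rep.normalized_rf == 0.0
        assert rep.displaced_leaves == []
        assert all(rep.genus_monophyly_cluster.values())

    def test_one_genus_per_leaf_trivially_monophyletic(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        rep = congruence_report(t1, t2, {x: x for x in "abcd"})
        assert all(rep.genus_monophyly_cluster.values())
        assert all(rep.genus_monophyly_species.values())

    def test_monophyly_unrooted_semantics(self):
        t = read_newick("((a1,a2),(b1,b2));")
        assert is_monophyletic(t, {"a1", "a2"})
        assert not is_monophyletic(t, {"a1", "b1"})

    def test_max_rf_normalization(self):
        assert max_rf(10) == 14
        assert max_rf(4) == 2

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_hgt_recipient_reported_displaced(self, seed):
        """A cross-genus transfer puts the recipient inside the donor's
        clade in the cluster tree; the congruence report names it."""
        tree = ("(((GenA_s1:0.03,GenA_s2:0.03):0.03,"
                "(GenA_s3:0.03,GenA_s4:0.03):0.03):0.15,"
                "((GenB_s1:0.03,GenB_s2:0.03):0.03,"
                "(GenB_s3:0.03,GenB_s4:0.03):0.03):0.15);")
        res = simulate_panel(SimulationConfig(
            species_tree=tree, n_lineages=8, seed=seed,
            hgt_events=(("GenA_s1", "GenB_s2"),)))
        cl = {s: res.genomes[s].contigs[0][1][r.start:r.end]
              for s, r in res.truth.items()}
        ct = nj_tree(pairwise_distance(build_msa(cl), "jc69"))
        st_ = nj_tree(pairwise_distance(build_msa(res.markers), "jc69"))
        rep = congruence_report(ct, st_, res.taxa)
        assert "GenB_s2" in rep.displaced_leaves

    def test_no_hgt_panels_congruent(self, small_panel):
        res = small_panel
        cl = {s: res.genomes[s].contigs[0][1][r.start:r.end]
              for s, r in res.truth.items()}
        ct = nj_tree(pairwise_distance(build_msa(cl), "jc69"))
        st_ = nj_tree(pairwise_distance(build_msa(res.markers), "jc69"))
        rep = congruence_report(ct, st_, res.taxa)
        assert rep.normalized_rf <= 0.1
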