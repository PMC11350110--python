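import numpy as np
import pytest
from Bio.Seq import Seq

from bgcsurvey.flanks import (FlankError, Orf, build_flank_profiles,
                              conservation_matrix, detect_interrupted_genes,
                              extract_flanks, flag_mobile_elements,
                              group_homologs, jaccard, predict_orfs)
from bgcsurvey.io import revcomp
from bgcsurvey.simulate import (SimulationConfig, inject_frameshift,
                                mge_reference_proteins, random_coding_gene,
                                simulate_panel)
from oracles import six_frame_orfs


class TestExtractFlanks:
    SEQ = "".join(np.random.default_rng(1).choice(list("ACGT"), size=30_000))

    def test_centered_cluster_full_flanks(self):
        up, dn = extract_flanks(self.SEQ, 12_000, 18_000, "+", 5000)
        assert len(up.sequence) == 5000 and len(dn.sequence) == 5000
        assert not up.truncated and not dn.truncated
        assert up.sequence == self.SEQ[7000:12_000]

    def test_cluster_at_contig_start_truncates_upstream(self):
        up, dn = extract_flanks(self.SEQ, 0, 6000, "+", 5000)
        assert up.sequence == "" and up.truncated

    def test_minus_strand_swaps_and_reverse_complements(self):
        up, dn = extract_flanks(self.SEQ, 12_000, 18_000, "-", 5000)
        assert up.sequence == revcomp(self.SEQ[18_000:23_000])
        assert dn.sequence == revcomp(self.SEQ[7000:12_000])

    def test_span_outside_contig_rejected(self):
        with pytest.raises(FlankError):
            extract_flanks(self.SEQ, 29_000, 31_000)


class TestPredictOrfs:
    def test_forced_reading_single_orf(self):
        orfs = predict_orfs("ATGAAATAA", min_length=9)
        assert len(orfs) == 1
        assert orfs[0].protein == "MK"
        assert orfs[0].length % 3 == 0

    def test_huge_min_length_empty(self):
        seq = random_coding_gene(900, 50, np.random.default_rng(2))
        assert predict_orfs(seq, min_length=1_000_000) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_six_frame_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        got = {(o.start, o.end, o.strand) for o in predict_orfs(seq, 150)}
        assert got == six_frame_orfs(seq, 150)

    def test_translation_table_11_gtg_start(self):
        # GTG start translates as M in bacterial practice; table 11 allows it
        orfs = predict_orfs("GTGAAATAA", min_length=9)
        assert len(orfs) == 1

    def test_no_two_orfs_share_a_stop_in_frame(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=6000))
        seen = set()
        for o in predict_orfs(seq, 150):
            key = (o.strand, o.end if o.strand == "+" else o.start, o.frame)
            assert key not in seen
            seen.add(key)


class TestGroupHomologs:
    def _orf(self, prot, i):
        return Orf(start=i * 1000, end=i * 1000 + 3 * len(prot), strand="+",
                   frame=0, protein=prot, contig=f"s{i}")

    def test_identical_proteins_one_group(self):
        p = "MKLVWEERTANNPQ" * 5
        groups = group_homologs([("a", self._orf(p, 0)), ("b", self._orf(p, 1))])
        assert len(groups) == 1

    def test_unrelated_random_proteins_two_groups(self):
        rng = np.random.default_rng(3)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        p1 = "M" + "".join(rng.choice(aa, size=99))
        p2 = "M" + "".join(rng.choice(aa, size=99))
        groups = group_homologs([("a", self._orf(p1, 0)),
                                 ("b", self._orf(p2, 1))])
        assert len(groups) == 2

    def test_single_linkage_chains_transitively(self):
        # A~B and B~C above the cutoff, A~C far below: one group
        base = "MKLVWEERTANNPQHHGFDSAEKLMNPQRSTVW"
        a = base * 3
        b = (base * 2) + "G" * 33
        c = base + "G" * 66
        groups = group_homologs([("x", self._orf(a, 0)),
                                 ("y", self._orf(b, 1)),
                                 ("z", self._orf(c, 2))], min_identity=30.0)
        assert len(groups) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        prots = ["M" + "".join(rng.choice(aa, size=60)) for _ in range(5)]
        items = [(f"s{i}", self._orf(p, i)) for i, p in enumerate(prots)]
        g1 = group_homologs(items)
        g2 = group_homologs(items[::-1])
        sets1 = sorted(sorted(m[0] for m in g.members) for g in g1)
        sets2 = sorted(sorted(m[0] for m in g.members) for g in g2)
        assert sets1 == sets2

    def test_empty_rejected(self):
        with pytest.raises(FlankError):
            group_homologs([])


class TestConservation:
    def test_identical_and_disjoint_jaccard(self):
        assert jaccard(frozenset("ab"), frozenset("ab")) == 1.0
        assert jaccard(frozenset("ab"), frozenset("cd")) == 0.0

    def test_sister_jaccard_tracks_flank_conservation(self):
        """flank_conservation 0.5 between sisters -> mean sister Jaccard
        within +/-0.15 of 0.5 (measured through the full ORF/grouping path)."""
        tree = ("((GenA_s1:0.02,GenA_s2:0.02):0.05,"
                "(GenB_s1:0.02,GenB_s2:0.02):0.05);")
        res = simulate_panel(SimulationConfig(
            species_tree=tree, n_lineages=4, seed=7, flank_conservation=0.5))
        fl = {}
        for s, r in res.truth.items():
            seq = res.genomes[s].contigs[0][1]
            fl[s] = extract_flanks(seq, r.start, r.end, "+", 5000)
        profiles = build_flank_profiles(fl, "clust")
        pro = {p.strain: p for p in profiles}
        js = [jaccard(pro[a].group_set, pro[b].group_set)
              for a, b in (("GenA_s1", "GenA_s2"), ("GenB_s1", "GenB_s2"))]
        assert abs(np.mean(js) - 0.5) <= 0.15

    def test_conservation_matrix_shapes(self, small_panel):
        res = small_panel
        fl = {}
        for s in ("GenA_s1", "GenA_s2", "GenB_s1"):
            r = res.truth[s]
            seq = res.genomes[s].contigs[0][1]
            fl[s] = extract_flanks(seq, r.start, r.end, "+", 5000)
        profiles = build_flank_profiles(fl, "clust")
        presence, jac = conservation_matrix(profiles)
        assert presence.shape[0] == 3 and jac.shape == (3, 3)
        assert (np.diag(jac.values) == 1.0).all()

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(FlankError):
            conservation_matrix([])


class TestMobileElements:
    def _orf(self, prot="MKL" * 40, ann=""):
        return Orf(start=0, end=3 * len(prot), strand="+", frame=0,
                   protein=prot, contig="c", annotation=ann)

    def test_lysr_regulator_not_flagged(self):
        o = self._orf(ann="LysR-family transcriptional regulator")
        flags = flag_mobile_elements([o], annotations={o.key: o.annotation})
        assert flags[o.key] is False

    def test_is3_transposase_flagged(self):
        o = self._orf(ann="IS3 family transposase")
        flags = flag_mobile_elements([o], annotations={o.key: o.annotation})
        assert flags[o.key] is True

    def test_tra_gene_flagged_but_transcription_not(self):
        a = self._orf(ann="conjugal transfer protein TraI")
        b = self._orf(ann="transcription antitermination factor")
        b.start, b.end = 5000, 5000 + 3 * len(b.protein)
        flags = flag_mobile_elements(
            [a, b], annotations={a.key: a.annotation, b.key: b.annotation})
        assert flags[a.key] is True

    def test_simulated_remnant_flagged_via_reference_route(self):
        res = simulate_panel(SimulationConfig(
            species_tree="(GenA_s1:0.01,GenA_s2:0.01);", n_lineages=2,
            seed=13, mge_prob=1.0))
        r = res.truth["GenA_s1"]
        seq = res.genomes["GenA_s1"].contigs[0][1]
        # remnant sits within 1 kb downstream of the cluster edge
        window = seq[r.end:r.end + 1000]
        orfs = predict_orfs(window, min_length=150)
        flags = flag_mobile_elements(
            orfs, reference_proteins=mge_reference_proteins())
        assert any(flags.values())

    def test_no_source_rejected(self):
        with pytest.raises(FlankError):
            flag_mobile_elements([self._orf()])


class TestInterruptedGenes:
    def _setup(self, seed, frameshift=True):
        rng = np.random.default_rng(seed)
        gene = random_coding_gene(720, 45, rng)
        ref = {"acbC_like": str(Seq(gene).translate(table=11)).rstrip("*")}
        if frameshift:
            pos = int(rng.integers(200, 500))
            gene = inject_frameshift(gene, pos, "deletion", seed=seed)
        ctx = "".join(rng.choice(list("ACGT"), size=300))
        orfs = predict_orfs(ctx + gene + ctx, min_length=90)
        return orfs, ref

    def test_intact_gene_no_candidate(self):
        orfs, ref = self._setup(1, frameshift=False)
        assert detect_interrupted_genes(orfs, ref) == []

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_frameshifted_gene_detected(self, seed):
        orfs, ref = self._setup(seed, frameshift=True)
        cands = detect_interrupted_genes(orfs, ref)
        assert [c.gene for c in cands] == ["acbC_like"]
        assert all(len(c.orfs) >= 2 for c in cands)

    def test_adjacent_orfs_of_different_genes_no_candidate(self):
        rng = np.random.default_rng(9)
        g1 = random_coding_gene(450, 45, rng)
        g2 = random_coding_gene(450, 45, rng)
        refs = {"g1": str(Seq(g1).translate(table=11)).rstrip("*"),
                "g2": str(Seq(g2).translate(table=11)).rstrip("*")}
        orfs = predict_orfs(g1 + "AC" + g2, min_length=150)
        assert detect_interrupted_genes(orfs, refs) == []

    def test_reference_required(self):
        with pytest.raises(FlankError):
            detect_interrupted_genes([], {})

    def test_recall_and_fpr_on_panel(self):
        """Recall >= 0.9 / FPR <= 0.05 at frameshift_prob 0.3, divergence
        <= 10%, measured per cluster gene over a 6-strain panel."""
        tree = ("((GenA_s1:0.02,GenA_s2:0.02):0.03,"
                "((GenA_s3:0.02,GenA_s4:0.02):0.03,"
                "(GenB_s1:0.02,GenB_s2:0.02):0.03):0.01);")
        res = simulate_panel(SimulationConfig(
            species_tree=tree, n_lineages=6, seed=31, frameshift_prob=0.3))
        refs = {g.name: str(Seq(res.template.gene_seq(g)).translate(
            table=11)).rstrip("*") for g in res.template.genes}
        tp = fn = fp = tn = 0
        for strain, rec in res.truth.items():
            seq = res.genomes[strain].contigs[0][1]
            region = seq[max(0, rec.start - 200):rec.end + 200]
            orfs = predict_orfs(region, min_length=90)
            found = {c.gene for c in detect_interrupted_genes(orfs, refs)}
            broken = {g for g, _, _ in rec.frameshifts}
            for g in refs:
                if g in broken:
                    tp += g in found
                    fn += g not in found
                else:
                    fp += g in found
                    tn += g not in found
        assert tp + fn > 0
        assert tp / (tp + fn) >= 0.9
        assert fp / max(fp + tn, 1) <= 0.05
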