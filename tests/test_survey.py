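import numpy as np
import pytest

from bgcsurvey.io import GenomeRecord, revcomp
from bgcsurvey.simulate import SimulationConfig, make_cluster_template, \
    simulate_panel
from bgcsurvey.survey import (GeneMatch, SurveyError, SurveyParams, align_pair,
                              check_synteny, detect_cluster,
                              find_candidate_loci, prevalence, survey_panel)
from oracles import dp_align


def _random_seq(n, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))


class TestAlignPair:
    def test_identical(self):
        identity, cov, _ = align_pair("ACGT", "ACGT")
        assert identity == 100.0 and cov == 1.0

    def test_single_mismatch(self):
        identity, _, _ = align_pair("ACGT", "ACGA")
        assert identity == 75.0

    def test_local_exact_substring(self):
        query = "ACGTACGTAC"
        subject = _random_seq(45, 1) + query + _random_seq(45, 2)
        identity, cov, _ = align_pair(query, subject, mode="local")
        assert identity == 100.0 and cov == 1.0

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(SurveyError):
            align_pair("ACGT", "MKWLPEF")

    def test_empty_rejected(self):
        with pytest.raises(SurveyError):
            align_pair("", "ACGT")

    def test_global_symmetric_on_equal_length(self):
        a, b = _random_seq(80, 3), _random_seq(80, 4)
        ia, _, _ = align_pair(a, b)
        ib, _, _ = align_pair(b, a)
        assert ia == pytest.approx(ib, abs=1e-9)

    @pytest.mark.parametrize("seed,n,rate", [
        (0, 120, 0.1), (1, 200, 0.2), (2, 60, 0.4), (3, 350, 0.05),
        (4, 500, 0.15),
    ])
    def test_identity_matches_full_dp_oracle(self, seed, n, rate):
        """Substitution-mutated equal-length pairs have a unique optimal
        alignment; implementation identity must equal the brute-force DP's."""
        rng = np.random.default_rng(seed)
        a = _random_seq(n, seed + 10)
        b = list(a)
        for i in range(n):
            if rng.random() < rate:
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        b = "".join(b)
        identity, _, _ = align_pair(a, b)
        _, oracle_identity = dp_align(a, b, mode="global")
        assert identity == pytest.approx(oracle_identity, abs=1.0)

    @pytest.mark.parametrize("seed,na,nb", [(1, 200, 180), (2, 60, 75),
                                            (5, 150, 140)])
    def test_alignment_score_matches_full_dp_oracle(self, seed, na, nb):
        """Even with co-optimal paths the optimal score is unique."""
        from bgcsurvey.survey import _make_aligner
        a, b = _random_seq(na, seed + 20), _random_seq(nb, seed + 21)
        impl_score = _make_aligner("global").score(a, b)
        oracle_score, _ = dp_align(a, b, mode="global")
        assert impl_score == pytest.approx(oracle_score, abs=1e-9)

    def test_glocal_exact_embedded_query(self):
        query = _random_seq(100, 30)
        subject = _random_seq(200, 31) + query + _random_seq(200, 32)
        identity, cov, _ = align_pair(query, subject, mode="glocal")
        assert identity == 100.0 and cov == 1.0


class TestCandidateDetection:
    @pytest.fixture(scope="class")
    def template(self):
        return make_cluster_template(gc_percent=45, seed=1)

    def test_verbatim_implant_found(self, template):
        genome_seq = _random_seq(20_000, 5) + template.sequence \
            + _random_seq(20_000, 6)
        g = GenomeRecord("s", [("c1", genome_seq)])
        cands = find_candidate_loci(g, template)
        assert len(cands) == 1
        assert cands[0].start <= 20_000 and cands[0].end >= 20_000 + template.length

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_genome_has_no_candidates(self, template, seed):
        """Random 100-kb sequence yields no chain above the score floor."""
        g = GenomeRecord("r", [("c1", _random_seq(100_000, 100 + seed))])
        assert find_candidate_loci(g, template, k=11) == []

    def test_split_cluster_yields_candidate_per_contig(self, template):
        cut = template.genes[3].start - 10   # split at a gene boundary gap
        left = _random_seq(5000, 7) + template.sequence[:cut]
        right = template.sequence[cut:] + _random_seq(5000, 8)
        g = GenomeRecord("s", [("c1", left), ("c2", right)])
        cands = find_candidate_loci(g, template)
        assert {c.contig for c in cands} == {"c1", "c2"}

    def test_word_size_floor(self, template):
        g = GenomeRecord("s", [("c1", template.sequence)])
        with pytest.raises(SurveyError):
            find_candidate_loci(g, template, k=7)


class TestEvaluateCandidate:
    @pytest.fixture(scope="class")
    def template(self):
        return make_cluster_template(gc_percent=45, seed=2)

    def _genome_with(self, insert, seed=9):
        seq = _random_seq(8000, seed) + insert + _random_seq(8000, seed + 1)
        return GenomeRecord("s", [("c1", seq)])

    def test_verbatim_implant_accepted_at_full_identity(self, template):
        g = self._genome_with(template.sequence)
        hit = detect_cluster(g, template)
        assert hit.accepted and hit.complete and hit.syntenic
        assert hit.overall_identity == pytest.approx(100.0, abs=0.5)

    def test_single_gene_deletion_breaks_completeness(self, template):
        g2 = template.genes[2]
        seq = template.sequence[:g2.start] + template.sequence[g2.end:]
        hit = detect_cluster(self._genome_with(seq), template)
        assert not hit.complete and not hit.accepted

    def test_swapped_genes_break_synteny(self, template):
        g1, g2 = template.genes[1], template.genes[4]
        s = template.sequence
        swapped = (s[:g1.start] + s[g2.start:g2.end] + s[g1.end:g2.start]
                   + s[g1.start:g1.end] + s[g2.end:])
        hit = detect_cluster(self._genome_with(swapped), template)
        assert hit.complete
        assert not hit.syntenic and not hit.accepted

    def test_detection_invariant_under_reverse_complement(self, template):
        g = self._genome_with(template.sequence)
        rc = GenomeRecord("s", [("c1", revcomp(g.contigs[0][1]))])
        h1, h2 = detect_cluster(g, template), detect_cluster(rc, template)
        assert h1.accepted and h2.accepted
        assert h1.overall_identity == pytest.approx(h2.overall_identity,
                                                    abs=0.5)

    def test_detection_invariant_under_contig_split(self, template):
        seq = _random_seq(8000, 11) + template.sequence + _random_seq(8000, 12)
        whole = GenomeRecord("s", [("c1", seq)])
        split = GenomeRecord("s", [("c1", seq[:4000]), ("c2", seq[4000:])])
        h1, h2 = detect_cluster(whole, template), detect_cluster(split, template)
        assert h1.accepted and h2.accepted

    def test_cross_contig_hit_accepted_with_flag(self, template):
        cut = template.genes[3].start - 10
        g = GenomeRecord("s", [
            ("c1", _random_seq(5000, 13) + template.sequence[:cut]),
            ("c2", template.sequence[cut:] + _random_seq(5000, 14))])
        hit = detect_cluster(g, template)
        assert hit.accepted and hit.cross_contig

    def test_acceptance_monotone_in_identity_threshold(self, template):
        res = simulate_panel(SimulationConfig(
            species_tree="((GenA_s1:0.08,GenA_s2:0.08):0.05,"
                         "(GenB_s1:0.08,GenB_s2:0.08):0.05);",
            n_lineages=4, seed=21, cluster_template=template))
        for strain in res.genomes:
            accepted = []
            for thr in (20.0, 60.0, 95.0):
                hit = detect_cluster(res.genomes[strain], template,
                                     SurveyParams(min_cluster_identity=thr))
                accepted.append(hit.accepted)
            # once rejection starts it cannot revert at higher thresholds
            assert accepted == sorted(accepted, reverse=True)


class TestCheckSynteny:
    def _m(self, rank, pos, strand, tstrand="+"):
        return GeneMatch(gene=f"g{rank}", order_index=rank, contig="c",
                         start=pos, end=pos + 10, strand=strand,
                         template_strand=tstrand, identity=99.0, coverage=1.0)

    def test_in_order_same_strand(self):
        ms = [self._m(i, 100 * i, "+") for i in range(3)]
        assert check_synteny(ms)

    def test_out_of_order_fails(self):
        ms = [self._m(r, 100 * i, "+") for i, r in enumerate([0, 2, 1])]
        assert not check_synteny(ms)

    def test_whole_cluster_inversion_allowed(self):
        ms = [self._m(r, 100 * i, "-") for i, r in enumerate([2, 1, 0])]
        assert check_synteny(ms)

    def test_inversion_with_unflipped_strand_fails(self):
        ms = [self._m(2, 0, "-"), self._m(1, 100, "+"), self._m(0, 200, "-")]
        assert not check_synteny(ms)

    def test_empty_rejected(self):
        with pytest.raises(SurveyError):
            check_synteny([])


class TestPrevalence:
    @pytest.mark.parametrize("count,total,expected", [
        (178, 516, 34.496),
        (11, 354, 3.107),
        (0, 100, 0.0),
        (1, 2527, 0.040),
        (47, 2527, 1.860),
        (171, 12230, 1.398),
        (38, 23425, 0.162),
        (1, 6933, 0.014),
    ])
    def test_three_decimal_rounding(self, count, total, expected):
        assert prevalence(count, total) == pytest.approx(expected, abs=5e-4)

    def test_half_away_from_zero(self):
        # 100*1/1600 = 0.0625 -> 0.063 under half-away-from-zero
        assert prevalence(1, 1600) == 0.063

    def test_zero_total_rejected(self):
        with pytest.raises(SurveyError):
            prevalence(0, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(SurveyError):
            prevalence(5, 4)


class TestSurveyPanel:
    def test_half_carrier_panel_prevalence(self, mixed_panel):
        taxa = {s: "GenusX" for s in mixed_panel.genomes}
        hits, table = survey_panel(mixed_panel.genomes,
                                   [mixed_panel.template], taxa)
        row = table.iloc[0]
        # 4 carriers + 2 clones of a carrier = 6 of 10 genomes
        assert row["strains_with_cluster"] == 6
        assert row["genomes_surveyed"] == 10
        assert row["percent"] == 60.0

    def test_missing_taxon_bucketed_as_unknown(self, small_panel):
        taxa = {s: "GenA" for s in small_panel.genomes if s != "GenB_s4"}
        with pytest.warns(UserWarning, match="unknown"):
            _, table = survey_panel(small_panel.genomes,
                                    [small_panel.template], taxa)
        assert "unknown" in set(table["genus"])

    def test_outputs_written(self, small_panel, tmp_path):
        survey_panel(small_panel.genomes, [small_panel.template],
                     small_panel.taxa, out_dir=tmp_path)
        for name in ("hits.tsv", "prevalence.tsv", "hits.gff3"):
            assert (tmp_path / name).stat().st_size > 0
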