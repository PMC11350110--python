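"""Cluster-homolog detection and the survey inclusion filters.

A reference cluster is located in a genome by a seed-and-chain scan of
shared k-mers (word size 11 by default, the blastn sensitivity regime for
short words), then each cluster gene is aligned into the candidate region.
A hit is *accepted* only if it is complete (every query gene matched),
syntenic (gene order preserved, whole-cluster inversion allowed) and its
overall nucleotide identity across the query cluster clears the floor
(default 40%, i.e. candidates diverged by more than 60% are excluded).
Hits split across contigs in draft assemblies are kept when the split is
consistent with a single breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import edlib
import pandas as pd
from Bio import Align

from .io import (ClusterDefinition, GenomeRecord, Gff3Feature, revcomp,
                 write_gff3, write_tsv)

_NT = set("ACGTUN")


class SurveyError(ValueError):
    pass


@dataclass
class SurveyParams:
    min_cluster_identity: float = 40.0   # percent over the query length
    min_gene_coverage: float = 0.5       # fraction of each query gene
    word_size: int = 11
    min_chain_bases: int = 60            # seed chain score floor (matched bp)
    max_seed_gap: int = 3000             # bp between chained seeds
    max_diag_drift: int = 400            # bp of indel tolerated along a chain
    region_margin: int = 500             # bp added around a chained span


# ---------------------------------------------------------------------------
# Pairwise alignment


def _alphabet(seq: str) -> str:
    return "nt" if set(seq.upper()) <= _NT else "aa"


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    if mode == "glocal":
        # semi-global: a query measured inside a longer target; free target
        # end gaps make the optimum unique for an embedded exact copy
        aligner.mode = "global"
        try:
            aligner.end_insertion_score = 0.0   # Biopython >= 1.88 name
        except AttributeError:
            aligner.target_end_gap_score = 0.0
    else:
        aligner.mode = mode
    return aligner


def align_pair(a: str, b: str, mode: str = "global"
               ) -> tuple[float, float, list[tuple[int, int, int, int]]]:
    """Align two sequences; return (percent identity, query coverage, blocks).

    Identity is matches / aligned columns, where the columns are those of the
    alignment excluding end gaps (global mode) or within the local hit.
    Coverage is the fraction of ``a`` inside the aligned region. Blocks are
    (a_start, a_end, b_start, b_end) gapless segments. Besides the standard
    ``global``/``local`` modes a ``glocal`` mode (free end gaps on ``b``) is
    provided for measuring a query embedded in a longer region.
    """
    if not a or not b:
        raise SurveyError("empty sequence")
    if mode not in ("global", "local", "glocal"):
        raise SurveyError(f"unknown mode {mode!r}")
    if _alphabet(a) != _alphabet(b):
        raise SurveyError("mixed nucleotide/protein alphabets")
    a, b = a.upper(), b.upper()
    aln = _make_aligner(mode).align(a, b)[0]
    a_spans, b_spans = aln.aligned
    if len(a_spans) == 0:
        return 0.0, 0.0, []
    matches = mismatches = 0
    for (as_, ae), (bs, be) in zip(a_spans, b_spans):
        for x, y in zip(a[as_:ae], b[bs:be]):
            if x == y:
                matches += 1
            else:
                mismatches += 1
    gap_cols = 0
    for i in range(len(a_spans) - 1):
        gap_cols += (a_spans[i + 1][0] - a_spans[i][1]) \
            + (b_spans[i + 1][0] - b_spans[i][1])
    cols = matches + mismatches + gap_cols
    identity = 100.0 * matches / cols if cols else 0.0
    a_aln = int(a_spans[-1][1] - a_spans[0][0])
    coverage = a_aln / len(a)
    blocks = [(int(s[0]), int(s[1]), int(t[0]), int(t[1]))
              for s, t in zip(a_spans, b_spans)]
    return identity, coverage, blocks


# ---------------------------------------------------------------------------
# Seed-and-chain candidate detection


@dataclass
class CandidateRegion:
    contig: str
    start: int
    end: int
    strand: str
    score: int          # matched (chained) genome bases


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def find_candidate_loci(genome: GenomeRecord, cluster: ClusterDefinition,
                        k: int = 11, params: SurveyParams | None = None
                        ) -> list[CandidateRegion]:
    """Regions sharing a chained run of exact k-mers with the cluster.

    Both strands of every contig are scanned, so draft assemblies with the
    cluster split across (possibly reverse-complemented) contigs still yield
    one candidate per piece.
    """
    if k < 8:
        raise SurveyError("word size must be >= 8")
    params = params or SurveyParams()
    fwd = _kmer_index(cluster.sequence, k)
    rev = _kmer_index(revcomp(cluster.sequence), k)
    out: list[CandidateRegion] = []
    for contig_id, seq in genome.contigs:
        per_strand: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        n = len(seq)
        for j in range(n - k + 1):
            w = seq[j:j + k]
            if w in fwd:
                per_strand["+"].extend((j, j - q) for q in fwd[w])
            if w in rev:
                per_strand["-"].extend((j, j - q) for q in rev[w])
        for strand, matches in per_strand.items():
            matches.sort()
            chains: list[list[tuple[int, int]]] = []
            for t, diag in matches:
                placed = False
                for chain in reversed(chains):
                    lt, ld = chain[-1]
                    if t - lt > params.max_seed_gap:
                        break
                    if abs(diag - ld) <= params.max_diag_drift:
                        chain.append((t, diag))
                        placed = True
                        break
                if not placed:
                    chains.append([(t, diag)])
            for chain in chains:
                covered = _covered_bases([t for t, _ in chain], k)
                if covered >= params.min_chain_bases:
                    out.append(CandidateRegion(
                        contig=contig_id,
                        start=max(0, chain[0][0] - params.region_margin),
                        end=min(n, chain[-1][0] + k + params.region_margin),
                        strand=strand, score=covered))
    return _merge_candidates(out)


def _covered_bases(starts: list[int], k: int) -> int:
    total = 0
    cur_s = cur_e = None
    for s in starts:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, s + k
        else:
            cur_e = max(cur_e, s + k)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _merge_candidates(cands: list[CandidateRegion]) -> list[CandidateRegion]:
    merged: list[CandidateRegion] = []
    for c in sorted(cands, key=lambda c: (c.contig, c.strand, c.start, c.end)):
        if merged and merged[-1].contig == c.contig \
                and merged[-1].strand == c.strand and c.start <= merged[-1].end:
            last = merged[-1]
            last.end = max(last.end, c.end)
            last.score += c.score
        else:
            merged.append(c)
    # highest chain score first, then leftmost (deterministic tie-break)
    return sorted(merged, key=lambda c: (-c.score, c.contig, c.start))


# ---------------------------------------------------------------------------
# Candidate evaluation


@dataclass
class GeneMatch:
    gene: str
    order_index: int            # rank of the gene in the template
    contig: str
    start: int                  # genome coords, 0-based half-open
    end: int
    strand: str                 # strand of the match in the genome
    template_strand: str
    identity: float             # percent
    coverage: float             # fraction of the query gene


@dataclass
class ClusterHit:
    cluster: str
    strain: str
    gene_matches: list[GeneMatch] = field(default_factory=list)
    overall_identity: float = 0.0
    complete: bool = False
    syntenic: bool = False
    cross_contig: bool = False
    accepted: bool = False
    missing_genes: list[str] = field(default_factory=list)


def _match_gene_in_region(gene_fwd_seq: str, region_seq: str,
                          max_divergence: float = 0.65) -> tuple | None:
    """Locate + align one gene inside an (oriented) candidate region.

    edlib (infix mode) finds the best-matching window quickly; the gene is
    then *locally* aligned within it, so identity and coverage reflect the
    genuinely homologous stretch — a gene that is absent only produces a
    short spurious local hit and fails the coverage filter downstream.
    """
    res = edlib.align(gene_fwd_seq, region_seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or \
            res["editDistance"] > max_divergence * len(gene_fwd_seq):
        return None
    s, e = res["locations"][0]
    e += 1
    pad = 30
    ws, we = max(0, s - pad), min(len(region_seq), e + pad)
    identity, coverage, blocks = align_pair(gene_fwd_seq, region_seq[ws:we],
                                            mode="local")
    if not blocks:
        return None
    b_start, b_end = ws + blocks[0][2], ws + blocks[-1][3]
    return b_start, b_end, identity, coverage


def evaluate_candidate(genome: GenomeRecord, candidates: list[CandidateRegion],
                       cluster: ClusterDefinition,
                       params: SurveyParams | None = None) -> ClusterHit:
    """Score one locus (possibly split across contigs) against the template."""
    params = params or SurveyParams()
    hit = ClusterHit(cluster=cluster.name, strain=genome.strain_id)
    best: dict[str, GeneMatch] = {}
    for cand in candidates:
        seq = genome.contig(cand.contig)[cand.start:cand.end]
        oriented = seq if cand.strand == "+" else revcomp(seq)
        for rank, g in enumerate(cluster.genes):
            gene_fwd = cluster.sequence[g.start:g.end]  # cluster-forward
            m = _match_gene_in_region(gene_fwd, oriented)
            if m is None:
                continue
            s, e, identity, coverage = m
            if cand.strand == "+":
                gs, ge = cand.start + s, cand.start + e
                genome_strand = g.strand
            else:
                gs, ge = cand.end - e, cand.end - s
                genome_strand = "-" if g.strand == "+" else "+"
            gm = GeneMatch(gene=g.name, order_index=rank, contig=cand.contig,
                           start=gs, end=ge, strand=genome_strand,
                           template_strand=g.strand,
                           identity=identity, coverage=coverage)
            prev = best.get(g.name)
            if prev is None or gm.identity * gm.coverage \
                    > prev.identity * prev.coverage:
                best[g.name] = gm
    hit.gene_matches = sorted(best.values(),
                              key=lambda m: (m.contig, m.start))
    hit.missing_genes = [g.name for g in cluster.genes if g.name not in best]
    covered = {m.gene for m in hit.gene_matches
               if m.coverage >= params.min_gene_coverage}
    hit.complete = all(g.name in covered for g in cluster.genes)
    hit.cross_contig = len({m.contig for m in hit.gene_matches}) > 1
    hit.syntenic = bool(hit.gene_matches) and (
        check_synteny(hit.gene_matches) if not hit.cross_contig
        else _check_split_synteny(hit.gene_matches))
    total = sum(g.length for g in cluster.genes)
    hit.overall_identity = (
        sum(m.identity * (cluster.genes[m.order_index].length)
            for m in hit.gene_matches) / total if total else 0.0)
    hit.accepted = (hit.complete and hit.syntenic
                    and hit.overall_identity >= params.min_cluster_identity)
    return hit


def check_synteny(gene_matches: list[GeneMatch]) -> bool:
    """Template order preserved, or exactly reversed with all strands flipped."""
    if not gene_matches:
        raise SurveyError("no gene matches")
    ms = sorted(gene_matches, key=lambda m: (m.contig, m.start))
    ranks = [m.order_index for m in ms]
    same = [m.strand == m.template_strand for m in ms]
    if len(ranks) == 1:
        return True
    forward = all(b > a for a, b in zip(ranks, ranks[1:])) and all(same)
    inverted = all(b < a for a, b in zip(ranks, ranks[1:])) \
        and not any(same)
    return forward or inverted


def _check_split_synteny(gene_matches: list[GeneMatch]) -> bool:
    """Cross-contig hit: each piece syntenic, pieces = one template breakpoint."""
    by_contig: dict[str, list[GeneMatch]] = {}
    for m in gene_matches:
        by_contig.setdefault(m.contig, []).append(m)
    if len(by_contig) > 2:
        return False
    blocks = []
    for contig, ms in by_contig.items():
        if not check_synteny(ms):
            return False
        ranks = sorted(m.order_index for m in ms)
        if ranks != list(range(ranks[0], ranks[-1] + 1)):
            return False
        blocks.append((ranks[0], ranks[-1]))
    blocks.sort()
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 != e1 + 1:
            return False
    return True


# ---------------------------------------------------------------------------
# Prevalence arithmetic and the whole-panel survey


def prevalence(count: int, total: int) -> float:
    """Percent of surveyed genomes carrying the cluster, 3 decimals,
    half-away-from-zero."""
    if total <= 0:
        raise SurveyError("total surveyed genomes must be positive")
    if not 0 <= count <= total:
        raise SurveyError("count outside [0, total]")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def detect_cluster(genome: GenomeRecord, cluster: ClusterDefinition,
                   params: SurveyParams | None = None) -> ClusterHit:
    """find_candidate_loci + evaluate_candidate for one genome/cluster pair."""
    params = params or SurveyParams()
    cands = find_candidate_loci(genome, cluster, k=params.word_size,
                                params=params)
    return evaluate_candidate(genome, cands, cluster, params)


def survey_panel(genomes: dict[str, GenomeRecord],
                 clusters: list[ClusterDefinition],
                 taxon_map: dict[str, str],
                 params: SurveyParams | None = None,
                 out_dir: str | Path | None = None,
                 include_zero_rows: bool = False
                 ) -> tuple[list[ClusterHit], pd.DataFrame]:
    """Survey every genome for every cluster; tabulate per-genus prevalence."""
    params = params or SurveyParams()
    hits: list[ClusterHit] = []
    genus: dict[str, str] = {}
    for strain in genomes:
        if strain not in taxon_map:
            warnings.warn(f"strain {strain!r} missing from taxon map; "
                          "bucketed as 'unknown'")
        genus[strain] = taxon_map.get(strain, "unknown")
    for cluster in clusters:
        for strain in sorted(genomes):
            hits.append(detect_cluster(genomes[strain], cluster, params))
    rows = []
    for cluster in clusters:
        per_genus: dict[str, list[str]] = {}
        for strain in genomes:
            per_genus.setdefault(genus[strain], []).append(strain)
        for gname in sorted(per_genus):
            strains = per_genus[gname]
            n_hit = sum(1 for h in hits
                        if h.cluster == cluster.name and h.accepted
                        and h.strain in strains)
            if n_hit == 0 and not include_zero_rows:
                continue
            rows.append((cluster.name, gname, n_hit, len(strains),
                         prevalence(n_hit, len(strains))))
    table = pd.DataFrame(rows, columns=["cluster", "genus", "strains_with_cluster",
                                        "genomes_surveyed", "percent"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hits_tsv(hits, out / "hits.tsv")
        write_tsv(out / "prevalence.tsv", list(table.columns),
                  table.itertuples(index=False),
                  comments=["percent = round(100*count/total, 3), "
                            "half-away-from-zero"])
        write_hits_gff3(hits, out / "hits.gff3")
    return hits, table


def write_hits_tsv(hits: list[ClusterHit], path: str | Path) -> None:
    rows = []
    for h in hits:
        span = (f"{h.gene_matches[0].contig}:{h.gene_matches[0].start}-"
                f"{h.gene_matches[-1].end}" if h.gene_matches else ".")
        rows.append((h.cluster, h.strain, len(h.gene_matches),
                     f"{h.overall_identity:.2f}", int(h.complete),
                     int(h.syntenic), int(h.cross_contig), int(h.accepted),
                     span))
    write_tsv(path, ["cluster", "strain", "genes_matched", "overall_identity",
                     "complete", "syntenic", "cross_contig", "accepted",
                     "span"], rows)


def write_hits_gff3(hits: list[ClusterHit], path: str | Path) -> None:
    feats = []
    for h in hits:
        if not h.accepted:
            continue
        for m in h.gene_matches:
            feats.append(Gff3Feature(
                m.contig, "gene_match", m.start, m.end, m.strand,
                score=f"{m.identity:.2f}",
                attributes={"ID": f"{h.strain}.{h.cluster}.{m.gene}",
                            "cluster": h.cluster, "gene": m.gene}))
    write_gff3(feats, path)
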