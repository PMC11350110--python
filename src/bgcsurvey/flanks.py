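"""Flanking-region conservation analysis around detected clusters.

The 5 kb on each side of a cluster is extracted (truncated at contig
edges), ORFs are predicted with a stop-to-stop heuristic (bacterial code,
table 11; starts ATG/GTG/TTG; default minimum 150 nt), proteins are
grouped across strains by single-linkage at 30% global amino-acid
identity, and two HGT-associated signals are flagged: mobile-genetic-
element ORFs (keyword or reference-protein route) and interrupted genes
whose adjacent ORF fragments tile one reference protein — the footprint a
single-base frameshift leaves in an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io import revcomp
from .survey import align_pair, _make_aligner

MGE_KEYWORDS = ("transposase", "integrase", "insertion sequence", "conjugal",
                "tra", "mobile element", "recombinase")

_STARTS = ("ATG", "GTG", "TTG")
_STOPS = {"TAA", "TAG", "TGA"}


class FlankError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Flank extraction


@dataclass
class Flank:
    sequence: str
    truncated: bool     # contig edge clipped the requested length
    side: str           # "upstream" | "downstream" (cluster-template sense)


def extract_flanks(contig_seq: str, start: int, end: int, strand: str = "+",
                   length: int = 5000) -> tuple[Flank, Flank]:
    """(upstream, downstream) flanks of a cluster span, template-oriented.

    For a minus-strand cluster the flanks swap and are reverse-complemented
    so that "upstream" always precedes the cluster in its own orientation.
    """
    if not (0 <= start < end <= len(contig_seq)):
        raise FlankError("cluster span outside contig")
    left = contig_seq[max(0, start - length):start]
    right = contig_seq[end:end + length]
    left_trunc = start - length < 0
    right_trunc = end + length > len(contig_seq)
    if strand == "+":
        return (Flank(left, left_trunc, "upstream"),
                Flank(right, right_trunc, "downstream"))
    return (Flank(revcomp(right), right_trunc, "upstream"),
            Flank(revcomp(left), left_trunc, "downstream"))


# ---------------------------------------------------------------------------
# ORF prediction (stop-to-stop heuristic, translation table 11)


@dataclass
class Orf:
    start: int          # 0-based half-open on the forward strand
    end: int
    strand: str
    frame: int          # 0..2 on its own strand
    protein: str        # translated, no trailing '*'
    partial: bool = False   # runs into a sequence edge
    contig: str = ""
    annotation: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand)


def _scan_strand(seq: str, min_length: int, include_partial: bool
                 ) -> list[tuple[int, int, int, bool]]:
    """(start, end, frame, partial) ORFs on one strand, local coordinates."""
    n = len(seq)
    out = []
    for frame in range(3):
        region_start = frame          # start of the current stop-free region
        at_edge = True                # region touches the 5' sequence edge
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon in _STOPS:
                out.extend(_orfs_in_region(seq, region_start, i + 3, frame,
                                           False, at_edge, min_length,
                                           include_partial))
                region_start = i + 3
                at_edge = False
            i += 3
        # trailing region without a stop: runs off the 3' edge
        if region_start < i:
            out.extend(_orfs_in_region(seq, region_start, i, frame,
                                       True, at_edge, min_length,
                                       include_partial))
    return out


def _orfs_in_region(seq: str, region_start: int, region_end: int, frame: int,
                    open_end: bool, open_start: bool, min_length: int,
                    include_partial: bool):
    """At most one ORF per stop-bounded region: from the first start codon
    (or the region edge, if the region touches the sequence edge)."""
    start = None
    partial = False
    for j in range(region_start, region_end - (0 if open_end else 3), 3):
        if seq[j:j + 3] in _STARTS:
            start = j
            break
    if start is None and open_start and include_partial:
        start = region_start
        partial = True
    if start is None:
        return
    if open_end:
        if not include_partial:
            return
        partial = True
    length = region_end - start
    if length >= min_length:
        yield (start, region_end, frame, partial or open_end)


def predict_orfs(seq: str, min_length: int = 150,
                 include_partial: bool = False, contig: str = "") -> list[Orf]:
    """All maximal ORFs >= min_length on both strands; one ORF per in-frame
    stop-bounded region. Coordinates are on the forward strand."""
    seq = seq.upper()
    n = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for start, end, frame, partial in _scan_strand(s, min_length,
                                                       include_partial):
            prot = str(Seq(s[start:end]).translate(table=11)).rstrip("*")
            if strand == "+":
                gs, ge = start, end
            else:
                gs, ge = n - end, n - start
            orfs.append(Orf(start=gs, end=ge, strand=strand, frame=frame,
                            protein=prot, partial=partial, contig=contig))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# Homolog grouping (single linkage at a global-identity cutoff)


@dataclass
class HomologGroup:
    group_id: str
    members: list[tuple[str, Orf]]       # (strain, orf)
    representative: str                  # protein sequence


def _kmer_set(prot: str, k: int = 3) -> frozenset[str]:
    return frozenset(prot[i:i + k] for i in range(len(prot) - k + 1))


def _protein_identity(a: str, b: str,
                      ka: frozenset | None = None,
                      kb: frozenset | None = None) -> float:
    if not a or not b:
        return 0.0
    # cheap length screen: global identity cannot exceed min/max length ratio
    if min(len(a), len(b)) / max(len(a), len(b)) < 0.15:
        return 0.0
    # shared-word screen (long proteins only): pairs above ~30% global
    # identity share 3-mers, unrelated pairs rarely share more than a couple
    if min(len(a), len(b)) >= 40:
        ka = _kmer_set(a) if ka is None else ka
        kb = _kmer_set(b) if kb is None else kb
        if len(ka & kb) < 2:
            return 0.0
    identity, _, _ = align_pair(a, b, mode="global")
    return identity


def group_homologs(proteins: Mapping[tuple[str, int], str] |
                   Sequence[tuple[str, Orf]],
                   min_identity: float = 30.0) -> list[HomologGroup]:
    """Single-linkage components over pairwise global percent identity.

    Accepts (strain, Orf) pairs; group ids are deterministic (ordered by the
    lexicographically smallest member key).
    """
    items = list(proteins.items()) if isinstance(proteins, Mapping) \
        else [((strain, orf.key), orf) for strain, orf in proteins]
    if not items:
        raise FlankError("no proteins to group")
    keys = [k for k, _ in items]
    seqs = [v.protein if isinstance(v, Orf) else v for _, v in items]
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    ksets = [_kmer_set(s) for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _protein_identity(seqs[i], seqs[j],
                                 ksets[i], ksets[j]) >= min_identity:
                union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for members in comps.values():
        members.sort(key=lambda i: keys[i])
        rep = max((seqs[i] for i in members), key=len)
        groups.append((min(keys[i] for i in members), members, rep))
    groups.sort(key=lambda t: t[0])
    out = []
    for gi, (_, members, rep) in enumerate(groups):
        out.append(HomologGroup(
            group_id=f"HG{gi + 1:04d}",
            members=[(keys[i][0], items[i][1]) if isinstance(items[i][1], Orf)
                     else (keys[i][0], keys[i]) for i in members],
            representative=rep))
    return out


# ---------------------------------------------------------------------------
# Flank profiles and conservation


@dataclass
class FlankProfile:
    strain: str
    cluster: str
    upstream: list[Orf] = field(default_factory=list)
    downstream: list[Orf] = field(default_factory=list)
    upstream_truncated: bool = False
    downstream_truncated: bool = False
    groups: dict[tuple, str] = field(default_factory=dict)   # orf.key -> group id
    mge_flags: dict[tuple, bool] = field(default_factory=dict)
    interrupted: list[str] = field(default_factory=list)

    @property
    def orfs(self) -> list[Orf]:
        return self.upstream + self.downstream

    @property
    def group_set(self) -> frozenset[str]:
        return frozenset(self.groups.values())


def build_flank_profiles(flank_seqs: Mapping[str, tuple[Flank, Flank]],
                         cluster: str, min_orf_length: int = 150,
                         min_identity: float = 30.0) -> list[FlankProfile]:
    """Predict flank ORFs for every strain and label them by homolog group."""
    profiles: list[FlankProfile] = []
    pool: list[tuple[str, Orf]] = []
    for strain in sorted(flank_seqs):
        up, dn = flank_seqs[strain]
        p = FlankProfile(strain=strain, cluster=cluster,
                         upstream_truncated=up.truncated,
                         downstream_truncated=dn.truncated)
        if up.sequence:
            p.upstream = predict_orfs(up.sequence, min_orf_length,
                                      contig=f"{strain}.up")
        if dn.sequence:
            p.downstream = predict_orfs(dn.sequence, min_orf_length,
                                        contig=f"{strain}.dn")
        profiles.append(p)
        pool.extend((strain, o) for o in p.orfs)
    if pool:
        for g in group_homologs(pool, min_identity=min_identity):
            for strain, orf in g.members:
                for p in profiles:
                    if p.strain == strain:
                        p.groups[orf.key] = g.group_id
    return profiles


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def conservation_matrix(profiles: Sequence[FlankProfile]):
    """Presence/absence of homolog groups per strain + pairwise Jaccard."""
    import pandas as pd
    if len(profiles) < 2:
        raise FlankError("need at least two profiles")
    all_groups = sorted({g for p in profiles for g in p.group_set})
    presence = pd.DataFrame(
        [[int(g in p.group_set) for g in all_groups] for p in profiles],
        index=[p.strain for p in profiles], columns=all_groups)
    strains = [p.strain for p in profiles]
    jac = pd.DataFrame(
        [[jaccard(a.group_set, b.group_set) for b in profiles]
         for a in profiles], index=strains, columns=strains)
    return presence, jac


# ---------------------------------------------------------------------------
# Mobile-element flags


def flag_mobile_elements(orfs: Sequence[Orf],
                         annotations: Mapping[tuple, str] | None = None,
                         reference_proteins: Mapping[str, str] | None = None,
                         min_identity: float = 30.0,
                         min_coverage: float = 0.5) -> dict[tuple, bool]:
    """Flag ORFs as MGE-like by annotation keyword or reference alignment."""
    if annotations is None and reference_proteins is None:
        raise FlankError("supply annotations or an MGE reference protein set")
    flags: dict[tuple, bool] = {}
    for orf in orfs:
        flagged = False
        text = (annotations or {}).get(orf.key, orf.annotation).lower()
        if text and any(_kw_hit(text, kw) for kw in MGE_KEYWORDS):
            flagged = True
        if not flagged and reference_proteins:
            for ref in reference_proteins.values():
                ident, cov = _local_identity_coverage(orf.protein, ref)
                if ident >= min_identity and cov >= min_coverage:
                    flagged = True
                    break
        flags[orf.key] = flagged
    return flags


def _kw_hit(text: str, kw: str) -> bool:
    # "tra" only as a word prefix (traI, tra operon), not inside e.g.
    # "transcriptional" -- but "transposase" is its own keyword
    if kw == "tra":
        import re
        return re.search(r"\btra(?![a-z]{3,})", text) is not None
    return kw in text


def _local_identity_coverage(query: str, ref: str) -> tuple[float, float]:
    """Local-alignment identity and reference coverage of a protein pair."""
    if not query or not ref:
        return 0.0, 0.0
    aln = _make_aligner("local").align(query, ref)
    if len(aln) == 0:
        return 0.0, 0.0
    best = aln[0]
    q_spans, r_spans = best.aligned
    if len(q_spans) == 0:
        return 0.0, 0.0
    matches = cols = 0
    for (qs, qe), (rs, re_) in zip(q_spans, r_spans):
        for x, y in zip(query[qs:qe], ref[rs:re_]):
            cols += 1
            if x == y:
                matches += 1
    for i in range(len(q_spans) - 1):
        cols += (q_spans[i + 1][0] - q_spans[i][1]) \
            + (r_spans[i + 1][0] - r_spans[i][1])
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = (r_spans[-1][1] - r_spans[0][0]) / len(ref)
    return identity, coverage


# ---------------------------------------------------------------------------
# Interrupted (frameshift-degraded) gene detection


@dataclass
class InterruptedGene:
    gene: str
    orfs: list[Orf]
    joint_coverage: float


def detect_interrupted_genes(orfs: Sequence[Orf],
                             reference_genes: Mapping[str, str],
                             min_identity: float = 40.0,
                             min_segment_aa: int = 15,
                             min_joint_coverage: float = 0.7,
                             intact_coverage: float = 0.8,
                             max_gap_nt: int = 2000,
                             max_overlap_aa: int = 15
                             ) -> list[InterruptedGene]:
    """Report reference genes tiled by >=2 adjacent same-strand ORF fragments.

    A gene covered >= ``intact_coverage`` by a single ORF is considered
    intact and never reported.
    """
    if not reference_genes:
        raise FlankError("reference gene proteins required")
    out: list[InterruptedGene] = []
    for gene in sorted(reference_genes):
        ref = reference_genes[gene]
        frags = []
        for orf in orfs:
            ident, cov, span = _ref_span(orf.protein, ref)
            if ident >= min_identity and span is not None \
                    and span[1] - span[0] >= min_segment_aa:
                frags.append((orf, span, cov))
        if any(cov >= intact_coverage for _, _, cov in frags):
            continue
        frags.sort(key=lambda t: (t[0].contig, t[0].start))
        for i in range(len(frags)):
            chain = [frags[i]]
            for j in range(i + 1, len(frags)):
                prev_orf, prev_span, _ = chain[-1]
                orf, span, _ = frags[j]
                if orf.contig != prev_orf.contig \
                        or orf.strand != prev_orf.strand:
                    continue
                if orf.start - prev_orf.end > max_gap_nt:
                    break
                ordered = (span[0] >= prev_span[1] - max_overlap_aa
                           if orf.strand == "+"
                           else span[1] <= prev_span[0] + max_overlap_aa)
                if ordered:
                    chain.append(frags[j])
            if len(chain) >= 2:
                covered = set()
                for _, (s, e), _ in chain:
                    covered.update(range(s, e))
                joint = len(covered) / len(ref)
                if joint >= min_joint_coverage:
                    out.append(InterruptedGene(
                        gene=gene, orfs=[o for o, _, _ in chain],
                        joint_coverage=joint))
                    break
    return out


def _ref_span(query: str, ref: str) -> tuple[float, float, tuple | None]:
    """Identity, reference coverage and reference span of a local alignment."""
    if not query or not ref:
        return 0.0, 0.0, None
    aln = _make_aligner("local").align(query, ref)
    if len(aln) == 0:
        return 0.0, 0.0, None
    best = aln[0]
    q_spans, r_spans = best.aligned
    if len(r_spans) == 0:
        return 0.0, 0.0, None
    matches = cols = 0
    for (qs, qe), (rs, re_) in zip(q_spans, r_spans):
        for x, y in zip(query[qs:qe], ref[rs:re_]):
            cols += 1
            matches += x == y
    for i in range(len(q_spans) - 1):
        cols += (q_spans[i + 1][0] - q_spans[i][1]) \
            + (r_spans[i + 1][0] - r_spans[i][1])
    identity = 100.0 * matches / cols if cols else 0.0
    span = (int(r_spans[0][0]), int(r_spans[-1][1]))
    coverage = (span[1] - span[0]) / len(ref)
    return identity, coverage, span
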