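"""Synthetic strain-panel generator with known ground truth.

Emulates the input universe of a comparative BGC survey: a panel of related
bacterial strains evolved along a known species tree, host genomes at a
chosen background %GC (enterobacterial chromosomes sit near 54-55%),
an implanted antibiotic biosynthetic gene cluster at an offset %GC,
variable flank-ORF conservation between sister lineages, transposase
remnants near some clusters, clonal duplicate genomes, frameshift-degraded
cluster copies, and horizontal transfers between lineages.

Evolution is a JC-like independent-site substitution process: a branch of
length b expected substitutions/site changes each site with probability
p = (3/4)(1 - exp(-4b/3)) to a uniformly chosen different base, which makes
JC69-corrected distances additive along the tree. There are no indels apart
from the single-base frameshifts that are injected deliberately.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .gc import gc_content
from .io import (ClusterDefinition, Gene, GenomeRecord, Gff3Feature,
                 read_newick, write_cluster_definition, write_fasta,
                 write_gff3, write_newick, write_tsv)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = ("ATG", "GTG", "TTG")


class SimulationError(ValueError):
    pass


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


# ---------------------------------------------------------------------------
# Sequence-level primitives


def mutate_sequence(seq: str, rate: float, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    on_invalid: str = "reject",
                    stationary_gc: float | None = None) -> str:
    """Substitute sites so the expected changed fraction equals ``rate``.

    Default model: each site is hit with probability ``rate`` and replaced
    by a uniformly chosen *different* base (JC-like). With ``stationary_gc``
    set, replacement bases are instead drawn from the stationary
    composition at that %GC (F81-like) and the hit probability is rescaled
    so the expected proportion of changed sites still equals ``rate``; this
    keeps a sequence's base composition at its target along a branch
    instead of drifting toward 50% GC.

    ``on_invalid`` controls non-ACGT characters: "reject" raises,
    "keep" passes them through unmutated.
    """
    if not 0.0 <= rate <= 0.75:
        raise SimulationError(f"substitution rate {rate} outside [0, 0.75]")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    invalid = codes < 0
    if invalid.any() and on_invalid != "keep":
        raise SimulationError("non-ACGT characters in sequence (set on_invalid='keep')")
    if rate == 0.0 or arr.size == 0:
        return seq
    if stationary_gc is None:
        hit = (rng.random(arr.shape[0]) < rate) & ~invalid
        n = int(hit.sum())
        if n:
            # shift by 1..3 mod 4 guarantees a different base
            shift = rng.integers(1, 4, size=n)
            codes_hit = (codes[hit].astype(np.int64) + shift) % 4
            arr[hit] = _BASES[codes_hit]
    else:
        # composition-preserving variant: the hit sites' bases are randomly
        # permuted among themselves, so the G+C count is exactly invariant;
        # a hit site "changes" only if it receives a different base, which
        # happens with probability ~beta, hence the rate rescaling
        g = stationary_gc / 100.0
        pi = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
        beta = 1.0 - float((pi ** 2).sum())
        raw = min(rate / beta, 1.0)
        hit = (rng.random(arr.shape[0]) < raw) & ~invalid
        n = int(hit.sum())
        if n:
            arr[hit] = rng.permutation(arr[hit])
    return arr.tobytes().decode()


def inject_frameshift(gene_seq: str, position: int, kind: str,
                      seed: int = 0) -> str:
    """Insert or delete one base at ``position`` (0-based), shifting the frame."""
    if not 0 <= position < len(gene_seq):
        raise SimulationError(f"frameshift position {position} out of range")
    if kind == "insertion":
        base = "ACGT"[_rng(seed, 7).integers(0, 4)]
        return gene_seq[:position] + base + gene_seq[position:]
    if kind == "deletion":
        return gene_seq[:position] + gene_seq[position + 1:]
    raise SimulationError(f"unknown frameshift kind {kind!r}")


def branch_substitution_probability(branch_length: float) -> float:
    """JC69: expected fraction of differing sites after b substitutions/site."""
    return 0.75 * (1.0 - float(np.exp(-4.0 * branch_length / 3.0)))


def _revert_nonsense(parent: str, child: str,
                     coding_spans: list[tuple[int, int]]) -> str:
    """Purifying-selection stand-in: undo substitutions that break a gene's
    reading frame (lost start, lost terminal stop, or a new internal stop)
    in plus-strand coding spans. Everything else evolves neutrally."""
    if parent == child:
        return child
    arr = None
    for s, e in coding_spans:
        for j in range(s, e - 2, 3):
            cod = child[j:j + 3]
            bad = (cod not in _STARTS if j == s
                   else cod not in _STOPS if j == e - 3
                   else cod in _STOPS)
            if bad and cod != parent[j:j + 3]:
                if arr is None:
                    arr = bytearray(child.encode())
                arr[j:j + 3] = parent[j:j + 3].encode()
    return arr.decode() if arr is not None else child


# ---------------------------------------------------------------------------
# Composition-targeted sequence generation


def random_sequence(length: int, gc_percent: float,
                    rng: np.random.Generator, exact: bool = True) -> str:
    """Random sequence at the requested %GC.

    With ``exact`` (the default) the realized G+C count is fixed to
    round(gc * length) and the bases are shuffled, so the composition of
    every emitted genome matches its target to within one base; with
    ``exact=False`` bases are iid and only the expectation matches.
    """
    g = gc_percent / 100.0
    if exact:
        n_gc = int(round(g * length))
        n_at = length - n_gc
        halves = [n_gc // 2, n_gc - n_gc // 2, n_at // 2, n_at - n_at // 2]
        arr = np.repeat(np.frombuffer(b"GCAT", dtype=np.uint8), halves)
        rng.shuffle(arr)
    else:
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng.choice(4, size=length, p=p)]
    return arr.tobytes().decode()


def _codon_gc_given_not_stop(theta: float) -> float:
    """E[GC fraction of a codon | codon is not a stop], bases iid GC-prob theta."""
    q = theta / 2.0          # per-base probability of G (same for C)
    h = (1.0 - theta) / 2.0  # per-base probability of A (same for T)
    p_stop = h * h * (h + 2 * q)          # TAA + TAG + TGA
    e_gc = 3.0 * theta - 2.0 * h * h * q  # GC bases lost with TAG/TGA removal
    return e_gc / (3.0 * (1.0 - p_stop))


def _solve_coding_theta(target_frac: float) -> float:
    """Per-base GC probability whose post-stop-rejection composition hits target."""
    lo, hi = 1e-6, 1.0 - 1e-6
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _codon_gc_given_not_stop(mid) < target_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def random_coding_gene(length: int, gc_percent: float,
                       rng: np.random.Generator) -> str:
    """ATG + stop-free random codons + TAA, composition-corrected to target GC.

    ``length`` must be a multiple of 3 and >= 9.
    """
    if length % 3 or length < 9:
        raise SimulationError("gene length must be a multiple of 3, >= 9")
    n_body = length // 3 - 2
    target = gc_percent / 100.0
    # ATG carries 1 GC base, TAA none; load the difference onto the body
    body_target = (target * length - 1.0) / (3 * n_body)
    body_target = min(max(body_target, 0.01), 0.99)
    theta = _solve_coding_theta(body_target)
    codons: list[str] = []
    while len(codons) < n_body:
        chunk = random_sequence(3 * (n_body - len(codons)), 100 * theta, rng,
                                exact=False)
        codons.extend(c for i in range(0, len(chunk), 3)
                      if (c := chunk[i:i + 3]) not in _STOPS)
    gene = "ATG" + "".join(codons[:n_body]) + "TAA"
    return _repair_gc(gene, int(round(target * length)), rng)


def _repair_gc(gene: str, target_count: int, rng: np.random.Generator) -> str:
    """Flip bases in the gene body (start/stop kept) until the G+C count is
    exact, never introducing an in-frame stop codon."""
    arr = bytearray(gene.encode())
    count = gene.count("G") + gene.count("C")
    if count == target_count:
        return gene
    body = np.arange(3, len(gene) - 3)
    rng.shuffle(body)
    up = count < target_count   # need more GC
    swaps = {True: {ord("A"): ord("G"), ord("T"): ord("C")},
             False: {ord("G"): ord("A"), ord("C"): ord("T")}}[bool(up)]
    for pos in body:
        if count == target_count:
            break
        old = arr[pos]
        if old not in swaps:
            continue
        arr[pos] = swaps[old]
        c0 = 3 * (pos // 3)
        if arr[c0:c0 + 3].decode() in _STOPS:
            arr[pos] = old
            continue
        count += 1 if up else -1
    return arr.decode()


def _adjust_gc_count(sequence: str, target_count: int,
                     rng: np.random.Generator,
                     coding_spans: list[tuple[int, int]]) -> str:
    """Flip A/T<->G/C bases until the exact G+C count is hit, touching only
    plus-strand gene bodies (frame-aware, never creating an in-frame stop)
    and positions outside coding spans; start/stop codons stay intact."""
    seq = bytearray(sequence.encode())
    count = sequence.count("G") + sequence.count("C")
    if count == target_count:
        return sequence
    editable: list[tuple[int, int]] = []   # (position, gene_start or -1)
    in_gene = np.zeros(len(seq), dtype=bool)
    for s, e in coding_spans:
        in_gene[s:e] = True
        editable.extend((p, s) for p in range(s + 3, e - 3))
    editable.extend((p, -1) for p in range(len(seq)) if not in_gene[p])
    order = rng.permutation(len(editable))
    up = count < target_count
    swaps = {True: {ord("A"): ord("G"), ord("T"): ord("C")},
             False: {ord("G"): ord("A"), ord("C"): ord("T")}}[up]
    for idx in order:
        if count == target_count:
            break
        pos, gstart = editable[idx]
        old = seq[pos]
        if old not in swaps:
            continue
        seq[pos] = swaps[old]
        if gstart >= 0:
            c0 = gstart + 3 * ((pos - gstart) // 3)
            if seq[c0:c0 + 3].decode() in _STOPS:
                seq[pos] = old
                continue
        count += 1 if up else -1
    return seq.decode()


def retarget_cluster_gc(cluster: ClusterDefinition, target_count: int,
                        rng: np.random.Generator) -> ClusterDefinition:
    """Adjust a cluster sequence to an exact G+C count (stop-safe flips in
    plus-strand gene bodies and intergenic spacers)."""
    spans = [(g.start, g.end) for g in cluster.genes if g.strand == "+"]
    return ClusterDefinition(
        name=cluster.name,
        sequence=_adjust_gc_count(cluster.sequence, target_count, rng, spans),
        genes=[Gene(g.name, g.start, g.end, g.strand) for g in cluster.genes],
        source_strain=cluster.source_strain, accession=cluster.accession)


def make_cluster_template(name: str = "synthetic_cluster", n_genes: int = 6,
                          gene_length: int = 720, spacer: int = 60,
                          gc_percent: float = 40.0, seed: int = 0,
                          strands: Sequence[str] | None = None) -> ClusterDefinition:
    """Build a synthetic reference BGC with evenly spaced coding genes."""
    rng = _rng(seed, 11)
    strands = list(strands) if strands else ["+"] * n_genes
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i in range(n_genes):
        if i > 0:
            parts.append(random_sequence(spacer, gc_percent, rng))
            pos += spacer
        g = random_coding_gene(gene_length, gc_percent, rng)
        if strands[i] == "-":
            from .io import revcomp
            g = revcomp(g)
        genes.append(Gene(f"{name}_g{i + 1}", pos, pos + gene_length, strands[i]))
        parts.append(g)
        pos += gene_length
    return ClusterDefinition(name=name, sequence="".join(parts), genes=genes,
                             source_strain="synthetic", accession="synthetic")


# Fixed synthetic transposase-remnant cassette (300 bp ORF) used by the
# mge_prob option; its translation is shipped as the reference MGE protein.
MGE_REMNANT: str = random_coding_gene(300, 50.0, np.random.default_rng(9157))


def mge_reference_proteins() -> dict[str, str]:
    from Bio.Seq import Seq
    return {"tnp_synthetic": str(Seq(MGE_REMNANT).translate(table=11)).rstrip("*")}


# ---------------------------------------------------------------------------
# Panel simulation


@dataclass
class SimulationConfig:
    species_tree: str                       # newick with branch lengths
    n_lineages: int
    genome_length: int = 60_000
    host_gc: float = 54.6
    cluster_gc_offset: float = -15.0
    cluster_template: ClusterDefinition | None = None
    carrier_lineages: tuple[str, ...] | None = None   # None => all leaves
    hgt_events: tuple[tuple[str, str], ...] = ()      # (donor, recipient)
    frameshift_prob: float = 0.0
    clonal_lineages: tuple[str, ...] = ()
    clonal_copies: int = 0
    clonal_divergence_max: int = 2
    flank_conservation: float = 1.0
    n_flank_orfs: int = 5          # per side
    flank_orf_length: int = 630    # nt, multiple of 3
    flank_spacer: int = 30
    mge_prob: float = 0.0
    marker_length: int = 1800      # cpn60-like barcode gene
    seed: int = 0

    def validate(self, tree: dendropy.Tree,
                 template: ClusterDefinition) -> None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if len(leaves) != self.n_lineages:
            raise SimulationError(
                f"tree has {len(leaves)} leaves but n_lineages={self.n_lineages}")
        if not 0 <= self.host_gc <= 100:
            raise SimulationError("host_gc outside [0, 100]")
        if self.genome_length < 10 * template.length:
            raise SimulationError(
                f"genome_length {self.genome_length} < 10 x cluster length "
                f"{template.length}")
        for p in (self.frameshift_prob, self.flank_conservation, self.mge_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        for donor, recip in self.hgt_events:
            for name in (donor, recip):
                if name not in leaves:
                    raise SimulationError(f"HGT lineage {name!r} not in tree")
        if self.carrier_lineages is not None:
            for name in self.carrier_lineages:
                if name not in leaves:
                    raise SimulationError(f"carrier {name!r} not in tree")


@dataclass
class TruthRecord:
    strain: str
    present: bool
    contig: str | None = None
    start: int | None = None          # 0-based half-open, genome coords
    end: int | None = None
    strand: str = "+"
    acquisition: str = "absent"       # vertical | hgt:<donor> | absent
    frameshifts: list[tuple[str, int, str]] = field(default_factory=list)
    cluster_gc: float | None = None
    replicon_gc: float | None = None
    mge_adjacent: bool = False
    clonal_of: str | None = None
    gene_spans: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class PanelResult:
    genomes: dict[str, GenomeRecord]
    truth: dict[str, TruthRecord]
    markers: dict[str, str]           # strain -> cpn60-like sequence
    taxa: dict[str, str]              # strain -> genus label
    template: ClusterDefinition
    tree: dendropy.Tree
    config: SimulationConfig


def genus_of(strain: str) -> str:
    """Genus label convention: the leaf-name prefix before the first '_'."""
    return strain.split("_", 1)[0]


_SEG_BG, _SEG_MARKER, _SEG_FORF, _SEG_CLUSTER, _SEG_MGE = range(5)


def simulate_panel(config: SimulationConfig,
                   out_dir: str | Path | None = None) -> PanelResult:
    """Evolve a strain panel along the species tree and implant the cluster.

    Returns in-memory genomes plus a complete truth set; optionally writes
    FASTA/GFF3/JSON under ``out_dir``.
    """
    tree = read_newick(config.species_tree)
    template = config.cluster_template or make_cluster_template(
        gc_percent=config.host_gc + config.cluster_gc_offset,
        seed=config.seed)
    config.validate(tree, template)
    cluster_gc = config.host_gc + config.cluster_gc_offset
    if not 0 <= cluster_gc <= 100:
        raise SimulationError("host_gc + cluster_gc_offset outside [0, 100]")

    root_rng = _rng(config.seed, 1)
    # --- root genome as an ordered list of (kind, name, seq) segments
    marker = random_coding_gene(config.marker_length, config.host_gc, root_rng)
    up_orfs = [random_coding_gene(config.flank_orf_length, config.host_gc, root_rng)
               for _ in range(config.n_flank_orfs)]
    dn_orfs = [random_coding_gene(config.flank_orf_length, config.host_gc, root_rng)
               for _ in range(config.n_flank_orfs)]
    # regenerate the cluster sequence at the requested offset GC, keeping the
    # template's gene layout (the template itself may have been user-supplied
    # at a different composition)
    cluster_seq = template.sequence

    fixed = (len(marker) + len(cluster_seq) + 300
             + 2 * config.n_flank_orfs * (config.flank_orf_length
                                          + config.flank_spacer) + 6 * 150)
    bg_total = config.genome_length - fixed
    if bg_total < 3000:
        raise SimulationError("genome_length too small for the fixed layout")
    L_left = int(bg_total * 0.3)
    L_mid = int(bg_total * 0.2)
    L_right = bg_total - L_left - L_mid

    segments: list[tuple[int, str, str]] = []
    segments.append((_SEG_BG, "bg_left",
                     random_sequence(L_left, config.host_gc, root_rng)))
    segments.append((_SEG_MARKER, "cpn60", marker))
    segments.append((_SEG_BG, "bg_mid",
                     random_sequence(L_mid, config.host_gc, root_rng)))
    for i, orf in enumerate(up_orfs):
        segments.append((_SEG_FORF, f"up{i}", orf))
        segments.append((_SEG_BG, f"up{i}_sp",
                         random_sequence(config.flank_spacer, config.host_gc,
                                         root_rng)))
    segments.append((_SEG_BG, "gap_up",
                     random_sequence(150, config.host_gc, root_rng)))
    segments.append((_SEG_CLUSTER, template.name, cluster_seq))
    segments.append((_SEG_BG, "gap_dn1",
                     random_sequence(150, config.host_gc, root_rng)))
    segments.append((_SEG_MGE, "mge", ""))   # filled per-leaf
    segments.append((_SEG_BG, "gap_dn2",
                     random_sequence(150, config.host_gc, root_rng)))
    for i, orf in enumerate(dn_orfs):
        segments.append((_SEG_BG, f"dn{i}_sp",
                         random_sequence(config.flank_spacer, config.host_gc,
                                         root_rng)))
        segments.append((_SEG_FORF, f"dn{i}", orf))
    segments.append((_SEG_BG, "bg_right",
                     random_sequence(L_right, config.host_gc, root_rng)))

    if config.cluster_template is None and config.cluster_gc_offset != 0:
        # retarget the auto-generated cluster to the *realized* host baseline
        # plus the requested offset, rounding away from the host so that the
        # configured offset is a guaranteed lower bound on the injected
        # anomaly (per-segment count rounding would otherwise let a 5-point
        # offset land at 4.98 measured)
        baseline = "".join(s for kind, _, s in segments
                           if kind != _SEG_CLUSTER)
        base_gc = (baseline.count("G") + baseline.count("C")) / len(baseline)
        want = (base_gc + config.cluster_gc_offset / 100.0) * template.length
        # a ~0.15-point margin keeps the guarantee intact under the few
        # bases the reading-frame reversion step may later restore
        margin = max(1, int(round(0.0015 * template.length)))
        target_count = (int(np.floor(want)) - margin
                        if config.cluster_gc_offset < 0
                        else int(np.ceil(want)) + margin)
        target_count = min(max(target_count, 0), template.length)
        template = retarget_cluster_gc(template, target_count, root_rng)
        ci0 = next(i for i, s in enumerate(segments) if s[0] == _SEG_CLUSTER)
        segments[ci0] = (_SEG_CLUSTER, template.name, template.sequence)

    # --- evolve segments down the tree
    node_segments: dict[int, list[tuple[int, str, str]]] = {}
    for idx, node in enumerate(tree.preorder_node_iter()):
        node._sim_index = idx
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_segments[node._sim_index] = segments
            continue
        b = node.edge.length or 0.0
        p = branch_substitution_probability(b)
        rng = _rng(config.seed, 2, node._sim_index)
        parent = node_segments[node.parent_node._sim_index]
        cluster_spans = [(g.start, g.end) for g in template.genes
                         if g.strand == "+"]
        evolved = []
        for kind, name, seq in parent:
            if not seq:
                evolved.append((kind, name, seq))
                continue
            mut = mutate_sequence(seq, p, rng=rng,
                                  stationary_gc=(cluster_gc
                                                 if kind == _SEG_CLUSTER
                                                 else config.host_gc))
            # keep reading frames of designed genes intact (selection
            # stand-in); background evolves fully neutrally. Reversions are
            # composition-rebalanced so each segment's exact G+C count is
            # invariant along every branch.
            if kind == _SEG_CLUSTER:
                mut = _revert_nonsense(seq, mut, cluster_spans)
                mut = _adjust_gc_count(mut, seq.count("G") + seq.count("C"),
                                       rng, cluster_spans)
            elif kind in (_SEG_FORF, _SEG_MARKER):
                mut = _revert_nonsense(seq, mut, [(0, len(seq))])
                mut = _adjust_gc_count(mut, seq.count("G") + seq.count("C"),
                                       rng, [(0, len(seq))])
            evolved.append((kind, name, mut))
        node_segments[node._sim_index] = evolved

    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    leaf_segs = {lf.taxon.label: list(node_segments[lf._sim_index])
                 for lf in leaves}

    carriers = (set(leaf_segs) if config.carrier_lineages is None
                else set(config.carrier_lineages))
    hgt_recipient: dict[str, str] = {r: d for d, r in config.hgt_events}
    carriers |= set(hgt_recipient)

    def seg_index(segs, kind):
        return next(i for i, s in enumerate(segs) if s[0] == kind)

    # HGT: recipient's cluster is the donor's evolved copy (donor-derived,
    # not recipient-derived, divergence)
    donor_clusters = {name: leaf_segs[name][seg_index(leaf_segs[name],
                                                      _SEG_CLUSTER)][2]
                      for name in {d for d, _ in config.hgt_events}}
    for recip, donor in hgt_recipient.items():
        i = seg_index(leaf_segs[recip], _SEG_CLUSTER)
        kind, name, _ = leaf_segs[recip][i]
        leaf_segs[recip][i] = (kind, name, donor_clusters[donor])

    # flank divergence between sister lineages: for each cherry and each flank
    # ORF, with probability 1 - flank_conservation the ORF is lost from one
    # randomly chosen sister (expected sister Jaccard == flank_conservation)
    if config.flank_conservation < 1.0:
        cherries = [nd for nd in tree.preorder_internal_node_iter()
                    if all(ch.is_leaf() for ch in nd.child_nodes())
                    and len(nd.child_nodes()) == 2]
        for ci, nd in enumerate(cherries):
            a, b = sorted(ch.taxon.label for ch in nd.child_nodes())
            rng = _rng(config.seed, 3, ci)
            names = [s[1] for s in leaf_segs[a] if s[0] == _SEG_FORF]
            for orf_name in names:
                if rng.random() < config.flank_conservation:
                    continue
                victim = a if rng.random() < 0.5 else b
                segs = leaf_segs[victim]
                j = next(i for i, s in enumerate(segs)
                         if s[0] == _SEG_FORF and s[1] == orf_name)
                segs[j] = (_SEG_BG, orf_name + "_lost", "")

    # --- per-leaf finishing: frameshifts, MGE, assembly, truth
    genomes: dict[str, GenomeRecord] = {}
    truth: dict[str, TruthRecord] = {}
    markers: dict[str, str] = {}
    taxa: dict[str, str] = {}

    def finish_leaf(strain: str, segs: list[tuple[int, str, str]],
                    leaf_idx: int, clone_of: str | None = None,
                    frameshifts: list[tuple[str, int, str]] | None = None,
                    mge_here: bool | None = None):
        segs = list(segs)
        rng = _rng(config.seed, 4, leaf_idx)
        present = strain.split("-c")[0] in carriers if clone_of else strain in carriers
        ci = seg_index(segs, _SEG_CLUSTER)
        fs: list[tuple[str, int, str]] = []
        if present:
            cseq = segs[ci][2]
            if frameshifts is None:
                frameshifts = []
                for g in template.genes:
                    if rng.random() < config.frameshift_prob:
                        lo = g.start + g.length // 4
                        hi = g.start + (3 * g.length) // 4
                        pos = int(rng.integers(lo, hi))
                        kind = "insertion" if rng.random() < 0.5 else "deletion"
                        frameshifts.append((g.name, pos, kind))
            for g_name, pos, kind in sorted(frameshifts, key=lambda t: -t[1]):
                cseq = inject_frameshift(cseq, pos, kind,
                                         seed=config.seed + leaf_idx)
            fs = list(frameshifts)
            segs[ci] = (segs[ci][0], segs[ci][1], cseq)
            if mge_here is None:
                mge_here = rng.random() < config.mge_prob
            if mge_here:
                mi = seg_index(segs, _SEG_MGE)
                remnant = mutate_sequence(MGE_REMNANT, 0.01, rng=rng)
                # the remnant must stay an annotatable ORF
                remnant = _revert_nonsense(MGE_REMNANT, remnant,
                                           [(0, len(MGE_REMNANT))])
                segs[mi] = (segs[mi][0], segs[mi][1], remnant)
        else:
            segs[ci] = (segs[ci][0], segs[ci][1], "")
            mge_here = False
            frameshifts = []

        contig_id = f"{strain}.chr"
        pos = 0
        cluster_start = cluster_end = None
        seq_parts = []
        for kind, name, seq in segs:
            if kind == _SEG_CLUSTER and present:
                cluster_start, cluster_end = pos, pos + len(seq)
            if kind == _SEG_MARKER:
                markers[strain] = seq
            seq_parts.append(seq)
            pos += len(seq)
        genome_seq = "".join(seq_parts)
        genomes[strain] = GenomeRecord(strain_id=strain,
                                       contigs=[(contig_id, genome_seq)],
                                       replicon_labels={contig_id: "chromosome"})
        taxa[strain] = genus_of(strain)

        rec = TruthRecord(strain=strain, present=present, clonal_of=clone_of)
        if present:
            base = strain.split("-c")[0] if clone_of else strain
            rec.contig = contig_id
            rec.start, rec.end = cluster_start, cluster_end
            rec.acquisition = (f"hgt:{hgt_recipient[base]}"
                               if base in hgt_recipient else "vertical")
            rec.frameshifts = fs
            rec.cluster_gc = round(gc_content(
                genome_seq[cluster_start:cluster_end]), 2)
            rec.replicon_gc = round(gc_content(genome_seq), 2)
            rec.mge_adjacent = bool(mge_here)
            # gene spans in genome coordinates, shifted by injected indels
            deltas = [(p, +1 if k == "insertion" else -1) for _, p, k in fs]
            for g in template.genes:
                s, e = g.start, g.end
                for p, d in deltas:
                    if p < s:
                        s += d
                    if p < e:
                        e += d
                rec.gene_spans.append((g.name, cluster_start + s,
                                       cluster_start + e, g.strand))
        else:
            rec.replicon_gc = round(gc_content(genome_seq), 2)
        truth[strain] = rec
        return segs, frameshifts, mge_here

    for li, lf in enumerate(leaves):
        strain = lf.taxon.label
        segs, fs, mge_here = finish_leaf(strain, leaf_segs[strain], li)
        if strain in config.clonal_lineages:
            base_genome = genomes[strain].contigs[0][1]
            for c in range(config.clonal_copies):
                crng = _rng(config.seed, 5, li, c)
                n_subs = int(crng.integers(0, config.clonal_divergence_max + 1))
                cseq = base_genome
                if n_subs:
                    sites = crng.choice(len(cseq), size=n_subs, replace=False)
                    arr = bytearray(cseq.encode())
                    for s in sites:
                        cur = chr(arr[s])
                        choices = [b for b in "ACGT" if b != cur]
                        arr[s] = ord(choices[int(crng.integers(0, 3))])
                    cseq = arr.decode()
                cname = f"{strain}-c{c + 1}"
                base_rec = truth[strain]
                genomes[cname] = GenomeRecord(
                    strain_id=cname, contigs=[(f"{cname}.chr", cseq)],
                    replicon_labels={f"{cname}.chr": "chromosome"})
                rec = dataclasses.replace(
                    base_rec, strain=cname, clonal_of=strain,
                    contig=f"{cname}.chr" if base_rec.present else None,
                    frameshifts=list(base_rec.frameshifts),
                    gene_spans=[(g, s, e, st) for g, s, e, st
                                in base_rec.gene_spans])
                if base_rec.present:
                    rec.cluster_gc = round(
                        gc_content(cseq[rec.start:rec.end]), 2)
                rec.replicon_gc = round(gc_content(cseq), 2)
                truth[cname] = rec
                markers[cname] = cseq[_marker_span(segs)[0]:_marker_span(segs)[1]]
                taxa[cname] = genus_of(strain)

    result = PanelResult(genomes=genomes, truth=truth, markers=markers,
                         taxa=taxa, template=template, tree=tree,
                         config=config)
    if out_dir is not None:
        write_panel(result, out_dir)
    return result


def _marker_span(segs) -> tuple[int, int]:
    pos = 0
    for kind, _, seq in segs:
        if kind == _SEG_MARKER:
            return pos, pos + len(seq)
        pos += len(seq)
    raise SimulationError("no marker segment")


# ---------------------------------------------------------------------------
# On-disk emission


def truth_to_json(truth: dict[str, TruthRecord]) -> dict:
    return {name: dataclasses.asdict(rec) for name, rec in sorted(truth.items())}


def write_panel(result: PanelResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    for strain in sorted(result.genomes):
        write_fasta(result.genomes[strain], out / "genomes" / f"{strain}.fasta")
    write_fasta(dict(sorted(result.markers.items())), out / "cpn60.fasta")
    write_cluster_definition(result.template, out / "cluster_template.json")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_json(result.truth), fh, indent=1, default=str)
        fh.write("\n")
    feats = []
    for strain in sorted(result.truth):
        rec = result.truth[strain]
        if not rec.present:
            continue
        feats.append(Gff3Feature(rec.contig, "biosynthetic_gene_cluster",
                                 rec.start, rec.end, rec.strand,
                                 source="simulator",
                                 attributes={"ID": f"{strain}.cluster",
                                             "Name": result.template.name}))
        for g, s, e, st in rec.gene_spans:
            feats.append(Gff3Feature(rec.contig, "gene", s, e, st,
                                     source="simulator",
                                     attributes={"ID": f"{strain}.{g}",
                                                 "Parent": f"{strain}.cluster"}))
    write_gff3(feats, out / "truth.gff3")
    write_tsv(out / "taxa.tsv", ["strain", "genus"],
              sorted(result.taxa.items()),
              comments=["strain-to-genus map derived from leaf-name prefixes"])
    write_newick(result.tree, out / "species_tree.nwk")
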