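"""Readers and writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO, trees through dendropy; GFF3 and the JSON
cluster-definition / restriction-map dialects are small enough that they are
emitted and parsed directly here. All genomic coordinates are 0-based
half-open internally; GFF3 output converts to 1-based inclusive per the
standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class SequenceIOError(ValueError):
    """Malformed sequence input (empty file, duplicate ids, bad alphabet)."""


class ClusterDefinitionError(ValueError):
    """Cluster definition violates its own geometry (gene out of bounds...)."""


# IUPAC nucleotide codes; everything outside ACGT is normalized to N so that
# downstream identity and GC denominators have a single ambiguity symbol.
_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIG = str.maketrans({c: "N" for c in "URYSWKMBDHV"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, map IUPAC ambiguity codes to N, reject anything else."""
    s = seq.upper().replace("-", "")
    bad = set(s) - _IUPAC
    if bad:
        raise SequenceIOError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return s.translate(_AMBIG)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One strain's assembly: ordered contigs plus optional replicon labels."""

    strain_id: str
    contigs: list[tuple[str, str]]
    replicon_labels: dict[str, str] = field(default_factory=dict)

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class Gene:
    name: str
    start: int  # 0-based, within cluster sequence
    end: int    # half-open
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterDefinition:
    """A reference biosynthetic gene cluster: its sequence and gene layout."""

    name: str
    sequence: str
    genes: list[Gene]
    source_strain: str = ""
    accession: str = ""
    # gene order as supplied, before the by-start normalization
    supplied_order: list[str] = field(default_factory=list)

    OVERLAP_SLACK = 30  # bp of tolerated overlap between adjacent genes

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.sequence)):
                raise ClusterDefinitionError(
                    f"gene {g.name} span [{g.start},{g.end}) outside cluster "
                    f"of length {len(self.sequence)}"
                )
            if g.strand not in "+-":
                raise ClusterDefinitionError(f"gene {g.name}: bad strand {g.strand!r}")
        if not self.supplied_order:
            self.supplied_order = [g.name for g in self.genes]
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for a, b in zip(self.genes, self.genes[1:]):
            if b.start < a.end - self.OVERLAP_SLACK:
                raise ClusterDefinitionError(
                    f"genes {a.name} and {b.name} overlap by more than "
                    f"{self.OVERLAP_SLACK} bp"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def orf_count(self) -> int:
        return len(self.genes)

    def gene_seq(self, gene: Gene) -> str:
        s = self.sequence[gene.start:gene.end]
        return s if gene.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path, strain_id: str | None = None) -> GenomeRecord:
    """Read a (multi-contig) FASTA assembly into a GenomeRecord."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceIOError(f"empty FASTA file: {path}")
    seen: set[str] = set()
    contigs: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append((rec.id, normalize_sequence(str(rec.seq))))
    return GenomeRecord(strain_id=strain_id or path.stem, contigs=contigs)


def parse_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping (e.g. marker sets)."""
    rec = parse_fasta(path)
    return dict(rec.contigs)


def write_fasta(seqs: Mapping[str, str] | GenomeRecord, path: str | Path,
                width: int = 70) -> None:
    items = seqs.contigs if isinstance(seqs, GenomeRecord) else list(seqs.items())
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Cluster definitions (JSON dialect)


def parse_cluster_definition(path: str | Path) -> ClusterDefinition:
    with open(path) as fh:
        doc = json.load(fh)
    genes = [Gene(g["name"], int(g["start"]), int(g["end"]), g.get("strand", "+"))
             for g in doc["genes"]]
    return ClusterDefinition(
        name=doc["name"],
        sequence=doc["sequence"],
        genes=genes,
        source_strain=doc.get("source_strain", ""),
        accession=doc.get("accession", ""),
    )


def write_cluster_definition(cluster: ClusterDefinition, path: str | Path) -> None:
    doc = {
        "name": cluster.name,
        "source_strain": cluster.source_strain,
        "accession": cluster.accession,
        "length": cluster.length,
        "orf_count": cluster.orf_count,
        "sequence": cluster.sequence,
        "genes": [
            {"name": g.name, "start": g.start, "end": g.end, "strand": g.strand}
            for g in cluster.genes
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk, 0-based half-open in memory)


@dataclass
class Gff3Feature:
    seqid: str
    type: str
    start: int  # 0-based half-open in memory
    end: int
    strand: str = "+"
    source: str = "bgcsurvey"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t"
                f"{f.score}\t{f.strand}\t.\t{attrs}\n"
            )


def parse_gff3(path: str | Path) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise SequenceIOError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            feats.append(Gff3Feature(
                seqid=cols[0], source=cols[1], type=cols[2],
                start=int(cols[3]) - 1, end=int(cols[4]),
                score=cols[5], strand=cols[6], attributes=attrs,
            ))
    return feats


# ---------------------------------------------------------------------------
# Newick trees (dendropy)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    looks_literal = isinstance(source, str) and ("(" in source
                                                 or ";" in source)
    if isinstance(source, Path) or (not looks_literal
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise SequenceIOError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True,
                          real_value_format_specifier=".6f").strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def tree_leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# TSV with '#' header comments (the pipeline interchange dialect)


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence],
              comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
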