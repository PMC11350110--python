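"""End-to-end orchestration: simulate/load -> survey -> flanks -> gc -> phylo.

One config (YAML or JSON) drives a reproducible run; a single seed governs
every stochastic stage through deterministically derived substreams, and a
manifest records the tool version, config hash and seed so two runs with
the same config are byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .flanks import build_flank_profiles, conservation_matrix, extract_flanks
from .gc import gc_delta_span
from .io import (parse_cluster_definition, parse_fasta,
                 parse_fasta_dict, write_tsv)
from .phylo import bootstrap_support, build_msa, congruence_report
from .simulate import SimulationConfig, genus_of, simulate_panel
from .survey import SurveyParams, survey_panel


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # either a simulation block or on-disk inputs
    simulate: dict | None = None
    genomes_dir: str | None = None
    clusters_file: str | None = None
    taxa_file: str | None = None
    marker_file: str | None = None
    # thresholds
    min_cluster_identity: float = 40.0
    min_gene_coverage: float = 0.5
    flank_length: int = 5000
    homolog_identity: float = 30.0
    gc_flag_threshold: float = 5.0
    bootstrap_reps: int = 100
    distance_model: str = "jc69"

    def validate(self) -> None:
        if not 0 <= self.min_cluster_identity <= 100:
            raise PipelineError("min_cluster_identity outside [0, 100]")
        if not 0 <= self.min_gene_coverage <= 1:
            raise PipelineError("min_gene_coverage outside [0, 1]")
        if self.flank_length <= 0 or self.bootstrap_reps < 1:
            raise PipelineError("flank_length and bootstrap_reps must be positive")
        if not 0 <= self.homolog_identity <= 100:
            raise PipelineError("homolog_identity outside [0, 100]")
        if self.simulate is None and self.genomes_dir is None:
            raise PipelineError("config needs a 'simulate' block or genomes_dir")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as manifest)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            for key in ("hgt_events", "clonal_lineages", "carrier_lineages"):
                if key in sim_kwargs and sim_kwargs[key] is not None:
                    sim_kwargs[key] = tuple(
                        tuple(x) if isinstance(x, list) else x
                        for x in sim_kwargs[key])
            sim = SimulationConfig(**sim_kwargs)
            panel = simulate_panel(sim, out_dir=out / "panel")
            genomes = panel.genomes
            clusters = [panel.template]
            taxa = panel.taxa
            markers = panel.markers
        else:
            genomes = {}
            for f in sorted(Path(config.genomes_dir).glob("*.fasta")):
                rec = parse_fasta(f)
                genomes[rec.strain_id] = rec
            if not genomes:
                raise PipelineError(f"no FASTA in {config.genomes_dir}")
            clusters = [parse_cluster_definition(config.clusters_file)]
            taxa = {}
            if config.taxa_file:
                for line in Path(config.taxa_file).read_text().splitlines():
                    if line.startswith("#") or line.startswith("strain\t"):
                        continue
                    strain, genus = line.split("\t")[:2]
                    taxa[strain] = genus
            else:
                taxa = {s: genus_of(s) for s in genomes}
            markers = (parse_fasta_dict(config.marker_file)
                       if config.marker_file else {})

        stage = "survey"
        params = SurveyParams(min_cluster_identity=config.min_cluster_identity,
                              min_gene_coverage=config.min_gene_coverage)
        hits, prev_table = survey_panel(genomes, clusters, taxa,
                                        params=params, out_dir=out)
        accepted = [h for h in hits if h.accepted]

        stage = "flanks"
        summary_flanks = {}
        for cluster in clusters:
            flank_seqs = {}
            spans = {}
            for h in accepted:
                if h.cluster != cluster.name or h.cross_contig:
                    continue
                contig = h.gene_matches[0].contig
                s = min(m.start for m in h.gene_matches)
                e = max(m.end for m in h.gene_matches)
                strand = "+" if h.gene_matches[0].strand \
                    == h.gene_matches[0].template_strand else "-"
                spans[h.strain] = (contig, s, e, strand)
                flank_seqs[h.strain] = extract_flanks(
                    genomes[h.strain].contig(contig), s, e, strand,
                    length=config.flank_length)
            if len(flank_seqs) >= 2:
                profiles = build_flank_profiles(
                    flank_seqs, cluster.name,
                    min_identity=config.homolog_identity)
                presence, jac = conservation_matrix(profiles)
                presence.to_csv(out / f"flank_groups.{cluster.name}.tsv",
                                sep="\t")
                jac.to_csv(out / f"flank_conservation.{cluster.name}.tsv",
                           sep="\t")
                summary_flanks[cluster.name] = {
                    "strains": len(profiles),
                    "groups": int(presence.shape[1]),
                }

        stage = "gc"
        gc_rows = []
        for cluster in clusters:
            for h in accepted:
                if h.cluster != cluster.name or h.cross_contig:
                    continue
                contig = h.gene_matches[0].contig
                s = min(m.start for m in h.gene_matches)
                e = max(m.end for m in h.gene_matches)
                contig_seq = genomes[h.strain].contig(contig)
                rep = gc_delta_span(contig_seq, s, e,
                                    cluster=cluster.name, strain=h.strain,
                                    flag_threshold=config.gc_flag_threshold)
                gc_rows.append((rep.cluster, f"{rep.cluster_gc:.2f}",
                                rep.strain, f"{rep.replicon_gc:.2f}",
                                f"{rep.delta:.2f}", int(rep.hgt_flag),
                                rep.direction))
        write_tsv(out / "gc.tsv",
                  ["cluster", "cluster_gc", "strain", "replicon_gc",
                   "delta", "hgt_flag", "direction"], gc_rows,
                  comments=[f"seed={config.seed}",
                            f"flag threshold={config.gc_flag_threshold} points"])

        stage = "phylo"
        congruence: dict = {}
        for cluster in clusters:
            seqs = {}
            for h in accepted:
                if h.cluster != cluster.name or h.cross_contig:
                    continue
                contig = h.gene_matches[0].contig
                s = min(m.start for m in h.gene_matches)
                e = max(m.end for m in h.gene_matches)
                seqs[h.strain] = genomes[h.strain].contig(contig)[s:e]
            if len(seqs) < 3 or len(markers) < 3:
                continue
            msa = build_msa(seqs)
            support = bootstrap_support(msa, n_reps=config.bootstrap_reps,
                                        seed=config.seed,
                                        model=config.distance_model)
            (out / f"cluster_tree.{cluster.name}.nwk").write_text(
                support.annotated_newick())
            marker_msa = build_msa({s: markers[s] for s in seqs
                                    if s in markers})
            sp_support = bootstrap_support(marker_msa,
                                           n_reps=config.bootstrap_reps,
                                           seed=config.seed + 1,
                                           model=config.distance_model)
            (out / "species_tree.nwk").write_text(
                sp_support.annotated_newick())
            genus_map = {s: taxa.get(s, "unknown") for s in seqs}
            report = congruence_report(support.tree, sp_support.tree,
                                       genus_map)
            congruence[cluster.name] = report.to_dict()
        with open(out / "congruence.json", "w") as fh:
            json.dump(congruence, fh, indent=1, sort_keys=True)
            fh.write("\n")

        stage = "manifest"
        manifest = {
            "tool": "bgcsurvey",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_genomes": len(genomes),
            "n_accepted_hits": len(accepted),
            "prevalence_rows": len(prev_table),
            "flanks": summary_flanks,
            "congruence": congruence,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
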