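# bgcsurvey

Comparative-genomics survey toolkit for antimicrobial **biosynthetic gene
clusters (BGCs)** in bacterial genome assemblies, built for the workflow
used to chart the distribution and evolutionary history of the *Pantoea*
antibiotic clusters (agglomerin, andrimid, AGA, dapdiamide, herbicolin,
pantocins A/B, PNP-1…5) across enterobacterial genera. It is aimed at
microbial comparative genomicists who want each step of that workflow as
a tested, scriptable library rather than a one-off pipeline:

- **survey** — detect homologs of a reference cluster in (draft)
  assemblies by a seed-and-chain k-mer scan plus per-gene alignment, and
  apply the survey's inclusion filters: *completeness* (all query genes
  present), *synteny* (gene order preserved; whole-cluster inversion
  allowed; single-breakpoint contig splits accepted), and a nucleotide
  *identity floor* across the query cluster. Prevalence per genus is
  `round(100·k/n, 3)` half-away-from-zero.
- **restriction** — in-silico digestion and localization of a cluster by
  an ordered restriction-site fingerprint: windows of the map's span are
  scored +1/−1/−1 for matched/missed/extra sites with positional slack
  `tolerance × span` — the trick that pins an undescribed ~17-kb cluster
  inside a ~25-kb signature region.
- **flanks** — 5-kb flank extraction, stop-to-stop ORF prediction
  (table 11), single-linkage homolog grouping at ≥ 30% amino-acid
  identity, Jaccard flank-conservation matrices, mobile-element flags,
  and detection of frameshift-interrupted genes (adjacent ORFs tiling
  ≥ 70% of one reference protein).
- **gc** — %GC of each cluster vs its host replicon; the HGT flag fires
  at |Δ| ≥ 5 points (clusters in this family sit 5–20 points below, one
  ~5 above, their hosts).
- **phylo** — cluster trees and cpn60 marker species trees (NJ over
  p/JC69/K2P distances, column-resampling bootstrap) and a congruence
  report: Robinson–Foulds distance, per-genus monophyly, and a greedy
  *displaced-leaf* set in which horizontally transferred copies surface.
- **simulate** — a synthetic strain-panel generator with complete ground
  truth (cluster presence, GC offsets, HGT events, frameshifts, clonal
  duplicates, transposase remnants, tunable flank conservation), so the
  whole pipeline is exercised end-to-end with no downloads.

`docs/methods.md` documents the models, defaults and design choices.

## Worked example

The analysis scripts share one synthetic demo panel: two genera × 8
lineages, genus A carrying a 6-gene, 4.6-kb cluster at 15 GC points below
the 54.6%-GC host, one horizontal transfer into genus B, 80% sister
flank conservation, occasional frameshifts, one clonal pair.

```bash
python analysis/01_simulate_panel.py
python analysis/02_survey_prevalence.py
python analysis/06_tree_congruence.py
```

prints, among other things:

```
simulated 17 genomes (10 carriers) along the demo tree; ...
horizontal acquisitions: GenB_s2 (hgt:GenA_s1)

demo panel per-genus prevalence:
          cluster genus  strains_with_cluster  genomes_surveyed  percent
synthetic_cluster  GenA                     9                 9    100.0
synthetic_cluster  GenB                     1                 8     12.5

accepted hits vs truth: precision 1.000, recall 1.000

demo panel: RF 4, normalized 0.333; displaced leaves: ['GenB_s2']
HGT recipient displaced in 20/20 replicate panels
```

Read: every implanted cluster is recovered and accepted by the filters
(prevalence 9/9 in genus A; the single genus-B carrier is the transfer);
the cluster tree disagrees with the cpn60 species tree exactly at the
transferred copy, and the congruence report names the recipient.
`analysis/03…05` run the restriction localization (the true implant
window ranks first with 0 missed sites, and still first with 5% of map
sites dropped), the flank-conservation/MGE/frameshift profiling, and the
%GC screen (offsets −20…+5 recovered within 0.2 points; the 5-point flag
fires exactly for |offset| ≥ 5). Small result tables land in `results/`,
bulky FASTA output in `scratch/`.

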