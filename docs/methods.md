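# Methods

`bgcsurvey` reimplements, as a tested pipeline over synthetic data, the
comparative-genomics workflow used to survey antimicrobial biosynthetic
gene clusters (BGCs) across enterobacterial genera: detect syntenic
cluster homologs in assemblies, localize an undescribed cluster by its
restriction-site fingerprint, profile flanking-region conservation,
screen for %GC anomalies, and compare cluster trees against a cpn60
marker species tree. This note records the models, the parameters that
matter, and the design choices made where the workflow left them open.

## The synthetic strain panel

Real surveys run over thousands of public assemblies; this package ships
a generator (`bgcsurvey.simulate`) that produces panels with known ground
truth so every downstream stage is testable without downloads.

**Genome layout.** Each root genome is a single circular-free contig:
background sequence at the host composition (default 54.6% GC, typical of
*Pantoea*-like chromosomes), a cpn60-like marker gene (1,800 nt), a
cassette of flank ORFs on each side of the cluster slot (five 630-nt
genes per side, 30-nt spacers), a slot for a 300-nt transposase-remnant
cassette within 1 kb of the cluster edge, and the cluster itself. The
default synthetic cluster template has six 720-nt genes with 60-nt
spacers (~4.6 kb); the restriction worked example uses a 13-gene,
~17.4-kb template mirroring the dimensions of the largest clusters the
survey style targets.

**Composition targeting.** Background sequence is sampled with an exact
G+C count (fixed counts, shuffled), not merely an expected one. Coding
genes are sampled codon-wise with in-frame stops rejected; the per-base
G+C probability is pre-solved by bisection so the post-rejection
composition hits its target, and a stop-safe repair pass then pins the
exact count. When the cluster is auto-generated, its count is retargeted
to *realized baseline + offset*, rounded away from the host with a small
(~0.15 point) margin, so a configured offset is a lower bound on the
injected anomaly — a 5-point offset is guaranteed to trip a 5-point flag.

**Evolution.** Branch lengths are expected substitutions per site; a
branch of length *b* substitutes each site with probability
p = (3/4)(1 − e^(−4b/3)) (the JC69 relation), making corrected distances
additive along the tree. Two deliberate departures from a textbook JC
process:

- *Composition preservation.* Substituted sites receive a random
  permutation of their own bases rather than uniform random bases, and the
  hit rate is rescaled so the expected changed fraction still equals the
  branch rate. A uniform-replacement process drifts every sequence toward
  50% GC (about 1 point per 0.15 substitutions/site at 54.6% GC), which
  would erase the injected cluster/host offsets the %GC screen is supposed
  to recover. The public `mutate_sequence` keeps uniform replacement as
  its default; the stationary variant is opt-in.
- *Reading-frame preservation.* Substitutions that destroy a designed
  gene's start codon, terminal stop, or create an internal stop are
  reverted (and the reversion is composition-rebalanced). This is a
  purifying-selection stand-in: under a fully neutral process a 240-codon
  gene acquires roughly one nonsense mutation per 3% divergence, which
  fragments ORFs everywhere and swamps the deliberately injected
  frameshifts. Background sequence evolves fully neutrally.

**Events.** Horizontal transfers copy the *donor leaf's* evolved cluster
into the recipient, so the recipient's cluster carries donor-derived
divergence. Frameshifts are single-base insertions/deletions injected
per gene with probability `frameshift_prob`, placed uniformly in the
central half of the gene so both fragments remain resolvable ORFs.
Clonal copies differ from their parent genome by 0–2 substitutions.
Flank divergence operates on sister pairs (cherries): each flank ORF is
lost from one randomly chosen sister with probability
1 − `flank_conservation`, which makes the expected sister Jaccard index
equal `flank_conservation` exactly (a symmetric replacement scheme would
give f/(2−f) instead).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: codon usage and amelioration of transferred
DNA, indels beyond single-base frameshifts, recombination within
clusters, rearrangements, plasmids as separate replicons, and assembly
artifacts other than contig splits introduced by tests themselves.

**Divergence defaults.** The source survey does not state divergence
levels among its strains; panel trees here use branch lengths in the
0.01–0.15 substitutions/site range as an assumption, chosen so that
within-genus identity stays ≥ ~90% and between-genus identity ~70–85%,
the regime where nucleotide-level homolog detection is still the right
tool.

## Homolog detection and the inclusion filters

BLAST itself is out of scope; `find_candidate_loci` is a seed-and-chain
scan: exact k-mers (word size 11, the sensitivity regime of short-word
blastn) shared between cluster and contig are chained when colinear
(gap ≤ 3 kb, diagonal drift ≤ 400 bp), and chains covering ≥ 60 bp are
reported as candidate regions on either strand of any contig. On a
random 100-kb genome the expected chained coverage is far below this
floor, so random sequence yields no candidates; a true cluster at ≤ 20%
divergence yields hundreds of seeds.

Each cluster gene is then located inside the candidate with edlib
(infix alignment) and measured with a local alignment under the simple
scoring match +1 / mismatch −1 / gap −2 (Bio.Align.PairwiseAligner).
Identity is matches over aligned columns; coverage is the aligned
fraction of the query gene. A gene that is actually absent produces only
a short spurious local hit and fails the coverage filter
(`min_gene_coverage`, default 0.5).

The three filters mirror the survey's inclusion rules:

- **complete** — every query gene matched at sufficient coverage;
- **syntenic** — genomic order of matches equals template order with
  consistent orientation; a whole-cluster inversion (reversed order, all
  strands flipped) is allowed; hits split across two contigs are accepted
  when each piece is internally syntenic and the pieces partition the
  template at a single breakpoint;
- **identity** — length-weighted mean per-gene identity across the query
  cluster ≥ `min_cluster_identity`.

The published criterion "diverged by more than 60% nucleotide identity"
is ambiguous between *identity < 60%* and *divergence > 60%*; the default
here is `min_cluster_identity = 40%` (the divergence reading), exposed as
a knob so the other reading (60%) is one flag away. Overall identity is
computed over concatenated per-gene alignments weighted by gene length;
the original work states no formula for clusters split across contigs,
so the same rule is applied to the union of the pieces.

Prevalence is `round(100·count/total, 3)` with half-away-from-zero
rounding, which reproduces the published three-decimal percentages
exactly from the published counts.

## Restriction-map localization

The enzymes and fragment sizes used to localize the real pantocin B
cluster live in prior literature, so the module accepts any map and the
shipped example is synthetic (labeled as such): a ~25-kb signature window
around a ~17-kb implant, digested with three 6-cutters. `find_sites`
reports each duplex site once (palindromes once, non-palindromic patterns
searched on both strands); `digest` fragments always sum to the sequence
length. `locate_by_map` slides windows of the map's span along each
contig in both orientations and scores them by order-preserving greedy
matching of expected to observed sites: +1 matched, −1 missed, −1 extra,
positional slack = tolerance × span (default tolerance 0.05). Ranking is
deterministic (score, contig, position) and overlapping windows are
suppressed to the best of each stack. This is the simplest scoring that
makes "nearly identical restriction site pattern" operational.

## Flank profiling

5-kb flanks are extracted on each side of a detected cluster, truncated
(and flagged) at contig edges, and oriented so "upstream" precedes the
cluster in template orientation. ORFs are predicted with a stop-to-stop
heuristic — both strands, starts ATG/GTG/TTG, translation table 11, one
ORF per stop-bounded region (first start after the previous stop),
minimum 150 nt — an internal, deliberately simple stand-in for
GeneMark.hmm's heuristic models; it affects comparability of absolute ORF
counts, not the pipeline's logic. Homologs are grouped by single linkage
at ≥ 30% global amino-acid identity (identity-only, no coverage
requirement, matching common cluster-comparison practice); a 3-mer
shared-word screen skips hopeless pairs before alignment. Conservation
between strains is the Jaccard index over flank homolog-group sets.

Mobile-element flags fire on an annotation keyword (transposase,
integrase, insertion sequence, conjugal, tra‑, recombinase — "tra" only
as a gene-name prefix so "transcriptional regulator" stays unflagged) or
by alignment to a reference MGE protein set at ≥ 30% identity over ≥ 50%
coverage; the package ships the synthetic remnant's translation as that
reference.

Interrupted genes are reported when ≥ 2 adjacent same-strand ORFs align
to essentially disjoint segments (≥ 15 aa each, overlap ≤ 15 aa, gap ≤
2 kb) of one reference protein, jointly covering ≥ 70% of it, while no
single ORF covers ≥ 80% — the annotation footprint of a single-base
frameshift.

## %GC screening

`gc_content` is 100·(G+C)/(A+C+G+T) with N excluded from the
denominator; reports round to two decimals, internals stay full
precision. The HGT flag fires at |replicon − cluster| ≥ 5 points
(configurable), the low edge of the 5–20-point offsets seen in the
surveyed clusters, with the sign recorded (one real cluster sits ~5
points *above* its host plasmid). On real, multi-megabase replicons the
cluster is a negligible fraction of the baseline; on desk-scale
simulated genomes it is not, so `gc_delta_span` excludes the cluster
span from its baseline by default to avoid a finite-size shrinkage of
the measured offset.

## Phylogenetics and congruence

Maximum-likelihood inference with model selection is out of scope; the
deterministic substitutes are: a star-progressive aligner (sequences join
a k-mer-central seed, "once a gap, always a gap" — adequate because the
simulator produces substitution-only data apart from ±1-bp frameshifts),
p/JC69/K2P distances with pairwise deletion of gap/N columns (JC69
saturating at p ≥ 0.75, capped at 5.0 substitutions/site and flagged),
neighbor joining (via scikit-bio; exactly inverts additive matrices),
and column-resampling bootstrap (support = % of replicates containing
each original split; single RNG stream, replicate r uses draw block r).

Congruence between a cluster tree and the species tree is summarized by
the Robinson–Foulds distance (dendropy; normalized by 2(n−3)), per-genus
monophyly in both trees (unrooted semantics: the genus leaf set is one
side of some edge), and a **displaced-leaf set**: a greedy approximation
of the minimal leaves whose removal restores agreement. Disagreement is
the pair (monophyly violations, RF); leaves are removed one at a time,
each step taking the leaf whose removal most reduces that pair
(lexicographically, ties by label), stopping when agreement is reached,
no single removal improves, or four leaves remain. Driving residual RF
to zero matters when only one member of a genus carries the cluster —
its transfer breaks no monophyly but still displaces it topologically.

## Problem sizes and reproducibility

The shipped analyses and the acceptance script use panels of 16–40
genomes of 50–200 kb, clusters of 4.6–17.4 kb, 3 restriction-map
replicates, a sweep of seven GC offsets, 20 congruence replicates and
100–200 bootstrap replicates; one full pass takes about a minute on one
CPU. A single integer seed drives every stochastic stage through
deterministically derived substreams (numpy `SeedSequence`-style keyed
streams per tree node, leaf and event), and identical configurations
produce byte-identical outputs apart from the manifest timestamp.

## Known limitations

- Nucleotide-level seed-and-chain detection loses sensitivity past ~40%
  cluster divergence; the survey design shares this property, and no
  protein-level (HMM) detection is attempted.
- The ORF heuristic over-predicts relative to GeneMark-style models
  (no coding-potential score), inflating absolute flank ORF counts;
  conservation statistics are over homolog groups and are insensitive to
  this inflation.
- The star-progressive aligner is not a general MSA tool; with real
  indel-rich data a dedicated aligner should replace it behind
  `build_msa`.
- The displaced-leaf search is greedy and can over-report under heavy
  topological noise; it is an approximation, not a minimal set.
- Restriction-map scoring assumes complete digestion and ignores
  methylation and partial-digest effects.
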