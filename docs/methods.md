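# Methods

`cytopan` analyzes how multiheme cytochromes (MHCs) evolve within a
clade of metal-reducing bacteria: whether they mutate faster than the
core proteome, whether homology tools can name them reliably, and
whether the clade-wide cytochrome repertoire saturates as genomes are
added.  Every stage can be exercised on synthetic pangenomes with known
ground truth, so the pipeline's behavior is testable without genome
downloads.  This note records the models, conventions and numerical
choices behind each stage.

## MHC detection

A c-type heme is attached through the CXXCH motif (two thioether-bonded
cysteines plus the histidine axial ligand).  `count_heme_motifs` counts
non-overlapping, leftmost-first matches: overlapping candidate motifs
cannot both ligate heme, and leftmost-first makes the count
deterministic.  The default pattern set is `{CxxCH}`; the rarer
CX3CH/CX4CH variants are available behind `EXTENDED_PATTERNS` but off by
default, since most surveys count only the canonical motif.  A gene is
called an MHC at >= 2 motifs ("multi"); the threshold is a parameter.

## Homolog clustering

BLASTP is replaced by exact global alignment (Biopython
`PairwiseAligner`) under BLOSUM62 with affine gaps, open 11 / extend 1
(the first gap residue costs 11, each further residue 1).  Edge weights
are `score(a,b) / min(self(a), self(b))` clipped to [0, 1] — a bounded,
monotone surrogate for bitscore normalization — and edges below 0.3 are
dropped.  The default threshold was chosen so that unrelated random
proteins of typical gene length essentially never connect while family
members at the simulator's default divergence always do; it is a
configuration dial, not a claim of equivalence to any BLAST e-value
setting.

The similarity graph is partitioned with the Markov Cluster algorithm:
self-loops at each node's maximum incident weight (1.0 for isolated
nodes), column normalization, then alternating expansion (matrix
squaring) and inflation (elementwise power + renormalization), pruning
entries below 1e-6, until the matrix changes by less than 1e-8 or 200
iterations (non-convergence emits a warning and the current partition).
Clusters are read off attractor rows and merged into a strict
partition; MCL cannot move probability between disconnected components,
so components never merge.  Inflation 1 / 1.5 / 5 reproduces the
loose / default / stringent sweep used in the robustness checks.

Bidirectional best hits use the same graph; score ties are broken
lexicographically by gene id and flagged.  Annotation transfer copies
the reference name through each BBH pair, suffixing `_1.._k` in target
gene order when several targets hit one name — deliberately reproducing
the failure mode that turns paralogous periplasmic cytochromes into
arbitrary numbered annotations.

## Cluster curation

Clusters containing a reference-genome sequence are filtered before
dN/dS: members must be within 20% of the reference protein length
(|len − len_ref| <= 0.20·len_ref, i.e. relative to the reference — the
alternative pairwise-mean reading is not used) and carry a heme count
within ±2 of the reference.  Genomes that still contribute more than
one member are resolved by synteny: each flank gene within ±3 positions
of the candidate is counted as support when its homolog cluster also
occurs among the reference gene's ±3-position flank region.  Matching
against the flank *region* rather than the offset-identical position is
intentional: gene gain/loss and insertions shift offsets without
destroying neighborhood conservation.  The unique member reaching
support >= 2 is kept; otherwise the genome's members are removed as
unresolved paralogs.  This operationalizes, as a stated proxy, a
verification step that is manual in practice.  Genomes lacking the
reference gene contribute no data point; nothing is imputed.

## Pairwise dN/dS (NG86)

Proteins are aligned pairwise to the reference (every comparison is
against the reference, so no multiple alignment is required; externally
aligned sequences can be supplied via axt for exact replication of an
MSA-based workflow) and codons are threaded back onto the gapped
protein alignment.

Counting follows Nei–Gojobori:

* **Sites.**  Per codon position, the synonymous fraction of its
  single-nucleotide changes, renormalized over non-stop neighbors, so
  every codon contributes exactly 3 sites (s + n = 3).  Excluding stop
  mutations with renormalization (rather than counting them as
  nonsynonymous) matches the simulator, which rejects stop-creating
  proposals; the two conventions differ in the third decimal for
  typical genes.
* **Differences.**  For codon pairs differing at k positions, all k!
  minimal pathways are enumerated, pathways through stop codons
  discarded, and step classifications averaged over survivors.
* **Correction.**  pS = Sd/S and pN = Nd/N are corrected with
  Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p >= 3/4 is saturation and is
  reported as missing.

Codon columns containing gaps, stops or ambiguity characters in either
sequence are excluded pairwise (KaKs-Calculator-compatible behavior);
site totals are averaged over the two sequences, making the estimate
symmetric in sequence order.  ω = dN/dS is reported missing, with a
reason, when dS = 0 or either distance is saturated; such comparisons
are excluded from downstream statistics with counts logged.  The
genetic code is the standard bacterial code (translation table 11).
NG86 is the supported estimator; transition/transversion- and
codon-frequency-corrected estimators are deliberately out of scope, and
all calibration claims are made for κ = 1, where NG86 is unbiased.

## Statistics

Two-sample comparisons (core vs MHC ω within a genome) walk a fixed
decision tree: Shapiro–Wilk on each sample at α = 0.05; both normal →
F-test routes to Student's t (equal variance) or Welch's t; exactly one
non-normal → both samples are log-transformed (non-positive values
dropped and counted) and the variance logic re-applied; both non-normal
→ Wilcoxon rank-sum.  All tests are two-sided; samples below three
values return "insufficient data".  Significance tiers follow the
unusual legend convention preserved throughout: `*` P < 0.05, `**`
P < 0.001, `***` P < 0.0001.

Localization-class comparisons use Kruskal–Wallis with Dunn's post hoc
pairwise z-tests (pooled-rank means, tie-corrected variance), adjusted
with Bonferroni by default.  Dunn's test is implemented in-package; the
other statistics are scipy's.

## Pangenome spectra and accumulation

Cluster sizes (distinct genomes per cluster) are binned {1}, {2–9},
{>=10}; whether exactly-10 belongs to the top bin is a documented
convention (`bin10_inclusive`, default true; the {>=11} alternative is
selectable).  Accumulation curves add genomes in order of patristic
distance from the reference (ties lexicographic, flagged) and
re-cluster from scratch at each step.  Pairwise similarities do not
depend on which genomes are present, so the all-vs-all graph is built
once and MCL runs per step on the induced subgraph — identical results
to a full re-run at a fraction of the cost.

In the dichotomy check, "the total curve keeps rising" means new
clusters still appear when the most distant genome is added, and "the
shared (>= 2-genome) curve plateaus" means it gains at most one cluster
over the final two genome additions while the total curve gains at
least two more than that.  Saturation of a finite shared-family pool is
asymptotic, not exact — an accessory family whose second occurrence
happens to arrive with the last genome is sampling noise, not a failure
of saturation — hence the one-cluster allowance.

## Profile scoring

Profiles are per-column log-odds scores in bits: column residue
frequencies with additive pseudocounts (1.0 split evenly over the
alphabet; a single-sequence alignment warns and uses a 5× pseudocount)
against the alignment's overall residue distribution (uniform
background selectable); gap-majority columns are dropped.  A candidate
sequence's score is the best ungapped *local* match: over every
placement, the best contiguous run of profile columns (columns outside
the sequence or trimmed from the run contribute nothing).  Local
matching makes the score monotone under sequence extension — prepending
residues never lowers the maximum — which full-width scoring with
zero-scoring overhangs does not guarantee once matched columns can
score negative.  Column maxima of a log-odds profile are always >= 0,
so a consensus sequence still attains the profile's maximal achievable
score.  This is explicitly not a profile-HMM implementation: no
insert/delete states, no E-values, and scores are not on HMMER's scale
(any bitscore cutoff is a configuration value).  The question it
answers — does any threshold separate family members from paralogs — is
a property of score overlap, which `separability` reports as
min(trained) − max(other), an overlap fraction, and whether a perfect
threshold exists.

## The synthetic pangenome generator

The generator emulates a clade of genomes related by a pure-birth
(Yule) tree: waiting times between splits are exponential in the number
of extant lineages, a final waiting time follows the last split so
terminal branches are positive, and branch lengths are rescaled so
every tip sits at a root-to-tip depth equal to `divergence` (expected
proposed mutations per site; default 0.2).  Only patristic distances
feed the analysis, so the topology model is immaterial.

Sequence evolution is proposal/acceptance on point mutations: proposals
are Poisson(branch length × sites); each picks a uniform site and an
alternative base (transition weighted κ against the two transversions,
default κ = 1); proposals creating stops or touching locked positions
are rejected; synonymous proposals are accepted with min(1, 1/ω),
nonsynonymous with min(1, ω).  With κ = 1 the realized dN/dS equals ω
by construction, giving an analytic acceptance surface against which
NG86 recovery is tested.  κ ≠ 1 is supported but excluded from
calibration claims because NG86 is biased under transition bias.

Genome content: core families (default 30) are present everywhere at
ω = 0.1; accessory MHC families (default 20) carry 2–12 CXXCH motifs at
locked codons, a planted localization cycling through inner-membrane /
complexed-periplasmic / free-periplasmic / outer-surface classes with
ω = 0.1 / 0.5 / 1.0 / 1.0 respectively, and are retained per genome
with probability 0.6; retained copies duplicate with probability 0.1
(the paralog re-evolves over half the root-to-tip divergence and is
inserted at a random genome position, so orthologs keep their
neighborhoods and duplicates do not); per genome, Poisson(5) de novo
singleton genes emulate cytochromes without homologs in any other
strain.  The planted ω classes reproduce the qualitative low / medium /
high ordering of localization classes; no quantitative per-gene rates
are claimed.  Motif positions are locked rather than re-imposed, and
nonsynonymous proposals that would change a gene's motif count are
additionally rejected — locking alone cannot prevent new motifs arising
elsewhere — so curation always sees stable heme counts.  Planted motif
density is capped at one motif per 15 codons; real multiheme
cytochromes run from roughly one heme per 25 residues upward, and
without the cap short genes at the top of the motif range would be
mostly motif residues, linking unrelated families in the similarity
graph.

Two auxiliary generators encode the annotation case studies.
`simulate_ortholog_paralog_pool` builds a duplication-rich pool of
small, weakly constrained cytochromes: one deeply diverged ortholog per
genome (branch 0.3–1.0, ω = 1) plus recent within-genome duplicates
(branch 0.02–0.3).  A profile trained on the orthologs cannot threshold
out the paralogs: a recent duplicate is a near-identical sister of a
training sequence, so its score tracks its parent's.
`simulate_divergent_families` builds anciently split (branch 0.8),
internally tight (branch 0.05, ω = 0.1) families, where a profile
trained on one family separates cleanly.  These two regimes — not clean
clades of equal depth — are what make threshold-based annotation fail
for one cytochrome class and work for another.

What the generator does *not* model: indels (alignment code is still
exercised through synthetic gap injection in tests), recombination or
horizontal transfer mechanics (singletons appear de novo rather than
arriving by HGT), nucleotide composition skew, and genuine operon
structure.  Passing tests therefore demonstrate the pipeline's
correctness and the qualitative phenomena under these idealized
conditions, not quantitative agreement with any real genome set.

## Problem sizes and determinism

All randomness flows through seeded numpy generators; identical seeds
give byte-identical genomes, trees, tables and pipeline outputs.  The
packaged property checks use deliberately desk-scale conditions chosen
to keep each check's Monte-Carlo error well inside its assertion
margin: estimator calibration and recovery use 100–200 replicate pairs
of 500 codons; the accumulation and separability contrasts use 50
replicates of 8-genome / 12-genome pools with 40–85-codon genes; the
statistical calibration uses 1000 null comparisons of 20 values each.
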