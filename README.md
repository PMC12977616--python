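# cytopan

Multiheme cytochrome pangenome and molecular-evolution analysis.

Dissimilatory metal-reducing bacteria (*Geobacter*, *Shewanella* and
relatives) move electrons to extracellular acceptors through chains of
multiheme *c*-type cytochromes (MHCs).  These proteins are notoriously
hard to annotate: genomes carry many paralogs, homologs are poorly
conserved between strains, and each newly sequenced genome brings
cytochromes found nowhere else.  `cytopan` is a toolkit for
quantifying exactly that, aimed at comparative genomicists working on
extracellular electron transfer:

* **detect** MHCs by counting CXXCH heme-binding motifs;
* **cluster** homologs from all-vs-all protein similarity with the
  Markov Cluster (MCL) algorithm at configurable stringency, with
  bidirectional-best-hit annotation transfer and its documented failure
  modes;
* **curate** clusters for safe ortholog comparisons (length within 20%
  of the reference, heme count within ±2, paralogs resolved by gene
  synteny);
* **estimate dN/dS** (ω) for each homolog against a reference genome
  using Nei–Gojobori counting — fractional site counts per codon,
  pathway-averaged differences, Jukes–Cantor correction:

  ω = dN/dS,  d = −(3/4)·ln(1 − 4p/3),  ω ≈ 1 neutral, ω < 1 purifying;

* **compare** core-gene vs cytochrome ω per genome through a fixed
  statistical decision tree (Shapiro–Wilk → F-test → t / Welch /
  log-transform / Wilcoxon; Kruskal–Wallis + Dunn across localization
  classes);
* **characterize the pangenome** with cluster-size spectra (singleton /
  2–9 / ≥10-genome bins) and accumulation curves that add genomes in
  order of patristic distance from the reference, with and without
  singletons;
* **score profiles**: position-specific log-odds profiles built from
  family alignments, to ask whether any bitscore threshold can separate
  a cytochrome family from its paralogs.

A synthetic pangenome generator (`cytopan.synthetic_data`) plants known
selection strengths (ω per localization class), gene gain/loss,
duplication, locked heme motifs, and per-genome singleton genes on a
simulated phylogeny, so the entire pipeline runs and is tested without
downloading a single genome.

## Worked example

Run the full pipeline on a simulated 8-genome clade (12 core families,
10 accessory MHC families, ~3 unique singleton genes per genome):

```bash
cytopan run --config demo.yaml --out-dir demo_out
```

with `demo.yaml`:

```yaml
simulate:
  n_genomes: 8
  n_core: 12
  n_accessory: 10
  singleton_rate: 3.0
  seed: 1
```

The run prints a per-stage summary:

```
detect: {'n_genes': 178, 'n_mhc': 82}
cluster: {'n_clusters': 43, 'inflation': 1.5}
curate: {'n_clusters_with_reference': 21, 'n_kept': 143}
dnds: {'n_comparisons': 122, 'n_missing_omega': 0}
stats: {'n_genomes_tested': 7, 'n_significant': 5}
pangenome: {'n_mhc_clusters': 31, 'spectrum_bins': {'1': 21, '2-9': 10, '>=10': 0},
            'final_total': 31, 'final_shared': 10}
```

`demo_out/stats.tsv` holds the per-genome core-vs-MHC comparison:

```
genome_id    test  transformed        p tier  n_core  n_mhc
      g02 Welch-t        False 0.013004    *      12      5
      g03 Welch-t        False 0.038107    *      12      6
      g04 Welch-t        False 0.014285    *      12      8
      g05 Welch-t        False 0.130333   ns      12      3
      g06 Welch-t        False 0.132558   ns      12      4
      g07 Welch-t        False 0.008884    *      12      6
      g08 Welch-t        False 0.014753    *      12      6
```

Five of seven genomes show significantly higher cytochrome mutation
rates than core genes (`*` = P < 0.05); the two non-significant genomes
are precisely the ones with the fewest curated cytochrome comparisons
(n = 3–4), where power is limited.  `demo_out/curve.tsv` shows the
pangenome dichotomy — the total MHC cluster count keeps climbing with
every genome added (9 → 31) because of per-genome singletons, while the
count of clusters shared by ≥ 2 genomes saturates at 10 by the fifth
genome:

```
 step genome_id  distance  n_clusters_total  n_clusters_shared
    1       g01     0.000                 9                  0
    2       g02     0.161                13                  5
    5       g05     0.378                21                 10
    8       g08     0.400                31                 10
```

Every stage is also exposed as a library function and as an individual
CLI subcommand (`simulate`, `detect`, `cluster`, `curate`, `dnds`,
`pangenome`, `profile`, `stats`, `run`) reading and writing plain
FASTA / Newick / TSV / axt files.

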