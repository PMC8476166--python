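# orthocomplete

Completeness and redundancy assessment of genome assemblies, annotated gene
sets and transcriptomes from **universal single-copy orthologs** — genes
expected to occur exactly once in nearly every genome of a lineage.  The
toolkit is aimed at people QC-ing assemblies and metagenome-assembled
genomes: it answers *"how much of the expected gene content is actually in
this assembly, and is anything duplicated or contaminated?"* without needing
a reference genome.

## The model

A **marker dataset** is a set of `n` single-copy ortholog families for one
lineage.  Each family carries an aligned seed set, a bit-score cutoff and a
length band (mean ± 2σ of the ungapped seed lengths).  Assessment searches
the input's proteins against a position-specific profile per family
(local alignment with match/insert/delete states; Viterbi max-path and
forward sum-over-paths scores, both exact) and classifies every marker:

- **Complete (C = S + D)** — some locus scores ≥ cutoff with an aligned
  length inside the band; **S**ingle if exactly one such locus,
  **D**uplicated if more;
- **F**ragmented — a cutoff-passing hit whose length falls outside the band;
- **M**issing — nothing reaches the cutoff.

Counts aggregate into the canonical score string

```
C:99.1%[S:9.6%,D:89.5%],F:0.1%,M:0.8%,n:4896
```

with percentages rounded half-up to one decimal.

For nucleotide input, genome mode extracts six-frame ORFs, auto-selects the
genetic code among the dataset's candidates by **coding density** (fraction
of the genome covered by ORFs — reading a TGA-recoding genome with the wrong
table truncates genes and visibly lowers the density), and runs a second,
more sensitive search pass (relaxed minimum ORF length, higher sensitivity)
restricted to the markers the first pass missed.  Auto-lineage mode scores
the input against the domain-level root datasets and then descends the
dataset hierarchy greedily to the most specific dataset the input supports;
completeness against *off-domain* roots doubles as a contamination screen.
A depletion benchmark harness removes known fractions of marker genes (and
masks their genomic spans via GFF3) to verify that reported missingness
tracks true gene loss, with FP/FN/precision computed against a frozen
marker-to-gene truth mapping.

Everything is testable end-to-end without downloads: a simulator evolves
marker families along a species tree and emits genomes, gene sets, GFF3 and
truth tables, plus marker datasets derived from any subset of its species.

## Worked example

`python examples/assess_genome.py` simulates a five-species lineage, builds
a 30-marker dataset from four species and assesses the held-out genome:

```
input: sp5  dataset: demo_bacteria (n=30 markers)
workflow: genome_orf_two_pass, genetic code 11
C:96.7%[S:96.7%,D:0.0%],F:3.3%,M:0.0%,n:30
```

29 of 30 markers are complete in a single copy; one scored above its cutoff
but aligned slightly shorter than its family's length band (fragmented), and
none is missing — the assembly contains the lineage's expected gene content.
The other examples show genetic-code selection (`genetic_code_selection.py`),
auto-lineage descent plus the contamination screen (`auto_lineage.py`; a
50/50 bacterial/eukaryotic mixture reports `eukaryota C:50.0% <- flagged`)
and the depletion benchmark (`depletion_benchmark.py`, where mean missing
counts rise one-for-one with the number of removed genes and precision stays
1 wherever defined).

A thin CLI mirrors the shell workflows:

```bash
orthocomplete fixture demo/ --seed 3            # materialise a fixture bundle
orthocomplete assess demo/sp1_genome.fna DATASET_DIR --mode genome
orthocomplete batch *.fna --datasets DATASETS_DIR   # auto-lineage + summary TSV
orthocomplete screen genome.fna --datasets DATASETS_DIR
```

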