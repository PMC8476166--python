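# Methods

This note documents the models, defaults and design choices behind
`orthocomplete`, and what the synthetic fixtures do and do not demonstrate.

## Profile model and scoring

Each marker family compiles to a local-alignment profile. Match columns are
the alignment columns with gap fraction < 0.5; emissions are residue counts
with add-one smoothing over the 20-letter alphabet (a single-seed column
emits its residue with probability 2/21), converted to natural-log odds
against a uniform background. Insert states emit at background (log-odds 0);
unknown residues (X and friends) likewise score 0 everywhere. Transition
log-probabilities are fixed rather than estimated — match→insert =
match→delete = ln 0.05, insert→insert = delete→delete = ln 0.4, with the
complements ln 0.9 and ln 0.6 — because estimating them from a handful of
seeds would be noise, and fixed values make scores exactly reproducible.

Alignment is local on both sides: a path enters any match state at any
target position for free, and exits any match state for free. The Viterbi
score is the best path, the forward score the log-sum over all paths; both
are reported in bits (nats / ln 2), and the hit envelope always comes from
the Viterbi traceback. The dynamic programs are validated against an
exhaustive enumeration of every legal path on small cases (profiles ≤ 4
columns, targets ≤ 5 residues), which bounds the implementation error at
the 1e-9-bit level; forward ≥ viterbi holds by construction.

The profile engine deliberately replaces an external HMM search stage: it is
single-hit, uncalibrated (no E-values) and simpler than a Plan7
architecture, but exact and self-contained, which is what the test
surface needs.

`search()` exposes a sensitivity dial in [1, 7]: below 6, a target is only
scored against a family when it shares ≥ ceil(8 − s) exact 4-mers with a
seed sequence; at 6 and above every pair is scored. The prefilter can only
remove candidates, so recovered markers are non-decreasing in sensitivity.
Hits are reported down to half the family cutoff so that downstream
consumers can inspect near-misses; classification applies the full cutoff.

## Datasets and cutoff calibration

A dataset is built by keeping the orthogroups present in exactly one copy in
at least `single_copy_threshold` (default 0.9) of the covered species. The
family bit cutoff is 0.9 × the minimum self-score of the seed members
against the family profile: every seed clears it with margin, and orthologs
about as diverged as the seeds are from each other still pass. The length
band is mean ± 2σ of the ungapped seed lengths (population σ; σ = 0 demands
an exact aligned length). The on-disk layout is a plain-text directory —
`dataset.cfg`, `scores_cutoff.tsv`, `lengths_cutoff.tsv` (two-decimal
floats, fixed ordering, byte-stable), `seeds/<marker>.faa` — and
translation tables use NCBI numbering.

## Genome mode

Gene extraction is ORF-based: maximal start→stop spans in all six frames,
one call per stop codon starting at the first initiator after the previous
stop, minimum span 90 nt. Only ATG is treated as an initiator by default:
the NCBI tables list many alternative starts that only make sense weighed
by a trained gene model, and an unweighted scanner honouring them fragments
real genes. Coordinates are 1-based inclusive on the forward strand
(GFF3 convention); codons containing N translate to X.

The genetic code is chosen among the dataset's candidates by coding density
(fraction of positions covered by the union of ORF spans). When candidate
codes have nested stop sets — table 4's {TAA, TAG} is a subset of table 11's
{TAA, TAG, TGA} — the relaxed code's density can never be lower, so an
exact argmax would always drift to the relaxed code on spurious-ORF noise.
The decision is therefore a margin test: densities within
`code_tie_tolerance` (default 0.01, i.e. one percentage point of density)
are tied and the earliest-listed candidate wins. A genome that truly uses
TGA read-through loses an order of magnitude more density than that when
read with the strict table (every internal TGA truncates a gene), so the
margin separates the cases cleanly.

Two passes realise the rescue workflow: pass 1 searches all markers at
sensitivity 4.5 over ORFs ≥ 90 nt; pass 2 halves the ORF floor to 45 nt,
raises sensitivity to 6 (prefilter off) and searches only the markers
without a pass-1 hit at or above cutoff. Each hit records its pass.
Transcriptome mode translates each transcript in six frames, splits at
stops and searches the resulting peptides directly.

This ORF model carries no codon-usage or RBS scoring and no intron
awareness; genome mode is valid for prokaryote-style, intron-poor input and
for the simulator's fixtures, and that limitation is intentional scope.

## Classification

Hits are clustered into loci before status calls: two hits on the same
sequence whose envelopes overlap by ≥ 50% of the shorter envelope are one
locus (best score kept). In genome mode the envelope used is the hit's
*genomic* span, so overlapping ORFs in different frames over one gene do
not fake a duplication, while an exact gene copy elsewhere does count.
Percentages round half-up to one decimal, and S + D + F + M = n is asserted
on every result. The parasitic recalculation removes a user-supplied marker
exclusion list (markers legitimately absent in genome-reduced parasites)
and recomputes all percentages on the reduced n.

The cross-domain screen assesses the input against each domain root dataset
and flags any off-domain root whose completeness exceeds an advisory
threshold (default 40%, configurable). A background of cross-domain matches
is normal, which is why the flag is advisory evidence rather than a verdict,
and why the tool never claims to separate duplication from contamination.

## Auto-lineage

Root selection assesses the input against every candidate root (optionally
prokaryote-only) and keeps the highest completeness, breaking ties by fewer
missing markers and then a fixed domain order. Descent then walks the
dataset hierarchy greedily: at each node every child dataset is assessed and
the best child is entered if its completeness is within
`descent_tolerance` (default 2.0 percentage points) of the current node's —
higher-resolution datasets carry more markers and score slightly more
conservatively, so a small allowance prevents spurious stops. This
score-driven descent is a functional stand-in for phylogenetic placement:
same contract (root scoring first, then the most specific supported
dataset), different mechanism, and the difference is stated loudly here on
purpose. Batch mode applies the full workflow per input and emits one
summary row per input in input order; a failing input yields an error row,
never an abort.

## Depletion benchmark

Protocol `full_gene_set` removes a fraction of *all* genes and only measures
score degradation. Protocol `marker_only` first freezes a truth mapping
(each marker's best complete-quality gene from an exhaustive proteins-mode
search), then removes genes only from the mapped set, adding an exhaustive
100% level with a single replicate. Removal counts are rounded half-up;
one master seed spawns per-(level, replicate) child seeds so replicates are
independent but the whole report reproduces byte-for-byte. Genome-mode
depletion masks each removed gene's GFF3 span with N, preserving lengths.
Against the frozen truth: a marker still reported after its gene was removed
is a false positive, a marker reported missing while its gene remains is a
false negative, and precision is TP/(TP+FP) (undefined when TP+FP = 0).

## The simulator, and what passing tests show

`simulate_lineage` draws ancestor proteins i.i.d. from a background
distribution (uniform by default; first residue fixed to M so genes keep a
start codon), evolves them along a newick species tree with per-site
substitution probability 1 − exp(−branch length) and background-proportional
replacement, reverse-translates with uniformly chosen synonymous codons,
and lays genes on random strands separated by random intergenic spacers.
Defaults: 30 markers of 60–120 aa, intergenic 60–100 nt, genetic code 11,
single contig per species. Terminal stop codons are drawn from {TAA, TAG}
so gene boundaries read identically under every candidate code.

Two deliberate departures from pure uniformity keep ground truth exact.
First, spacers are flanked by 12-nt TTAA-repeat walls (stop codons in all
six frames, self-reverse-complementary), so no reading frame crosses a gene
boundary and every gene's ORF equals its annotated span. Second, synonymous
choices are locally revised to scrub TGA (non-coding phases) and TCA motifs
from gene bodies where composition allows: these are exactly the motifs
whose stop status differs between nested candidate codes, so scrubbing them
makes coding density code-independent on genomes that do not use TGA
read-through. A coding-phase TGA (tryptophan under table 4) is never
touched — it is the biological signal the code-selection test relies on.

The model has no indels, no rate heterogeneity, no realistic codon usage,
no introns and no rearrangements. Fixture-passing therefore demonstrates
the engine's bookkeeping and score semantics — conservation of counts,
exact duplication accounting, missingness tracking true gene loss, sound
lineage descent — not calling performance on real assemblies, where gene
finding and marker divergence are far harsher.

## Numerical and degenerate-input conventions

Scores use natural log internally and bits at interfaces; −1e30 stands in
for −∞ inside the numba kernels (logaddexp-safe). Empty proteins are
no-hits, not errors; empty input files are errors before any search; a
dataset with zero markers refuses to serialise; excluding every marker in
the parasitic recalculation is an error. Ties in root selection fall back
to fewer missing markers, then the fixed domain order (bacteria, archaea,
eukaryota, viruses); ties in descent fall back the same way, then to
dataset name. Problem sizes in the test suite and acceptance script (10–100
markers, 5–12 species, genomes of 5–60 kb) were chosen so the full suite
exercises every workflow end-to-end in about a minute on one CPU.
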