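# Methods

This note records the algorithmic conventions used throughout `pandorapan`,
in enough detail to reproduce every number the pipeline reports.

## Input conventions

Predicted proteins are read from per-genome FASTA files. The genome identity
of a record is taken from the header prefix before `|` (`>G1|orf001` →
genome `G1`, gene `orf001`), falling back to the file stem when no `|` is
present. Proteins shorter than 50 amino acids are excluded (the conventional
minimum ORF length for giant-virus annotation); every exclusion is logged.
Ambiguous residue codes (`B Z J U O *`) are coerced to `X`. Duplicate gene
identifiers across input files are an error, not a warning.

Tabular homology hits use the 12-column BLAST "outfmt 6" dialect with
1-based inclusive coordinates. Conversion to 0-based half-open intervals
happens in exactly one place (`HitRecord.q_interval`/`s_interval`) so
off-by-one drift cannot accumulate.

## Pairwise alignment

All within-pipeline alignments are exact Smith–Waterman local alignments
with affine gaps — no heuristic seeding, banding, or X-drop. Protein
alignments use BLOSUM62 with gap open 11 / extend 1; nucleotide alignments
use match +2 / mismatch −3 with gap open 5 / extend 2. A contiguous gap of
length *g* costs `open + g·extend` (the NCBI convention: the first gap
column is charged open+extend). The kernel is deterministic: among
equal-scoring traceback moves the preference is diagonal > up > left, and
the reported optimum is the first-encountered maximal cell in row-major
order. The kernel is compiled with numba and is verified in the test suite
against an independent pure-Python dynamic-programming oracle implementing
the same conventions.

Two identity conventions coexist and are never mixed implicitly:

* **identity over the shorter sequence** (identical columns / length of the
  shorter sequence) — the CD-HIT convention, used by the clustering
  thresholds and the reciprocal-hit orthology thresholds;
* **identity over alignment columns** (identical columns / alignment
  columns, gaps included) — the BLAST-style convention, used for AAI and
  when interpreting tabular hits.

E-values are Karlin–Altschul approximations `E = K·m·n·exp(−λS)` with
*ungapped* constants: λ=0.3176, K=0.134 for BLOSUM62 protein scores, and
for the +2/−3 nucleotide scheme λ solved numerically from
`Σ pᵢpⱼ·exp(λ·sᵢⱼ) = 1` at uniform base frequencies with K=0.41. They are
filtering devices for synthetic data, not reproductions of BLAST output.

## Greedy clustering and pangenome delineation

Proteins from all genomes are pooled, sorted by decreasing length (ties
broken lexicographically by gene id, which makes the result independent of
input file order), and processed once. Each sequence joins the cluster of
the **best-identity** existing representative that passes both thresholds —
identity ≥ 30% over the shorter sequence and aligned coverage ≥ 50% of the
shorter sequence (`cov_mode="both"` additionally requires 50% of the longer
one) — or founds a new cluster. Joining the best qualifying representative
rather than the first one (CD-HIT's rule) removes residual order
sensitivity at the cost of aligning against every current representative.

No k-mer pre-filter is applied, deliberately: at a 30% identity floor the
shared-k-mer count lower bound is vacuous (a pair at exactly 30% identity
can share no k-mer of any length k ≥ 2), so no pair can be *proven* below
threshold without running the dynamic program. Every comparison therefore
runs the full DP.

The **pangenome** is the set of all clusters; the **strict core** is the
subset with at least one member in every genome. A gene is a core gene iff
its cluster is core; a gene is a paralog iff it shares a cluster with
another gene of the same genome (counted as genes, not pairs). Coding
capacity is genes per kbp reported to two decimals, with an optional
truncation mode for tables that truncate rather than round the second
decimal.

Accumulation curves add genomes one at a time: at step *k* the pangenome is
every cluster seen among the first *k* genomes and the core is every
cluster covering all *k*. Pan curves are checked non-decreasing and core
curves non-increasing at construction time. The endpoints are
order-invariant; the paths are not, so the openness verdict averages over
orderings: the pangenome is called **open** when the mean relative pangenome
increase at the final genome addition exceeds 5%.

## Orthology and AAI

A best hit is the highest-scoring subject (raw alignment score for the
built-in aligner, bitscore for tabular input), with ties broken by higher
identity then lexicographically smaller subject id. A best-reciprocal-hit
(BRH) pair is two genes that are each other's best hits with identity
strictly greater than 30% and coverage ≥ 70% on both sequences
(`cov_mode="query"` relaxes to the query side). Ortholog groups are the
connected components of the graph whose edges are all pairwise BRH pairs;
the headline statistic is the number of groups containing at least one gene
from every genome.

AAI between two proteomes is the unweighted mean of per-pair percent
identity (BLAST-style, over alignment columns) across BRH pairs (symmetric)
or one-way best hits (asymmetric; the two directions are reported
separately, never silently averaged). Zero qualifying pairs yields an
explicit empty result, never an AAI of 0.

## ORFan and marker classification

An ORFan is a predicted ORF with no qualifying database hit at e ≤ 1e−3 and
query coverage ≥ 30%. By default the single best (highest-bitscore) hit is
judged against both thresholds; `cov_source="any"` rescues a gene if any
single hit passes, and `cov_source="union"` pools the spans of all hits
with e ≤ 1e−3 and requires their merged coverage to reach the threshold.
Marker (NCVOG) presence is a binary marker × genome matrix built from
qualifying hits, with the all-genome count as the headline. Taxon tallies
count non-ORFan genes by the label of their best hit, as integer
percentages of genes with a best hit.

## MITE scanning

MITE queries are aligned locally against each scaffold on both strands.
Multiple hits are found by iterative masking: the best local alignment is
recorded, its genomic span is masked with `N` (which scores −3 against
everything, so masked runs cannot re-align), and the scan repeats until no
hit passes e ≤ 1e−3. Hits overlapping by more than 50% of the shorter hit
are merged, keeping the higher-scoring one. A hit is called **full-length**
when it covers ≥ 90% of its query and its genomic span is 100–600 bp.
TIR/TSD structure is then verified directly on the genome sequence: the TIR
arm is the longest element prefix whose reverse complement matches the
element suffix with ≤ 2 mismatches, and the TSD is the longest identical
direct repeat (2–10 bp, exact match, searched longest-first) immediately
flanking both ends. Hits at contig edges are flagged `contig_edge` instead
of being assigned a TSD.

## Synthetic data with planted truth

The generator emulates a giant-virus pangenome: families are partitioned
into **core** (in every genome), **shell** (in each genome with probability
`shell_p`) and **cloud** (unique to one genome; the ORFan-like fraction).
Protein lengths follow a gamma distribution with mean 250 aa and SD 200 aa,
truncated to [50, 2500].

Family members derive from a common ancestral sequence by independent
per-site substitution (no indels). The per-site rate μ is chosen so the
**expected pairwise identity between two members** equals the requested
target *t*: two members agree at a site if neither mutated, `(1−μ)²`, or if
both mutated to the same of the 19 alternatives, `μ²/19`, giving
`μ = (19/20)(1 − sqrt(1 − (20/19)(1−t)))`. (Mutating each member at rate
`1−t` would give pairwise identity ≈ t², which is not what a target
identity means.) Paralogs are duplicated from a genome's member and
re-mutated at μ/2, so within-genome copies are detectably more similar than
cross-genome orthologs.

Planted MITEs are built as TIR + internal region + reverse-complemented TIR,
flanked by two identical TSD copies, placed without overlap by drawing
sorted offsets into the free sequence. Diverged copies mutate only the
internal region so TIRs and TSDs stay exact.

## Expression integration

An ORF is **transcribed** when its read counts summed over all timepoints
reach 10. Proteomics input is a flat set of detected gene ids. The
cross-tabulation joins these calls with core/ORFan status and asserts
margin conservation (core + non-core = all genes; concordant ⊆ transcribed
and ⊆ detected) on every run.

## Rounding and determinism

Reported percentages use round-half-up (via `decimal`), not Python's
half-even rounding; ORFan fractions are reported to one decimal, most other
percentages as integers or one decimal as noted per function. All file
writers emit records in lexicographic order and no output contains a
timestamp, so the complete pipeline is byte-identical when re-run with the
same configuration and seed; this is asserted in the acceptance tests.
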