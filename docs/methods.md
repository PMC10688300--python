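# Methods

This note documents the models, parameter choices and numerical behavior
of genescout's stages, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the design was open.

## Sequence primitives

Reads are Phred+33 FASTQ only (modern Illumina); FASTA/FASTQ I/O is
gzip-transparent by `.gz` suffix. Mate suffixes (`/1`, `/2`, and CASAVA
`1:...`/`2:...` description tails) are stripped from read ids and stored
as a mate flag, so mate pairing and the recruitment "unique id" rule both
operate on bare ids. All internal coordinates are 0-based half-open;
only the GFF3 writer emits 1-based inclusive coordinates.

Six NCBI translation tables ship as a plain-text data file (1 standard,
2 vertebrate mitochondrial, 4, 5 invertebrate mitochondrial, 9, 11
bacterial/plastid). Codons containing N translate to X; an ORF never
starts at an X residue. Protein local alignment is a Gotoh affine-gap
Smith-Waterman (BLOSUM62, gap open 11 / extend 1 — the tblastn default;
a k-long gap costs open + k·extend). Among equal-scoring optima the
alignment with the smallest (q_start, t_start) is reported, making every
downstream statistic deterministic. Identity is matched columns over
aligned columns; query coverage is the aligned query span over query
length.

## Trimming

Steps run in the conventional trimmer order: adapter clip (earliest
position where a full adapter occurs internally, or where a read suffix
matches an adapter prefix with overlap ≥ 8 and ≤ 1 mismatch), then
leading/trailing clipping of bases below quality 3, then a left-to-right
sliding window (4 bases, mean quality 20) cutting at the start of the
first failing window, then a 36-base length floor. A surviving read
therefore contains no full adapter occurrence and no failing window, and
trimming is idempotent. Defaults are conventional values for 150 bp
Illumina data and all are configurable. k-mer error *correction* is
deliberately not performed; the assembler's k-mer count floor absorbs
random errors instead (see Assembly), at the cost of slightly ragged
contig ends at modest coverage.

## Read filtering

One exact canonical-k-mer classifier (k = 31, odd so no k-mer is its own
reverse complement) covers both roles that read filtering plays in
practice — binning organelle/pathogen reads against user references and
passing everything else through. A read pair's k-mer hits are summed
over both mates so mates never separate; the winning reference must
collect at least `min_frac` = 0.25 of the pair's k-mers, a tie above
threshold is "ambiguous", everything else is "unclassified" (the
pass-through set). The threshold semantics are a design choice (no
published value exists for this construction) and stay configurable. At
these defaults, a 31-mer match against a 10 kb random reference by
chance has probability ~10⁴/4³¹ per position, so false assignment of
unrelated reads is effectively impossible; concordance failures come
only from genuinely shared sequence.

## Query sets

A search strategy pools protein FASTAs, drops sequences outside its
length range, and greedily prunes near-duplicates: candidates are
visited longest-first (ties by id) and kept iff their identity to every
kept sequence — matched columns over the *shorter* length, from the
local alignment — is below `dedup_identity` = 0.98. Keeping the longest
representative of a redundant cluster maximizes the sequence diversity a
query can recruit; a centroid rule would be the alternative, and the
choice is deliberately exposed here rather than hidden. Remote query
sources (family databases, accession fetchers) are out of scope; the
`QUERY_FETCHERS` hook marks where they would plug in.

## Recruitment

Stage 1 is a translated seed-and-extend: exact amino-acid words of
length 4 shared between any of the read's six frame translations and any
query are extended ungapped in both directions, stopping when the
running score falls `x_drop` = 20 below its running maximum; one
extension per (query, diagonal, frame). A pair is recruited when either
mate's best extension reaches `min_score` = 50 raw BLOSUM62 — a
deliberately permissive floor standing in for an e-value threshold
(random 150 bp reads reach it in well under 1% of trials; a single
conserved 10-residue block scores ~50 alone). Gapped per-read DP is
avoided entirely for speed.

Stage 2 enriches at the nucleotide level: canonical 25-mers of all
stage-1 reads form a bait set, and one additional pass recruits any pair
sharing ≥ 2 distinct bait k-mers. This is what recovers UTR- and
flank-derived pairs with no protein signal. A single pass (not a
fixpoint iteration) is used: each further pass recruits neighbors of
neighbors and drifts off-target, and in the simulated mixtures one pass
already saturates target recall.

## Assembly

Recruited read sets are small and local to one gene family, so a
straightforward single-k de Bruijn assembler suffices: canonical 31-mer
counts, nodes with count ≥ `min_count` = 2 kept in both orientations
(so every contig exists as two mirror paths and strand bookkeeping
reduces to removing twins together), edges as (k−1)-overlaps. Cleaning:

- **Tips** — dead-end simple paths of ≤ 2k nodes attached to the rest of
  the graph are removed iteratively to a fixpoint.
- **Bubbles** — a simple arm from a branching node to a rejoin node is
  removed when a vertex-disjoint alternative path between the same
  endpoints exists with ≥ 95% sequence identity (edit distance) and at
  least the arm's mean coverage. The alternative path is found by
  bounded BFS and may itself pass through junctions; this resolves
  chains of *overlapping* bubbles (two recurrent errors within k bases),
  which the textbook two-simple-arm rule cannot pop and which otherwise
  fragment the contig.

Maximal non-branching paths are spelled and reported once each in
canonical orientation (lexicographic min of sequence and reverse
complement), filtered at 200 bp, with ids assigned in (length desc,
sequence asc) order — output is byte-deterministic. No paired-end
scaffolding and no multi-k iteration are attempted; that is the fidelity
gap versus a full transcriptome assembler, visible as contig ends ~1-3%
short of the true transcript at 30x coverage (terminal k-mers fall under
the count floor). The planted-transcript benchmark at 1% substitution
errors and 30x recovers a single contig at 100% identity covering
94-98% of the transcript, depending on seed.

## Annotation

A contig is kept when its best local alignment — over all six frames and
all queries — passes the strategy's score (60), identity (0.40) and
query-coverage (0.50) thresholds; the winning frame fixes the strand,
and ORF search is restricted to that strand (the protein match already
determines it). Genetic codes follow the contig's genomic source:
nucleus → table 1, plastid → table 11, mitochondrion → table 1 by
default, all overridable (e.g. mitochondrion → 5 for invertebrates).

ORFs per frame: complete (start codon to stop, only the longest of
nested ORFs sharing a stop), 5'-partial (contig edge in frame to first
stop, no upstream start), 3'-partial (start codon to contig edge without
stop), internal (edge to edge with neither). Partial classes require
`allow_partial_orfs` (default on; applied to all three partial classes).
Start codons default to {ATG} and are configurable per strategy;
alternative starts are translated as M at the ORF start. Lengths are
gated to [orf_min_len, orf_max_len] in residues.

"Highest scoring ORF becomes the CDS" needed a concrete scoring
definition — the largest single invented semantic in the package: score
= best local-alignment score of the ORF's protein against any query
(protein length in the query-less control mode), ties broken by
completeness (complete > partial > internal), then longer protein, then
smaller start. Exactly one CDS per contig.

Outputs per strategy: transcript FASTA, GFF3 (one mRNA per matched
transcript, one CDS per selected ORF), ORF nucleotide FASTA
(coding-strand sequence) and ORF protein FASTA — the latter being the
input a downstream functional-annotation tool would consume. GFF3 CDS
phase: 0 when the start codon is present; for edge-truncated starts the
feature begins at the contig edge and the phase equals the frame offset
(equivalently (3 − (missing upstream bases of the split codon) mod 3)
mod 3).

## Synthetic data

The generator emulates the pipeline's intended input — a stranded
paired-end 150 bp mRNA-seq library — at desk scale. Defaults: 50 random
background transcripts (500-3,000 bp), one target transcript = 5'UTR +
back-translated target protein + 3'UTR (UTRs 50-300 bp, uniform
synonymous codons), a random 10 kb "organelle" contaminant sampled at
200 pairs, 30x coverage, inserts Normal(350, 50) truncated to the read
length, i.i.d. substitution errors at 1%, qualities Normal(38, 2)
clipped to [2, 41] that do *not* mark the errors (as in real data). All
randomness flows from one integer seed through numpy's PCG64; outputs
are byte-identical across platforms. Two realism constraints matter for
benchmarking: the default target protein is M-initial, and the 5'UTR is
rejection-sampled so no in-frame start codon sits upstream of the
planted ATG without an intervening stop — real 5'UTRs almost always
satisfy this, and without it exact CDS recovery is not a property even
of a perfect assembler.

Not modeled: indels (substitution-only is the dominant Illumina error
mode, and it keeps assembly benchmarks crisp), expression heterogeneity,
strand-specific library artifacts, PCR duplicates, and real homologous
gene families (backgrounds are random sequence). Passing tests therefore
demonstrate algorithmic correctness on clean planted signal, not
robustness to paralog interference or alignment-twilight-zone queries.

## Orchestration

Both configuration files are INI (one project file; one strategies file
with a shipped template). Unknown keys are hard errors. SRA-style
accessions in the input section are recognized and rejected with a
message naming the external fetch tools — no network access is ever
attempted. Output layout: trimmed reads under
`01-global/02-trimmed-fq-data/[SAMPLE]`, filtered bins under
`01-global/05-filtered-fq-data/[SAMPLE]`, per-gene results under
`02-strategies/[STRATEGY]`; a layout path occupied by a non-directory is
an error, never an overwrite. Each stage records SHA-256 hashes of its
input file contents and parameters in `run_manifest.json`; a stage is
skipped iff its record matches and its outputs exist, which yields both
no-op re-runs and crash resume. All parameters are logged to `run.log`
per run.

## Problem sizes in the test suite

Unit tests use sequences of tens to hundreds of bases and oracle checks
of 200-1,000 random instances. Integration and acceptance tests run the
full default mixture (51 transcripts + contaminant, ~9,000 read pairs,
~1.4 Mb of sequence), which exercises every stage end to end in seconds;
these sizes are the package's intended desk scale.
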