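# Search-strategies template.
#
# One section per gene family to hunt for; the section name becomes the
# strategy name and its output directory under 02-strategies/. All keys
# except query_fasta_paths are optional and default to the values shown.
# Relative FASTA paths resolve against this file's directory.

[my_gene_family]
# whitespace- or comma-separated protein FASTA files (required)
query_fasta_paths = queries.fasta

# query pruning: pooled sequences outside the length range are dropped,
# then near-duplicates (identity >= dedup_identity over the shorter
# sequence) are pruned keeping the longest representative
min_query_len = 30
max_query_len = 100000
dedup_identity = 0.98

# transcript matching thresholds (local alignment of query vs six-frame
# translation; BLOSUM62, gap open 11 / extend 1)
match_min_score = 60
match_min_identity = 0.40
match_min_qcov = 0.50

# ORF detection: amino-acid length range, accepted start codons, and
# whether edge-truncated (partial/internal) ORFs are reported
orf_min_len = 30
orf_max_len = 100000
start_codons = ATG
allow_partial_orfs = true
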