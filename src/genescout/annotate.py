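"""Transcript matching, ORF discovery and annotation output.

Assembled contigs are kept only when they align to the strategy's protein
queries above the configured score/identity/query-coverage thresholds.
ORFs are then enumerated on the matched strand under the genetic code of
the contig's genomic source (nuclear, plastid or mitochondrial), classified
by completeness, and the highest-scoring one is labeled the CDS. Scoring
is similarity to the best query (amino-acid length when no queries are
given); the spec of "highest scoring" is otherwise open, so the tie
cascade is completeness, then length, then position.

Outputs per strategy: transcript FASTA, GFF3 annotation, ORF nucleotide
FASTA and ORF amino-acid FASTA. GFF3 is the only place 1-based inclusive
coordinates appear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .seqcore import (
    GeneticCode,
    LocalAlignment,
    PathLike,
    ProteinSeq,
    ScoringScheme,
    blosum62_scheme,
    genetic_code,
    revcomp,
    smith_waterman,
    translate,
)
from .strategy import SearchStrategy

log = logging.getLogger(__name__)

COMPLETE = "complete"
PARTIAL_5 = "5prime_partial"
PARTIAL_3 = "3prime_partial"
INTERNAL = "internal"

_COMPLETENESS_RANK = {COMPLETE: 2, PARTIAL_5: 1, PARTIAL_3: 1, INTERNAL: 0}


@dataclass
class TranscriptMatch:
    contig_id: str
    query_id: str
    alignment: LocalAlignment
    strand: str  # '+' or '-'


@dataclass
class Orf:
    """A located ORF; start/end are 0-based half-open on the contig's
    forward strand regardless of ORF strand."""

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    completeness: str
    aa: ProteinSeq
    contig_len: int
    score: int = 0

    def oriented_span(self) -> tuple[int, int]:
        """Span in coding-strand coordinates."""
        if self.strand == "+":
            return self.start, self.end
        return self.contig_len - self.end, self.contig_len - self.start

    def phase(self) -> int:
        """GFF3 phase: bases to skip from the feature's 5' end to reach the
        first complete codon. Zero unless the start is truncated by the
        contig edge."""
        o_start, _ = self.oriented_span()
        return (self.frame - o_start) % 3


@dataclass
class SourceCodeMap:
    """Genomic source -> NCBI translation table."""

    mapping: dict[str, int] = field(
        default_factory=lambda: {"nucleus": 1, "plastid": 11, "mitochondrion": 1}
    )


def genetic_code_for(source: str, m: Optional[SourceCodeMap] = None) -> GeneticCode:
    m = m or SourceCodeMap()
    if source not in m.mapping:
        raise KeyError(
            f"unknown genomic source {source!r}; known: {sorted(m.mapping)}"
        )
    return genetic_code(m.mapping[source])


# ---------------------------------------------------------------------------
# transcript matching
# ---------------------------------------------------------------------------


def match_transcripts(
    contigs: Sequence,
    queries: Sequence[ProteinSeq],
    s: SearchStrategy,
    scheme: Optional[ScoringScheme] = None,
    code: Optional[GeneticCode] = None,
) -> list[TranscriptMatch]:
    """Best translated alignment per contig over all six frames and all
    queries; a contig is retained iff it passes the strategy's score,
    identity and query-coverage thresholds. The winning frame's strand is
    recorded for downstream ORF search."""
    scheme = scheme or blosum62_scheme()
    code = code or genetic_code(1)
    matches: list[TranscriptMatch] = []
    for contig in contigs:
        best: Optional[tuple[int, str, str, LocalAlignment]] = None
        rc = revcomp(contig.seq)
        for strand, nt in (("+", contig.seq), ("-", rc)):
            for frame in range(3):
                if frame >= len(nt):
                    continue
                aa = translate(nt, code, frame)
                if not aa:
                    continue
                for q in queries:
                    aln = smith_waterman(q, aa, scheme)
                    key = (aln.score, strand, q.id)
                    if best is None or aln.score > best[0]:
                        best = (aln.score, strand, q.id, aln)
        if best is None:
            continue
        score, strand, qid, aln = best
        if (
            score >= s.match_min_score
            and aln.identity >= s.match_min_identity
            and aln.q_cov >= s.match_min_qcov
        ):
            matches.append(TranscriptMatch(contig.id, qid, aln, strand))
        else:
            log.debug(
                "contig %s dropped: score=%d identity=%.2f qcov=%.2f",
                contig.id, score, aln.identity, aln.q_cov,
            )
    return matches


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------


def find_orfs(
    contig,
    strand: str,
    code: GeneticCode,
    s: SearchStrategy,
) -> list[Orf]:
    """Enumerate ORFs in the three frames of one strand.

    Classes: complete (start codon to stop), 5prime_partial (contig edge
    to first stop with no upstream start), 3prime_partial (start codon to
    contig edge, no stop), internal (edge to edge, neither). Partial
    classes require ``allow_partial_orfs``; nested complete ORFs sharing a
    stop report only the longest; amino-acid length is gated by
    [orf_min_len, orf_max_len]; an ORF never starts at an X residue.
    """
    seq = contig.seq
    L = len(seq)
    oriented = seq if strand == "+" else revcomp(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        if L - frame < 3:
            continue
        aa = translate(oriented, code, frame)
        n = len(aa)
        codon = lambda i: oriented[frame + 3 * i : frame + 3 * i + 3]
        seg_start = 0
        for idx in range(n + 1):
            at_end = idx == n
            if not at_end and aa[idx] != "*":
                continue
            # segment [seg_start, idx) of coding codons; stop at idx unless at_end
            start_ci = next(
                (i for i in range(seg_start, idx) if codon(i) in s.start_codons),
                None,
            )
            if not at_end:  # segment closed by a stop codon
                if start_ci is not None:
                    _add_complete(orfs, contig, strand, frame, start_ci, idx, aa, L, s)
                elif seg_start == 0 and s.allow_partial_orfs:
                    _add_partial5(orfs, contig, strand, frame, seg_start, idx, aa, L, s)
                seg_start = idx + 1
            else:  # segment runs to the contig edge
                if start_ci is not None:
                    if s.allow_partial_orfs:
                        _add_partial3(orfs, contig, strand, frame, start_ci, idx, aa, L, s)
                elif seg_start == 0 and s.allow_partial_orfs:
                    _add_internal(orfs, contig, strand, frame, seg_start, idx, aa, L, s)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def _mk_orf(contig, strand, frame, o_start, o_end, completeness, aa_str, L, s):
    if not aa_str or not (s.orf_min_len <= len(aa_str) <= s.orf_max_len):
        return None
    if strand == "+":
        start, end = o_start, o_end
    else:
        start, end = L - o_end, L - o_start
    return Orf(
        contig_id=contig.id,
        strand=strand,
        frame=frame,
        start=start,
        end=end,
        completeness=completeness,
        aa=ProteinSeq(f"{contig.id}_orf", aa_str),
        contig_len=L,
    )


def _add_complete(orfs, contig, strand, frame, a, stop_i, aa, L, s):
    aa_str = "M" + aa[a + 1 : stop_i]  # initiator convention
    o = _mk_orf(contig, strand, frame, frame + 3 * a, frame + 3 * (stop_i + 1),
                COMPLETE, aa_str, L, s)
    if o:
        orfs.append(o)


def _add_partial5(orfs, contig, strand, frame, seg_start, stop_i, aa, L, s):
    a0 = seg_start
    while a0 < stop_i and aa[a0] == "X":
        a0 += 1  # never start at an X
    aa_str = aa[a0:stop_i]
    o_start = 0 if a0 == seg_start else frame + 3 * a0
    o = _mk_orf(contig, strand, frame, o_start, frame + 3 * (stop_i + 1),
                PARTIAL_5, aa_str, L, s)
    if o:
        orfs.append(o)


def _add_partial3(orfs, contig, strand, frame, a, n_codons, aa, L, s):
    aa_str = "M" + aa[a + 1 : n_codons]
    o = _mk_orf(contig, strand, frame, frame + 3 * a, L, PARTIAL_3, aa_str, L, s)
    if o:
        orfs.append(o)


def _add_internal(orfs, contig, strand, frame, seg_start, n_codons, aa, L, s):
    a0 = seg_start
    while a0 < n_codons and aa[a0] == "X":
        a0 += 1
    aa_str = aa[a0:n_codons]
    o_start = 0 if a0 == seg_start else frame + 3 * a0
    o = _mk_orf(contig, strand, frame, o_start, L, INTERNAL, aa_str, L, s)
    if o:
        orfs.append(o)


# ---------------------------------------------------------------------------
# CDS selection
# ---------------------------------------------------------------------------


def select_cds(
    orfs: Sequence[Orf],
    queries: Sequence[ProteinSeq],
    scheme: Optional[ScoringScheme] = None,
) -> Orf:
    """Pick the highest-scoring ORF of one contig as its CDS.

    Score is the best local-alignment score of the ORF's protein against
    any query (amino-acid length in the query-less control mode). Ties go
    to completeness (complete > partial > internal), then longer protein,
    then smaller start.
    """
    if not orfs:
        raise ValueError("select_cds needs at least one ORF")
    scheme = scheme or blosum62_scheme()
    scored = []
    for o in orfs:
        if queries:
            o.score = max(smith_waterman(o.aa, q, scheme).score for q in queries)
        else:
            o.score = len(o.aa)
        scored.append(o)
    scored.sort(
        key=lambda o: (
            -o.score,
            -_COMPLETENESS_RANK[o.completeness],
            -len(o.aa),
            o.start,
        )
    )
    return scored[0]


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------


def _gff_escape(v: str) -> str:
    return v.replace(";", "%3B").replace("=", "%3D")


def write_outputs(
    contigs: Sequence,
    matches: Sequence[TranscriptMatch],
    cds: dict[str, Orf],
    out_dir: PathLike,
) -> dict[str, Path]:
    """Write the four per-strategy output files.

    transcripts.fasta (matched transcripts), transcripts.gff3 (one mRNA
    per transcript, one CDS per selected ORF; 1-based inclusive
    coordinates), orfs_nt.fasta (coding-strand nucleotide ORFs) and
    orfs_aa.fasta (ORF translations, ready for downstream functional
    annotation tools).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {c.id: c for c in contigs}
    matched = [m for m in matches if m.contig_id in by_id]

    paths = {
        "transcripts": out_dir / "transcripts.fasta",
        "gff3": out_dir / "transcripts.gff3",
        "orfs_nt": out_dir / "orfs_nt.fasta",
        "orfs_aa": out_dir / "orfs_aa.fasta",
    }

    with open(paths["transcripts"], "w") as fa, open(paths["gff3"], "w") as gff, open(
        paths["orfs_nt"], "w"
    ) as fnt, open(paths["orfs_aa"], "w") as faa:
        gff.write("##gff-version 3\n")
        for m in matched:
            contig = by_id[m.contig_id]
            cov = getattr(contig, "mean_cov", None)
            desc = f" cov={cov:.1f}" if cov is not None else ""
            fa.write(f">{contig.id}{desc} query={m.query_id}\n{contig.seq}\n")
            attrs = f"ID={_gff_escape(contig.id)}.mRNA;query={_gff_escape(m.query_id)}"
            gff.write(
                f"{contig.id}\tgenescout\tmRNA\t1\t{len(contig.seq)}\t"
                f"{m.alignment.score}\t{m.strand}\t.\t{attrs}\n"
            )
            orf = cds.get(m.contig_id)
            if orf is None:
                log.info("contig %s has no CDS; transcript still reported", m.contig_id)
                continue
            o_start, o_end = orf.oriented_span()
            nt = (
                contig.seq[orf.start : orf.end]
                if orf.strand == "+"
                else revcomp(contig.seq)[o_start:o_end]
            )
            attrs = (
                f"ID={_gff_escape(contig.id)}.cds;"
                f"Parent={_gff_escape(contig.id)}.mRNA;"
                f"completeness={orf.completeness};score={orf.score}"
            )
            gff.write(
                f"{contig.id}\tgenescout\tCDS\t{orf.start + 1}\t{orf.end}\t"
                f"{orf.score}\t{orf.strand}\t{orf.phase()}\t{attrs}\n"
            )
            fnt.write(f">{contig.id}.cds {orf.completeness}\n{nt}\n")
            faa.write(f">{contig.id}.cds {orf.completeness}\n{orf.aa.seq}\n")
    return paths
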