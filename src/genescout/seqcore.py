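"""Core sequence machinery shared by every pipeline stage.

Sequence record types, FASTA/FASTQ streaming I/O (gzip-transparent),
reverse complementation, NCBI genetic-code tables with translation and
six-frame expansion, and protein local alignment (Gotoh affine-gap
Smith-Waterman) used for read recruitment, query pruning and ORF scoring.

All internal coordinates are 0-based half-open; conversion to 1-based
inclusive happens only in the GFF3 writer (:mod:`genescout.annotate`).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio.Align import substitution_matrices
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

PHRED_OFFSET = 33  # Phred+33 is the only supported FASTQ quality encoding
MAX_PHRED = 93

_NT_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: mate suffix conventions: "/1" and "/2", or Illumina CASAVA 1.8+
#: descriptions whose first word is "1:..." or "2:..."
_MATE_SLASH = re.compile(r"^(?P<id>.+)/(?P<mate>[12])$")
_MATE_CASAVA = re.compile(r"^(?P<mate>[12]):[YN]:\d+:")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input; carries file context."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class NucRead:
    """A nucleotide read, optionally with per-base Phred qualities.

    ``id`` has any mate suffix stripped; the mate number (1 or 2), if it
    was present, is kept in ``mate`` so pairing is by bare id.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.seq) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid nucleotide letters {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.qual)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinSeq:
    """An amino-acid sequence; '*' permitted only as the final character."""

    id: str
    seq: str

    _ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - self._ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )
        if "*" in self.seq[:-1]:
            raise ValueError(
                f"protein {self.id!r}: internal stop ('*') not allowed"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: all 64 codons plus the start-codon set."""

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"table {self.table_id}: {len(self.codon_to_aa)} codons, need 64"
            )
        for c in self.start_codons:
            if self.codon_to_aa[c] == "*":
                raise ValueError(f"table {self.table_id}: stop {c} marked as start")


@dataclass(frozen=True)
class ScoringScheme:
    """Protein substitution matrix plus affine gap penalties.

    A k-long gap costs ``gap_open + k * gap_extend``.
    """

    matrix: dict[tuple[str, str], int]
    gap_open: int = 11
    gap_extend: int = 1

    def score(self, a: str, b: str) -> int:
        return self.matrix.get((a, b), self.matrix.get((b, a), -4))


@dataclass
class LocalAlignment:
    """Result of a local protein alignment (0-based half-open coordinates)."""

    score: int
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    identity: float = 0.0
    q_cov: float = 0.0
    n_matches: int = 0
    n_columns: int = 0


# ---------------------------------------------------------------------------
# basic sequence ops
# ---------------------------------------------------------------------------


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement letters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def split_read_id(header: str) -> tuple[str, Optional[int], str]:
    """Split a FASTQ/FASTA header into (bare id, mate flag, description).

    Handles ``name/1`` suffixes and CASAVA-style ``name 1:N:0:...``
    descriptions; returns mate ``None`` when no convention matches.
    """
    parts = header.split(None, 1)
    rid, desc = parts[0], (parts[1] if len(parts) > 1 else "")
    mate: Optional[int] = None
    m = _MATE_SLASH.match(rid)
    if m:
        rid, mate = m.group("id"), int(m.group("mate"))
    elif desc:
        m = _MATE_CASAVA.match(desc)
        if m:
            mate = int(m.group("mate"))
    return rid, mate, desc


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (gzip transparent by ".gz" suffix)
# ---------------------------------------------------------------------------


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""


def read_fasta(path: PathLike) -> Iterator[FastaRecord]:
    """Stream records from a (possibly gzipped) FASTA file.

    Multi-line sequences are concatenated; the description after the
    first whitespace is kept separately from the id.
    """
    with _open_text(path) as fh:
        header: Optional[str] = None
        header_line = 0
        chunks: list[str] = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _fasta_record(header, chunks, header_line, path)
                header, header_line, chunks = line[1:], lineno, []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before any "
                        f"'>' header"
                    )
                chunks.append(line.strip())
        if header is not None:
            yield _fasta_record(header, chunks, header_line, path)


def _fasta_record(
    header: str, chunks: list[str], lineno: int, path: PathLike
) -> FastaRecord:
    parts = header.split(None, 1)
    if not parts:
        raise ParseError(f"{path}: line {lineno}: empty FASTA header")
    seq = "".join(chunks).upper()
    if not seq:
        raise ParseError(f"{path}: line {lineno}: record {parts[0]!r} has no sequence")
    return FastaRecord(parts[0], seq, parts[1] if len(parts) > 1 else "")


def write_fasta(records: Iterable, path: PathLike, width: int = 70) -> None:
    """Write records with ``.id`` and ``.seq`` attributes (or (id, seq) pairs)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if hasattr(rec, "id") else rec
            desc = getattr(rec, "description", "")
            fh.write(f">{rid} {desc}\n" if desc else f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: PathLike) -> Iterator[NucRead]:
    """Stream :class:`NucRead` from a (possibly gzipped) FASTQ file.

    Phred+33 qualities only; mate suffixes are stripped into the mate flag.
    """
    with _open_text(path) as fh:
        try:
            for header, seq, qual in FastqGeneralIterator(fh):
                rid, mate, _ = split_read_id(header)
                quals = [ord(c) - PHRED_OFFSET for c in qual]
                if any(q < 0 or q > MAX_PHRED for q in quals):
                    raise ParseError(
                        f"{path}: read {rid!r}: quality characters outside "
                        f"the Phred+33 range"
                    )
                yield NucRead(rid, seq.upper(), quals, mate)
        except ValueError as exc:  # FastqGeneralIterator's own diagnostics
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[NucRead], path: PathLike) -> None:
    """Write reads in 4-line FASTQ; round-trips bit-exactly with read_fastq."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            if r.qual is None:
                raise ValueError(f"read {r.id!r} has no qualities; write FASTA instead")
            rid = f"{r.id}/{r.mate}" if r.mate else r.id
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qual)
            fh.write(f"@{rid}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# genetic codes and translation
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_CODON_ORDER = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


@lru_cache(maxsize=1)
def load_genetic_codes() -> dict[int, GeneticCode]:
    """Load the shipped NCBI translation tables (1, 2, 4, 5, 9, 11)."""
    codes: dict[int, GeneticCode] = {}
    text = (
        resources.files("genescout").joinpath("data/genetic_codes.tsv").read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        tid_s, aas, starts = line.split("\t")
        if len(aas) != 64:
            raise ValueError(f"genetic code table {tid_s}: bad amino-acid string")
        tid = int(tid_s)
        codes[tid] = GeneticCode(
            table_id=tid,
            codon_to_aa=dict(zip(_CODON_ORDER, aas)),
            start_codons=frozenset(starts.split(",")),
        )
    return codes


def genetic_code(table_id: int) -> GeneticCode:
    codes = load_genetic_codes()
    if table_id not in codes:
        raise KeyError(
            f"no embedded genetic code table {table_id}; have {sorted(codes)}"
        )
    return codes[table_id]


def translate(seq: str, code: GeneticCode, frame: int = 0) -> str:
    """Translate one frame; trailing partial codon dropped, N codons -> X.

    Internal stops are reported as '*'; the caller decides their meaning.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, not {frame}")
    if frame >= len(seq):
        raise ValueError(f"frame {frame} >= sequence length {len(seq)}")
    table = code.codon_to_aa
    n = (len(seq) - frame) // 3
    out = []
    for i in range(frame, frame + 3 * n, 3):
        codon = seq[i : i + 3].replace("U", "T")
        out.append(table.get(codon, "X"))
    return "".join(out)


def six_frame(seq: str, code: GeneticCode) -> list[tuple[str, int, str]]:
    """All six frame translations in fixed order (+0,+1,+2,-0,-1,-2)."""
    if len(seq) < 3:
        raise ValueError("six-frame translation needs >= 3 bases")
    rc = revcomp(seq)
    out = []
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            aa = translate(s, code, f) if f < len(s) else ""
            out.append((strand, f, aa))
    return out


# ---------------------------------------------------------------------------
# protein local alignment (Gotoh affine-gap Smith-Waterman)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def blosum62_scheme(gap_open: int = 11, gap_extend: int = 1) -> ScoringScheme:
    """BLOSUM62 with tblastn-default affine gap penalties (11/1)."""
    blosum = substitution_matrices.load("BLOSUM62")
    matrix: dict[tuple[str, str], int] = {}
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            matrix[(a, b)] = int(blosum[a, b])
    return ScoringScheme(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)


def smith_waterman(
    a: Union[ProteinSeq, str], b: Union[ProteinSeq, str], scheme: ScoringScheme
) -> LocalAlignment:
    """Optimal local alignment of protein ``a`` (query) against ``b`` (target).

    Affine gaps (a k-long gap costs ``gap_open + k*gap_extend``); among
    equal-scoring optima the alignment with the smallest (q_start, t_start)
    is returned. A score of 0 means no positive-scoring cell exists and the
    spans are empty.
    """
    qa = a.seq if isinstance(a, ProteinSeq) else a
    tb = b.seq if isinstance(b, ProteinSeq) else b
    if not qa or not tb:
        raise ValueError("smith_waterman requires non-empty sequences")
    n, m = len(qa), len(tb)
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    sub = scheme.matrix
    NEG = -(10**9)

    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes target)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consumes query)

    best = 0
    ends: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        ai = qa[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            f = max(Hi1[j] - go, Fi1[j] - ge)
            s = sub.get((ai, tb[j - 1]), -4)
            h = Hi1[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, ends = h, [(i, j)]
            elif h and h == best:
                ends.append((i, j))

    if best == 0:
        return LocalAlignment(score=0)

    candidates = []
    for end in ends:
        aln = _traceback(qa, tb, H, E, F, sub, go, ge, end)
        candidates.append(aln)
    aln = min(candidates, key=lambda x: (x.q_start, x.t_start, x.q_end, x.t_end))
    aln.score = best
    aln.identity = aln.n_matches / aln.n_columns if aln.n_columns else 0.0
    aln.q_cov = (aln.q_end - aln.q_start) / n
    return aln


def _traceback(qa, tb, H, E, F, sub, go, ge, end) -> LocalAlignment:
    i, j = end
    matches = columns = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if h == H[i - 1][j - 1] + sub.get((qa[i - 1], tb[j - 1]), -4):
                columns += 1
                if qa[i - 1] == tb[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - go:
                state = "H"
                j -= 1
            else:
                j -= 1
        else:  # F
            columns += 1
            if F[i][j] == H[i - 1][j] - go:
                state = "H"
                i -= 1
            else:
                i -= 1
    return LocalAlignment(
        score=0,
        q_start=i,
        q_end=end[0],
        t_start=j,
        t_end=end[1],
        n_matches=matches,
        n_columns=columns,
    )


def global_identity(
    a: Union[ProteinSeq, str], b: Union[ProteinSeq, str], scheme: ScoringScheme
) -> float:
    """Identity used for query pruning: matched columns / shorter length."""
    la = len(a.seq if isinstance(a, ProteinSeq) else a)
    lb = len(b.seq if isinstance(b, ProteinSeq) else b)
    aln = smith_waterman(a, b, scheme)
    return aln.n_matches / min(la, lb)
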