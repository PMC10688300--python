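"""Two-stage targeted read recruitment.

Stage 1 is a translated seed-and-extend search: every exact amino-acid
word shared between a read's six-frame translations and the protein
queries is extended without gaps under BLOSUM62 with an x-drop rule, and
a read pair is recruited when either mate's best extension score reaches
``min_score``. Stage 2 enriches the hit set at the nucleotide level:
reads sharing canonical k-mers with any stage-1 read are pulled in,
which recovers pairs from the untranslated ends of the target transcript
that carry no protein signal. Duplicate ids are kept once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .readfilter import canonical_kmers
from .seqcore import (
    GeneticCode,
    NucRead,
    ProteinSeq,
    ScoringScheme,
    blosum62_scheme,
    genetic_code,
    six_frame,
)

Pair = tuple[NucRead, Optional[NucRead]]


@dataclass
class SeedParams:
    """Translated seeding: exact aa word size, score floor, x-drop."""

    aa_word: int = 4
    min_score: int = 50
    x_drop: int = 20

    def __post_init__(self) -> None:
        if self.aa_word < 3:
            raise ValueError("aa_word must be >= 3")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@dataclass
class EnrichParams:
    """Nucleotide enrichment: canonical k-mer size and sharing floor."""

    nt_k: int = 25
    min_shared: int = 2

    def __post_init__(self) -> None:
        if self.nt_k % 2 == 0:
            raise ValueError("nt_k must be odd")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")


@dataclass
class ReadSet:
    """Recruited pairs keyed by bare read id, with recruitment provenance."""

    reads: dict[str, Pair] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, pair: Pair, stage: str) -> bool:
        """Insert unless the id is already present; returns True if added."""
        rid = pair[0].id
        if rid in self.reads:
            return False
        self.reads[rid] = pair
        self.provenance[rid] = stage
        return True

    def __len__(self) -> int:
        return len(self.reads)

    def __contains__(self, rid: str) -> bool:
        return rid in self.reads

    def all_reads(self) -> Iterable[NucRead]:
        for r1, r2 in self.reads.values():
            yield r1
            if r2 is not None:
                yield r2


def index_queries(
    queries: list[ProteinSeq], p: SeedParams
) -> dict[str, list[tuple[int, int]]]:
    """Map every exact aa_word-length substring of any query to its
    (query index, offset) occurrences."""
    if not queries:
        raise ValueError("query set is empty")
    index: dict[str, list[tuple[int, int]]] = {}
    for qi, q in enumerate(queries):
        if len(q) < p.aa_word:
            logging.getLogger(__name__).warning(
                "query %r shorter than aa_word=%d: contributes no seeds",
                q.id, p.aa_word,
            )
            continue
        seq = q.seq
        for off in range(len(seq) - p.aa_word + 1):
            index.setdefault(seq[off : off + p.aa_word], []).append((qi, off))
    return index


def _extend(aa: str, q: str, pos: int, qoff: int, w: int,
            sub: dict, x_drop: int) -> int:
    """Ungapped x-drop extension of an exact word hit on one diagonal."""
    score = sum(sub.get((aa[pos + i], q[qoff + i]), -4) for i in range(w))
    # rightward
    best_right = 0
    run = 0
    i, j = pos + w, qoff + w
    while i < len(aa) and j < len(q):
        run += sub.get((aa[i], q[j]), -4)
        if run > best_right:
            best_right = run
        if best_right - run > x_drop:
            break
        i += 1
        j += 1
    # leftward
    best_left = 0
    run = 0
    i, j = pos - 1, qoff - 1
    while i >= 0 and j >= 0:
        run += sub.get((aa[i], q[j]), -4)
        if run > best_left:
            best_left = run
        if best_left - run > x_drop:
            break
        i -= 1
        j -= 1
    return score + best_right + best_left


def score_read(
    read: NucRead,
    query_index: dict[str, list[tuple[int, int]]],
    queries: list[ProteinSeq],
    p: SeedParams,
    scheme: Optional[ScoringScheme] = None,
    code: Optional[GeneticCode] = None,
) -> int:
    """Best ungapped extension score of the read against any query.

    Each exact word hit in any of the six frame translations is extended
    in both directions without gaps, stopping when the running score drops
    ``x_drop`` below its running maximum; 0 when no word hits exist.
    """
    scheme = scheme or blosum62_scheme()
    code = code or genetic_code(1)
    if len(read.seq) < 3 * p.aa_word:
        return 0
    sub = scheme.matrix
    w = p.aa_word
    best = 0
    for _strand, _frame, aa in six_frame(read.seq, code):
        if len(aa) < w:
            continue
        seen_diag: set[tuple[int, int]] = set()
        for pos in range(len(aa) - w + 1):
            hits = query_index.get(aa[pos : pos + w])
            if not hits:
                continue
            for qi, qoff in hits:
                diag = (qi, pos - qoff)
                if diag in seen_diag:
                    continue
                seen_diag.add(diag)
                s = _extend(aa, queries[qi].seq, pos, qoff, w, sub, p.x_drop)
                if s > best:
                    best = s
    return best


def recruit_stage1(
    pairs: Iterable[Pair],
    queries: list[ProteinSeq],
    p: SeedParams = SeedParams(),
    scheme: Optional[ScoringScheme] = None,
    code: Optional[GeneticCode] = None,
) -> ReadSet:
    """Translated-seeding recruitment: a pair enters the set iff either
    mate scores >= min_score; duplicate ids are stored once."""
    if not queries:
        raise ValueError("cannot recruit with an empty query set")
    scheme = scheme or blosum62_scheme()
    index = index_queries(queries, p)
    out = ReadSet()
    for pair in pairs:
        for mate in pair:
            if mate is None:
                continue
            if score_read(mate, index, queries, p, scheme, code) >= p.min_score:
                out.add(pair, "seed")
                break
    return out


def enrich(
    pairs: Iterable[Pair],
    stage1: ReadSet,
    p: EnrichParams = EnrichParams(),
) -> ReadSet:
    """Nucleotide k-mer enrichment of the stage-1 hit set.

    A single pass over the full read stream recruits any pair not already
    in the set that shares at least ``min_shared`` distinct canonical
    k-mers with the union of stage-1 read sequences. Returns the union;
    ids stay unique.
    """
    out = ReadSet(dict(stage1.reads), dict(stage1.provenance))
    if not stage1.reads:
        return out
    bait: set[str] = set()
    for read in stage1.all_reads():
        bait.update(canonical_kmers(read.seq, p.nt_k))
    for pair in pairs:
        rid = pair[0].id
        if rid in out:
            continue
        shared: set[str] = set()
        for mate in pair:
            if mate is None:
                continue
            for km in canonical_kmers(mate.seq, p.nt_k):
                if km in bait:
                    shared.add(km)
                    if len(shared) >= p.min_shared:
                        break
            if len(shared) >= p.min_shared:
                break
        if len(shared) >= p.min_shared:
            out.add(pair, "enrich")
    return out
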