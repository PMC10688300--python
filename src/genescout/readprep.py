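"""Quality and adapter trimming of raw reads.

Steps are applied in the conventional order for read trimmers:
adapter clipping, leading/trailing low-quality base removal, sliding-window
quality cut, then a minimum-length gate. k-mer error correction is
deliberately not performed; the assembler's k-mer count floor absorbs
random sequencing errors instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import accumulate
from typing import Iterable, Iterator, Optional

from .seqcore import NucRead


@dataclass
class TrimParams:
    """Trimming thresholds (Phred scores are integers, lengths in bases)."""

    window: int = 4
    window_minq: float = 20.0
    lead_q: int = 3
    trail_q: int = 3
    min_len: int = 36
    adapters: list[str] = field(default_factory=list)
    adapter_min_overlap: int = 8
    adapter_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        for v in (self.window_minq, self.lead_q, self.trail_q,
                  self.adapter_min_overlap, self.adapter_max_mismatch):
            if v < 0:
                raise ValueError("trim thresholds must be >= 0")
        self.adapters = [a.upper() for a in self.adapters]


@dataclass
class TrimResult:
    """Outcome of trimming paired streams; reads are conserved across bins."""

    paired1: list[NucRead]
    paired2: list[NucRead]
    orphans: list[NucRead]
    n_input_reads: int
    n_discarded: int


def _adapter_cut(seq: str, p: TrimParams) -> Optional[int]:
    """Earliest position where an adapter (or its 3' prefix) starts, or None.

    A full internal adapter occurrence, or a read suffix matching an
    adapter prefix with overlap >= adapter_min_overlap, both with at most
    adapter_max_mismatch mismatches, truncate the read at that position.
    """
    n = len(seq)
    best: Optional[int] = None
    for adapter in p.adapters:
        la = len(adapter)
        for i in range(n):
            overlap = min(n - i, la)
            if overlap < la and overlap < p.adapter_min_overlap:
                break  # remaining suffixes are too short to call
            mism = 0
            for x, y in zip(seq[i : i + overlap], adapter):
                if x != y:
                    mism += 1
                    if mism > p.adapter_max_mismatch:
                        break
            if mism <= p.adapter_max_mismatch:
                if best is None or i < best:
                    best = i
                break
    return best


def trim_read(read: NucRead, p: TrimParams) -> Optional[NucRead]:
    """Trim one read; returns None when it is discarded.

    Order: (1) adapter clip, (2) leading/trailing quality clip,
    (3) left-to-right sliding-window cut at the first window whose mean
    quality falls below ``window_minq`` (cut at the window start),
    (4) discard if shorter than ``min_len``.
    """
    if read.qual is None:
        raise ValueError(
            f"read {read.id!r} has no qualities; use the FASTA-only entry "
            f"points for quality-less data"
        )
    seq, qual = read.seq, read.qual

    if p.adapters:
        cut = _adapter_cut(seq, p)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]

    lo, hi = 0, len(seq)
    while lo < hi and qual[lo] < p.lead_q:
        lo += 1
    while hi > lo and qual[hi - 1] < p.trail_q:
        hi -= 1
    seq, qual = seq[lo:hi], qual[lo:hi]

    if len(qual) >= p.window:
        prefix = [0, *accumulate(qual)]
        thresh = p.window_minq * p.window
        for i in range(len(qual) - p.window + 1):
            if prefix[i + p.window] - prefix[i] < thresh:
                seq, qual = seq[:i], qual[:i]
                break

    if len(seq) < p.min_len:
        return None
    return NucRead(read.id, seq, qual, read.mate)


def trim_reads(
    reads: Iterable[NucRead], p: TrimParams
) -> Iterator[Optional[NucRead]]:
    """Trim a single-end stream; yields None for discarded reads."""
    for read in reads:
        yield trim_read(read, p)


def trim_pairs(
    r1: Iterable[NucRead], r2: Iterable[NucRead], p: TrimParams
) -> TrimResult:
    """Trim aligned paired streams.

    A pair survives into the paired outputs iff both mates survive; a lone
    survivor goes to the orphan bin. Input order is preserved and every
    input read ends up in exactly one of {paired, orphan, discarded}.
    """
    paired1: list[NucRead] = []
    paired2: list[NucRead] = []
    orphans: list[NucRead] = []
    n_in = n_discarded = 0
    it1, it2 = iter(r1), iter(r2)
    recno = 0
    while True:
        a = next(it1, None)
        b = next(it2, None)
        if a is None and b is None:
            break
        recno += 1
        if a is None or b is None:
            raise ValueError(
                f"paired FASTQ streams end at different lengths "
                f"(record {recno})"
            )
        if a.id != b.id:
            raise ValueError(
                f"record {recno}: mate ids differ ({a.id!r} vs {b.id!r})"
            )
        n_in += 2
        ta, tb = trim_read(a, p), trim_read(b, p)
        if ta is not None and tb is not None:
            paired1.append(ta)
            paired2.append(tb)
        elif ta is not None:
            orphans.append(ta)
            n_discarded += 1
        elif tb is not None:
            orphans.append(tb)
            n_discarded += 1
        else:
            n_discarded += 2
    return TrimResult(paired1, paired2, orphans, n_in, n_discarded)
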