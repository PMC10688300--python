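"""k-mer classification of reads against user-supplied references.

One exact canonical-k-mer classifier plays the role that read mappers and
taxonomic classifiers play in conventional pipelines: reads (or whole
pairs) are assigned to the reference whose k-mer set they share the most
k-mers with, and written to one FASTQ bin per reference. The
"unclassified" bin is the contaminant-filtered read set that downstream
stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .seqcore import NucRead, PathLike, read_fasta, revcomp, write_fastq

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
AMBIGUOUS = "ambiguous"


def canonical_kmers(seq: str, k: int) -> list[str]:
    """All canonical k-mers of ``seq`` (lexicographic min of k-mer and its
    reverse complement); k-mers containing N are skipped."""
    n = len(seq)
    if n < k:
        return []
    rc = revcomp(seq)
    out = []
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        rk = rc[n - k - i : n - i]
        out.append(km if km <= rk else rk)
    return out


@dataclass
class KmerIndex:
    """Canonical k-mer sets keyed by reference label."""

    k: int
    labels: list[str]
    kmer_sets: dict[str, set[str]]


@dataclass
class ClassifyParams:
    """min_frac: minimum fraction of a read's (or pair's) k-mers that must
    hit the winning label for a call to be made."""

    min_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")


def build_index(refs: Mapping[str, PathLike], k: int = 31) -> KmerIndex:
    """Build a :class:`KmerIndex` from label -> FASTA path."""
    if not refs:
        raise ValueError("at least one reference FASTA is required")
    if k % 2 == 0:
        raise ValueError("k must be odd (canonicalization needs odd k)")
    labels = list(refs)
    if len(set(labels)) != len(labels):
        raise ValueError("reference labels must be unique")
    kmer_sets: dict[str, set[str]] = {}
    for label, path in refs.items():
        kmers: set[str] = set()
        for rec in read_fasta(path):
            kmers.update(canonical_kmers(rec.seq, k))
        if not kmers:
            log.warning("reference %r contributed no k-mers (too short or all N)", label)
        kmer_sets[label] = kmers
    return KmerIndex(k=k, labels=labels, kmer_sets=kmer_sets)


def _hit_counts(
    reads: Iterable[NucRead], index: KmerIndex
) -> tuple[dict[str, int], int]:
    hits = {label: 0 for label in index.labels}
    total = 0
    for read in reads:
        for km in canonical_kmers(read.seq, index.k):
            total += 1
            for label in index.labels:
                if km in index.kmer_sets[label]:
                    hits[label] += 1
    return hits, total


def classify_read(
    read: NucRead, index: KmerIndex, p: ClassifyParams = ClassifyParams()
) -> str:
    """Classify a single read; see :func:`classify_pair` for the rule."""
    return classify_pair(read, None, index, p)


def classify_pair(
    r1: NucRead,
    r2: Optional[NucRead],
    index: KmerIndex,
    p: ClassifyParams = ClassifyParams(),
) -> str:
    """Winner-takes-all canonical-k-mer vote over both mates.

    Returns the winning label iff its hit fraction reaches ``min_frac``
    and the maximum is unique; "ambiguous" on a tied passing maximum;
    "unclassified" otherwise (including reads shorter than k).
    """
    reads = [r1] if r2 is None else [r1, r2]
    hits, total = _hit_counts(reads, index)
    if total == 0:
        log.debug("read %r shorter than k=%d: unclassified", r1.id, index.k)
        return UNCLASSIFIED
    if not hits:
        return UNCLASSIFIED
    best = max(hits.values())
    if best == 0 or best / total < p.min_frac:
        return UNCLASSIFIED
    winners = [label for label, h in hits.items() if h == best]
    return winners[0] if len(winners) == 1 else AMBIGUOUS


def split_fastq(
    r1: Iterable[NucRead],
    r2: Optional[Iterable[NucRead]],
    index: KmerIndex,
    p: ClassifyParams,
    out_dir: PathLike,
    prefix: str = "reads",
) -> pd.DataFrame:
    """Partition reads (jointly as pairs when ``r2`` given) into per-label
    FASTQ bins plus an "unclassified" pass-through bin.

    Returns a summary table (label, read count, fraction); also written as
    ``summary.tsv`` next to the bins. Bins are disjoint and exhaustive.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    bins: dict[str, list[tuple[NucRead, Optional[NucRead]]]] = {}
    n_units = 0
    if r2 is None:
        for a in r1:
            n_units += 1
            bins.setdefault(classify_pair(a, None, index, p), []).append((a, None))
    else:
        for a, b in zip(r1, r2, strict=True):
            n_units += 1
            bins.setdefault(classify_pair(a, b, index, p), []).append((a, b))

    rows = []
    for label in [*index.labels, AMBIGUOUS, UNCLASSIFIED]:
        units = bins.get(label, [])
        if units or label == UNCLASSIFIED or label in index.labels:
            _write_bin(units, out_dir, prefix, label, paired=r2 is not None)
        n_reads = sum(2 if b is not None else 1 for _, b in units)
        rows.append(
            {
                "label": label,
                "units": len(units),
                "reads": n_reads,
                "fraction": len(units) / n_units if n_units else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return summary


def _write_bin(units, out_dir: Path, prefix: str, label: str, paired: bool) -> None:
    if paired:
        write_fastq((a for a, _ in units), out_dir / f"{prefix}_{label}_1.fastq")
        write_fastq((b for _, b in units), out_dir / f"{prefix}_{label}_2.fastq")
    else:
        write_fastq((a for a, _ in units), out_dir / f"{prefix}_{label}.fastq")
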