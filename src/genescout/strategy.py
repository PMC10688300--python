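"""Search-strategy configuration and protein query-set construction.

A search strategy names one gene family to hunt for: where its protein
queries come from, how the query set is pruned, the match thresholds a
transcript must pass, and the ORF parameters used during annotation.

Queries come from user FASTA files only. Remote sources (protein-family
databases, accession fetchers) would plug in at :data:`QUERY_FETCHERS`,
which is intentionally left empty.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .seqcore import (
    PathLike,
    ProteinSeq,
    ScoringScheme,
    blosum62_scheme,
    global_identity,
    read_fasta,
)

#: hook: name -> callable returning a list of ProteinSeq; remote query
#: sources would register here.
QUERY_FETCHERS: dict[str, Callable[[str], list[ProteinSeq]]] = {}


@dataclass
class SearchStrategy:
    """One named gene-family search definition."""

    name: str
    query_fasta_paths: list[Path]
    min_query_len: int = 30
    max_query_len: int = 100_000
    dedup_identity: float = 0.98
    match_min_score: int = 60
    match_min_identity: float = 0.40
    match_min_qcov: float = 0.50
    orf_min_len: int = 30
    orf_max_len: int = 100_000
    start_codons: frozenset[str] = frozenset({"ATG"})
    allow_partial_orfs: bool = True

    def __post_init__(self) -> None:
        if self.min_query_len > self.max_query_len:
            raise ValueError(f"[{self.name}] min_query_len > max_query_len")
        if self.orf_min_len > self.orf_max_len:
            raise ValueError(f"[{self.name}] orf_min_len > orf_max_len")
        for key in ("dedup_identity", "match_min_identity", "match_min_qcov"):
            v = getattr(self, key)
            if not 0 < v <= 1:
                raise ValueError(f"[{self.name}] {key} must be in (0, 1]")


_INT_KEYS = {"min_query_len", "max_query_len", "match_min_score",
             "orf_min_len", "orf_max_len"}
_FLOAT_KEYS = {"dedup_identity", "match_min_identity", "match_min_qcov"}
_KNOWN_KEYS = (
    {"query_fasta_paths", "start_codons", "allow_partial_orfs"}
    | _INT_KEYS
    | _FLOAT_KEYS
)


def parse_strategies(path: PathLike) -> list[SearchStrategy]:
    """Parse the INI-style search-strategies file (one section per strategy).

    Unknown keys and duplicate section names are errors; missing keys take
    their documented defaults; strategies come back in file order. Query
    FASTA paths are checked for readability at parse time (fail fast);
    relative paths resolve against the file's directory.
    """
    path = Path(path)
    cp = configparser.ConfigParser(strict=True, interpolation=None)
    cp.optionxform = str  # keep key case so typos are reported verbatim
    try:
        with open(path) as fh:
            cp.read_file(fh)
    except configparser.DuplicateSectionError as exc:
        raise ValueError(f"{path}: duplicate strategy section: {exc.section!r}") from exc

    strategies = []
    seen: set[str] = set()
    for section in cp.sections():
        if section in seen:
            raise ValueError(f"{path}: duplicate strategy name {section!r}")
        seen.add(section)
        items = dict(cp.items(section))
        unknown = sorted(set(items) - _KNOWN_KEYS)
        if unknown:
            raise ValueError(
                f"{path}: [{section}]: unknown key(s): {', '.join(unknown)}"
            )
        if "query_fasta_paths" not in items:
            raise ValueError(f"{path}: [{section}]: query_fasta_paths is required")
        paths = []
        for token in items["query_fasta_paths"].replace(",", " ").split():
            qp = Path(token)
            if not qp.is_absolute():
                qp = path.parent / qp
            if not qp.is_file():
                raise ValueError(
                    f"{path}: [{section}]: query FASTA not readable: {qp}"
                )
            paths.append(qp)

        kwargs: dict = {"name": section, "query_fasta_paths": paths}
        for key, raw in items.items():
            if key == "query_fasta_paths":
                continue
            if key in _INT_KEYS:
                kwargs[key] = int(raw)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(raw)
            elif key == "start_codons":
                kwargs[key] = frozenset(
                    c.upper() for c in raw.replace(",", " ").split()
                )
            elif key == "allow_partial_orfs":
                kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
        strategies.append(SearchStrategy(**kwargs))
    return strategies


def build_query_set(
    s: SearchStrategy, scheme: Optional[ScoringScheme] = None
) -> list[ProteinSeq]:
    """Pool, length-gate and identity-prune the strategy's protein queries.

    Pruning is greedy: candidates are visited longest-first (ties by id)
    and accepted iff their identity to every already-accepted sequence is
    below ``dedup_identity`` (identity = matched alignment columns divided
    by the shorter sequence's length). Keeping the longest representative
    of a redundant cluster maximizes the read diversity it can recruit.
    """
    scheme = scheme or blosum62_scheme()
    pool: list[ProteinSeq] = []
    for qp in s.query_fasta_paths:
        for rec in read_fasta(qp):
            seq = rec.seq.rstrip("*")
            if not seq:
                continue
            pool.append(ProteinSeq(rec.id, seq))

    gated = [q for q in pool if s.min_query_len <= len(q) <= s.max_query_len]
    gated.sort(key=lambda q: (-len(q), q.id))

    accepted: list[ProteinSeq] = []
    for cand in gated:
        if all(
            global_identity(cand, kept, scheme) < s.dedup_identity
            for kept in accepted
        ):
            accepted.append(cand)
    if not accepted:
        raise ValueError(
            f"strategy {s.name!r}: query set is empty after length gating "
            f"and identity pruning"
        )
    return accepted
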