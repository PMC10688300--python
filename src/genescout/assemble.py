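"""Targeted de Bruijn graph assembly of recruited reads.

Recruited read sets are small and local to one gene family, so a
straightforward single-k de Bruijn assembler suffices: count canonical
k-mers, keep those above a count floor (which absorbs random sequencing
errors), build the doubled (both-orientation) graph, clip short dead-end
tips, pop near-identical bubbles (heterozygous variants), and spell out
maximal non-branching paths as contigs reported once each in canonical
orientation. No scaffolding or multi-k iteration is attempted; that is
the documented fidelity gap versus a full transcriptome assembler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import edlib

from .readfilter import canonical_kmers
from .recruit import ReadSet
from .seqcore import NucRead, revcomp


@dataclass
class AssemblyParams:
    k: int = 31
    min_count: int = 2
    tip_len: int = 0  # 0 means the default 2*k, set in __post_init__
    bubble_identity: float = 0.95
    min_contig_len: int = 200

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 15")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.tip_len <= 0:
            self.tip_len = 2 * self.k


@dataclass
class Contig:
    """An assembled transcript in canonical orientation."""

    id: str
    seq: str
    mean_cov: float

    def __len__(self) -> int:
        return len(self.seq)


def count_kmers(
    reads: Iterable[Union[NucRead, str]], k: int
) -> Counter[str]:
    """Count canonical k-mers over all reads (N-containing k-mers skipped)."""
    counts: Counter[str] = Counter()
    max_len = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        max_len = max(max_len, len(seq))
        counts.update(canonical_kmers(seq, k))
    if max_len and max_len < k:
        raise ValueError(f"k={k} exceeds the longest read ({max_len} bases)")
    return counts


class DebruijnGraph:
    """Doubled de Bruijn graph: every kept k-mer is present in both
    orientations, so each contig exists as two mirror paths and strand
    bookkeeping reduces to removing/reporting canonical twins together."""

    def __init__(self, k: int, nodes: set[str], counts: Counter[str]):
        self.k = k
        self.nodes = nodes
        self.counts = counts

    def cov(self, node: str) -> int:
        rc = revcomp(node)
        return self.counts[min(node, rc)]

    def succs(self, node: str) -> list[str]:
        suf = node[1:]
        return [suf + c for c in "ACGT" if suf + c in self.nodes]

    def preds(self, node: str) -> list[str]:
        pre = node[:-1]
        return [c + pre for c in "ACGT" if c + pre in self.nodes]

    def remove_with_twin(self, node: str) -> None:
        self.nodes.discard(node)
        self.nodes.discard(revcomp(node))


def build_graph(counts: Counter[str], p: AssemblyParams) -> DebruijnGraph:
    """Nodes are k-mers with canonical count >= min_count, in both
    orientations; edges are implicit (k-1)-overlaps within the node set."""
    nodes: set[str] = set()
    for km, c in counts.items():
        if c >= p.min_count:
            nodes.add(km)
            nodes.add(revcomp(km))
    return DebruijnGraph(p.k, nodes, counts)


def _walk_unitig(g: DebruijnGraph, start: str, limit: Optional[int] = None) -> list[str]:
    """Maximal non-branching walk forward from ``start``."""
    path = [start]
    while limit is None or len(path) <= limit:
        s = g.succs(path[-1])
        if len(s) != 1:
            break
        nxt = s[0]
        if len(g.preds(nxt)) != 1 or nxt == start:
            break
        path.append(nxt)
    return path


def clip_tips(g: DebruijnGraph, p: AssemblyParams) -> DebruijnGraph:
    """Iteratively remove dead-end paths of <= tip_len nodes that attach to
    the rest of the graph; the node set only shrinks."""
    changed = True
    while changed:
        changed = False
        for node in sorted(g.nodes):
            if node not in g.nodes or g.preds(node):
                continue  # removed this sweep, or not a dead end
            path = _walk_unitig(g, node, limit=p.tip_len + 1)
            if len(path) > p.tip_len:
                continue
            if not g.succs(path[-1]):
                continue  # isolated path, not a tip
            for n in path:
                g.remove_with_twin(n)
            changed = True
    return g


def _walk_arm(g: DebruijnGraph, first: str, limit: int) -> Optional[tuple[list[str], str]]:
    """Follow a bubble arm from its first internal node to the join node.

    Returns (internal nodes, join node) or None if the arm branches or
    exceeds ``limit`` before reconverging.
    """
    if len(g.preds(first)) != 1:
        return None
    internal = [first]
    while len(internal) <= limit:
        cur = internal[-1]
        s = g.succs(cur)
        if len(s) != 1:
            return None
        nxt = s[0]
        if len(g.preds(nxt)) > 1:
            return internal, nxt
        internal.append(nxt)
    return None


def _spell(g: DebruijnGraph, path: list[str]) -> str:
    return path[0] + "".join(n[-1] for n in path[1:])


def _alt_path(
    g: DebruijnGraph, s: str, t: str, excluded: set[str], limit: int
) -> Optional[list[str]]:
    """Shortest s->t path avoiding ``excluded`` internal nodes (BFS, bounded).

    Unlike an arm walk this may pass through junction nodes, which is what
    resolves overlapping bubbles."""
    from collections import deque

    prev: dict[str, str] = {}
    queue = deque([(s, 0)])
    seen = {s}
    while queue:
        cur, d = queue.popleft()
        if d >= limit:
            continue
        for nxt in g.succs(cur):
            if nxt == t:
                path = [cur]
                while path[-1] != s:
                    path.append(prev[path[-1]])
                return list(reversed(path))[1:]  # internal nodes only
            if nxt in seen or nxt in excluded:
                continue
            seen.add(nxt)
            prev[nxt] = cur
            queue.append((nxt, d + 1))
    return None


def pop_bubbles(g: DebruijnGraph, p: AssemblyParams) -> DebruijnGraph:
    """Collapse bubbles, keeping the higher-mean-coverage path.

    A bubble is a simple arm from a branching node to a rejoin node for
    which a vertex-disjoint alternative path between the same endpoints
    exists with near-identical sequence (identity >= bubble_identity).
    The alternative path may itself pass through junctions, so chains of
    overlapping bubbles collapse one arm at a time."""
    limit = 3 * g.k
    changed = True
    while changed:
        changed = False
        for node in sorted(g.nodes):
            if node not in g.nodes:
                continue
            heads = sorted(g.succs(node))
            if len(heads) < 2:
                continue
            for head in heads:
                arm = _walk_arm(g, head, limit)
                if arm is None:
                    continue
                internal, join = arm
                if join == node:
                    continue
                alt = _alt_path(g, node, join, set(internal), limit)
                if alt is None:
                    continue
                seq_arm = _spell(g, [node, *internal, join])
                seq_alt = _spell(g, [node, *alt, join])
                dist = edlib.align(seq_arm, seq_alt)["editDistance"]
                ident = 1.0 - dist / max(len(seq_arm), len(seq_alt))
                if ident < p.bubble_identity:
                    continue
                cov_arm = sum(g.cov(n) for n in internal) / len(internal)
                cov_alt = sum(g.cov(n) for n in alt) / len(alt) if alt else cov_arm
                if cov_arm > cov_alt or (cov_arm == cov_alt and seq_arm < seq_alt):
                    continue  # this arm is the stronger path; keep it
                for n in internal:
                    g.remove_with_twin(n)
                changed = True
                break
    return g


def contigs(g: DebruijnGraph, p: AssemblyParams) -> list[Contig]:
    """Spell maximal non-branching paths, once each in canonical
    orientation, filtered by min_contig_len; ids follow (length desc,
    sequence asc) order."""
    visited: set[str] = set()
    seqs: dict[str, float] = {}

    def emit(path: list[str]) -> None:
        visited.update(path)
        seq = _spell(g, path)
        canon = min(seq, revcomp(seq))
        cov = sum(g.cov(n) for n in path) / len(path)
        seqs.setdefault(canon, cov)

    for node in sorted(g.nodes):
        if node in visited:
            continue
        preds = g.preds(node)
        is_start = len(preds) != 1 or len(g.succs(preds[0])) != 1
        if is_start:
            emit(_walk_unitig(g, node))
    for node in sorted(g.nodes):  # pure cycles: every node has in=out=1
        if node not in visited:
            emit(_walk_unitig(g, node, limit=len(g.nodes)))

    kept = [(s, c) for s, c in seqs.items() if len(s) >= p.min_contig_len]
    kept.sort(key=lambda x: (-len(x[0]), x[0]))
    return [
        Contig(id=f"contig_{i}", seq=s, mean_cov=c)
        for i, (s, c) in enumerate(kept, 1)
    ]


def assemble_targeted(
    readset: Union[ReadSet, Iterable[NucRead]], p: AssemblyParams = AssemblyParams()
) -> list[Contig]:
    """Full assembly of a recruited read set; deterministic given inputs."""
    reads = readset.all_reads() if isinstance(readset, ReadSet) else readset
    counts = count_kmers(reads, p.k)
    if not counts:
        return []
    g = build_graph(counts, p)
    if not g.nodes:
        return []
    clip_tips(g, p)
    pop_bubbles(g, p)
    return contigs(g, p)
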