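"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written against the *definitions* (plain dynamic
programming, exhaustive scans) and share no code with the package paths
they verify.
"""

from __future__ import annotations

from genescout.seqcore import GeneticCode, ScoringScheme, revcomp


def sw_score_oracle(a: str, b: str, scheme: ScoringScheme) -> int:
    """Affine-gap local alignment score by the textbook three-matrix DP."""
    n, m = len(a), len(b)
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + scheme.score(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def orf_oracle(
    seq: str,
    strand: str,
    code: GeneticCode,
    start_codons: frozenset[str],
    min_len: int,
    max_len: int,
    allow_partial: bool,
) -> set[tuple[int, int, str, str]]:
    """Exhaustive ORF enumeration; returns {(start, end, completeness, aa)}
    with forward-strand half-open coordinates.

    Enumerates start/stop codon positions per frame directly and applies
    the classification rules: complete = first start before each stop;
    5'-partial = edge to first stop with no upstream start; 3'-partial =
    start to edge without stop; internal = edge to edge with neither.
    """
    oriented = seq if strand == "+" else revcomp(seq)
    L = len(oriented)
    table = code.codon_to_aa
    found: set[tuple[int, int, str, str]] = set()

    def to_fwd(a: int, b: int) -> tuple[int, int]:
        return (a, b) if strand == "+" else (L - b, L - a)

    def keep(a: int, b: int, cls: str, aa: str) -> None:
        if aa and min_len <= len(aa) <= max_len:
            s, e = to_fwd(a, b)
            found.add((s, e, cls, aa))

    for f in range(3):
        codons = [oriented[i : i + 3] for i in range(f, L - 2, 3)]
        aas = [table.get(c, "X") for c in codons]
        stops = [i for i, x in enumerate(aas) if x == "*"]
        starts = [i for i, c in enumerate(codons) if c in start_codons]
        n = len(codons)
        prev_stop = -1
        for t in stops:
            cand = [a for a in starts if prev_stop < a < t]
            if cand:
                a = cand[0]
                keep(f + 3 * a, f + 3 * (t + 1), "complete",
                     "M" + "".join(aas[a + 1 : t]))
            elif prev_stop == -1 and allow_partial:
                a0 = 0
                while a0 < t and aas[a0] == "X":
                    a0 += 1  # an ORF never starts at an X
                keep(0 if a0 == 0 else f + 3 * a0, f + 3 * (t + 1),
                     "5prime_partial", "".join(aas[a0:t]))
            prev_stop = t
        tail_starts = [a for a in starts if a > prev_stop]
        if tail_starts and allow_partial:
            a = tail_starts[0]
            keep(f + 3 * a, L, "3prime_partial", "M" + "".join(aas[a + 1 :]))
        if not stops and not starts and allow_partial:
            a0 = 0
            while a0 < n and aas[a0] == "X":
                a0 += 1
            keep(0 if a0 == 0 else f + 3 * a0, L, "internal",
                 "".join(aas[a0:n]))
    return found
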