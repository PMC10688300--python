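"""Seeded synthetic data for every pipeline stage.

Emulates the pipeline's intended input — a stranded paired-end 150 bp
mRNA-seq library — at desk scale: a transcriptome of random background
transcripts plus one planted target transcript (5'UTR + back-translated
target protein + 3'UTR), an unrelated "organelle" contaminant genome, and
error-bearing read pairs with a ground-truth manifest recording every
read's origin and the planted CDS. Errors are silent substitutions
(qualities do not flag them, as in real data); indels, expression
heterogeneity and library artifacts are not modeled.

All randomness flows from one integer seed through numpy's PCG64
generator, so outputs are byte-identical across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqcore import (
    FastaRecord,
    GeneticCode,
    NucRead,
    PathLike,
    ProteinSeq,
    genetic_code,
    revcomp,
    write_fasta,
    write_fastq,
)

_NT = np.array(list("ACGT"))

#: synthetic 220-residue target protein used by examples and tests when the
#: user supplies none; generated once from a fixed seed, comparable in
#: length to a typical single-domain enzyme, and M-initial so the planted
#: CDS begins with a genuine start codon.
EXAMPLE_TARGET_PROTEIN = ProteinSeq(
    "target_protein",
    "M"
    + "".join(
        np.array(list("ACDEFGHIKLMNPQRSTVWY"))[
            np.random.default_rng(20230915).integers(0, 20, 219)
        ]
    ),
)


@dataclass
class SimParams:
    seed: int = 0
    n_background: int = 50
    background_len: tuple[int, int] = (500, 3000)
    target_protein: ProteinSeq = field(
        default_factory=lambda: EXAMPLE_TARGET_PROTEIN
    )
    utr_len: tuple[int, int] = (50, 300)
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 30.0
    error_rate: float = 0.01
    organelle_len: int = 10_000
    organelle_pairs: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        for v in (self.read_len, self.insert_mean, self.coverage, self.organelle_len):
            if v <= 0:
                raise ValueError("all simulation sizes must be positive")


@dataclass
class TruthManifest:
    """Ground truth: per-read origins and the planted target gene."""

    origins: dict[str, str] = field(default_factory=dict)
    target_transcript: str = ""
    cds_start: int = 0
    cds_end: int = 0
    protein: str = ""

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "origins": self.origins,
                    "target_transcript": self.target_transcript,
                    "cds_start": self.cds_start,
                    "cds_end": self.cds_end,
                    "protein": self.protein,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: PathLike) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origins=d["origins"],
            target_transcript=d["target_transcript"],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
            protein=d["protein"],
        )


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def backtranslate(
    protein: ProteinSeq, code: GeneticCode, rng: np.random.Generator
) -> str:
    """Back-translate a protein choosing synonymous codons uniformly;
    a uniformly chosen stop codon is appended."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(code.codon_to_aa.items()):
        by_aa.setdefault(aa, []).append(codon)
    seq = protein.seq.rstrip("*")
    if "*" in seq:
        raise ValueError("internal stop in protein to back-translate")
    out = []
    for res in seq:
        options = by_aa.get(res)
        if not options:
            raise ValueError(f"residue {res!r} has no codon in table {code.table_id}")
        out.append(options[rng.integers(0, len(options))])
    stops = by_aa["*"]
    out.append(stops[rng.integers(0, len(stops))])
    return "".join(out)


def _utr5_clean(utr5: str, code: GeneticCode) -> bool:
    """True when no in-frame start codon sits upstream of the CDS without
    an intervening stop, so the planted ATG is the true ORF start (the
    usual situation in real 5'UTRs)."""
    for j in range(len(utr5) - 3, -1, -3):
        codon = utr5[j : j + 3]
        if code.codon_to_aa[codon] == "*":
            return True
        if codon in code.start_codons:
            return False
    return True


def make_transcriptome(p: SimParams) -> tuple[list[FastaRecord], TruthManifest]:
    """n_background random transcripts plus the planted target transcript
    (5'UTR + CDS + 3'UTR); the manifest records the CDS location."""
    rng = np.random.default_rng([0, p.seed])
    code = genetic_code(1)
    records: list[FastaRecord] = []
    for i in range(p.n_background):
        length = int(rng.integers(p.background_len[0], p.background_len[1] + 1))
        records.append(FastaRecord(f"background_{i}", _rand_nt(rng, length)))
    utr5 = _rand_nt(rng, int(rng.integers(p.utr_len[0], p.utr_len[1] + 1)))
    while not _utr5_clean(utr5, code):
        utr5 = _rand_nt(rng, int(rng.integers(p.utr_len[0], p.utr_len[1] + 1)))
    utr3 = _rand_nt(rng, int(rng.integers(p.utr_len[0], p.utr_len[1] + 1)))
    cds = backtranslate(p.target_protein, genetic_code(1), rng)
    target = utr5 + cds + utr3
    records.append(FastaRecord("target", target))
    manifest = TruthManifest(
        target_transcript=target,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        protein=p.target_protein.seq,
    )
    return records, manifest


def make_organelle(p: SimParams, rng: Optional[np.random.Generator] = None) -> FastaRecord:
    """A random contaminant reference genome (unrelated to the transcripts)."""
    rng = rng if rng is not None else np.random.default_rng([1, p.seed])
    return FastaRecord("organelle", _rand_nt(rng, p.organelle_len))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    idx = np.nonzero(hit)[0]
    for i in idx:
        base = arr[i].decode()
        choices = [b for b in "ACGT" if b != base]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def _qualities(n: int, rng: np.random.Generator) -> list[int]:
    q = np.clip(np.rint(rng.normal(38.0, 2.0, n)), 2, 41).astype(int)
    return q.tolist()


def simulate_reads(
    transcripts: Sequence[FastaRecord],
    p: SimParams,
    rng: Optional[np.random.Generator] = None,
    n_pairs_override: Optional[dict[str, int]] = None,
) -> tuple[list[tuple[NucRead, NucRead]], TruthManifest]:
    """Draw error-bearing read pairs from each source sequence.

    Pair counts per source reach the target fold coverage (overridable per
    source id); insert lengths are Normal(insert_mean, insert_sd) truncated
    to [read_len, source length]; mate 1 is the fragment's 5' end and mate 2
    the reverse complement of its 3' end. Substitutions are i.i.d. at
    ``error_rate``; qualities are drawn Normal(38, 2) clipped to [2, 41]
    and do not mark the errors.
    """
    rng = rng if rng is not None else np.random.default_rng([2, p.seed])
    pairs: list[tuple[NucRead, NucRead]] = []
    manifest = TruthManifest()
    for rec in transcripts:
        L = len(rec.seq)
        if L < p.read_len:
            continue
        if n_pairs_override and rec.id in n_pairs_override:
            n_pairs = n_pairs_override[rec.id]
        else:
            n_pairs = max(1, int(round(p.coverage * L / (2 * p.read_len))))
        for i in range(n_pairs):
            insert = int(np.clip(rng.normal(p.insert_mean, p.insert_sd), p.read_len, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = rec.seq[start : start + insert]
            r1 = _mutate(frag[: p.read_len], p.error_rate, rng)
            r2 = _mutate(revcomp(frag)[: p.read_len], p.error_rate, rng)
            rid = f"{rec.id}.{i}"
            pairs.append(
                (
                    NucRead(rid, r1, _qualities(len(r1), rng), 1),
                    NucRead(rid, r2, _qualities(len(r2), rng), 2),
                )
            )
            manifest.origins[rid] = rec.id
    return pairs, manifest


def simulate_dataset(
    p: SimParams,
) -> tuple[
    list[tuple[NucRead, NucRead]], list[FastaRecord], FastaRecord, TruthManifest
]:
    """The full study mixture: transcriptome reads plus organelle
    contamination, with a complete manifest."""
    transcripts, manifest = make_transcriptome(p)
    organelle = make_organelle(p)
    pairs, read_manifest = simulate_reads(
        [*transcripts, organelle],
        p,
        n_pairs_override={organelle.id: p.organelle_pairs},
    )
    manifest.origins = read_manifest.origins
    return pairs, transcripts, organelle, manifest


def simulate_project(p: SimParams, out_dir: PathLike) -> dict[str, Path]:
    """Write a ready-to-run project: paired FASTQ, organelle reference
    FASTA, target-protein query FASTA and the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, transcripts, organelle, manifest = simulate_dataset(p)
    paths = {
        "reads_1": out / "reads_1.fastq",
        "reads_2": out / "reads_2.fastq",
        "organelle": out / "organelle.fasta",
        "query": out / "query.fasta",
        "transcripts": out / "true_transcripts.fasta",
        "truth": out / "truth.json",
    }
    write_fastq((a for a, _ in pairs), paths["reads_1"])
    write_fastq((b for _, b in pairs), paths["reads_2"])
    write_fasta([organelle], paths["organelle"])
    write_fasta([p.target_protein], paths["query"])
    write_fasta(transcripts, paths["transcripts"])
    manifest.to_json(paths["truth"])
    return paths
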