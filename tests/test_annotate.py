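"""Transcript matching, ORF discovery, CDS selection and output files."""

import numpy as np
import pytest

from genescout.annotate import (
    COMPLETE,
    INTERNAL,
    PARTIAL_3,
    PARTIAL_5,
    Orf,
    SourceCodeMap,
    find_orfs,
    genetic_code_for,
    match_transcripts,
    select_cds,
    write_outputs,
)
from genescout.seqcore import (
    FastaRecord,
    ProteinSeq,
    genetic_code,
    revcomp,
    translate,
)
from genescout.simdata import SimParams, backtranslate, make_transcriptome
from genescout.strategy import SearchStrategy

from conftest import random_aa, random_nt
from oracles import orf_oracle


def strat(**kw):
    kw.setdefault("orf_min_len", 1)
    return SearchStrategy("s", [], **kw)


@pytest.fixture()
def query(rng):
    return ProteinSeq("q", "M" + random_aa(rng, 119))


@pytest.fixture()
def coding_contig(rng, query, code1):
    nt = backtranslate(query, code1, rng)
    return FastaRecord("c1", random_nt(rng, 60) + nt + random_nt(rng, 60))


class TestMatchTranscripts:
    def test_exact_backtranslation_retained(self, coding_contig, query, scheme):
        m = match_transcripts([coding_contig], [query], strat(), scheme)
        assert len(m) == 1
        assert m[0].strand == "+" and m[0].alignment.identity == 1.0
        assert m[0].alignment.q_cov == 1.0

    def test_random_contigs_dropped(self, scheme):
        """Empirical null: random contigs vs an unrelated query set pass the
        default thresholds in <1% of 500 trials."""
        rng = np.random.default_rng(17)
        queries = [ProteinSeq("q", random_aa(rng, 80))]
        kept = 0
        s = strat()
        for _ in range(500):
            contig = FastaRecord("c", random_nt(rng, 150))
            kept += bool(match_transcripts([contig], queries, s, scheme))
        assert kept <= 5

    def test_minus_strand_coordinates_stay_forward(self, coding_contig, query, scheme):
        rc = FastaRecord("c2", revcomp(coding_contig.seq))
        m = match_transcripts([rc], [query], strat(), scheme)
        assert len(m) == 1 and m[0].strand == "-"
        code = genetic_code(1)
        s = strat()
        orfs = find_orfs(rc, "-", code, s)
        cds = select_cds(orfs, [query], scheme)
        assert cds.aa.seq == query.seq
        # forward-strand slice, reverse-complemented, re-translates to the query
        nt = revcomp(rc.seq[cds.start : cds.end])
        assert translate(nt, code).rstrip("*") == query.seq


class TestGeneticCodeFor:
    def test_default_map(self):
        assert genetic_code_for("nucleus").table_id == 1
        assert genetic_code_for("plastid").table_id == 11
        assert genetic_code_for("mitochondrion").table_id == 1

    def test_user_override(self):
        m = SourceCodeMap({"nucleus": 1, "plastid": 11, "mitochondrion": 5})
        assert genetic_code_for("mitochondrion", m).table_id == 5

    def test_unknown_source_is_error(self):
        with pytest.raises(KeyError):
            genetic_code_for("apicoplast")


class TestFindOrfs:
    def test_simple_complete_orf(self, code1):
        contig = FastaRecord("c", "AAATGAAATAGGG")
        orfs = find_orfs(contig, "+", code1, strat())
        complete = [o for o in orfs if o.completeness == COMPLETE]
        assert len(complete) == 1
        o = complete[0]
        assert (o.start, o.end) == (2, 11) and o.aa.seq == "MK"

    def test_no_start_yields_5prime_partial(self, code1):
        contig = FastaRecord("c", "AAAAAACCCTAGGGG")  # stop in frame 0, no ATG
        orfs = find_orfs(contig, "+", code1, strat())
        p5 = [o for o in orfs if o.completeness == PARTIAL_5]
        assert p5 and p5[0].start == 0

    def test_partials_suppressed_when_disallowed(self, code1):
        contig = FastaRecord("c", "AAAAAACCCTAGGGG")
        orfs = find_orfs(contig, "+", code1, strat(allow_partial_orfs=False))
        assert all(o.completeness == COMPLETE for o in orfs)

    def test_nested_starts_report_longest(self, code1):
        # two ATGs sharing one stop: only the upstream (longer) ORF reported
        contig = FastaRecord("c", "ATGAAAATGAAATAG")
        orfs = find_orfs(contig, "+", code1, strat())
        complete = [o for o in orfs if o.completeness == COMPLETE]
        assert len(complete) == 1 and complete[0].start == 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_bruteforce_enumerator(self, code1, strand):
        """300 random contigs: implementation output equals the independent
        exhaustive ORF enumeration, class by class."""
        rng = np.random.default_rng(300)
        s = strat()
        for _ in range(300):
            n = int(rng.integers(30, 400))
            seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, n)])
            contig = FastaRecord("c", seq)
            got = {
                (o.start, o.end, o.completeness, o.aa.seq)
                for o in find_orfs(contig, strand, code1, s)
            }
            want = orf_oracle(
                seq, strand, code1, s.start_codons, s.orf_min_len,
                s.orf_max_len, s.allow_partial_orfs,
            )
            assert got == want

    def test_length_gates_applied(self, code1):
        contig = FastaRecord("c", "AAATGAAATAGGG")
        assert find_orfs(contig, "+", code1, strat(orf_min_len=10)) == [] or all(
            len(o.aa) >= 10 for o in find_orfs(contig, "+", code1, strat(orf_min_len=10))
        )


class TestSelectCds:
    def test_planted_orf_equals_query(self, rng, query, code1, scheme):
        p = SimParams(seed=8, n_background=0, target_protein=query)
        recs, manifest = make_transcriptome(p)
        target = next(r for r in recs if r.id == "target")
        orfs = find_orfs(target, "+", code1, strat())
        cds = select_cds(orfs, [query], scheme)
        assert cds.aa.seq == query.seq == manifest.protein
        assert (cds.start, cds.end) == (manifest.cds_start, manifest.cds_end)

    def test_completeness_breaks_score_ties(self, code1):
        a = Orf("c", "+", 0, 0, 9, COMPLETE, ProteinSeq("a", "MK"), 30)
        b = Orf("c", "+", 0, 12, 18, PARTIAL_3, ProteinSeq("b", "MK"), 30)
        assert select_cds([a, b], []).completeness == COMPLETE

    def test_no_queries_longest_wins(self, code1):
        a = Orf("c", "+", 0, 0, 9, COMPLETE, ProteinSeq("a", "MK"), 60)
        b = Orf("c", "+", 0, 12, 33, COMPLETE, ProteinSeq("b", "MKLPQW"), 60)
        assert select_cds([a, b], []).aa.seq == "MKLPQW"


class TestWriteOutputs:
    def annotate_one(self, contig, query, scheme, tmp_path, strand="+"):
        code = genetic_code(1)
        s = strat()
        matches = match_transcripts([contig], [query], s, scheme)
        orfs = find_orfs(contig, matches[0].strand, code, s)
        cds = {contig.id: select_cds(orfs, [query], scheme)}
        return write_outputs([contig], matches, cds, tmp_path), cds

    def test_coordinate_conversion_and_phase(self, tmp_path, scheme):
        contig = FastaRecord("c", "AAATGAAAAAATAGGG")
        query = ProteinSeq("q", "MKKK")
        s = strat(match_min_score=10, match_min_qcov=0.5, match_min_identity=0.4)
        code = genetic_code(1)
        matches = match_transcripts([contig], [query], s, scheme)
        orfs = find_orfs(contig, "+", code, s)
        cds = {"c": select_cds(orfs, [query], scheme)}
        paths = write_outputs([contig], matches, cds, tmp_path)
        lines = [
            l.split("\t") for l in paths["gff3"].read_text().splitlines()
            if not l.startswith("#")
        ]
        cds_row = next(l for l in lines if l[2] == "CDS")
        # internal [2, 14) becomes 1-based inclusive 3..14, phase 0
        assert (cds_row[3], cds_row[4], cds_row[6], cds_row[7]) == ("3", "14", "+", "0")

    def test_minus_strand_orf_nt_is_revcomp_slice(self, tmp_path, rng, query, scheme, code1):
        nt = backtranslate(query, code1, rng)
        contig = FastaRecord("m", revcomp(random_nt(rng, 50) + nt + random_nt(rng, 50)))
        paths, cds = self.annotate_one(contig, query, scheme, tmp_path)
        orf = cds["m"]
        assert orf.strand == "-"
        from genescout.seqcore import read_fasta

        rec = next(read_fasta(paths["orfs_nt"]))
        assert rec.seq == revcomp(contig.seq[orf.start : orf.end])
        assert "*" not in translate(rec.seq, code1).rstrip("*")

    def test_gff3_roundtrip_and_nesting(self, tmp_path, rng, query, scheme, code1):
        nt = backtranslate(query, code1, rng)
        contig = FastaRecord("c", random_nt(rng, 40) + nt + random_nt(rng, 40))
        paths, cds = self.annotate_one(contig, query, scheme, tmp_path)
        text = paths["gff3"].read_text()
        assert text.startswith("##gff-version 3\n")
        rows = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
        assert all(len(r) == 9 for r in rows)
        mrna = next(r for r in rows if r[2] == "mRNA")
        cds_row = next(r for r in rows if r[2] == "CDS")
        # coordinates round-trip to the stored ORF
        orf = cds["c"]
        assert int(cds_row[3]) == orf.start + 1 and int(cds_row[4]) == orf.end
        assert cds_row[6] == orf.strand
        # CDS nested within its mRNA span, both within contig bounds
        assert int(mrna[3]) <= int(cds_row[3]) <= int(cds_row[4]) <= int(mrna[4])
        assert int(mrna[4]) <= len(contig.seq)
        assert f"Parent={contig.id}.mRNA" in cds_row[8]

    def test_every_cds_translates_cleanly(self, tmp_path, rng, scheme, code1):
        from genescout.seqcore import read_fasta

        for i in range(5):
            q = ProteinSeq("q", "M" + random_aa(rng, 80))
            nt = backtranslate(q, code1, rng)
            contig = FastaRecord(f"c{i}", random_nt(rng, 30) + nt + random_nt(rng, 30))
            paths, _ = self.annotate_one(contig, q, scheme, tmp_path / str(i))
            for rec in read_fasta(paths["orfs_nt"]):
                assert "*" not in translate(rec.seq, code1).rstrip("*")
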