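"""Progressive alignment, primer location and primer-interior trimming."""

import numpy as np
import pytest

import barcodiag as bd
from barcodiag.alignment import (
    Alignment,
    AlignmentError,
    PrimerNotFoundError,
    PrimerRole,
    PrimerSpec,
    Strand,
)
from barcodiag.seqio import SequenceRecord, reverse_complement


def _nw_score(a, b, match=1.0, mismatch=-1.0, gap_open=-6.0, gap_extend=-0.5):
    """Independent affine-gap Needleman-Wunsch score (full DP table)."""
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def _pair_score(row_a, row_b, match=1.0, mismatch=-1.0, gap_open=-6.0, gap_extend=-0.5):
    """Score of an aligned pair of rows under the affine model."""
    score, in_gap = 0.0, False
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += match if x == y else mismatch
            in_gap = False
    return score


class TestAlign:
    def test_identical_sequences_align_gap_free(self):
        s = "ACGTACGTACGTACGTACGT"
        aln = bd.align([SequenceRecord("a", s), SequenceRecord("b", s)])
        assert aln.ncol == len(s)
        assert all(r.residues == s for r in aln.records)

    def test_pairwise_matches_nw_oracle(self):
        a, b = "ACGT", "ACT"
        aln = bd.align([SequenceRecord("a", a), SequenceRecord("b", b)])
        rows = {r.id: r.residues for r in aln.records}
        assert rows["a"].replace("-", "") == a
        assert rows["b"].replace("-", "") == b
        assert sum(1 for x in rows["b"] if x == "-") == 1
        assert _pair_score(rows["a"], rows["b"]) == pytest.approx(_nw_score(a, b))

    def test_substitution_only_set_is_gap_free(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        recs = []
        for i in range(5):
            s = list(base)
            s[3 + i * 4] = "T" if s[3 + i * 4] != "T" else "A"
            recs.append(SequenceRecord(f"r{i}", "".join(s)))
        aln = bd.align(recs)
        assert aln.ncol == len(base)
        assert all("-" not in r.residues for r in aln.records)

    def test_two_sequence_alignment_order_invariant(self):
        a = SequenceRecord("a", "ACGTACGTTTACGT")
        b = SequenceRecord("b", "ACGTACGTACGT")
        r1 = {r.id: r.residues for r in bd.align([a, b]).records}
        r2 = {r.id: r.residues for r in bd.align([b, a]).records}
        assert r1 == r2

    def test_row_invariant_degapping_round_trip(self):
        recs = [
            SequenceRecord("a", "ACGTACGTACGTAAGGTT"),
            SequenceRecord("b", "ACGTACGTACGTAAGG"),
            SequenceRecord("c", "ACGTACTACGTAAGGTT"),
        ]
        aln = bd.align(recs)
        degapped = {r.id: r.residues.replace("-", "") for r in aln.records}
        assert degapped == {r.id: r.residues for r in recs}


class TestImportExport:
    def test_import_checks_and_round_trip(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nAC-GT\n>b\nACCGT\n>c\nAC-GT\n")
        aln = bd.import_alignment(path)
        assert aln.ncol == 5
        out = tmp_path / "out.fasta"
        bd.export_alignment(aln, out)
        assert [r.residues for r in bd.import_alignment(out).records] == [
            r.residues for r in aln.records
        ]

    def test_ragged_rows_error_lists_ids(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentError, match="b"):
            bd.import_alignment(path)


PRIMER = "GATTTCAGGATCCAGGATTCACG"


class TestLocatePrimer:
    def test_verbatim_site(self):
        seq = "A" * 10 + PRIMER + "C" * 30
        spec = PrimerSpec("p", PRIMER)
        site = bd.locate_primer(seq, spec, max_mismatch=0)
        assert (site.start, site.end, site.mismatches) == (11, 33, 0)

    def test_substituted_site_within_budget(self):
        mutated = list(PRIMER)
        mutated[4] = "A" if mutated[4] != "A" else "C"
        mutated[15] = "T" if mutated[15] != "T" else "G"
        seq = "A" * 10 + "".join(mutated) + "C" * 30
        site = bd.locate_primer(seq, PrimerSpec("p", PRIMER), max_mismatch=3)
        assert (site.start, site.end, site.mismatches) == (11, 33, 2)

    def test_minus_strand_search(self):
        seq = "T" * 8 + reverse_complement(PRIMER) + "G" * 12
        spec = PrimerSpec("p", PRIMER, PrimerRole.UNIVERSAL_REV, Strand.MINUS)
        site = bd.locate_primer(seq, spec, max_mismatch=0)
        assert (site.start, site.end) == (9, 9 + len(PRIMER) - 1)

    def test_absent_primer_errors(self):
        with pytest.raises(PrimerNotFoundError):
            bd.locate_primer("A" * 60, PrimerSpec("p", PRIMER), max_mismatch=1)


def _flanked_alignment(interior_cols=54):
    fwd = "GTTATGCATGAACGTAATGCTCA"  # 23
    rev = "CGCGCATGGTGGATTCACAATCC"  # 23
    rng = np.random.default_rng(5)
    interior = "".join(rng.choice(list("ACGT"), size=interior_cols))
    row = fwd + interior + reverse_complement(rev)
    recs = [SequenceRecord(f"r{i}", row) for i in range(4)]
    return Alignment(tuple(recs)), PrimerSpec("f", fwd), PrimerSpec(
        "r", rev, PrimerRole.UNIVERSAL_REV, Strand.MINUS
    )


class TestTrim:
    def test_interior_columns_arithmetic(self):
        aln, fwd, rev = _flanked_alignment(54)
        trimmed = bd.trim_to_primer_interior(aln, fwd, rev)
        # fwd at 1..23, rev at 78..100 -> interior 24..77
        assert trimmed.meta["fwd_interval"] == (1, 23)
        assert trimmed.meta["rev_interval"] == (78, 100)
        assert trimmed.ncol == 54
        assert trimmed.ncol == trimmed.meta["rev_interval"][0] - trimmed.meta[
            "fwd_interval"
        ][1] - 1

    def test_trim_is_not_reapplicable(self):
        aln, fwd, rev = _flanked_alignment()
        trimmed = bd.trim_to_primer_interior(aln, fwd, rev)
        with pytest.raises((PrimerNotFoundError, AlignmentError)):
            bd.trim_to_primer_interior(trimmed, fwd, rev)

    def test_reverse_before_forward_errors(self):
        aln, fwd, rev = _flanked_alignment()
        # swap roles: search the reverse primer as forward and vice versa
        swapped_f = PrimerSpec("f", rev.sequence)
        swapped_r = PrimerSpec("r", fwd.sequence, PrimerRole.UNIVERSAL_REV, Strand.MINUS)
        with pytest.raises((AlignmentError, PrimerNotFoundError)):
            bd.trim_to_primer_interior(aln, swapped_f, swapped_r)

    def test_all_gap_columns_retained(self):
        aln, fwd, rev = _flanked_alignment(30)
        rows = []
        for r in aln.records:
            s = r.residues
            rows.append(SequenceRecord(r.id, s[:30] + "---" + s[30:]))
        gapped = Alignment(tuple(rows))
        trimmed = bd.trim_to_primer_interior(gapped, fwd, rev)
        assert trimmed.ncol == 33
        assert trimmed.meta["ncol_after_gapfree"] == 30
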