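"""Native matching, BLAST tabular ingestion, and the true-mismatch filter."""

import io
import random

import pytest

from conftest import make_match, simple_spacer_db
from oracles import brute_force_scan, revcomp
from spacerhost import (
    filter_matches,
    filter_matches_simple,
    native_match,
    read_blast_tabular,
    true_mismatch_count,
    write_blast_tabular,
)


class TestTrueMismatchCount:
    @pytest.mark.parametrize(
        "spacer_len,aln_len,raw,expected",
        [(30, 30, 0, 0), (35, 33, 1, 3), (43, 41, 0, 2)],
    )
    def test_formula(self, spacer_len, aln_len, raw, expected):
        assert true_mismatch_count(spacer_len, aln_len, raw) == expected

    def test_alignment_longer_than_spacer_is_inconsistent(self):
        with pytest.raises(ValueError, match="exceeds"):
            true_mismatch_count(30, 31, 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            true_mismatch_count(30, -1, 0)


@pytest.fixture
def db_one_spacer():
    db, ids = simple_spacer_db({"hostA": [0.1]})
    return db, ids["hostA"][0]


class TestReadBlastTabular:
    def _row(self, sid, qstart=11, qend=40, sstart=1, send=30, length=30,
             mismatch=0, gapopen=0):
        return (
            f"ctg1\t{sid}\t100.000\t{length}\t{mismatch}\t{gapopen}"
            f"\t{qstart}\t{qend}\t{sstart}\t{send}\t0.0\t60.0\n"
        )

    def test_full_length_hit_true_mismatches(self, db_one_spacer):
        db, sid = db_one_spacer
        matches = read_blast_tabular(io.StringIO(self._row(sid, mismatch=1)), db)
        (m,) = matches
        assert m.true_mismatches == 1
        assert m.host_id == "hostA"
        assert m.strand == "+"

    def test_descending_subject_coordinates_mean_minus_strand(self, db_one_spacer):
        db, sid = db_one_spacer
        (m,) = read_blast_tabular(
            io.StringIO(self._row(sid, sstart=30, send=1)), db
        )
        assert m.strand == "-"
        assert m.contig_start <= m.contig_end

    def test_contig_as_subject_orientation(self, db_one_spacer):
        # subject side is the contig: descending contig coordinates flag "-"
        db, sid = db_one_spacer
        row = f"{sid}\tctg1\t100.000\t30\t0\t0\t1\t30\t40\t11\t0.0\t60.0\n"
        (m,) = read_blast_tabular(io.StringIO(row), db, query_is_contig=False)
        assert m.strand == "-"
        assert (m.contig_start, m.contig_end) == (11, 40)

    def test_truncated_hit_accumulates_true_mismatches(self, db_one_spacer):
        db, sid = db_one_spacer
        (m,) = read_blast_tabular(
            io.StringIO(self._row(sid, qend=37, send=27, length=27, mismatch=1)), db
        )
        assert m.true_mismatches == 30 - 27 + 1

    def test_unknown_spacer_id_fatal_with_line_number(self, db_one_spacer):
        db, _ = db_one_spacer
        with pytest.raises(ValueError, match="line 1"):
            read_blast_tabular(io.StringIO(self._row("nobody|x|0|r:1-30")), db)

    def test_malformed_row_fatal(self, db_one_spacer):
        db, _ = db_one_spacer
        with pytest.raises(ValueError, match="malformed"):
            read_blast_tabular(io.StringIO("ctg1\tonly\tthree\n"), db)

    def test_native_hits_roundtrip_through_tabular(self):
        rng = random.Random(3)
        db, ids = simple_spacer_db({"hostA": [0.1, 0.5], "hostB": [0.3]})
        spacers = list(db.spacers.values())
        contig = "".join(rng.choice("ACGT") for _ in range(600))
        contig = contig[:50] + spacers[0].sequence + contig[80:]
        contig = contig[:300] + revcomp(spacers[2].sequence) + contig[330:]
        hits = native_match(db, {"ctg": contig})
        buf = io.StringIO()
        write_blast_tabular(hits, buf)
        buf.seek(0)
        again = read_blast_tabular(buf, db)
        assert again == hits


class TestNativeMatch:
    def _mk(self, seed=0, n=400):
        rng = random.Random(seed)
        return rng, "".join(rng.choice("ACGT") for _ in range(n))

    def test_exact_plus_strand_hit_coordinates(self):
        db, ids = simple_spacer_db({"hostA": [0.1]})
        spacer = db.spacer(ids["hostA"][0])
        rng, background = self._mk(1)
        contig = background[:100] + spacer.sequence + background[130:]
        hits = native_match(db, {"ctg": contig})
        exact = [h for h in hits if h.true_mismatches == 0]
        assert any(
            (h.contig_start, h.strand) == (101, "+") for h in exact
        )

    def test_reverse_complement_found_on_minus_strand(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGT") for _ in range(32))
        db, ids = simple_spacer_db({"hostA": [0.1]})
        # replace stored sequence by building a custom contig around revcomp
        spacer = db.spacer(ids["hostA"][0])
        contig = (
            "".join(rng.choice("ACGT") for _ in range(90))
            + revcomp(spacer.sequence)
            + "".join(rng.choice("ACGT") for _ in range(90))
        )
        hits = [h for h in native_match(db, {"ctg": contig}) if h.raw_mismatches == 0]
        assert hits and all(h.strand == "-" for h in hits)
        assert hits[0].contig_start == 91

    def test_mismatch_threshold_honoured(self):
        rng = random.Random(4)
        from spacerhost import CrisprArray, Spacer, SpacerDatabase
        from spacerhost.crispr_arrays import make_spacer_id
        spacer = "".join(rng.choice("ACGT") for _ in range(30))
        arr = CrisprArray("a", "h", "r", 100, 400)
        sid = make_spacer_id("h", "a", 0, "r", 130, 159)
        db = SpacerDatabase([arr], [Spacer(sid, "a", "h", "r", 130, 159, spacer, 0)])
        def mutate(seq, k):
            chars = list(seq)
            for pos in rng.sample(range(len(seq)), k):
                chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
            return "".join(chars)
        contig = (
            "G" * 50 + mutate(spacer, 0) + "G" * 50 + mutate(spacer, 2)
            + "G" * 50 + mutate(spacer, 3) + "G" * 50
        )
        hits = native_match(db, {"ctg": contig})
        starts = sorted(h.contig_start for h in hits)
        assert starts == [51, 131]  # 0- and 2-substitution implants only

    def test_n_matches_nothing(self):
        db, ids = simple_spacer_db({"hostA": [0.1]})
        spacer = db.spacer(ids["hostA"][0]).sequence
        contig = "G" * 20 + "N" * 3 + spacer[3:] + "G" * 20
        hits = native_match(db, {"ctg": contig}, max_true_mismatches=3)
        assert hits and all(h.true_mismatches == 3 for h in hits)
        assert not native_match(db, {"ctg": contig}, max_true_mismatches=2)

    def test_empty_spacer_database_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            native_match([], {"ctg": "ACGT" * 20})

    def test_contig_shorter_than_spacer_yields_no_hits(self):
        db, _ = simple_spacer_db({"hostA": [0.1]})
        assert native_match(db, {"ctg": "ACGTAC"}) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(99)
        db, ids = simple_spacer_db({"hostA": [0.1]})
        for trial in range(25):
            L = rng.randint(28, 43)
            spacer_seq = "".join(rng.choice("ACGT") for _ in range(L))
            contig = "".join(rng.choice("ACGTN") for _ in range(rng.randint(60, 200)))
            # rebuild a db whose single spacer carries this sequence
            from spacerhost import CrisprArray, Spacer, SpacerDatabase
            from spacerhost.crispr_arrays import make_spacer_id
            arr = CrisprArray("a", "h", "r", 100, 100 + 10 * L)
            sid = make_spacer_id("h", "a", 0, "r", 130, 130 + L - 1)
            sp = Spacer(sid, "a", "h", "r", 130, 130 + L - 1, spacer_seq, 0)
            tiny = SpacerDatabase([arr], [sp])
            max_mm = rng.choice([0, 1, 2, 3])
            got = [
                (h.contig_start, h.strand, h.true_mismatches)
                for h in native_match(tiny, {"ctg": contig}, max_mm)
            ]
            assert got == brute_force_scan(spacer_seq, contig, max_mm)

    def test_strand_symmetry(self):
        rng = random.Random(7)
        db, ids = simple_spacer_db({"hostA": [0.1]})
        spacer = db.spacer(ids["hostA"][0])
        contig = (
            "".join(rng.choice("ACGT") for _ in range(70))
            + spacer.sequence
            + "".join(rng.choice("ACGT") for _ in range(70))
        )
        fwd = native_match(db, {"ctg": contig})
        rev = native_match(db, {"ctg": revcomp(contig)})
        n = len(contig)
        mirrored = sorted(
            (n - h.contig_end + 1, {"+": "-", "-": "+"}[h.strand], h.true_mismatches)
            for h in rev
        )
        assert mirrored == sorted(
            (h.contig_start, h.strand, h.true_mismatches) for h in fwd
        )


class TestFilter:
    def test_gapped_match_removed(self):
        m = make_match("s|a|0|r:1-30", "h", "c", 1, 32, gap_opens=1,
                       spacer_length=30, alignment_length=30)
        assert filter_matches([m]) == []

    def test_two_true_mismatches_kept(self):
        m = make_match("s|a|0|r:1-30", "h", "c", 1, 30, raw_mismatches=2)
        assert filter_matches([m]) == [m]

    def test_truncation_pushes_over_threshold(self):
        # 36 bp spacer aligned over 33 bp with 0 raw mismatches -> 3 true
        m = make_match("s|a|0|r:1-36", "h", "c", 1, 33, spacer_length=36)
        assert m.true_mismatches == 3
        assert filter_matches([m]) == []

    def test_idempotent_and_stable(self):
        matches = [
            make_match("s|a|0|r:1-30", "h", "c", i, i + 29, raw_mismatches=i % 4)
            for i in range(1, 9)
        ]
        once = filter_matches(matches)
        assert filter_matches(once) == once
        assert once == [m for m in matches if m.true_mismatches <= 2]

    def test_simple_mode_ignores_gaps_and_truncation(self):
        gapped = make_match("s|a|0|r:1-30", "h", "c", 1, 32, gap_opens=1,
                            raw_mismatches=1, spacer_length=30,
                            alignment_length=30)
        truncated = make_match("s|a|0|r:1-36", "h", "c", 1, 33, spacer_length=36)
        assert filter_matches_simple([gapped, truncated]) == [gapped, truncated]
        noisy = make_match("s|a|0|r:1-30", "h", "c", 1, 30, raw_mismatches=3)
        assert filter_matches_simple([noisy]) == []
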