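"""Parsing, coordinate conventions and best-hit selection."""

from __future__ import annotations

import io
import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from popanir import (
    AlignmentParseError,
    AlignmentRecord,
    best_hit_per_read,
    load_reference_index,
    parse_blast_tabular,
    parse_sam,
    write_blast_tabular,
)


def blast_line(read="r1", contig="c1", pident=98.0, length=150, mismatch=3,
               sstart=201, send=350, bitscore=200.0):
    return "\t".join(
        [read, contig, f"{pident:.2f}", str(length), str(mismatch), "0", "1",
         str(length), str(sstart), str(send), "1e-50", f"{bitscore:g}"]
    )


class TestBlastTabular:
    def test_plus_strand_coordinates_become_zero_based_half_open(self):
        (rec,) = parse_blast_tabular([blast_line()])
        assert rec.identity == 98.0
        assert (rec.ref_start, rec.ref_end) == (200, 350)
        assert rec.bitscore == 200.0

    def test_minus_strand_hit_is_swapped(self):
        (rec,) = parse_blast_tabular(
            [blast_line(read="r2", pident=95.0, length=100, sstart=500, send=401)]
        )
        assert (rec.ref_start, rec.ref_end) == (400, 500)

    def test_empty_stream_and_comments(self):
        assert parse_blast_tabular([]) == []
        assert parse_blast_tabular(["# header", "", "   "]) == []

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(AlignmentParseError, match="line 2"):
            parse_blast_tabular([blast_line(), "r2\tc1\tonly-three"])
        with pytest.raises(AlignmentParseError, match="line 1"):
            parse_blast_tabular([blast_line(pident=98.0).replace("98.00", "abc")])

    def test_coordinates_checked_against_reference(self, reference):
        with pytest.raises(AlignmentParseError, match="c9"):
            parse_blast_tabular([blast_line(contig="c9")], reference=reference)
        with pytest.raises(AlignmentParseError, match="c2"):
            parse_blast_tabular(
                [blast_line(contig="c2", sstart=350, send=499)], reference=reference
            )

    def test_identity_floor_discards_low_hits(self):
        lines = [blast_line(read="lo", pident=65.0), blast_line(read="hi")]
        records = parse_blast_tabular(lines)
        assert [r.read_id for r in records] == ["hi"]

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=70.0, max_value=100.0).map(lambda x: round(x, 2)),
                st.integers(min_value=1, max_value=500),
                st.integers(min_value=0, max_value=10_000),
                st.floats(min_value=0, max_value=1e4, allow_nan=False).map(
                    lambda x: round(x, 1)
                ),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_round_trip_is_identity(self, rows):
        records = [
            AlignmentRecord(
                read_id=f"r{i}", contig_id="c1", identity=pid, aln_length=ln,
                ref_start=start, ref_end=start + ln, bitscore=score,
            )
            for i, (pid, ln, start, score) in enumerate(rows)
        ]
        buffer = io.StringIO()
        write_blast_tabular(records, buffer)
        assert parse_blast_tabular(io.StringIO(buffer.getvalue())) == records


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:5000\n"


def sam_line(read="s1", flag=0, pos=101, cigar="150M", nm=3, extra=""):
    tags = f"NM:i:{nm}" if nm is not None else ""
    fields = [read, str(flag), "c1", str(pos), "60", cigar, "*", "0", "0",
              "*", "*"]
    if tags:
        fields.append(tags)
    if extra:
        fields.append(extra)
    return "\t".join(fields) + "\n"


def write_sam(tmp_path, body, name="toy.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + body)
    return path


class TestSam:
    @pytest.mark.parametrize(
        "cigar, nm, expected",
        [
            ("150M", 3, 98.0),  # 3 SNVs in a 150 bp read
            ("1000M", 1, 99.9),  # 1 mismatch in 1000 aligned columns
            ("100M", 0, 100.0),
        ],
    )
    def test_identity_from_edit_distance(self, tmp_path, cigar, nm, expected):
        path = write_sam(tmp_path, sam_line(cigar=cigar, nm=nm))
        (rec,) = parse_sam(path)
        assert rec.identity == pytest.approx(expected)

    def test_identity_invariant_to_match_mismatch_cigar_split(self, tmp_path):
        plain = write_sam(tmp_path, sam_line(cigar="150M", nm=3), "a.sam")
        split = write_sam(
            tmp_path, sam_line(cigar="50=1X40=2X57=", nm=3), "b.sam"
        )
        (rec_plain,) = parse_sam(plain)
        (rec_split,) = parse_sam(split)
        assert rec_plain.identity == rec_split.identity
        assert rec_plain.aln_length == rec_split.aln_length

    def test_indel_columns_count_toward_identity(self, tmp_path):
        # 95M + 5I + 50M = 150 aligned columns; NM counts the inserted bases
        path = write_sam(tmp_path, sam_line(cigar="95M5I50M", nm=5))
        (rec,) = parse_sam(path)
        assert rec.identity == pytest.approx(100 * 145 / 150)
        # the reference interval excludes insertion columns
        assert rec.ref_end - rec.ref_start == 145

    def test_secondary_supplementary_unmapped_skipped(self, tmp_path):
        body = (
            sam_line("keep")
            + sam_line("sec", flag=256)
            + sam_line("sup", flag=2048)
            + sam_line("unm", flag=4)
        )
        path = write_sam(tmp_path, body)
        assert [r.read_id for r in parse_sam(path)] == ["keep"]

    def test_missing_nm_warns_but_all_missing_fails(self, tmp_path):
        mixed = write_sam(
            tmp_path, sam_line("ok", nm=2) + sam_line("bad", nm=None), "mixed.sam"
        )
        with pytest.warns(UserWarning, match="NM tag"):
            records = parse_sam(mixed)
        assert [r.read_id for r in records] == ["ok"]
        hopeless = write_sam(tmp_path, sam_line("bad", nm=None), "none.sam")
        with pytest.raises(AlignmentParseError, match="NM"):
            parse_sam(hopeless)


class TestBestHit:
    def make(self, read, bitscore=100.0, identity=99.0, length=100):
        return AlignmentRecord(read_id=read, contig_id="c1", identity=identity,
                               aln_length=length, ref_start=0, ref_end=length,
                               bitscore=bitscore)

    def test_highest_bitscore_wins(self):
        records = [self.make("r1", 200), self.make("r1", 180)]
        assert best_hit_per_read(records) == [records[0]]

    def test_single_hit_unchanged(self):
        records = [self.make("r1")]
        assert best_hit_per_read(records) == records

    def test_tie_break_order_identity_then_length_then_first_seen(self):
        # four hits tied on bitscore: comparator must prefer identity, then
        # length, then first-seen, for every presentation order
        hits = [
            self.make("r1", 100, identity=99.0, length=120),
            self.make("r1", 100, identity=99.0, length=100),
            self.make("r1", 100, identity=97.0, length=300),
            self.make("r1", 100, identity=99.0, length=120),
        ]
        winner_key = (99.0, 120)
        for perm in itertools.permutations(hits):
            (best,) = best_hit_per_read(list(perm))
            assert (best.identity, best.aln_length) == winner_key
            # stability: first hit with the winning key is kept
            first = next(p for p in perm
                         if (p.identity, p.aln_length) == winner_key)
            assert best is first

    def test_output_size_equals_distinct_read_ids(self):
        records = [self.make(f"r{i % 7}", bitscore=i) for i in range(40)]
        assert len(best_hit_per_read(records)) == 7


class TestReferenceIndex:
    def test_lengths_and_total(self, tmp_path):
        fasta = tmp_path / "ref.fasta"
        fasta.write_text(">a\n" + "A" * 600 + "\n>b\n" + "C" * 400 + "\n")
        index = load_reference_index(fasta)
        assert index.contig_lengths == {"a": 600, "b": 400}
        assert index.total_length == 1000

    def test_duplicate_contig_and_empty_fasta_error(self, tmp_path):
        dup = tmp_path / "dup.fasta"
        dup.write_text(">a\nAAAA\n>a\nCCCC\n")
        with pytest.raises(AlignmentParseError, match="duplicate"):
            load_reference_index(dup)
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(AlignmentParseError, match="no sequences"):
            load_reference_index(empty)
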