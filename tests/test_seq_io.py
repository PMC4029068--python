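"""FASTQ/FASTA/SAM IO: parsing, validation, Phred handling, round trips."""

import gzip

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from srnapipe.aligner import Alignment
from srnapipe.seq_io import (FastaFormatError, FastqFormatError, Read,
                             ReferenceRecord, ReferenceSet, read_fasta,
                             read_fastq, revcomp, write_fasta, write_fastq,
                             write_sam)


def write_text(path, text):
    path.write_text(text)
    return path


class TestReadFastq:
    def test_phred33_decoding(self, tmp_path):
        p = write_text(tmp_path / "a.fastq", "@r1\nACGT\n+\nIIII\n")
        (read,) = read_fastq(p, encoding="phred33")
        assert read.read_id == "r1"
        assert read.bases == "ACGT"
        assert read.quals == (40, 40, 40, 40)
        assert not read.trimmed and read.original_length == 4

    def test_length_mismatch_names_record(self, tmp_path):
        p = write_text(tmp_path / "a.fastq",
                       "@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIII\n")
        with pytest.raises(FastqFormatError, match="record 2"):
            list(read_fastq(p, encoding="phred33"))

    @pytest.mark.parametrize("content, message", [
        ("r1\nACGT\n+\nIIII\n", "does not start with '@'"),
        ("@r1\nACGT\nIIII\nIIII\n", "'\\+' separator"),
        ("@r1\nACGT\n+\n", "truncated"),
    ])
    def test_malformed_records(self, tmp_path, content, message):
        p = write_text(tmp_path / "bad.fastq", content)
        with pytest.raises(FastqFormatError, match=message):
            list(read_fastq(p, encoding="phred33"))

    def test_gzip_by_suffix(self, tmp_path):
        p = tmp_path / "a.fastq.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("@r1\nACGTN\n+\n!!IJ@\n")
        (read,) = read_fastq(p, encoding="phred33")
        assert read.bases == "ACGTN"
        assert read.quals == (0, 0, 40, 41, 31)

    def test_auto_detects_phred33_on_low_chars(self, tmp_path):
        p = write_text(tmp_path / "a.fastq", "@r1\nACGT\n+\n!#IJ\n")
        (read,) = read_fastq(p, encoding="auto")
        assert read.quals == (0, 2, 40, 41)

    def test_auto_detects_phred64_from_char_range(self, tmp_path):
        # quality characters spanning [';'..'h'] can only be an offset-64
        # file; ';' is a Solexa-era score below zero, clamped at 0
        p = write_text(tmp_path / "a.fastq", "@r1\nACGT\n+\n;Khh\n")
        (read,) = read_fastq(p, encoding="auto")
        assert read.quals == (0, 11, 40, 40)

    def test_auto_detection_matches_char_range_oracle(self, tmp_path, rng):
        # oracle: brute-force min/max scan over all quality characters
        for trial in range(30):
            offset = 33 if rng.random() < 0.5 else 64
            lo = 0 if offset == 33 else -5
            records = []
            for i in range(int(rng.integers(1, 5))):
                quals = rng.integers(lo, 41, size=8)
                chars = "".join(chr(int(q) + offset) for q in quals)
                records.append(f"@r{i}\n{'A' * 8}\n+\n{chars}\n")
            p = write_text(tmp_path / f"t{trial}.fastq", "".join(records))
            allchars = "".join(r.splitlines()[3] for r in records)
            if min(allchars) < ";":
                expected = "phred33"
            elif max(allchars) >= "K":
                expected = "phred64"
            else:
                expected = None  # ambiguous
            if expected is None:
                with pytest.raises(FastqFormatError, match="consistent with both"):
                    list(read_fastq(p, encoding="auto"))
            else:
                got = list(read_fastq(p, encoding="auto"))
                want = list(read_fastq(p, encoding=expected))
                assert [r.quals for r in got] == [r.quals for r in want]

    def test_ambiguous_range_asks_for_explicit_encoding(self, tmp_path):
        p = write_text(tmp_path / "a.fastq", "@r1\nACGT\n+\n;<=J\n")
        with pytest.raises(FastqFormatError, match="explicit encoding"):
            list(read_fastq(p, encoding="auto"))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.text(alphabet="ACGTN", min_size=1, max_size=40),
                  st.data()),
        min_size=1, max_size=5))
    def test_fastq_round_trip(self, tmp_path_factory, records):
        reads = []
        for i, (bases, data) in enumerate(records):
            quals = tuple(
                data.draw(st.integers(0, 62)) for _ in bases)
            reads.append(Read(f"r{i}", bases, quals))
        p = tmp_path_factory.mktemp("rt") / "x.fastq"
        write_fastq(reads, p, encoding="phred33")
        back = list(read_fastq(p, encoding="phred33"))
        assert [(r.read_id, r.bases, r.quals) for r in back] == \
            [(r.read_id, r.bases, r.quals) for r in reads]

    def test_phred_conversion_is_a_bijection(self, tmp_path):
        for offset, encoding in ((33, "phred33"), (64, "phred64")):
            quals = tuple(range(63))
            p = tmp_path / f"{encoding}.fastq"
            write_fastq([Read("r", "A" * 63, quals)], p, encoding=encoding)
            (back,) = read_fastq(p, encoding=encoding)
            assert back.quals == quals


class TestReadInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="quality scores"):
            Read("r", "ACGT", (1, 2, 3))

    def test_rejects_out_of_range_phred(self):
        with pytest.raises(ValueError, match="\\[0, 62\\]"):
            Read("r", "AC", (0, 63))

    def test_rejects_invalid_bases(self):
        with pytest.raises(ValueError, match="invalid bases"):
            Read("r", "ACXT", (1, 2, 3, 4))


class TestFasta:
    def test_basic_records(self, tmp_path):
        p = write_text(tmp_path / "r.fasta", ">a\nACGT\n>b\nGG\n")
        refs = read_fasta(p)
        assert [(r.ref_id, r.seq) for r in refs] == [("a", "ACGT"), ("b", "GG")]

    def test_line_wrapped_sequence(self, tmp_path):
        p = write_text(tmp_path / "r.fasta", ">a\nAC\nGT\n")
        assert read_fasta(p)["a"].seq == "ACGT"

    def test_header_token_up_to_whitespace(self, tmp_path):
        p = write_text(tmp_path / "r.fasta", ">a some description\nACGT\n")
        assert read_fasta(p).ids() == ["a"]

    def test_duplicate_id_aborts(self, tmp_path):
        p = write_text(tmp_path / "r.fasta", ">a x\nAC\n>a y\nGG\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_sequence_aborts(self, tmp_path):
        p = write_text(tmp_path / "r.fasta", ">a\n>b\nGG\n")
        with pytest.raises(FastaFormatError, match="empty"):
            read_fasta(p)

    def test_n_bases_illegal_in_references(self):
        with pytest.raises(FastaFormatError, match="invalid bases"):
            ReferenceRecord("a", "ACGNT")

    def test_round_trip(self, tmp_path, random_refs):
        p = tmp_path / "refs.fasta"
        write_fasta(random_refs, p)
        back = read_fasta(p)
        assert [(r.ref_id, r.seq) for r in back] == \
            [(r.ref_id, r.seq) for r in random_refs]


class TestWriteSam:
    REFS = ReferenceSet([("a", "ACGTACGTAC"), ("b", "GGGGCCCC")])

    def test_forward_alignment_fields(self, tmp_path, mk_read):
        p = tmp_path / "x.sam"
        read = mk_read("r1", "ACGT")
        write_sam([Alignment("r1", "a", 0, "+", 0)], self.REFS, p,
                  reads={"r1": read})
        line = [l for l in p.read_text().splitlines() if not l.startswith("@")][0]
        fields = line.split("\t")
        assert fields[0:6] == ["r1", "0", "a", "1", "255", "4M"]
        assert fields[9] == "ACGT"
        assert "NM:i:0" in fields

    def test_reverse_strand_flag_and_revcomp_seq(self, tmp_path, mk_read):
        p = tmp_path / "x.sam"
        read = mk_read("r1", "ACGT")
        write_sam([Alignment("r1", "a", 5, "-", 1)], self.REFS, p,
                  reads={"r1": read})
        fields = [l for l in p.read_text().splitlines()
                  if not l.startswith("@")][0].split("\t")
        assert fields[1] == "16"
        assert fields[3] == "6"  # 0-based offset 5 -> 1-based POS 6
        assert fields[9] == revcomp("ACGT")
        assert "NM:i:1" in fields

    def test_empty_stream_is_header_only(self, tmp_path):
        p = tmp_path / "x.sam"
        write_sam([], self.REFS, p)
        lines = p.read_text().splitlines()
        assert all(l.startswith("@") for l in lines)
        assert sum(l.startswith("@SQ") for l in lines) == 2

    def test_unknown_ref_aborts(self, tmp_path):
        with pytest.raises(KeyError, match="nope"):
            write_sam([Alignment("r1", "nope", 0, "+", 0)], self.REFS,
                      tmp_path / "x.sam")

    def test_output_is_valid_sam_for_pysam(self, tmp_path, mk_read):
        # independent parser check on headers, coordinates and the NM tag
        p = tmp_path / "x.sam"
        reads = {"r1": mk_read("r1", "ACGTAC"), "r2": mk_read("r2", "GGGG")}
        write_sam([Alignment("r1", "a", 2, "+", 1),
                   Alignment("r2", "b", 0, "-", 0)], self.REFS, p, reads=reads)
        with pysam.AlignmentFile(str(p), "r") as sam:
            recs = list(sam.fetch(until_eof=True))
        assert [(r.query_name, r.reference_name, r.reference_start,
                 r.is_reverse, r.get_tag("NM")) for r in recs] == \
            [("r1", "a", 2, False, 1), ("r2", "b", 0, True, 0)]
        assert recs[1].query_sequence == revcomp("GGGG")
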