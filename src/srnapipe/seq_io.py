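"""Sequence file IO: FASTQ, FASTA and minimal SAM.

FASTQ records are strict 4-line records; gzip input/output is selected by a
``.gz`` suffix.  Quality strings may be Phred+33 or Phred+64 encoded; with
``encoding="auto"`` the offset is inferred from the observed quality
characters before any record is emitted (the file is scanned once up front).
Solexa-era Phred+64 scores below zero are clamped to 0 on decode.

Internal coordinates are 0-based half-open everywhere; the SAM writer is the
single place that converts to 1-based POS.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "ReferenceRecord",
    "ReferenceSet",
    "FastqFormatError",
    "FastaFormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_sam",
    "revcomp",
]

_READ_ALPHABET = frozenset("ACGTN")
_REF_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Malformed FASTQ input; the message names the offending record."""


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate id, empty sequence, bad alphabet)."""


@dataclass
class Read:
    """One sequencing read with per-base Phred scores and trimming state.

    ``original_length`` is the read length before any trimming; it never
    shrinks when the read is truncated.
    """

    read_id: str
    bases: str
    quals: tuple[int, ...]
    trimmed: bool = False
    original_length: int = -1

    def __post_init__(self) -> None:
        self.quals = tuple(self.quals)
        if self.original_length < 0:
            self.original_length = len(self.bases)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 or q > 62 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred score outside [0, 62]")
        if self.original_length < len(self.bases):
            raise ValueError(f"read {self.read_id!r}: original_length < current length")
        bad = set(self.bases) - _READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence (e.g. a mature miRNA or a genome slice)."""

    ref_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaFormatError(f"reference {self.ref_id!r} has an empty sequence")
        bad = set(self.seq) - _REF_ALPHABET
        if bad:
            raise FastaFormatError(
                f"reference {self.ref_id!r}: invalid bases {sorted(bad)} "
                "(references must be over {A,C,G,T})"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class ReferenceSet:
    """Ordered collection of uniquely named reference records."""

    def __init__(self, records: Iterable[ReferenceRecord | tuple[str, str]]):
        self.records: list[ReferenceRecord] = []
        self._by_id: dict[str, int] = {}
        for rec in records:
            if not isinstance(rec, ReferenceRecord):
                rec = ReferenceRecord(*rec)
            if rec.ref_id in self._by_id:
                raise FastaFormatError(f"duplicate reference id {rec.ref_id!r}")
            self._by_id[rec.ref_id] = len(self.records)
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> ReferenceRecord:
        if isinstance(key, str):
            return self.records[self._by_id[key]]
        return self.records[key]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def index_of(self, ref_id: str) -> int:
        return self._by_id[ref_id]

    def ids(self) -> list[str]:
        return [r.ref_id for r in self.records]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _detect_encoding(path: str | Path) -> str:
    """Infer the Phred ASCII offset from the observed quality characters.

    Any character below ';' (ASCII 59) is impossible under Phred+64, so the
    file must be Phred+33.  Otherwise a maximum character at or above 'K'
    (ASCII 75, Phred+33 score 42) indicates Phred+64.  Files whose quality
    characters all fall in [';'..'J'] are consistent with both offsets and
    are rejected rather than silently misinterpreted.
    """
    lo, hi = None, None
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 3:
                qline = line.rstrip("\n")
                if qline:
                    a, b = min(qline), max(qline)
                    lo = a if lo is None or a < lo else lo
                    hi = b if hi is None or b > hi else hi
    if lo is None:
        raise FastqFormatError(f"{path}: no quality lines found for auto-detection")
    if lo < ";":
        return "phred33"
    if hi >= "K":
        return "phred64"
    raise FastqFormatError(
        f"{path}: quality characters all in [{lo!r}..{hi!r}] are consistent with "
        "both Phred+33 and Phred+64; pass an explicit encoding"
    )


def _decode_quals(qline: str, offset: int) -> tuple[int, ...]:
    # Phred+64 inputs may carry Solexa scores down to -5; clamp at 0.
    return tuple(max(0, ord(c) - offset) for c in qline)


def read_fastq(path: str | Path, encoding: str = "auto") -> Iterator[Read]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Malformed records abort with the 1-based record number.  ``encoding``
    is one of ``auto``, ``phred33``, ``phred64``.
    """
    if encoding not in ("auto", "phred33", "phred64"):
        raise ValueError(f"unknown quality encoding {encoding!r}")
    if encoding == "auto":
        encoding = _detect_encoding(path)
    offset = 33 if encoding == "phred33" else 64

    with _open_text(path) as fh:
        recno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            recno += 1
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if "" in lines[1:]:
                raise FastqFormatError(f"{path}: record {recno} is truncated")
            header, bases, plus, quals = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {recno} does not start with '@'"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {recno} is missing the '+' separator"
                )
            bases = bases.upper()
            if len(bases) != len(quals):
                raise FastqFormatError(
                    f"{path}: record {recno}: {len(bases)} bases vs "
                    f"{len(quals)} quality characters"
                )
            try:
                yield Read(header[1:].split()[0] if len(header) > 1 else "",
                           bases, _decode_quals(quals, offset))
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {recno}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path,
                encoding: str = "phred33") -> None:
    """Write reads as 4-line FASTQ (gzip by '.gz' suffix)."""
    offset = {"phred33": 33, "phred64": 64}[encoding]
    with _open_text(path, "wt") as fh:
        for read in reads:
            qline = "".join(chr(q + offset) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qline}\n")


def read_fasta(path: str | Path) -> ReferenceSet:
    """Load an ordered ReferenceSet from FASTA.

    The header token up to the first whitespace becomes the reference id;
    duplicate ids, empty sequences and non-ACGT characters abort.
    """
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(ReferenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return ReferenceSet(records)


def write_fasta(refs: ReferenceSet, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(r.seq), id=r.ref_id, description="") for r in refs),
            fh, "fasta",
        )


def write_sam(alignments, refs: ReferenceSet, path: str | Path,
              reads: Mapping[str, Read] | None = None) -> None:
    """Write reported alignments as minimal SAM v1.

    Emits @HD/@SQ headers plus the 11 mandatory fields and the NM tag.
    POS is 1-based; reverse-strand alignments carry flag 16 with
    reverse-complemented SEQ and reversed QUAL.  ``reads`` maps read_id to
    the Read providing SEQ/QUAL; without it both are written as '*'.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in refs:
            fh.write(f"@SQ\tSN:{rec.ref_id}\tLN:{rec.length}\n")
        for aln in alignments:
            if aln.ref_id not in refs:
                raise KeyError(f"alignment references unknown id {aln.ref_id!r}")
            flag = 16 if aln.strand == "-" else 0
            seq, qual = "*", "*"
            length = None
            if reads is not None and aln.read_id in reads:
                read = reads[aln.read_id]
                length = len(read)
                if aln.strand == "-":
                    seq = revcomp(read.bases)
                    qual = "".join(chr(q + 33) for q in reversed(read.quals))
                else:
                    seq = read.bases
                    qual = "".join(chr(q + 33) for q in read.quals)
            cigar = f"{length}M" if length else "*"
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.offset + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{aln.mismatches}\n"
            )
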