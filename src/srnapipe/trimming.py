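"""3' adapter trimming for small-RNA reads.

Small-RNA inserts (mature miRNAs are ~21-23 nt) are shorter than the read
length, so every informative read runs into the 3' sequencing adapter.  The
trimmer scans each read left to right for the first position ``p`` at which
the adapter prefix matches the read suffix with at most
``floor(max_error_rate × overlap)`` substitutions, requiring an overlap of
at least ``min_overlap`` bases (a full internal adapter occurrence always
qualifies).  The retained insert ``read[:p]`` is then length-filtered to
the plausible small-RNA window ``[min_len, max_len]``.

Substitution-only matching (no indels) keeps the scorer exact and mirrors
mismatch-count (-v style) alignment downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .seq_io import Read

__all__ = ["TrimPolicy", "TrimOutcome", "TrimStats", "trim_read", "trim_sample"]

STATUSES = ("trimmed", "untrimmed", "too_short", "too_long")


@dataclass(frozen=True)
class TrimPolicy:
    """Adapter sequence plus matching and length-filter parameters.

    Defaults reflect common small-RNA practice: Illumina TruSeq small-RNA
    3' adapter, >=5 nt overlap, 10% mismatch tolerance, inserts kept when
    16-28 nt (bracketing the 21-23 nt mature-miRNA range).
    """

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    max_error_rate: float = 0.1
    min_len: int = 16
    max_len: int = 28

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class TrimOutcome:
    """Per-read trimming result.

    ``read`` is the truncated insert when status is ``trimmed`` and the
    untouched input read otherwise (kept for audit).  ``trim_pos`` is the
    0-based position where the adapter starts, or None if no qualifying
    match was found.
    """

    read: Read
    status: str
    trim_pos: int | None = None


def _find_adapter(bases: str, policy: TrimPolicy) -> int | None:
    """Leftmost position whose adapter-prefix overlap qualifies, else None."""
    adapter = policy.adapter
    L = len(bases)
    for p in range(0, L - policy.min_overlap + 1):
        overlap = min(len(adapter), L - p)
        allowed = int(policy.max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(bases[p : p + overlap], adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return p
    return None


def trim_read(read: Read, policy: TrimPolicy) -> TrimOutcome:
    """Trim the 3' adapter off one read and length-filter the insert."""
    p = _find_adapter(read.bases, policy)
    if p is None:
        return TrimOutcome(read, "untrimmed")
    if p < policy.min_len:
        return TrimOutcome(read, "too_short", trim_pos=p)
    if p > policy.max_len:
        return TrimOutcome(read, "too_long", trim_pos=p)
    insert = Read(read.read_id, read.bases[:p], read.quals[:p],
                  trimmed=True, original_length=read.original_length)
    return TrimOutcome(insert, "trimmed", trim_pos=p)


@dataclass
class TrimStats:
    counts: Counter = field(default_factory=Counter)
    insert_lengths: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["metric\tkey\tvalue"]
        for status in STATUSES:
            lines.append(f"status\t{status}\t{self.counts.get(status, 0)}")
        for length in sorted(self.insert_lengths):
            lines.append(f"insert_length\t{length}\t{self.insert_lengths[length]}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def trim_sample(reads: Iterable[Read], policy: TrimPolicy,
                keep_untrimmed: bool = False) -> tuple[list[Read], TrimStats]:
    """Trim a read stream; return retained inserts and per-status stats.

    Retained reads are the trimmed inserts plus, when ``keep_untrimmed`` is
    set, untrimmed reads whose full length already falls inside
    ``[min_len, max_len]``.  The length histogram covers retained reads.
    """
    stats = TrimStats()
    retained: list[Read] = []
    for read in reads:
        outcome = trim_read(read, policy)
        stats.counts[outcome.status] += 1
        keep = outcome.status == "trimmed" or (
            keep_untrimmed
            and outcome.status == "untrimmed"
            and policy.min_len <= len(outcome.read) <= policy.max_len
        )
        if keep:
            retained.append(outcome.read)
            stats.insert_lengths[len(outcome.read)] += 1
    return retained, stats
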