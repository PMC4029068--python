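"""Ungapped short-read alignment with explicit reporting semantics.

The aligner reproduces Bowtie1's -v-mode reporting contract: a placement is
reportable when it has at most ``v`` substitutions (no gaps); with
``best_strata`` only the minimal-mismatch stratum is kept; and a read whose
kept placements exceed the multi-map threshold ``m`` is *suppressed* —
reported nowhere rather than reported partially.  These semantics are what
make identical-sequence miRNAs (e.g. miR-519c-5p / miR-523-5p) disappear
under ``m=1`` and what the fractional read counter later compensates for.

Candidate generation uses a pigeonhole seed index: the read is split into
``v+1`` contiguous partitions, so any placement with <= v mismatches matches
at least one partition exactly; that partition's leading k-mer is looked up
in an exact-substring index over the reference sequences.  References
shorter than the seed length — or reads too short to give every partition a
full seed — fall back to full enumeration, which is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .seq_io import Read, ReferenceSet, revcomp

__all__ = [
    "AlignmentPolicy",
    "Alignment",
    "AlignResult",
    "MismatchIndex",
    "build_index",
    "align_read",
    "align_sample",
]

DEFAULT_SEED_LENGTH = 8


@dataclass(frozen=True)
class AlignmentPolicy:
    """Reporting parameters: -v, -m, best-stratum flag and strand mode.

    ``m=None`` means unlimited (never suppress).  ``strand_mode`` is
    ``both`` or ``forward_only`` (the --norc analogue).
    """

    v: int = 0
    m: int | None = 1
    best_strata: bool = True
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if not 0 <= self.v <= 3:
            raise ValueError("v must be in [0, 3]")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1 or None (unlimited)")
        if self.strand_mode not in ("both", "forward_only"):
            raise ValueError("strand_mode must be 'both' or 'forward_only'")


@dataclass(frozen=True)
class Alignment:
    """One reported placement of a read on a reference (0-based offset)."""

    read_id: str
    ref_id: str
    offset: int
    strand: str  # '+' or '-'
    mismatches: int
    round: int = 1


@dataclass
class AlignResult:
    """Outcome for one read: aligned (with placements), unaligned, or
    suppressed (had reportable placements, but more than m of them)."""

    read_id: str
    status: str  # {aligned, unaligned, suppressed}
    alignments: list[Alignment] = field(default_factory=list)


class MismatchIndex:
    """Exact k-mer index over a ReferenceSet for pigeonhole candidate lookup.

    ``kmers`` maps each seed-length substring of every reference to its
    (reference index, offset) occurrences.  References shorter than the
    seed length are kept aside and always scanned by full enumeration.
    """

    def __init__(self, refs: ReferenceSet, max_v: int = 3,
                 seed_length: int = DEFAULT_SEED_LENGTH):
        self.refs = refs
        self.max_v = max_v
        self.seed_length = seed_length
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        self.short_ref_indices: list[int] = []
        for ri, rec in enumerate(refs):
            if rec.length < seed_length:
                self.short_ref_indices.append(ri)
                continue
            seq = rec.seq
            for off in range(rec.length - seed_length + 1):
                self.kmers.setdefault(seq[off : off + seed_length], []).append((ri, off))

    def candidates(self, query: str, v: int) -> set[tuple[int, int]]:
        """Candidate (ref index, offset) placements for an ungapped query.

        Complete for every placement with <= v mismatches: either the
        pigeonhole seeds cover it, or the query/reference falls back to
        full enumeration.
        """
        L = len(query)
        cands: set[tuple[int, int]] = set()
        parts = v + 1
        bounds = [i * L // parts for i in range(parts + 1)]
        chunk_ok = all(bounds[i + 1] - bounds[i] >= self.seed_length
                       for i in range(parts))
        if chunk_ok:
            for i in range(parts):
                start = bounds[i]
                seed = query[start : start + self.seed_length]
                for ri, roff in self.kmers.get(seed, ()):
                    off = roff - start
                    if 0 <= off <= self.refs[ri].length - L:
                        cands.add((ri, off))
            ref_indices: Iterable[int] = self.short_ref_indices
        else:
            ref_indices = range(len(self.refs))
        for ri in ref_indices:
            for off in range(self.refs[ri].length - L + 1):
                cands.add((ri, off))
        return cands


def build_index(refs: ReferenceSet, v: int = 3,
                seed_length: int = DEFAULT_SEED_LENGTH) -> MismatchIndex:
    """Build the pigeonhole seed index supporting alignment up to v mismatches."""
    return MismatchIndex(refs, max_v=v, seed_length=seed_length)


def count_mismatches(query: str, ref: str, offset: int, limit: int) -> int:
    """Substitutions between query and ref[offset:offset+len(query)].

    Stops early past ``limit``.  'N' in the query never matches (references
    are N-free by construction), so it falls out of plain inequality.
    """
    mismatches = 0
    for a, b in zip(query, ref[offset : offset + len(query)]):
        if a != b:
            mismatches += 1
            if mismatches > limit:
                break
    return mismatches


def align_read(read: Read, index: MismatchIndex, policy: AlignmentPolicy,
               round: int = 1) -> AlignResult:
    """Align one read under the policy; returns aligned/unaligned/suppressed.

    Enumerates every ungapped placement on every reference (reverse strand =
    reverse complement of the read against the forward reference) with
    <= v mismatches; applies best-stratum filtering then the m threshold.
    Reported placements are sorted by (reference input order, offset,
    strand) with '+' before '-'.
    """
    if policy.v > index.max_v:
        raise ValueError(f"index was built for v <= {index.max_v}")
    queries = [(read.bases, "+")]
    if policy.strand_mode == "both":
        queries.append((revcomp(read.bases), "-"))

    kept: list[tuple[int, int, str, int]] = []
    for query, strand in queries:
        for ri, off in index.candidates(query, policy.v):
            mm = count_mismatches(query, index.refs[ri].seq, off, policy.v)
            if mm <= policy.v:
                kept.append((ri, off, strand, mm))

    if not kept:
        return AlignResult(read.read_id, "unaligned")
    if policy.best_strata:
        best = min(mm for *_, mm in kept)
        kept = [p for p in kept if p[3] == best]
    if policy.m is not None and len(kept) > policy.m:
        return AlignResult(read.read_id, "suppressed")
    kept.sort(key=lambda p: (p[0], p[1], p[2] != "+"))
    alignments = [
        Alignment(read.read_id, index.refs[ri].ref_id, off, strand, mm, round)
        for ri, off, strand, mm in kept
    ]
    return AlignResult(read.read_id, "aligned", alignments)


def align_sample(reads: Iterable[Read], refs: ReferenceSet,
                 policy: AlignmentPolicy, round: int = 1,
                 seed_length: int = DEFAULT_SEED_LENGTH) -> list[AlignResult]:
    """Align a read stream against one reference set, preserving input order."""
    index = build_index(refs, v=policy.v, seed_length=seed_length)
    return [align_read(read, index, policy, round=round) for read in reads]
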