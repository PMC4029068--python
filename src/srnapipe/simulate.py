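"""Deterministic synthetic small-RNA library generator with ground truth.

Emulates a single-end small-RNA sequencing library: each read is a mature
miRNA insert drawn from an abundance vector, with iid substitution errors,
the 3' adapter appended, and random filler bases out to the fixed read
length (36 cycles by default).  Per-cycle Phred scores are Gaussian.  All
randomness flows through one seeded numpy Generator, so a given
configuration is byte-reproducible, and every draw is recorded in a
:class:`GroundTruth` that tests reconcile against the emitted files.

What it deliberately does not emulate: position-dependent Illumina error
profiles, indels, adapter dimers, and quality/error correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np

from .samples import Sample, SampleSheet
from .seq_io import Read, ReferenceRecord, ReferenceSet, write_fasta, write_fastq

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedLibrary",
    "simulate_library",
    "simulate_dataset",
    "make_homolog_pair",
]

_BASES = np.array(list("ACGT"))

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Defaults: 20 mature-miRNA-length references (20-23 nt), Dirichlet(1)
    abundances, 50,000 reads, 1% per-base substitution rate, TruSeq
    small-RNA adapter, 36-cycle reads, per-cycle Phred ~ N(34, 3) clamped
    to [2, 40].
    """

    seed: int = 0
    n_refs: int = 20
    ref_len_range: tuple[int, int] = (20, 23)
    n_reads: int = 50_000
    abundance: tuple[float, ...] | None = None  # explicit vector, else Dirichlet
    dirichlet_concentration: float = 1.0
    sub_error_rate: float = 0.01
    adapter: str = DEFAULT_ADAPTER
    read_len: int = 36
    qual_mean: float = 34.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_refs < 1 or self.n_reads < 1:
            raise ValueError("n_refs and n_reads must be >= 1")
        if not 0.0 <= self.sub_error_rate <= 1.0:
            raise ValueError("sub_error_rate must be in [0, 1]")
        if self.abundance is not None:
            if len(self.abundance) != self.n_refs:
                raise ValueError("abundance length must equal n_refs")
            if any(a < 0 for a in self.abundance):
                raise ValueError("abundance entries must be >= 0")


@dataclass
class GroundTruth:
    """Per-read provenance and per-feature totals for a simulated library."""

    source_ref: list[str]            # per read
    insert_seq: list[str]            # per read, after error injection
    insert_len: list[int]            # per read
    error_positions: list[tuple[int, ...]]  # per read, 0-based insert positions
    true_counts: Counter = field(default_factory=Counter)  # ref_id -> reads
    abundance: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_index\tsource_ref\tinsert_len\terror_positions\tinsert_seq\n")
            for i, (ref, seq, length, errs) in enumerate(
                zip(self.source_ref, self.insert_seq, self.insert_len,
                    self.error_positions)
            ):
                pos = ",".join(map(str, errs)) if errs else "-"
                fh.write(f"{i}\t{ref}\t{length}\t{pos}\t{seq}\n")


@dataclass
class SimulatedLibrary:
    reads: list[Read]
    refs: ReferenceSet
    truth: GroundTruth
    config: SimulationConfig


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_refs(rng: np.random.Generator, config: SimulationConfig) -> ReferenceSet:
    lo, hi = config.ref_len_range
    records = []
    for i in range(config.n_refs):
        length = int(rng.integers(lo, hi + 1))
        records.append(ReferenceRecord(f"mir-{i + 1:03d}", _random_seq(rng, length)))
    return ReferenceSet(records)


def simulate_library(config: SimulationConfig,
                     refs: ReferenceSet | None = None) -> SimulatedLibrary:
    """Generate one library: reads, references and recorded ground truth.

    A caller-supplied ReferenceSet (e.g. the homolog pair) overrides the
    random references; abundances then cover its records.
    """
    rng = np.random.default_rng(config.seed)
    if refs is None:
        refs = _random_refs(rng, config)
    n_refs = len(refs)

    if config.abundance is not None:
        p = np.asarray(config.abundance, dtype=float)
    else:
        p = rng.dirichlet([config.dirichlet_concentration] * n_refs)
    p = p / p.sum()

    truth = GroundTruth([], [], [], [],
                        abundance={r.ref_id: float(pi) for r, pi in zip(refs, p)})
    sources = rng.choice(n_refs, size=config.n_reads, p=p)
    reads: list[Read] = []
    for i, src in enumerate(sources):
        rec = refs[int(src)]
        insert = list(rec.seq)
        errs = np.flatnonzero(rng.random(len(insert)) < config.sub_error_rate)
        for pos in errs:
            alternatives = [b for b in "ACGT" if b != insert[pos]]
            insert[pos] = alternatives[int(rng.integers(3))]
        insert_seq = "".join(insert)

        full = insert_seq + config.adapter
        if len(full) < config.read_len:
            full += _random_seq(rng, config.read_len - len(full))
        bases = full[: config.read_len]
        quals = np.clip(
            np.rint(rng.normal(config.qual_mean, config.qual_sd, config.read_len)),
            2, 40,
        ).astype(int)
        reads.append(Read(f"sim_{i}", bases, tuple(int(q) for q in quals)))

        truth.source_ref.append(rec.ref_id)
        truth.insert_seq.append(insert_seq)
        truth.insert_len.append(len(insert_seq))
        truth.error_positions.append(tuple(int(e) for e in errs))
        truth.true_counts[rec.ref_id] += 1
    return SimulatedLibrary(reads, refs, truth, config)


def simulate_dataset(outdir: str | Path, config: SimulationConfig,
                     n_samples: int = 4,
                     traits: Sequence[str] = ("tumor", "normal")
                     ) -> tuple[SampleSheet, Path, dict[str, GroundTruth]]:
    """Write a multi-sample dataset: FASTQs, shared reference FASTA, sheet.

    Samples share one reference set (drawn from the base seed) but get
    independent reads via per-sample sub-seeds; the sheet alternates trait
    labels across samples.  Returns (sheet, reference FASTA path, per-sample
    ground truth).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw_dir = outdir / "raw"
    raw_dir.mkdir(exist_ok=True)

    base = simulate_library(replace(config, n_reads=1))  # fixes the references
    refs = base.refs
    ref_path = outdir / "mature.fasta"
    write_fasta(refs, ref_path)

    samples: list[Sample] = []
    truths: dict[str, GroundTruth] = {}
    rows = ["sample_id\tfile\tgroup"]
    for s in range(n_samples):
        sub = replace(config, seed=(config.seed * 1000 + s + 1) % (2**31))
        lib = simulate_library(sub, refs=refs)
        sid = f"sample{s + 1:02d}"
        fq = raw_dir / f"{sid}.fastq"
        write_fastq(lib.reads, fq)
        lib.truth.to_tsv(outdir / f"{sid}.truth.tsv")
        trait = traits[s % len(traits)]
        samples.append(Sample(sid, [fq], {"group": trait}))
        truths[sid] = lib.truth
        # file column holds the name only; loaders resolve it against raw_dir
        rows.append(f"{sid}\t{fq.name}\t{trait}")
    sheet = SampleSheet(samples, mode="program")
    (outdir / "samples.tsv").write_text("\n".join(rows) + "\n")
    return sheet, ref_path, truths


def make_homolog_pair() -> ReferenceSet:
    """Two distinct miRNA ids sharing one identical 22-nt sequence.

    Canonical input for the identical-sequence multi-mapping case
    (miR-519c-5p vs miR-523-5p): under m=1 an exact read is suppressed,
    under fractional counting with unlimited m it is split 0.5/0.5.
    The sequence itself is synthetic.
    """
    seq = "CTCTAGAGGGAAGCGCTTTCTG"
    return ReferenceSet([
        ReferenceRecord("hsa-miR-519c-5p", seq),
        ReferenceRecord("hsa-miR-523-5p", seq),
    ])
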