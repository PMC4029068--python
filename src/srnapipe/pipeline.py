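"""End-to-end miRNA identification runs: trim → cascade → count → QC.

A run is described by a :class:`RunConfig`, persisted as a ``variables.txt``
key=value file in the result directory so any run can be replayed exactly
from its own output folder.

Execution is parallel at sample granularity: samples are packed into worker
bins by total raw-data size (LPT) and each bin runs in its own process with
no shared mutable state, so outputs are bitwise identical for any worker
count.  Every step caches its outputs under a content hash of its inputs
and parameters; a refreshed run with, say, only the counting policy changed
re-derives counts from the cached per-stage SAM files and leaves alignment
outputs untouched.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import pysam

from . import qc
from .aligner import AlignmentPolicy
from .cascade import CascadePlan, CascadeStage, run_cascade, stage_summary
from .counting import Feature, assemble_matrix, count_sample
from .samples import SampleSheet, autodetect_samples, load_sample_sheet, partition_by_size
from .seq_io import Read, read_fasta, read_fastq, write_fastq, write_sam
from .trimming import TrimPolicy, trim_read, trim_sample

__all__ = ["StageSpec", "RunConfig", "selftest", "run_mirna",
           "write_variables", "load_variables"]


@dataclass(frozen=True)
class StageSpec:
    """One cascade stage as configured: a name, a FASTA path and a policy."""

    name: str
    fasta: str
    v: int = 0
    m: int | None = 1
    best_strata: bool = True
    strand_mode: str = "both"

    def policy(self) -> AlignmentPolicy:
        return AlignmentPolicy(self.v, self.m, self.best_strata, self.strand_mode)


@dataclass
class RunConfig:
    raw_dir: str
    result_dir: str
    stages: list[StageSpec]
    sheet: str | None = None          # program mode; None -> auto mode
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    max_error_rate: float = 0.1
    min_len: int = 16
    max_len: int = 28
    keep_untrimmed: bool = False
    encoding: str = "auto"
    cascade_mode: str = "iterative"
    suppressed_continue: bool = False
    count_policy: str = "fractional"
    workers: int = 1

    def trim_policy(self) -> TrimPolicy:
        return TrimPolicy(self.adapter, self.min_overlap, self.max_error_rate,
                          self.min_len, self.max_len)

    def load_sheet(self) -> SampleSheet:
        if self.sheet:
            return load_sample_sheet(self.sheet, self.raw_dir)
        return autodetect_samples(self.raw_dir)

    def load_plan(self) -> CascadePlan:
        stages = [CascadeStage(s.name, read_fasta(s.fasta), s.policy())
                  for s in self.stages]
        return CascadePlan(stages, mode=self.cascade_mode,
                           suppressed_continue=self.suppressed_continue)


# ---------------------------------------------------------------- variables.txt

def write_variables(config: RunConfig, path: str | Path) -> None:
    """Persist the run configuration as key=value lines."""
    items = asdict(config)
    stages = items.pop("stages")
    lines = []
    for key, value in items.items():
        lines.append(f"{key}={'' if value is None else value}")
    stage_specs = []
    for s in stages:
        m = "inf" if s["m"] is None else s["m"]
        stage_specs.append(
            f"{s['name']}:{s['fasta']}:{s['v']}:{m}:{int(s['best_strata'])}:{s['strand_mode']}"
        )
    lines.append("stages=" + ";".join(stage_specs))
    Path(path).write_text("\n".join(lines) + "\n")


def load_variables(path: str | Path) -> RunConfig:
    """Rebuild a RunConfig from a variables.txt file."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    stages = []
    for spec in raw.pop("stages", "").split(";"):
        if not spec:
            continue
        name, fasta, v, m, best, strand = spec.split(":")
        stages.append(StageSpec(name, fasta, int(v),
                                None if m == "inf" else int(m),
                                bool(int(best)), strand))
    bools = {"keep_untrimmed", "suppressed_continue"}
    ints = {"min_overlap", "min_len", "max_len", "workers"}
    floats = {"max_error_rate"}
    kwargs: dict = {"stages": stages}
    for key, value in raw.items():
        if key == "sheet":
            kwargs[key] = value or None
        elif key in bools:
            kwargs[key] = value == "True"
        elif key in ints:
            kwargs[key] = int(value)
        elif key in floats:
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------- selftest

def selftest(config: RunConfig) -> list[dict]:
    """Pre-flight checks; every check runs and reports pass/fail."""
    report: list[dict] = []

    def check(name: str, fn) -> None:
        try:
            detail = fn()
            report.append({"check": name, "ok": True, "detail": detail or ""})
        except Exception as exc:  # report, never raise
            report.append({"check": name, "ok": False, "detail": str(exc)})

    def _raw_dir():
        if not Path(config.raw_dir).is_dir():
            raise FileNotFoundError(f"raw_dir not found: {config.raw_dir}")

    def _result_dir():
        p = Path(config.result_dir)
        p.mkdir(parents=True, exist_ok=True)
        probe = p / ".write_probe"
        probe.write_text("")
        probe.unlink()

    def _sheet():
        sheet = config.load_sheet()
        return f"{len(sheet.samples)} samples"

    def _plotting():
        import matplotlib  # noqa: F401

    check("raw_dir", _raw_dir)
    check("result_dir", _result_dir)
    check("sample_sheet", _sheet)
    for s in config.stages:
        check(f"reference:{s.name}",
              lambda s=s: f"{len(read_fasta(s.fasta))} records in {s.fasta}")
    check("plotting_backend", _plotting)
    return report


# ---------------------------------------------------------------- caching

def _sha(*parts: str) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode())
        h.update(b"\0")
    return h.hexdigest()


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _step_hashes(files: list[Path], config: RunConfig) -> dict[str, str]:
    h_files = _sha(*sorted(_file_digest(f) for f in files))
    trim = config.trim_policy()
    h_trim = _sha(h_files, repr(trim), str(config.keep_untrimmed), config.encoding)
    stage_sig = [
        f"{s.name}:{_file_digest(s.fasta)}:{s.v}:{s.m}:{s.best_strata}:{s.strand_mode}"
        for s in config.stages
    ]
    h_align = _sha(h_trim, config.cascade_mode, str(config.suppressed_continue),
                   *stage_sig)
    h_count = _sha(h_align, config.count_policy)
    return {"qc": h_files, "trim": h_trim, "align": h_align, "count": h_count}


def _outputs_exist(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


# ---------------------------------------------------------------- per-sample

def _counts_from_sam(stage_sams: list[tuple[str, Path]],
                     policy: str) -> dict[Feature, Fraction]:
    """Re-derive feature counts from cached per-stage SAM files."""
    counts: dict[Feature, Fraction] = {}
    for stage_name, sam_path in stage_sams:
        by_read: dict[str, set[str]] = {}
        with pysam.AlignmentFile(str(sam_path), "r") as sam:
            for rec in sam.fetch(until_eof=True):
                by_read.setdefault(rec.query_name, set()).add(rec.reference_name)
        for ref_ids in by_read.values():
            k = len(ref_ids)
            if policy == "unique_only" and k != 1:
                continue
            share = Fraction(1, k) if policy == "fractional" else Fraction(1)
            for ref_id in sorted(ref_ids):
                feature = (stage_name, ref_id)
                counts[feature] = counts.get(feature, Fraction(0)) + share
    return counts


def _process_sample(sample_id: str, files: list[Path],
                    config: RunConfig) -> dict[Feature, Fraction]:
    """Run (or refresh) one sample end to end; returns its feature counts."""
    result_dir = Path(config.result_dir)
    hashes = _step_hashes(files, config)
    hash_path = result_dir / f"{sample_id}.hashes.json"
    cached: dict[str, str] = {}
    if hash_path.exists():
        cached = json.loads(hash_path.read_text())

    trimmed_fq = result_dir / f"{sample_id}.trimmed.fastq"
    trim_outputs = [trimmed_fq,
                    result_dir / f"{sample_id}.trimstats.tsv",
                    result_dir / f"{sample_id}.il.tsv"]
    qs_path = result_dir / f"{sample_id}.qs.tsv"
    stage_sams = [(s.name, result_dir / f"{sample_id}.{s.name}.sam")
                  for s in config.stages]
    align_outputs = ([p for _, p in stage_sams]
                     + [result_dir / f"{sample_id}.unmapped.txt",
                        result_dir / f"{sample_id}.stages.tsv"])
    counts_path = result_dir / f"{sample_id}.counts.tsv"

    def merged_reads() -> list[Read]:
        reads: list[Read] = []
        for f in files:  # files are in sorted order already (sheet contract)
            reads.extend(read_fastq(f, encoding=config.encoding))
        return reads

    # QC on raw reads (per-cycle quality) — keyed on raw file content only
    if cached.get("qc") != hashes["qc"] or not qs_path.exists():
        qc.cycle_quality(merged_reads()).to_tsv(qs_path)

    # Trimming
    if cached.get("trim") != hashes["trim"] or not _outputs_exist(trim_outputs):
        raw = merged_reads()
        policy = config.trim_policy()
        retained, stats = trim_sample(raw, policy, config.keep_untrimmed)
        write_fastq(retained, trimmed_fq)
        stats.to_tsv(result_dir / f"{sample_id}.trimstats.tsv")
        qc.insert_lengths(trim_read(r, policy) for r in raw).to_tsv(
            result_dir / f"{sample_id}.il.tsv")
        trimmed = retained
    else:
        trimmed = None  # load lazily only if alignment must rerun

    # Alignment cascade
    if cached.get("align") != hashes["align"] or not _outputs_exist(align_outputs):
        if trimmed is None:
            trimmed = list(read_fastq(trimmed_fq, encoding="phred33"))
        plan = config.load_plan()
        cascade = run_cascade(trimmed, plan)
        reads_by_id = {r.read_id: r for r in trimmed}
        lengths = {r.read_id: len(r) for r in trimmed}
        for stage, (stage_name, sam_path) in zip(plan.stages, stage_sams):
            aligned = cascade.per_stage.get(stage_name, [])
            alignments = [a for res in aligned for a in res.alignments]
            write_sam(alignments, stage.refs, sam_path, reads=reads_by_id)
            profiles = qc.depth_profile(alignments, lengths, stage.refs)
            with open(result_dir / f"{sample_id}.{stage_name}.depth.tsv", "w") as fh:
                fh.write("ref_id\tposition\tdepth\n")
                for rid in stage.refs.ids():
                    for pos, d in enumerate(profiles[rid].depth):
                        fh.write(f"{rid}\t{pos + 1}\t{d}\n")
        with open(result_dir / f"{sample_id}.unmapped.txt", "w") as fh:
            for read_id in cascade.final_unmapped:
                fh.write(read_id + "\n")
        summary, unmapped = stage_summary(cascade)
        summary["final_unmapped"] = unmapped
        summary.to_csv(result_dir / f"{sample_id}.stages.tsv", sep="\t", index=False)
        counts = count_sample(cascade, config.count_policy)
        align_fresh = True
    else:
        counts = None
        align_fresh = False

    # Counting (from the cascade when fresh, else from the cached SAMs)
    if (align_fresh or cached.get("count") != hashes["count"]
            or not counts_path.exists()):
        if counts is None:
            counts = _counts_from_sam(stage_sams, config.count_policy)
        with open(counts_path, "w") as fh:
            fh.write("feature\tcount\tcount_exact\n")
            for (stage, ref), value in sorted(counts.items()):
                fh.write(f"{stage}:{ref}\t{float(value):.4f}\t"
                         f"{value.numerator}/{value.denominator}\n")
    else:
        counts = _counts_from_sam(stage_sams, config.count_policy)

    hash_path.write_text(json.dumps(hashes, indent=1, sort_keys=True))
    return counts


def _process_bin(sample_ids: list[str], file_map: dict[str, list[str]],
                 config: RunConfig) -> list[tuple[str, dict | None, str | None]]:
    """Worker lane: process the bin's samples sequentially; never raises."""
    out: list[tuple[str, dict | None, str | None]] = []
    for sid in sample_ids:
        try:
            counts = _process_sample(sid, [Path(f) for f in file_map[sid]], config)
            out.append((sid, counts, None))
        except Exception:
            out.append((sid, None, traceback.format_exc()))
    return out


# ---------------------------------------------------------------- run

def run_mirna(config: RunConfig) -> dict:
    """Execute the full pipeline for every sample in the sheet.

    Returns a report dict with per-sample status, the partition used and
    the path of the merged count matrix.  Individual sample failures are
    reported without aborting the other samples.
    """
    result_dir = Path(config.result_dir)
    result_dir.mkdir(parents=True, exist_ok=True)
    write_variables(config, result_dir / "variables.txt")

    sheet = config.load_sheet()
    sheet.to_tsv(result_dir / "samples.resolved.tsv")
    partition = partition_by_size(sheet, config.workers)
    file_map = {s.sample_id: [str(f) for f in s.files] for s in sheet.samples}

    bins = [b for b in partition.bins if b]
    if config.workers > 1 and len(bins) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            futures = [pool.submit(_process_bin, b, file_map, config) for b in bins]
            results = [item for fut in futures for item in fut.result()]
    else:
        results = [item for b in bins for item in _process_bin(b, file_map, config)]

    per_sample: dict[str, dict[Feature, Fraction]] = {}
    failures: dict[str, str] = {}
    for sid, counts, error in results:
        if error is None:
            per_sample[sid] = counts
        else:
            failures[sid] = error

    plan = config.load_plan()
    matrix = assemble_matrix(per_sample, sheet, config.count_policy, plan=plan)
    matrix.to_tsv(result_dir / "counts.tsv")

    with open(result_dir / "run_report.tsv", "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid in sheet.sample_ids():
            status = "failed" if sid in failures else "ok"
            fh.write(f"{sid}\t{status}\n")
    return {
        "samples_ok": sorted(per_sample),
        "samples_failed": failures,
        "partition": partition.bins,
        "counts_path": str(result_dir / "counts.tsv"),
    }
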