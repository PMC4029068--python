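"""Sample management: file→sample association and size-balanced scheduling.

Two ways to build a :class:`SampleSheet`:

* **auto mode** — scan a directory of FASTQ files and group them into
  samples by stripping lane/read/part suffixes from the filenames;
* **program mode** — load a tab-separated sheet (columns ``sample_id``,
  ``file`` plus arbitrary trait columns); rows sharing a sample_id are
  biological/technical replicates and their files are merged.

For parallel execution, :func:`partition_by_size` splits samples across a
requested number of workers with the longest-processing-time (LPT) greedy
heuristic keyed on total raw-data bytes per sample.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Sample",
    "SampleSheet",
    "WorkPartition",
    "SampleSheetError",
    "autodetect_samples",
    "load_sample_sheet",
    "partition_by_size",
]

FASTQ_EXTENSIONS = (".fastq.gz", ".fq.gz", ".fastq", ".fq")

# lane / read / part suffixes stripped from the basename, e.g. S1_L001_R1
_SUFFIX_RE = re.compile(r"(?:_(?:L\d+|R1|\d+))+$")


class SampleSheetError(ValueError):
    """Invalid sample sheet or sample directory."""


@dataclass
class Sample:
    sample_id: str
    files: list[Path]
    traits: dict[str, str] = field(default_factory=dict)

    def total_bytes(self) -> int:
        return sum(os.path.getsize(f) for f in self.files)


@dataclass
class SampleSheet:
    samples: list[Sample]
    mode: str  # {auto, program}

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SampleSheetError("duplicate sample ids in sheet")
        seen: dict[Path, str] = {}
        for s in self.samples:
            for f in s.files:
                if f in seen:
                    raise SampleSheetError(
                        f"file {f} assigned to both {seen[f]!r} and {s.sample_id!r}"
                    )
                seen[f] = s.sample_id

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def trait_names(self) -> list[str]:
        names: list[str] = []
        for s in self.samples:
            for t in s.traits:
                if t not in names:
                    names.append(t)
        return names

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Deterministic TSV serialization (one row per sample/file pair)."""
        traits = self.trait_names()
        lines = ["\t".join(["sample_id", "file"] + traits)]
        for s in self.samples:
            for f in s.files:
                lines.append(
                    "\t".join([s.sample_id, str(f)] + [s.traits.get(t, "") for t in traits])
                )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _strip_fastq_extension(name: str) -> str | None:
    for ext in FASTQ_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return None


def autodetect_samples(directory: str | Path) -> SampleSheet:
    """Group the FASTQ files of a directory into samples by filename.

    The sample id is the basename with the extension and any trailing
    lane/read/part suffixes (``_L<d>``, ``_R1``, ``_<d>``) removed; files
    sharing a sample id become one sample, files fitting no grouping rule
    each become their own sample (with a warning).
    """
    directory = Path(directory)
    groups: dict[str, list[Path]] = {}
    for entry in sorted(directory.iterdir()):
        if not entry.is_file():
            continue
        stem = _strip_fastq_extension(entry.name)
        if stem is None:
            continue
        sample_id = _SUFFIX_RE.sub("", stem)
        if not sample_id:
            warnings.warn(f"{entry.name}: filename matches no grouping rule; "
                          "it becomes its own sample")
            sample_id = stem
        groups.setdefault(sample_id, []).append(entry)
    if not groups:
        raise SampleSheetError(f"{directory}: no FASTQ files found")
    samples = [Sample(sid, sorted(files)) for sid, files in sorted(groups.items())]
    return SampleSheet(samples, mode="auto")


def load_sample_sheet(path: str | Path, directory: str | Path | None = None) -> SampleSheet:
    """Load a program-mode sheet: TSV with sample_id, file and trait columns.

    Rows sharing a sample_id merge their files (replicate combination, files
    kept in sorted order); their trait values must agree.  Relative file
    paths are resolved against ``directory`` (default: the sheet's folder).
    """
    path = Path(path)
    base = Path(directory) if directory is not None else path.parent
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "file"):
        if col not in df.columns:
            raise SampleSheetError(f"{path}: missing required column {col!r}")
    trait_cols = [c for c in df.columns if c not in ("sample_id", "file")]

    order: list[str] = []
    files: dict[str, set[Path]] = {}
    traits: dict[str, dict[str, str]] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.sample_id
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        if not fpath.exists():
            raise SampleSheetError(f"{path}: row {rownum}: file not found: {fpath}")
        if sid not in files:
            order.append(sid)
            files[sid] = set()
            traits[sid] = {}
        if fpath in files[sid]:
            raise SampleSheetError(
                f"{path}: duplicate row for sample {sid!r} and file {fpath}"
            )
        files[sid].add(fpath)
        for t in trait_cols:
            value = getattr(row, t)
            if t in traits[sid] and traits[sid][t] != value:
                raise SampleSheetError(
                    f"{path}: sample {sid!r} has conflicting values for trait "
                    f"{t!r}: {traits[sid][t]!r} vs {value!r}"
                )
            traits[sid][t] = value
    samples = [Sample(sid, sorted(files[sid]), traits[sid]) for sid in order]
    return SampleSheet(samples, mode="program")


@dataclass
class WorkPartition:
    """Assignment of samples to worker bins with their total byte loads."""

    bins: list[list[str]]
    sizes: list[int]

    def __post_init__(self) -> None:
        flat = [sid for b in self.bins for sid in b]
        if len(set(flat)) != len(flat):
            raise ValueError("partition bins are not disjoint")


def partition_by_size(sheet: SampleSheet, workers: int) -> WorkPartition:
    """LPT greedy schedule: heaviest sample first onto the lightest bin.

    Ties (equal sample sizes, equally light bins) break by sheet order and
    lowest bin index, so the partition is deterministic for a fixed input.
    Empty bins are allowed when workers exceed the sample count.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    loads = [(s.sample_id, s.total_bytes()) for s in sheet.samples]
    loads.sort(key=lambda item: -item[1])  # stable: sheet order breaks ties
    bins: list[list[str]] = [[] for _ in range(workers)]
    sizes = [0] * workers
    for sid, nbytes in loads:
        target = min(range(workers), key=lambda i: sizes[i])
        bins[target].append(sid)
        sizes[target] += nbytes
    return WorkPartition(bins, sizes)
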