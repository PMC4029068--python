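"""Sequencing QC statistics: per-cycle quality (QS), per-position depth (SD)
and insert-length distribution (IL).

Each statistic is a table first and a plot second: the tables are the
testable surface, the optional matplotlib renderings mirror the classic
three QC viewers (per-cycle quality box plot, depth line plot, insert
length bar plot).  Quartiles use linear interpolation between order
statistics (numpy's default percentile definition).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import Alignment
from .seq_io import Read, ReferenceSet
from .trimming import TrimOutcome

__all__ = [
    "CycleQuality",
    "DepthProfile",
    "InsertLengthHist",
    "cycle_quality",
    "depth_profile",
    "insert_lengths",
    "plot_cycle_quality",
    "plot_depth_profile",
    "plot_insert_lengths",
]


@dataclass
class CycleQuality:
    """Per-cycle Phred score summaries over all reads reaching each cycle."""

    table: pd.DataFrame  # columns: cycle, n, mean_q, min, q1, median, q3, max

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DepthProfile:
    ref_id: str
    depth: np.ndarray  # int depth per 0-based reference position


@dataclass
class InsertLengthHist:
    counts: Counter

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("insert_length\tcount\n")
            for length in sorted(self.counts):
                fh.write(f"{length}\t{self.counts[length]}\n")


def cycle_quality(reads: Iterable[Read]) -> CycleQuality:
    """Quality-score distribution per sequencing cycle.

    Cycle i summarizes the i-th base quality of every read at least i+1
    bases long, so the cycle count equals the longest read length.  An
    empty stream yields an empty table.
    """
    per_cycle: list[list[int]] = []
    for read in reads:
        while len(per_cycle) < len(read):
            per_cycle.append([])
        for i, q in enumerate(read.quals):
            per_cycle[i].append(q)
    rows = []
    for i, scores in enumerate(per_cycle):
        arr = np.asarray(scores, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append({
            "cycle": i + 1, "n": len(scores), "mean_q": arr.mean(),
            "min": int(arr.min()), "q1": q1, "median": med, "q3": q3,
            "max": int(arr.max()),
        })
    cols = ["cycle", "n", "mean_q", "min", "q1", "median", "q3", "max"]
    return CycleQuality(pd.DataFrame(rows, columns=cols))


def depth_profile(alignments: Sequence[Alignment], read_lengths: Mapping[str, int],
                  refs: ReferenceSet) -> dict[str, DepthProfile]:
    """Per-position sequencing depth per reference.

    Each alignment adds one to every position in [offset, offset+read_len);
    strand is ignored.  References with no alignments get an all-zero
    profile so depth tables always cover the full reference set.
    """
    profiles = {
        rec.ref_id: DepthProfile(rec.ref_id, np.zeros(rec.length, dtype=np.int64))
        for rec in refs
    }
    for aln in alignments:
        length = read_lengths[aln.read_id]
        depth = profiles[aln.ref_id].depth
        if aln.offset + length > len(depth):
            raise ValueError(
                f"alignment of {aln.read_id!r} overruns reference {aln.ref_id!r}"
            )
        depth[aln.offset : aln.offset + length] += 1
    return profiles


def insert_lengths(outcomes: Iterable[TrimOutcome],
                   include_untrimmed: bool = False) -> InsertLengthHist:
    """Histogram of retained insert lengths from trimming outcomes.

    Counts status=trimmed inserts; with ``include_untrimmed`` the full
    lengths of untrimmed reads are included as well.
    """
    counts: Counter = Counter()
    for outcome in outcomes:
        if outcome.status == "trimmed":
            counts[len(outcome.read)] += 1
        elif include_untrimmed and outcome.status == "untrimmed":
            counts[len(outcome.read)] += 1
    return InsertLengthHist(counts)


def _matplotlib_axes():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_cycle_quality(cq: CycleQuality, path: str | Path) -> None:
    """Box-style plot of per-cycle quality (median, IQR, min-max whiskers)."""
    plt = _matplotlib_axes()
    t = cq.table
    fig, ax = plt.subplots(figsize=(8, 4))
    if len(t):
        ax.fill_between(t["cycle"], t["q1"], t["q3"], alpha=0.4, label="IQR")
        ax.plot(t["cycle"], t["median"], label="median")
        ax.plot(t["cycle"], t["min"], linestyle=":", color="grey", label="min/max")
        ax.plot(t["cycle"], t["max"], linestyle=":", color="grey")
    ax.set_xlabel("sequencing cycle")
    ax.set_ylabel("Phred quality")
    ax.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_depth_profile(profile: DepthProfile, path: str | Path) -> None:
    plt = _matplotlib_axes()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(np.arange(1, len(profile.depth) + 1), profile.depth)
    ax.set_xlabel(f"position on {profile.ref_id}")
    ax.set_ylabel("depth")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_insert_lengths(hist: InsertLengthHist, path: str | Path) -> None:
    plt = _matplotlib_axes()
    fig, ax = plt.subplots(figsize=(6, 3))
    lengths = sorted(hist.counts)
    ax.bar(lengths, [hist.counts[l] for l in lengths])
    ax.set_xlabel("insert length (nt)")
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
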