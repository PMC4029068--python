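"""Separate and iterative (cascade) alignment over ordered reference sets.

Small-RNA pipelines align against several references — typically mature
miRNAs, then precursors, then genome — and the strategy matters because
mature sequences are embedded in their precursors:

* **separate** mode aligns every read against every stage independently,
  so a read can be reported under several stages;
* **iterative** mode forwards only the reads left unassigned by earlier
  stages, so each read is assigned at most once and stage order changes
  per-stage totals (never the overall total).

Reads suppressed by the multi-map threshold are terminal in iterative mode
by default — they were reportable, just not reported — but
``suppressed_continue=True`` forwards them like unmapped reads instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .aligner import AlignmentPolicy, AlignResult, align_sample
from .seq_io import Read, ReferenceSet

__all__ = [
    "CascadeStage",
    "CascadePlan",
    "CascadeResult",
    "run_cascade",
    "stage_summary",
]


@dataclass(frozen=True)
class CascadeStage:
    name: str
    refs: ReferenceSet
    policy: AlignmentPolicy


@dataclass
class CascadePlan:
    stages: list[CascadeStage]
    mode: str = "iterative"  # {separate, iterative}
    suppressed_continue: bool = False

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a cascade needs at least one stage")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")
        if self.mode not in ("separate", "iterative"):
            raise ValueError("mode must be 'separate' or 'iterative'")


@dataclass
class CascadeResult:
    """Aligned results per stage, suppressed read ids per stage, and the
    reads left unassigned after the last stage."""

    mode: str
    stage_names: list[str]
    per_stage: dict[str, list[AlignResult]] = field(default_factory=dict)
    suppressed: dict[str, list[str]] = field(default_factory=dict)
    final_unmapped: list[str] = field(default_factory=list)
    n_reads: int = 0


def run_cascade(reads: Iterable[Read], plan: CascadePlan) -> CascadeResult:
    """Run the staged alignment plan over a trimmed read stream.

    Iterative mode partitions every read into exactly one of {aligned at
    some stage, suppressed at some stage, final_unmapped} (with the default
    terminal-suppression semantics).  Separate mode evaluates every read at
    every stage; final_unmapped then holds the reads assigned nowhere.
    """
    reads = list(reads)
    result = CascadeResult(plan.mode, [s.name for s in plan.stages],
                           n_reads=len(reads))

    if plan.mode == "separate":
        assigned: set[str] = set()
        for stage in plan.stages:
            outcomes = align_sample(reads, stage.refs, stage.policy)
            result.per_stage[stage.name] = [r for r in outcomes if r.status == "aligned"]
            result.suppressed[stage.name] = [
                r.read_id for r in outcomes if r.status == "suppressed"
            ]
            assigned.update(r.read_id for r in outcomes if r.status != "unaligned")
        result.final_unmapped = [r.read_id for r in reads if r.read_id not in assigned]
        return result

    remaining = reads
    for round_no, stage in enumerate(plan.stages, start=1):
        outcomes = align_sample(remaining, stage.refs, stage.policy, round=round_no)
        result.per_stage[stage.name] = [r for r in outcomes if r.status == "aligned"]
        result.suppressed[stage.name] = [
            r.read_id for r in outcomes if r.status == "suppressed"
        ]
        if plan.suppressed_continue:
            carry = {"unaligned", "suppressed"}
        else:
            carry = {"unaligned"}
        remaining = [read for read, r in zip(remaining, outcomes) if r.status in carry]
    result.final_unmapped = [read.read_id for read in remaining]
    return result


def stage_summary(result: CascadeResult) -> tuple[pd.DataFrame, int]:
    """Per-stage aligned/suppressed read counts plus the final unmapped count.

    In iterative mode (terminal suppression) the stage counts and the
    unmapped count sum to the input read count.
    """
    rows = [
        {
            "stage_name": name,
            "aligned_reads": len(result.per_stage.get(name, [])),
            "suppressed_reads": len(result.suppressed.get(name, [])),
        }
        for name in result.stage_names
    ]
    return pd.DataFrame(rows, columns=["stage_name", "aligned_reads",
                                       "suppressed_reads"]), len(result.final_unmapped)
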