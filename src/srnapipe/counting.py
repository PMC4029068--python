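"""Read counting with an explicit multi-mapping policy.

Mature miRNAs can share identical or near-identical sequences, so a read's
reported stratum may span several references.  Three policies resolve the
ambiguity for a read with k distinct reported references:

* ``fractional`` (default) — 1/k to each, preserving library totals while
  acknowledging ambiguity; counts are exact rationals internally;
* ``all`` — 1 to each (inflates totals);
* ``unique_only`` — 1 iff k == 1, else the read is dropped.

Multiple placements on the *same* reference count once toward that
reference's k: counting is feature-level, not placement-level.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd

from .cascade import CascadePlan, CascadeResult
from .samples import SampleSheet

__all__ = ["CountMatrix", "count_sample", "assemble_matrix"]

POLICIES = ("fractional", "all", "unique_only")

Feature = tuple[str, str]  # (stage_name, ref_id)


def count_sample(result: CascadeResult, policy: str = "fractional") -> dict[Feature, Fraction]:
    """Per-feature counts for one sample's cascade result.

    Suppressed and unmapped reads contribute nothing.  Features are keyed
    (stage_name, ref_id) so the same reference id may appear under several
    stages in separate mode.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown counting policy {policy!r}")
    counts: dict[Feature, Fraction] = {}
    for stage_name in result.stage_names:
        for res in result.per_stage.get(stage_name, []):
            ref_ids = sorted({a.ref_id for a in res.alignments})
            k = len(ref_ids)
            if policy == "unique_only" and k != 1:
                continue
            share = Fraction(1, k) if policy == "fractional" else Fraction(1)
            for ref_id in ref_ids:
                feature = (stage_name, ref_id)
                counts[feature] = counts.get(feature, Fraction(0)) + share
    return counts


@dataclass
class CountMatrix:
    """Features × samples matrix of exact rational counts."""

    features: list[Feature]
    samples: list[str]
    values: list[list[Fraction]]  # row per feature, column per sample
    policy: str

    def to_dataframe(self) -> pd.DataFrame:
        index = [f"{stage}:{ref}" for stage, ref in self.features]
        data = [[float(v) for v in row] for row in self.values]
        return pd.DataFrame(data, index=index, columns=self.samples)

    def column_sums(self) -> dict[str, Fraction]:
        return {
            sid: sum((row[j] for row in self.values), Fraction(0))
            for j, sid in enumerate(self.samples)
        }

    def to_tsv(self, path: str | Path) -> None:
        """Write counts to 4 decimal places plus an exact-rational sidecar.

        The sidecar (<path>.exact.tsv) renders each count as num/den so the
        fractional policy round-trips without floating-point loss.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("feature\t" + "\t".join(self.samples) + "\n")
            for feature, row in zip(self.features, self.values):
                fid = f"{feature[0]}:{feature[1]}"
                fh.write(fid + "\t" + "\t".join(f"{float(v):.4f}" for v in row) + "\n")
        sidecar = path.with_name(path.name + ".exact.tsv")
        with open(sidecar, "w") as fh:
            fh.write("feature\t" + "\t".join(self.samples) + "\n")
            for feature, row in zip(self.features, self.values):
                fid = f"{feature[0]}:{feature[1]}"
                fh.write(fid + "\t" + "\t".join(
                    f"{v.numerator}/{v.denominator}" for v in row) + "\n")


def _feature_sort_key(plan: CascadePlan | None):
    if plan is None:
        return lambda feature: feature
    stage_order = {s.name: i for i, s in enumerate(plan.stages)}
    ref_order = {
        s.name: {rid: j for j, rid in enumerate(s.refs.ids())} for s in plan.stages
    }
    def key(feature: Feature):
        stage, ref = feature
        return (stage_order.get(stage, len(stage_order)),
                ref_order.get(stage, {}).get(ref, ref))
    return key


def assemble_matrix(per_sample: Mapping[str, Mapping[Feature, Fraction]],
                    sheet: SampleSheet, policy: str = "fractional",
                    plan: CascadePlan | None = None) -> CountMatrix:
    """Merge per-sample counts into one matrix.

    Features are the union over samples, ordered by (stage, reference input
    order) when the cascade plan is given, else lexicographically; missing
    entries are zero.  Columns follow sheet order; sample ids absent from
    the sheet abort.
    """
    sheet_ids = sheet.sample_ids()
    unknown = set(per_sample) - set(sheet_ids)
    if unknown:
        raise KeyError(f"sample ids not in sheet: {sorted(unknown)}")
    samples = [sid for sid in sheet_ids if sid in per_sample]
    feature_union = {f for counts in per_sample.values() for f in counts}
    features = sorted(feature_union, key=_feature_sort_key(plan))
    values = [
        [per_sample[sid].get(feature, Fraction(0)) for sid in samples]
        for feature in features
    ]
    return CountMatrix(features, samples, values, policy)
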