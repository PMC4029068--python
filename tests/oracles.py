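"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's index/scan code paths: placements
are enumerated with numpy sliding windows over every (reference, offset,
strand), policies are applied literally, and the trimmer oracle scores
every candidate position.  Only plain data structures cross the boundary.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_placements(read_bases: str, refs) -> list[tuple]:
    """Every ungapped placement: (ref_index, ref_id, offset, strand, mm)."""
    out = []
    for ri, rec in enumerate(refs):
        ref = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        for strand, query in (("+", read_bases), ("-", rc(read_bases))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            if len(q) > len(ref):
                continue
            windows = sliding_window_view(ref, len(q))
            mm = (windows != q).sum(axis=1)
            for off in range(len(mm)):
                out.append((ri, rec.ref_id, off, strand, int(mm[off])))
    return out


def apply_policy(placements, v, m, best_strata, strand_mode):
    """Literal reporting semantics; returns (status, [(ref_id,off,strand,mm)])."""
    keep = [p for p in placements
            if p[4] <= v and (strand_mode == "both" or p[3] == "+")]
    if best_strata and keep:
        best = min(p[4] for p in keep)
        keep = [p for p in keep if p[4] == best]
    if not keep:
        return "unaligned", []
    if m is not None and len(keep) > m:
        return "suppressed", []
    keep.sort(key=lambda p: (p[0], p[2], p[3] != "+"))
    return "aligned", [(p[1], p[2], p[3], p[4]) for p in keep]


def brute_trim_position(bases: str, adapter: str, min_overlap: int,
                        max_error_rate: float):
    """Leftmost qualifying adapter position by exhaustive scoring, or None."""
    best = None
    for p in range(0, len(bases) - min_overlap + 1):
        overlap = min(len(adapter), len(bases) - p)
        if overlap < min_overlap:
            continue
        mm = sum(a != b for a, b in zip(bases[p:p + overlap], adapter[:overlap]))
        if mm <= int(max_error_rate * overlap) and best is None:
            best = p
    return best


def random_read_set(rng, refs, n, len_range=(16, 28), max_subs=3):
    """Half uniform-random reads, half reads sampled from refs with 0..max_subs
    substitutions — exercises unaligned, unique, multi-map and stratum paths."""
    bases_arr = np.array(list("ACGT"))
    reads = []
    for i in range(n):
        if i % 2 == 0:
            L = int(rng.integers(*len_range[0:1] + (len_range[1] + 1,)))
            seq = "".join(rng.choice(bases_arr, L))
        else:
            rec = refs[int(rng.integers(len(refs)))]
            L = min(len(rec.seq), int(rng.integers(len_range[0], len_range[1] + 1)))
            off = int(rng.integers(0, len(rec.seq) - L + 1))
            s = list(rec.seq[off:off + L])
            n_subs = int(rng.integers(0, max_subs + 1))
            for pos in rng.choice(L, size=min(n_subs, L), replace=False):
                s[int(pos)] = str(rng.choice(bases_arr))
            seq = "".join(s)
            if rng.random() < 0.5:
                seq = rc(seq)
        reads.append((f"q{i}", seq))
    return reads
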