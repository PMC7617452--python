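"""Terminal substitution profiles and an ancient-like damage verdict.

Substitutions are tallied read-relative: reverse-strand alignments are
reoriented so offset 0 is always the read's own 5' (or 3') terminus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import DNA, revcomp

_BASE_IDX = {b: i for i, b in enumerate(DNA)}


@dataclass
class DamageProfile:
    """counts[end, offset, ref_base, read_base]; end 0 = 5', end 1 = 3'."""

    counts: np.ndarray  # (2, K, 4, 4) integer tallies, diagonal = matches
    k: int

    def opportunities(self, end: int, offset: int, ref_base: str) -> int:
        return int(self.counts[end, offset, _BASE_IDX[ref_base]].sum())

    def count(self, end: int, offset: int, ref_base: str, read_base: str) -> int:
        return int(self.counts[end, offset, _BASE_IDX[ref_base], _BASE_IDX[read_base]])

    def frequency(self, end: int, offset: int, ref_base: str, read_base: str) -> float:
        opp = self.opportunities(end, offset, ref_base)
        return self.count(end, offset, ref_base, read_base) / opp if opp else 0.0

    def ct5(self) -> np.ndarray:
        """Headline 5' C->T frequency series over offsets 0..K-1."""
        return np.array([self.frequency(0, i, "C", "T") for i in range(self.k)])

    def ga3(self) -> np.ndarray:
        """Headline 3' G->A frequency series over offsets 0..K-1."""
        return np.array([self.frequency(1, i, "G", "A") for i in range(self.k)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for end, end_name in ((0, "5p"), (1, "3p")):
            for off in range(self.k):
                for rb in DNA:
                    for qb in DNA:
                        if rb == qb:
                            continue
                        rows.append({
                            "end": end_name, "offset": off, "ref": rb, "read": qb,
                            "count": self.count(end, off, rb, qb),
                            "opportunities": self.opportunities(end, off, rb),
                            "frequency": self.frequency(end, off, rb, qb),
                        })
        return pd.DataFrame(rows)


def damage_profile(alignments, reads: dict[str, str], references: dict[str, str],
                   k: int = 25) -> DamageProfile:
    """Exact per-offset substitution tallies from end-to-end alignments."""
    counts = np.zeros((2, k, 4, 4), dtype=np.int64)
    for rec in alignments:
        ref_seq = references[rec.ref_id]
        if rec.start + rec.aligned_length > len(ref_seq):
            raise ValueError(f"read {rec.read_id!r} extends past the reference end")
        window = ref_seq[rec.start : rec.start + rec.aligned_length]
        read_seq = reads[rec.read_id]
        if len(read_seq) != rec.aligned_length:
            raise ValueError(f"read {rec.read_id!r}: sequence/alignment length mismatch")
        if rec.strand == "-":
            window = revcomp(window)  # put the reference in read orientation
        L = rec.aligned_length
        for off in range(min(k, L)):
            for end, idx in ((0, off), (1, L - 1 - off)):
                rb, qb = window[idx], read_seq[idx]
                if rb in _BASE_IDX and qb in _BASE_IDX:
                    counts[end, off, _BASE_IDX[rb], _BASE_IDX[qb]] += 1
    return DamageProfile(counts, k)


@dataclass
class DamageVerdict:
    ancient_like: bool
    terminal_rate: float
    interior_rate: float
    two_proportion_z: float
    status: str = "ok"  # "undefined" when the interior has no opportunities


def damage_verdict(profile: DamageProfile, terminal_threshold: float = 0.10,
                   interior_window: tuple[int, int] = (10, 20)) -> DamageVerdict:
    """Ancient-like iff terminal 5' C->T is both high and significantly
    elevated over the interior (two-proportion z > 3)."""
    n1 = profile.opportunities(0, 0, "C")
    if n1 == 0:
        raise ValueError("no C opportunities at 5' offset 0")
    x1 = profile.count(0, 0, "C", "T")
    lo, hi = interior_window
    x2 = sum(profile.count(0, i, "C", "T") for i in range(lo, hi + 1))
    n2 = sum(profile.opportunities(0, i, "C") for i in range(lo, hi + 1))
    if n2 == 0:
        return DamageVerdict(False, x1 / n1, math.nan, math.nan, status="undefined")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / denom if denom > 0 else 0.0
    ancient = p1 >= terminal_threshold and z > 3.0
    return DamageVerdict(ancient, p1, p2, z)
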