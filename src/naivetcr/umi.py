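"""Frequency-dependent UMI error correction.

Two random 12-nt UMIs differ at H ~ Binomial(n=12, p=3/4) positions (uniform
base composition).  For a sequence supported by i distinct UMIs there are
C(i, 2) pairs, so the expected number of pairs at Hamming distance h is
n_i(h) = C(i, 2) P(H = h).  UMI pairs closer than expected under this null
are treated as PCR/sequencing errors; the distance threshold adapts to i:

    D_alpha = max({ d : sum_{h=1..d} n_i(h) <= alpha })

so sequences seen by many UMIs (where close pairs arise by chance) are merged
conservatively, while a sequence with two nearly identical UMIs among i = 2
is merged up to distance 5 (alpha = 0.05).  Merging transfers the read count
of the less frequent UMI of a pair to the more frequent one, iterating
d = 1..D_alpha; total reads are conserved.

A fixed-threshold "legacy" mode (merge all pairs within a constant edit
distance, classically 2) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "UMICorrectionParams",
    "UMIGroup",
    "hamming",
    "threshold_distance",
    "correct_group",
    "correct_table",
]


@dataclass(frozen=True)
class UMICorrectionParams:
    umi_length: int = 12
    mismatch_prob: float = 0.75  # P(two random UMIs differ at one position)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")


@dataclass
class UMIGroup:
    """All UMIs supporting one clonotype: (umi, reads) pairs."""

    key: str
    umis: list[str]
    reads: list[int]

    def __post_init__(self) -> None:
        if len(self.umis) != len(set(self.umis)):
            raise ValueError("UMIs must be unique within a group")
        if any(r < 1 for r in self.reads):
            raise ValueError("read counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(sum(self.reads))


def hamming(u1: str, u2: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(u1) != len(u2):
        raise ValueError("UMIs must have equal length")
    return sum(a != b for a, b in zip(u1, u2))


@lru_cache(maxsize=None)
def _threshold(i: int, umi_length: int, mismatch_prob: float, alpha: float) -> int:
    pairs = comb(i, 2)
    pmf = stats.binom.pmf(np.arange(1, umi_length + 1), umi_length, mismatch_prob)
    cumulative = pairs * np.cumsum(pmf)
    below = np.nonzero(cumulative <= alpha)[0]
    return 0 if len(below) == 0 else int(below[-1]) + 1


def threshold_distance(i: int, params: UMICorrectionParams | None = None) -> int:
    """Largest d with sum_{h<=d} C(i,2) P(H=h) <= alpha; 0 means no merging."""
    if params is None:
        params = UMICorrectionParams()
    if i < 2:
        raise ValueError("threshold is defined for groups of >= 2 UMIs")
    return _threshold(i, params.umi_length, params.mismatch_prob, params.alpha)


def _merge_pass(reads: dict[str, int], d_max: int, fixed_d: bool = False) -> dict[str, int]:
    """Merge UMI pairs within distance d = 1..d_max (single pass at exactly
    ``d_max`` when ``fixed_d``), less-frequent into more-frequent.

    At each d, majors are visited in descending read count (ties broken by
    lexicographic order, the smaller string winning); merges are applied
    immediately, so chains of merges can form within a pass, and sweeps
    repeat until no pair within distance d remains.
    """
    distances = (d_max,) if fixed_d else range(1, d_max + 1)
    for d in distances:
        changed = True
        while changed:
            changed = False
            order = sorted(reads, key=lambda u: (-reads[u], u))
            for a, major in enumerate(order):
                if major not in reads:
                    continue
                for minor in order[a + 1 :]:
                    if minor not in reads:
                        continue
                    if hamming(major, minor) <= d:
                        reads[major] += reads.pop(minor)
                        changed = True
    return reads


def correct_group(
    group: UMIGroup,
    params: UMICorrectionParams | None = None,
    legacy_threshold: int | None = None,
) -> UMIGroup:
    """Correct one clonotype's UMI set.

    The adaptive threshold D_alpha is computed once from the *original* UMI
    count and held fixed while merging proceeds from d = 1 upward.  With
    ``legacy_threshold`` set, a fixed-distance single pass (the classical
    collapse-within-2-edits rule) is applied instead.
    """
    if params is None:
        params = UMICorrectionParams()
    if len(group.umis) < 2:
        return group
    reads = dict(zip(group.umis, (int(r) for r in group.reads)))
    if legacy_threshold is not None:
        if legacy_threshold > 0:
            reads = _merge_pass(reads, legacy_threshold, fixed_d=True)
    else:
        d_alpha = threshold_distance(len(group.umis), params)
        if d_alpha > 0:
            reads = _merge_pass(reads, d_alpha)
    umis = sorted(reads, key=lambda u: (-reads[u], u))
    return UMIGroup(group.key, umis, [reads[u] for u in umis])


def correct_table(
    umi_groups: dict[str, list[tuple[str, int]]],
    params: UMICorrectionParams | None = None,
    legacy_threshold: int | None = None,
):
    """Correct every clonotype group; returns a DataFrame with the corrected
    molecule count (surviving distinct UMIs) and conserved read totals."""
    import pandas as pd

    rows = []
    for key, entries in umi_groups.items():
        group = UMIGroup(key, [u for u, _ in entries], [r for _, r in entries])
        corrected = correct_group(group, params, legacy_threshold)
        rows.append(
            {
                "clonotype_key": key,
                "count": len(corrected.umis),
                "reads": corrected.total_reads,
                "raw_count": len(group.umis),
            }
        )
    return pd.DataFrame(rows)
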