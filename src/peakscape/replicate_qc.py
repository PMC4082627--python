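"""ENCODE-style replicate-consistency QC and replicate merging.

The consistency rule for two biological ChIP-seq replicates: truncate both
peak lists to the length of the shorter one (keeping the highest-scoring
peaks), overlap the top 40% of each truncated list against the other's full
truncated list, and require that roughly 80% of each top set is contained
in the other list.  Replicates that pass are merged by interval union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

from .intervals import GenomicInterval, PeakSet, count_overlapping, _position_key

__all__ = [
    "ConsistencyReport",
    "truncate_to_equal_length",
    "cross_containment",
    "replicate_consistency",
    "merge_replicates",
]


@dataclass
class ConsistencyReport:
    """Result of the cross-containment replicate check."""

    containment_a_in_b: float
    containment_b_in_a: float
    truncated_length: int
    top_fraction: float = 0.4
    threshold: float = 0.8
    passed: bool = False

    def __post_init__(self) -> None:
        for frac in (self.containment_a_in_b, self.containment_b_in_a):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"containment fraction out of [0,1]: {frac}")
        self.passed = (
            self.containment_a_in_b >= self.threshold
            and self.containment_b_in_a >= self.threshold
        )

    def to_dict(self) -> dict:
        return asdict(self)


def truncate_to_equal_length(a: PeakSet, b: PeakSet) -> tuple[PeakSet, PeakSet]:
    """Truncate both lists to min(|A|, |B|), keeping top-scoring peaks.

    Score ties are broken by (chrom, start) ascending so the result is
    stable under permutation of the input order.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("replicate peak lists must be non-empty")
    n = min(len(a), len(b))
    return a.top(n), b.top(n)


def cross_containment(a: PeakSet, b: PeakSet, top_fraction: float = 0.4,
                      threshold: float = 0.8) -> ConsistencyReport:
    """Overlap the top fraction of each list against the other's full list.

    Expects A and B already truncated to equal length (see
    :func:`truncate_to_equal_length`); the top set holds
    ``ceil(top_fraction * len)`` peaks by score.
    """
    if len(a) != len(b):
        raise ValueError(
            "cross_containment expects equal-length (truncated) replicates; "
            f"got {len(a)} and {len(b)}"
        )
    if len(a) == 0:
        raise ValueError("replicate peak lists must be non-empty")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    n_top = math.ceil(top_fraction * len(a))
    if n_top == 0:
        raise ValueError("top set is empty")
    top_a = a.top(n_top)
    top_b = b.top(n_top)
    frac_a = count_overlapping(top_a, b) / n_top
    frac_b = count_overlapping(top_b, a) / n_top
    return ConsistencyReport(
        containment_a_in_b=frac_a,
        containment_b_in_a=frac_b,
        truncated_length=len(a),
        top_fraction=top_fraction,
        threshold=threshold,
    )


def replicate_consistency(a: PeakSet, b: PeakSet, top_fraction: float = 0.4,
                          threshold: float = 0.8) -> ConsistencyReport:
    """Truncate-then-check convenience wrapper over the two QC steps."""
    ta, tb = truncate_to_equal_length(a, b)
    return cross_containment(ta, tb, top_fraction=top_fraction,
                             threshold=threshold)


def merge_replicates(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union of two peak lists with overlapping groups collapsed.

    Each maximal group of transitively overlapping intervals becomes one
    interval spanning min(start)..max(end) with score = max over members.
    Adjacent (book-ended) intervals do not overlap under half-open
    semantics and are kept separate.  Output is coordinate-sorted and
    non-overlapping.
    """
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"genome_id mismatch: {a.genome_id!r} vs {b.genome_id!r}"
        )
    merged: list[GenomicInterval] = []
    pool = sorted(list(a.intervals) + list(b.intervals), key=_position_key)
    for iv in pool:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                score=max(prev.score, iv.score),
                name=prev.name,
            )
        else:
            merged.append(iv)
    return PeakSet(factor=a.factor, intervals=merged, genome_id=a.genome_id)
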