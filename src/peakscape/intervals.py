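"""Genomic interval data model, BED I/O, and the overlap engine.

Coordinates follow the BED standard throughout: 0-based, half-open
``[start, end)``.  Every downstream computation (replicate QC, location
annotation, co-association, multiway partitioning) is built on the two
primitives defined here: pairwise interval overlap and "how many intervals
of set A hit set B".
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "overlaps",
    "count_overlapping",
    "multiway_partition",
    "partition_table",
    "peak_center",
]


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A scored, half-open genomic interval (one ChIP-seq peak).

    ``score`` is the peak-caller significance (higher = stronger binding);
    ``name`` is an optional label carried through I/O.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def peak_center(a: GenomicInterval) -> int:
    """Midpoint of the interval, floor((start+end)/2)."""
    return a.center


def _score_key(iv: GenomicInterval):
    # descending score; ties broken deterministically by position
    return (-iv.score, iv.chrom, iv.start, iv.end, iv.name or "")


def _position_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end, -iv.score, iv.name or "")


@dataclass
class PeakSet:
    """An ordered collection of peaks for one factor or histone mark."""

    factor: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    genome_id: str = "genome"

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted_by_position(self) -> "PeakSet":
        return replace(self, intervals=sorted(self.intervals, key=_position_key))

    def sorted_by_score(self) -> "PeakSet":
        """Descending score, ties broken by (chrom, start) ascending."""
        return replace(self, intervals=sorted(self.intervals, key=_score_key))

    def top(self, n: int) -> "PeakSet":
        """The n highest-scoring peaks (deterministic tie-break)."""
        if n < 0:
            raise ValueError("n must be >= 0")
        return replace(self, intervals=self.sorted_by_score().intervals[:n])

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for O(log n) overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return trees


def read_bed(path: str | Path, factor: str | None = None,
             genome_id: str = "genome") -> PeakSet:
    """Read a BED3/BED5 file (tab-separated, headerless).

    Column 4 (name) and column 5 (score) are optional; a missing score is
    stored as 0.  Input order is preserved.  Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = None
            if len(fields) >= 4 and fields[3] not in ("", "."):
                name = fields[3]
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from exc
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, score=score, name=name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(factor=factor or path.stem, intervals=intervals,
                   genome_id=genome_id)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a 5-column BED (chrom, start, end, name, score).

    Scores are rendered with ``%g``; reading the result back and rewriting
    it is byte-identical.
    """
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:g}\n"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share >= min_bp bases under half-open semantics."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def _check_same_genome(a: PeakSet, b: PeakSet) -> None:
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"genome_id mismatch: {a.genome_id!r} vs {b.genome_id!r}"
        )


def count_overlapping(a: PeakSet, b: PeakSet) -> int:
    """Number of intervals of A overlapping (>=1 bp) at least one B interval.

    Directional: each A interval counts at most once no matter how many B
    intervals it hits.  This is the statistic behind reference-directional
    overlap fractions such as "41% of the reference factor's sites overlap
    factor X".
    """
    _check_same_genome(a, b)
    trees = b.trees()
    n = 0
    for iv in a.intervals:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            n += 1
    return n


def multiway_partition(sets: Sequence[PeakSet]) -> dict[tuple[int, ...], int]:
    """Partition the reference set by which other sets each interval hits.

    ``sets[0]`` is the reference.  Every reference interval is assigned
    exactly one membership signature: a tuple of 0/1 flags over
    ``sets[1:]`` marking which of the other sets it overlaps by >= 1 bp
    (the four-way Venn construction).  Counts sum to ``len(sets[0])``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    if len(sets) > 6:
        raise ValueError("at most 6 peak sets supported")
    ref = sets[0]
    for other in sets[1:]:
        _check_same_genome(ref, other)
    other_trees = [s.trees() for s in sets[1:]]
    counts: Counter[tuple[int, ...]] = Counter()
    for iv in ref.intervals:
        sig = tuple(
            int(
                (tree := trees.get(iv.chrom)) is not None
                and tree.overlaps(iv.start, iv.end)
            )
            for trees in other_trees
        )
        counts[sig] += 1
    # make the result total over all cells, including empty ones
    full = {
        sig: counts.get(sig, 0)
        for sig in itertools.product((0, 1), repeat=len(sets) - 1)
    }
    return full


def partition_table(sets: Sequence[PeakSet]):
    """Multiway partition as a tidy DataFrame (one row per signature)."""
    import pandas as pd

    part = multiway_partition(sets)
    names = [s.factor for s in sets[1:]]
    rows = []
    for sig in sorted(part, reverse=True):
        row = {name: flag for name, flag in zip(names, sig)}
        row["count"] = part[sig]
        rows.append(row)
    return pd.DataFrame(rows)


def write_partition_tsv(sets: Sequence[PeakSet], path: str | Path) -> None:
    partition_table(sets).to_csv(path, sep="\t", index=False)
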