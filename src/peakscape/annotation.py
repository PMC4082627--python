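"""Nearest-TSS assignment, distance binning, and genic-context classification.

Each peak is assigned to the RefSeq-style gene whose transcription start
site is nearest to the peak midpoint, with a strand-aware signed distance
(negative = upstream of the TSS).  Absolute distances are binned into the
four canonical ranges <1 kb / 1-10 kb / 10-100 kb / >100 kb, and every peak
gets exactly one genomic context with precedence
promoter > exon > intron > intergenic.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, PeakSet, peak_center

__all__ = [
    "GeneModel",
    "LocationAnnotation",
    "LocationSummary",
    "GeneIndex",
    "read_gene_table",
    "write_gene_table",
    "tss_of",
    "nearest_tss",
    "bin_distance",
    "classify_context",
    "annotate_peaks",
    "location_summary",
    "target_genes",
    "top_regions",
]

DISTANCE_BINS = ("<1kb", "1-10kb", "10-100kb", ">100kb")
PROMOTER_RADIUS = 1000  # bp around the TSS counted as promoter-proximal


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure (refFlat-style)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start must be < tx_end"
            )
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and within the transcript bounds"
                )
            prev_end = e


def tss_of(g: GeneModel) -> int:
    """Transcription start: tx_start on '+', tx_end - 1 on '-'."""
    return g.tx_start if g.strand == "+" else g.tx_end - 1


@dataclass(frozen=True)
class LocationAnnotation:
    peak: GenomicInterval
    nearest_gene: str | None
    signed_distance: int | None
    distance_bin: str
    context: str


@dataclass
class LocationSummary:
    """TSS-distance bin fractions plus the separate genic partition.

    ``bin_fractions`` partitions all peaks by absolute nearest-TSS
    distance.  ``genic_fraction`` is the independent fraction of peaks
    whose midpoint lies within a gene body (regardless of promoter
    precedence), and ``intron_share_of_genic`` the share of those falling
    in introns rather than exons — the two partitions are reported
    separately to avoid double counting.
    """

    n_peaks: int
    bin_fractions: dict[str, float]
    genic_fraction: float
    intron_share_of_genic: float
    context_fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "bin_fractions": dict(self.bin_fractions),
            "genic_fraction": self.genic_fraction,
            "intron_share_of_genic": self.intron_share_of_genic,
            "context_fractions": dict(self.context_fractions),
        }


class GeneIndex:
    """Per-chromosome TSS arrays and exon/gene-body trees for fast lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        self._body: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append((tss_of(g), g.gene_id))
            self._body.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, g.gene_id
            )
            for s, e in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e)
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        self._strand = {g.gene_id: g.strand for g in self.genes}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            ids = [gid for _, gid in pairs]
            self._tss[chrom] = (pos, ids)

    def nearest_tss(self, chrom: str, point: int) -> tuple[str, int] | None:
        """Nearest TSS to a point; ties resolved to the smallest gene_id.

        Returns (gene_id, signed_distance) where the sign is strand-aware:
        negative when the point is upstream of the gene's TSS.  None when
        the chromosome carries no gene.
        """
        entry = self._tss.get(chrom)
        if entry is None:
            return None
        pos, ids = entry
        i = int(np.searchsorted(pos, point))
        best = None  # (abs distance, gene_id, tss)
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                cand = (abs(point - int(pos[j])), ids[j], int(pos[j]))
                if best is None or cand[0] < best[0]:
                    best = cand
        assert best is not None
        dmin = best[0]
        # gather every TSS at exactly dmin from the point (tie-break on id)
        for tss in (point - dmin, point + dmin):
            lo = int(np.searchsorted(pos, tss, side="left"))
            hi = int(np.searchsorted(pos, tss, side="right"))
            for j in range(lo, hi):
                cand = (dmin, ids[j], int(pos[j]))
                if cand[1] < best[1]:
                    best = cand
        _, gene_id, tss = best
        strand = self._strand[gene_id]
        signed = point - tss if strand == "+" else tss - point
        return gene_id, signed

    def in_exon(self, chrom: str, point: int) -> bool:
        tree = self._exon.get(chrom)
        return tree is not None and bool(tree.overlaps(point, point + 1))

    def in_gene_body(self, chrom: str, point: int) -> bool:
        tree = self._body.get(chrom)
        return tree is not None and bool(tree.overlaps(point, point + 1))


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style TSV: gene_id, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 fields")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            tx_start, tx_end = int(fields[3]), int(fields[4])
            exons: tuple[tuple[int, int], ...] = ()
            if len(fields) >= 7 and fields[5]:
                starts = [int(x) for x in fields[5].rstrip(",").split(",")]
                ends = [int(x) for x in fields[6].rstrip(",").split(",")]
                exons = tuple(zip(starts, ends))
            try:
                genes.append(
                    GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}"
                f"\t{g.tx_end}\t{starts}\t{ends}\n"
            )


def nearest_tss(peak: GenomicInterval,
                genes: Sequence[GeneModel] | GeneIndex) -> tuple[str | None, int | None]:
    """Nearest gene by TSS distance from the peak midpoint.

    Returns (None, None) when no gene lies on the peak's chromosome —
    reported downstream as intergenic rather than raised.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hit = index.nearest_tss(peak.chrom, peak_center(peak))
    if hit is None:
        return None, None
    return hit


def bin_distance(d: int | None) -> str:
    """Absolute-distance bin with half-open boundaries at 1/10/100 kb.

    An undefined distance (no gene on the chromosome) is counted in the
    open-ended ">100kb" bin.
    """
    if d is None:
        return ">100kb"
    a = abs(d)
    if a < 1_000:
        return "<1kb"
    if a < 10_000:
        return "1-10kb"
    if a < 100_000:
        return "10-100kb"
    return ">100kb"


def classify_context(peak: GenomicInterval,
                     genes: Sequence[GeneModel] | GeneIndex) -> str:
    """promoter / exon / intron / intergenic with stated precedence.

    Promoter: midpoint within 1 kb of the nearest TSS.  Otherwise exon if
    the midpoint lies in any annotated exon, intron if inside a gene body
    but not an exon, else intergenic.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    center = peak_center(peak)
    hit = index.nearest_tss(peak.chrom, center)
    if hit is not None and abs(hit[1]) < PROMOTER_RADIUS:
        return "promoter"
    if index.in_exon(peak.chrom, center):
        return "exon"
    if index.in_gene_body(peak.chrom, center):
        return "intron"
    return "intergenic"


def annotate_peaks(peaks: PeakSet,
                   genes: Sequence[GeneModel] | GeneIndex) -> list[LocationAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    annos = []
    for iv in peaks:
        gene_id, signed = nearest_tss(iv, index)
        annos.append(
            LocationAnnotation(
                peak=iv,
                nearest_gene=gene_id,
                signed_distance=signed,
                distance_bin=bin_distance(signed),
                context=classify_context(iv, index),
            )
        )
    return annos


def location_summary(peaks: PeakSet,
                     genes: Sequence[GeneModel] | GeneIndex) -> LocationSummary:
    """Distance-bin fractions plus the separate genic/intronic partition."""
    if len(peaks) == 0:
        raise ValueError("location_summary requires a non-empty peak set")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    annos = annotate_peaks(peaks, index)
    n = len(annos)
    bins = Counter(a.distance_bin for a in annos)
    contexts = Counter(a.context for a in annos)
    genic = 0
    intronic = 0
    for a in annos:
        center = peak_center(a.peak)
        if index.in_gene_body(a.peak.chrom, center):
            genic += 1
            if not index.in_exon(a.peak.chrom, center):
                intronic += 1
    return LocationSummary(
        n_peaks=n,
        bin_fractions={b: bins.get(b, 0) / n for b in DISTANCE_BINS},
        genic_fraction=genic / n,
        intron_share_of_genic=(intronic / genic) if genic else 0.0,
        context_fractions={
            c: contexts.get(c, 0) / n
            for c in ("promoter", "exon", "intron", "intergenic")
        },
    )


def target_genes(annos: Iterable[LocationAnnotation]) -> tuple[set[str], set[str]]:
    """Distinct nearest genes and the subset hit by >=2 peaks."""
    counts: Counter[str] = Counter(
        a.nearest_gene for a in annos if a.nearest_gene is not None
    )
    distinct = set(counts)
    multi = {g for g, c in counts.items() if c >= 2}
    return distinct, multi


def top_regions(peaks: PeakSet, n: int = 5000) -> PeakSet:
    """Top-n peaks by score for export to external annotation tools."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return peaks.top(min(n, len(peaks)))
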