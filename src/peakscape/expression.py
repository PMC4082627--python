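"""Differential-expression filtering and binding integration.

A knockdown DE table (gene, fold change, FDR) is partitioned into
up / down / unchanged with symmetric fold-change cutoffs (fc >= c or
fc <= 1/c) plus an FDR threshold, then intersected with bound-gene sets
to produce the bound/unbound x up/down partition and its integer
percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DERecord",
    "DEPartition",
    "IntegrationSummary",
    "read_de_table",
    "filter_de",
    "integrate",
    "percent",
    "co_bound",
]


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression call (knockdown vs control)."""

    gene_id: str
    fold_change: float  # expression ratio knockdown/control, > 0
    fdr: float          # q-value in [0, 1]

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(
                f"{self.gene_id}: fold change must be > 0, "
                f"got {self.fold_change}"
            )
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(
                f"{self.gene_id}: fdr must be in [0,1], got {self.fdr}"
            )


@dataclass
class DEPartition:
    """Exhaustive, exclusive direction partition of a DE table."""

    up: set[str]
    down: set[str]
    unchanged: set[str]
    fc_cutoff: float
    fdr_cutoff: float

    @property
    def n_de(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self, gene_id: str) -> str:
        if gene_id in self.up:
            return "up"
        if gene_id in self.down:
            return "down"
        if gene_id in self.unchanged:
            return "unchanged"
        raise KeyError(gene_id)


def read_de_table(path: str | Path) -> list[DERecord]:
    """TSV with header (gene_id, fold_change, fdr)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fold_change", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DERecord(str(r.gene_id), float(r.fold_change), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def filter_de(records: Iterable[DERecord], fc_cutoff: float = 1.25,
              fdr_cutoff: float = 1e-4) -> DEPartition:
    """Assign every gene exactly one direction.

    up: fc >= fc_cutoff and fdr < fdr_cutoff; down: fc <= 1/fc_cutoff and
    fdr < fdr_cutoff; unchanged otherwise.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must be > 1")
    up, down, unchanged = set(), set(), set()
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if rec.fdr < fdr_cutoff and rec.fold_change >= fc_cutoff:
            up.add(rec.gene_id)
        elif rec.fdr < fdr_cutoff and rec.fold_change <= 1.0 / fc_cutoff:
            down.add(rec.gene_id)
        else:
            unchanged.add(rec.gene_id)
    return DEPartition(up=up, down=down, unchanged=unchanged,
                       fc_cutoff=fc_cutoff, fdr_cutoff=fdr_cutoff)


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class BoundSplit:
    """Direction split of the DE genes bound by one factor set."""

    n_de_bound: int
    n_bound_up: int
    n_bound_down: int
    pct_de_bound: int | None   # of all DE genes
    pct_bound_up: int | None   # of bound DE genes
    pct_bound_down: int | None

    def to_dict(self) -> dict:
        return {
            "n_de_bound": self.n_de_bound,
            "n_bound_up": self.n_bound_up,
            "n_bound_down": self.n_bound_down,
            "pct_de_bound": self.pct_de_bound,
            "pct_bound_up": self.pct_bound_up,
            "pct_bound_down": self.pct_bound_down,
        }


@dataclass
class IntegrationSummary:
    n_de_total: int
    n_up: int
    n_down: int
    per_set: dict[str, BoundSplit] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_de_total": self.n_de_total,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "per_set": {k: v.to_dict() for k, v in self.per_set.items()},
        }


def co_bound(bound_sets: Mapping[str, set[str]], *names: str) -> set[str]:
    """Genes bound by every one of the named factors."""
    out: set[str] | None = None
    for name in names:
        s = set(bound_sets[name])
        out = s if out is None else out & s
    return out or set()


def integrate(de: DEPartition,
              bound_sets: Mapping[str, set[str]]) -> IntegrationSummary:
    """Intersect the DE partition with bound-gene sets.

    Pass combination sets (e.g. genes co-bound by two factors, via
    :func:`co_bound`) as additional entries of ``bound_sets`` to get their
    splits too.
    """
    summary = IntegrationSummary(
        n_de_total=de.n_de, n_up=len(de.up), n_down=len(de.down)
    )
    for name, genes in bound_sets.items():
        genes = set(genes)
        bound_up = de.up & genes
        bound_down = de.down & genes
        n_bound = len(bound_up) + len(bound_down)
        summary.per_set[name] = BoundSplit(
            n_de_bound=n_bound,
            n_bound_up=len(bound_up),
            n_bound_down=len(bound_down),
            pct_de_bound=percent(n_bound, de.n_de) if de.n_de else None,
            pct_bound_up=percent(len(bound_up), n_bound) if n_bound else None,
            pct_bound_down=(
                percent(len(bound_down), n_bound) if n_bound else None
            ),
        )
    return summary
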