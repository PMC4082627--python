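"""Factor x factor colocalization matrix and correlation-distance clustering.

Entry (i, j) of the co-association matrix is the colocalization frequency
of factor i at factor j's peaks: the fraction of j's peaks coinciding
with an i peak, either by >=1 bp overlap or by peak centers within a
window.  Rows are clustered hierarchically with a Pearson-correlation
distance (1 - r) and average linkage, recovering groups of factors with
shared binding landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .intervals import PeakSet, count_overlapping, peak_center

__all__ = [
    "CoassocMatrix",
    "ClusterResult",
    "colocalization_frequency",
    "coassoc_matrix",
    "correlation_cluster",
]


@dataclass
class CoassocMatrix:
    factors: list[str]
    values: np.ndarray  # square, entries in [0,1]; not necessarily symmetric

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values, index=self.factors, columns=self.factors
        ).to_csv(path, sep="\t")


def colocalization_frequency(a: PeakSet, b: PeakSet,
                             mode: str = "overlap",
                             window: int = 1000) -> float:
    """Fraction of B's peaks coinciding with A.

    mode="overlap": fraction of B's peaks overlapping (>=1 bp) any A peak.
    mode="window": fraction of B's peaks with an A peak center within
    +/-window bp of B's center.
    """
    if len(b) == 0:
        raise ValueError("colocalization_frequency requires non-empty B")
    if mode == "overlap":
        return count_overlapping(b, a) / len(b)
    if mode == "window":
        centers: dict[str, np.ndarray] = {}
        for iv in a:
            centers.setdefault(iv.chrom, []).append(peak_center(iv))
        centers = {c: np.sort(np.array(v)) for c, v in centers.items()}
        n = 0
        for iv in b:
            pos = centers.get(iv.chrom)
            if pos is None or len(pos) == 0:
                continue
            c = peak_center(iv)
            i = int(np.searchsorted(pos, c))
            near = min(
                (abs(c - int(pos[j])) for j in (i - 1, i) if 0 <= j < len(pos)),
                default=None,
            )
            if near is not None and near <= window:
                n += 1
        return n / len(b)
    raise ValueError(f"unknown mode {mode!r}")


def coassoc_matrix(sets: Sequence[PeakSet], mode: str = "overlap",
                   window: int = 1000) -> CoassocMatrix:
    """Full pairwise colocalization matrix over the given factors."""
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            values[i, j] = colocalization_frequency(
                sets[i], sets[j], mode=mode, window=window
            )
    return CoassocMatrix(factors=[s.factor for s in sets], values=values)


@dataclass
class ClusterResult:
    """Hierarchical clustering of co-association rows."""

    factors: list[str]         # row order used for the linkage (sorted)
    linkage: np.ndarray        # scipy linkage matrix
    leaf_order: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.factors[node.id]
            return (
                f"({rec(node.get_left())},{rec(node.get_right())})"
                f":{node.dist:.6g}"
            )

        return rec(tree) + ";"

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node of the merge tree."""
        tree = hierarchy.to_tree(self.linkage)
        out: list[frozenset[str]] = []

        def rec(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.factors[node.id]])
            leaves = rec(node.get_left()) | rec(node.get_right())
            out.append(leaves)
            return leaves

        rec(tree)
        return out


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson(r) distances; constant rows get distance 1."""
    n = values.shape[0]
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    for i in range(n):
        if sd[i] == 0:
            dist[i, :] = 1.0
            dist[:, i] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(dist[i, j])
    return np.array(cond)


def correlation_cluster(m: CoassocMatrix,
                        linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of matrix rows, distance = 1 - Pearson r.

    Factors are ordered lexicographically before linkage so the result is
    deterministic regardless of input order (the documented tie-break).
    """
    if len(m.factors) < 2:
        raise ValueError("need at least 2 factors to cluster")
    order = np.argsort(np.array(m.factors, dtype=object))
    factors = [m.factors[i] for i in order]
    values = m.values[np.ix_(order, order)]
    cond = _correlation_distance(values)
    z = hierarchy.linkage(cond, method=linkage)
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(
        factors=factors,
        linkage=z,
        leaf_order=[factors[i] for i in leaves],
    )
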