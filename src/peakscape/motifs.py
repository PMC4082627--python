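"""Position-weight-matrix construction, scanning, and positional density.

PWMs are built from IUPAC consensus strings (probability mass split
uniformly over each code's allowed bases, then mixed with a uniform
background pseudocount).  Scanning scores every window on both strands
with log2 odds against the background and keeps windows reaching a
fraction of the maximum achievable score.  Per-peak occurrence is binary
(>=1 hit in the central window), matching how motif fractions of binding
sites are reported; hit offsets relative to peak centers give the
positional density profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import PeakSet, peak_center

__all__ = [
    "PWM",
    "MotifHit",
    "GenomeSource",
    "consensus_to_pwm",
    "scan_sequence",
    "scan_peaks",
    "motif_fraction",
    "motif_density",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass
class PWM:
    """Per-position base-probability matrix with a background model."""

    motif_id: str
    matrix: np.ndarray                     # shape (L, 4), rows sum to 1
    background: np.ndarray = None          # shape (4,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM probabilities must be > 0 (pseudocounted)")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, _COMPLEMENT_PERM].copy(),
            background=self.background[_COMPLEMENT_PERM].copy(),
        )

    def write(self, path: str | Path) -> None:
        """JASPAR-style probability matrix text (4 rows A/C/G/T)."""
        with open(path, "w") as fh:
            fh.write(f">{self.motif_id}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in self.matrix[:, i])
                fh.write(f"{base} [ {vals} ]\n")

    @classmethod
    def read(cls, path: str | Path) -> "PWM":
        motif_id = Path(path).stem
        rows = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    motif_id = line[1:].strip() or motif_id
                    continue
                base, rest = line.split(None, 1)
                vals = rest.strip().lstrip("[").rstrip("]").split()
                rows[base] = [float(v) for v in vals]
        matrix = np.column_stack([rows[b] for b in "ACGT"])
        return cls(motif_id=motif_id, matrix=matrix)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, positioned relative to its peak's center."""

    peak_index: int
    offset: int     # hit start minus peak center, bp (signed)
    strand: str
    score: float


def consensus_to_pwm(iupac: str, motif_id: str | None = None,
                     pseudocount: float = 0.02) -> PWM:
    """PWM from an IUPAC consensus string.

    Each position splits probability uniformly over the code's allowed
    bases, then mixes in a uniform-background pseudocount:
    p = (1 - pseudocount) * p0 + pseudocount * 0.25.  For a two-fold
    degenerate code (e.g. S) this yields 0.495 for each allowed base and
    0.005 for each disallowed one.
    """
    iupac = iupac.upper()
    if not iupac:
        raise ValueError("consensus string must be non-empty")
    rows = []
    for ch in iupac:
        allowed = IUPAC.get(ch)
        if allowed is None:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        p0 = np.zeros(4)
        for b in allowed:
            p0[_BASE_INDEX[b]] = 1.0 / len(allowed)
        rows.append((1.0 - pseudocount) * p0 + pseudocount * 0.25)
    return PWM(motif_id=motif_id or iupac, matrix=np.vstack(rows))


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(codes.shape, 4, dtype=np.int8)   # 4 = N / unknown
    for base, idx in _BASE_INDEX.items():
        out[codes == ord(base)] = idx
    return out


def _scan_one_strand(codes: np.ndarray, log_odds: np.ndarray,
                     threshold: float) -> tuple[np.ndarray, np.ndarray]:
    length = log_odds.shape[0]
    if codes.size < length:
        return np.empty(0, dtype=np.int64), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = (windows < 4).all(axis=1)
    safe = np.where(windows < 4, windows, 0)
    scores = log_odds[np.arange(length)[None, :], safe].sum(axis=1)
    keep = valid & (scores >= threshold)
    return np.nonzero(keep)[0], scores[keep]


def scan_sequence(seq: str, pwm: PWM,
                  threshold_frac: float = 0.8) -> list[tuple[int, str, float]]:
    """All windows (both strands) scoring >= threshold_frac * max score.

    Positions are 0-based window starts on the forward sequence; windows
    containing N are skipped.  A reverse-strand hit at position p means
    the reverse complement of the motif matches the forward sequence
    there.
    """
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must be in (0, 1]")
    codes = _encode(seq)
    threshold = threshold_frac * pwm.max_score()
    hits: list[tuple[int, str, float]] = []
    fwd_pos, fwd_scores = _scan_one_strand(codes, pwm.log_odds(), threshold)
    for p, s in zip(fwd_pos, fwd_scores):
        hits.append((int(p), "+", float(s)))
    rev_pos, rev_scores = _scan_one_strand(
        codes, pwm.reverse_complement().log_odds(), threshold
    )
    for p, s in zip(rev_pos, rev_scores):
        hits.append((int(p), "-", float(s)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


class GenomeSource:
    """Uniform sequence access over a pyfaidx FASTA or an in-memory dict.

    Requests beyond chromosome bounds are padded with N so every peak
    yields a window of the requested width.
    """

    def __init__(self, source):
        self._source = source

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSource":
        from pyfaidx import Fasta

        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._source:
            raise KeyError(f"no sequence for chromosome {chrom!r}")
        record = self._source[chrom]
        lo, hi = max(start, 0), min(end, len(record))
        body = str(record[lo:hi]).upper()
        return "N" * (lo - start) + body + "N" * (end - hi)


def scan_peaks(peaks: PeakSet, genome: GenomeSource, pwm: PWM,
               half_window: int = 500,
               threshold_frac: float = 0.8) -> list[MotifHit]:
    """Scan +/-half_window around every peak center; offsets are signed
    hit starts relative to the center."""
    hits: list[MotifHit] = []
    for i, iv in enumerate(peaks):
        center = peak_center(iv)
        try:
            seq = genome.fetch(iv.chrom, center - half_window,
                               center + half_window)
        except KeyError as exc:
            raise ValueError(f"missing sequence for peak {i} ({iv.chrom}:"
                             f"{iv.start}-{iv.end})") from exc
        for pos, strand, score in scan_sequence(seq, pwm, threshold_frac):
            hits.append(
                MotifHit(peak_index=i, offset=pos - half_window,
                         strand=strand, score=score)
            )
    return hits


def motif_fraction(peaks: PeakSet, genome: GenomeSource, pwm: PWM,
                   window: int = 200,
                   threshold_frac: float = 0.8) -> float:
    """Fraction of peaks with >=1 hit in the central `window` bp."""
    if window % 2 != 0:
        raise ValueError("window must be even")
    if len(peaks) == 0:
        raise ValueError("motif_fraction requires a non-empty peak set")
    half = window // 2
    n_hit = 0
    for i, iv in enumerate(peaks):
        center = peak_center(iv)
        try:
            seq = genome.fetch(iv.chrom, center - half, center + half)
        except KeyError as exc:
            raise ValueError(f"missing sequence for peak {i} ({iv.chrom}:"
                             f"{iv.start}-{iv.end})") from exc
        if scan_sequence(seq, pwm, threshold_frac):
            n_hit += 1
    return n_hit / len(peaks)


def motif_density(hits: Iterable[MotifHit], half_window: int = 500,
                  bin: int = 20) -> np.ndarray:
    """Histogram of hit offsets over [-half_window, half_window),
    normalized to sum to 1 (zero vector when there are no hits)."""
    if (2 * half_window) % bin != 0:
        raise ValueError("bin must divide the full window span")
    n_bins = 2 * half_window // bin
    offsets = np.array([h.offset for h in hits], dtype=np.float64)
    counts, _ = np.histogram(
        offsets, bins=n_bins, range=(-half_window, half_window)
    )
    total = counts.sum()
    if total == 0:
        return np.zeros(n_bins)
    return counts / total
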