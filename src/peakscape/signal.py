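"""Coverage profiles around peak centers and chromatin-state clustering.

Signal is modeled with bedGraph semantics: piecewise-constant per-base
coverage, zero where uncovered.  Profile matrices hold mean signal in
fixed-width bins across a +/-W window centered on each peak midpoint; they
feed heatmaps, average enrichment profiles, and the two-state
promoter-like vs enhancer-like k-means clustering of histone-mark signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import PeakSet, peak_center

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "StateAssignment",
    "BedGraphParseError",
    "read_bedgraph",
    "write_bedgraph",
    "window_signal",
    "profile_matrix",
    "average_profile",
    "cluster_states",
]


class BedGraphParseError(ValueError):
    """Raised for malformed bedGraph input (overlaps, negative values)."""


@dataclass
class SignalTrack:
    """Sorted, non-overlapping (chrom, start, end, value) segments."""

    track_id: str
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, values), sorted by start

    @classmethod
    def from_segments(
        cls, track_id: str,
        segments: Iterable[tuple[str, int, int, float]],
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if start >= end:
                raise BedGraphParseError(
                    f"segment start must be < end: {chrom}:{start}-{end}"
                )
            if value < 0 or not np.isfinite(value):
                raise BedGraphParseError(
                    f"segment value must be finite and >= 0: {value}"
                )
            by_chrom.setdefault(chrom, []).append((start, end, value))
        packed = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise BedGraphParseError(
                    f"overlapping segments on {chrom}"
                )
            packed[chrom] = (starts, ends, values)
        return cls(track_id=track_id, segments=packed)

    def n_segments(self) -> int:
        return sum(len(s) for s, _, _ in self.segments.values())


def read_bedgraph(path: str | Path, track_id: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping segments are rejected."""
    path = Path(path)
    segs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedGraphParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphParseError(f"{path}:{lineno}: {exc}") from exc
            if value < 0:
                raise BedGraphParseError(
                    f"{path}:{lineno}: negative value {value}"
                )
            segs.append((fields[0], start, end, value))
    try:
        return SignalTrack.from_segments(track_id or path.stem, segs)
    except BedGraphParseError as exc:
        raise BedGraphParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def window_signal(track: SignalTrack, chrom: str, center: int,
                  w: int = 2000, b: int = 50) -> np.ndarray:
    """Mean per-base signal in 2W/B bins over [center-W, center+W).

    Bin j covers [center-W+jB, center-W+(j+1)B).  Positions outside the
    covered genome (including windows extending past position 0) take
    value 0, so every window yields a full-length vector.
    """
    if (2 * w) % b != 0:
        raise ValueError(f"bin width {b} must divide window span {2 * w}")
    win_start = center - w
    base = np.zeros(2 * w, dtype=np.float64)
    entry = track.segments.get(chrom)
    if entry is not None:
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, win_start, side="right"))
        hi = int(np.searchsorted(starts, center + w, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]) - win_start, 0)
            e = min(int(ends[i]) - win_start, 2 * w)
            if s < e:
                base[s:e] = values[i]
    return base.reshape(-1, b).mean(axis=1)


@dataclass
class ProfileMatrix:
    """Peaks x position-bins matrix of mean signal around peak centers."""

    values: np.ndarray  # shape (n_peaks, 2W/B)
    w: int
    b: int
    track_id: str

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        cols = [str(-self.w + j * self.b) for j in range(self.n_bins)]
        pd.DataFrame(self.values, columns=cols).to_csv(
            path, sep="\t", index=False
        )


def profile_matrix(track: SignalTrack, peaks: PeakSet,
                   w: int = 2000, b: int = 50) -> ProfileMatrix:
    """Row i = binned window signal at peak i's midpoint."""
    rows = [
        window_signal(track, iv.chrom, peak_center(iv), w=w, b=b)
        for iv in peaks
    ]
    values = (
        np.vstack(rows) if rows else np.zeros((0, 2 * w // b))
    )
    return ProfileMatrix(values=values, w=w, b=b, track_id=track.track_id)


def average_profile(m: ProfileMatrix) -> np.ndarray:
    """Column means over peaks — the average enrichment profile."""
    if m.n_peaks == 0:
        raise ValueError("average_profile requires at least one row")
    return m.values.mean(axis=0)


@dataclass
class StateAssignment:
    """Two-state chromatin classification of peaks.

    Cluster "I" is, by convention, the state with the higher mean
    promoter-mark (H3K4me3) feature — promoter-like — and "II" the
    enhancer-like remainder.
    """

    labels: list[str]
    features: np.ndarray          # peaks x marks, log1p + z-scored
    marks: list[str]
    cluster_means: dict[str, dict[str, float]]  # label -> mark -> mean feature


def _central_mean(m: ProfileMatrix, half: int) -> np.ndarray:
    n_half_bins = max(half // m.b, 1)
    mid = m.n_bins // 2
    lo = max(mid - n_half_bins, 0)
    hi = min(mid + n_half_bins, m.n_bins)
    return m.values[:, lo:hi].mean(axis=1)


def cluster_states(matrices: Mapping[str, ProfileMatrix],
                   promoter_mark: str = "H3K4me3",
                   k: int = 2, seed: int = 0,
                   central_half: int = 500) -> StateAssignment:
    """k-means (k=2) on per-mark central signal, labeled I/II.

    Per-peak features are the mean signal over the central +/-500 bp for
    each mark, log(1+x)-transformed and z-scored per mark.  Ten k-means
    restarts with a fixed seed keep the assignment deterministic; the
    cluster with the higher mean promoter-mark feature is labeled "I".
    """
    if k != 2:
        raise ValueError("only k=2 chromatin states are supported")
    if promoter_mark not in matrices:
        raise ValueError(f"promoter mark {promoter_mark!r} not among matrices")
    marks = list(matrices)
    shapes = {m: matrices[m].values.shape for m in marks}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"profile matrices disagree in shape: {shapes}")
    feats = np.column_stack(
        [_central_mean(matrices[m], central_half) for m in marks]
    )
    feats = np.log1p(feats)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(feats)
    pm_col = marks.index(promoter_mark)
    mean0 = feats[raw == 0, pm_col].mean() if np.any(raw == 0) else -np.inf
    mean1 = feats[raw == 1, pm_col].mean() if np.any(raw == 1) else -np.inf
    cluster_I = 0 if mean0 >= mean1 else 1
    labels = ["I" if r == cluster_I else "II" for r in raw]
    cluster_means = {}
    for label in ("I", "II"):
        mask = np.array([l == label for l in labels])
        cluster_means[label] = {
            m: float(feats[mask, i].mean()) if mask.any() else float("nan")
            for i, m in enumerate(marks)
        }
    return StateAssignment(
        labels=labels, features=feats, marks=marks,
        cluster_means=cluster_means,
    )


def save_heatmap(m: ProfileMatrix, path: str | Path,
                 order: Sequence[int] | None = None) -> None:
    """Render the profile matrix as a heatmap image (requires matplotlib).

    Rows are ordered by descending total signal unless an explicit order
    is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = m.values
    if order is None:
        order = np.argsort(-values.sum(axis=1))
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(values[np.asarray(order)], aspect="auto", cmap="Reds",
              interpolation="nearest")
    ax.set_xlabel(f"position bin ({m.b} bp, +/-{m.w} bp)")
    ax.set_ylabel("peaks")
    ax.set_title(m.track_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
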