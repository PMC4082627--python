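"""Ground-truth-annotated synthetic cistrome generator.

Emulates the statistical structure of a multi-factor ChIP-seq / RNA-seq
study on a small synthetic genome: a reference factor binding mostly
distal to TSSs with a configurable TSS-distance mix, partner factors
sharing an exact fraction of the reference sites (coordinate reuse
guarantees overlap), replicate peak lists with score jitter and site
dropout, Gaussian-bump histone-mark coverage separating promoter-like
from enhancer-like sites, motif instances planted near peak centers in a
random genome, and a knockdown differential-expression table enriched for
bound genes.

All planted fractions use exact allocation — round(p*n) items drawn
uniformly without replacement — so recovery tests compare against the
configured value up to rounding rather than binomial noise.  A single
seeded generator drives every draw; identical configs produce
byte-identical output bundles.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, PeakSet, write_bed
from .signal import SignalTrack, write_bedgraph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticBundle",
    "generate",
    "plant_cooccupancy",
    "simulate_signal",
]

DISTANCE_BIN_RANGES = {
    "<1kb": (0, 1_000),
    "1-10kb": (1_000, 10_000),
    "10-100kb": (10_000, 100_000),
    ">100kb": (100_000, 400_000),
}
BIN_ORDER = ("<1kb", "1-10kb", "10-100kb", ">100kb")

# Relative bump amplitude of each histone mark in each chromatin state.
MARK_PROFILES = {
    "promoter": {"H3K4me3": 1.0, "H3K27ac": 0.5, "H3K4me1": 0.2},
    "enhancer": {"H3K4me3": 0.0, "H3K27ac": 0.8, "H3K4me1": 1.0},
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle (seed-deterministic)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 400
    n_sites: int = 2000
    site_halfwidth: int = 150
    # center-to-center spacing floors; reference sites are spread further
    # apart so histone bumps at neighbouring sites barely interact
    min_center_dist: int = 600
    ref_min_center_dist: int = 1200
    location_mix: tuple[float, float, float, float] = (0.07, 0.15, 0.52, 0.26)
    factors: tuple[str, ...] = ("ZNF217", "ERalpha", "GATA3", "FOXA1")
    cooccupancy: dict[str, float] = field(
        default_factory=lambda: {"ERalpha": 0.41, "GATA3": 0.34, "FOXA1": 0.31}
    )
    replicate_dropout: float = 0.10
    replicate_score_sd: float = 0.10
    marks: tuple[str, ...] = ("H3K4me3", "H3K27ac", "H3K4me1")
    promoter_mark: str = "H3K4me3"
    signal_height: float = 10.0
    signal_height_sd: float = 0.25
    signal_width: float = 150.0
    background_rate: float = 0.2
    background_block: int = 500
    signal_resolution: int = 20
    motif_consensus: str = "TGASTCAY"
    motif_plant_fraction: float = 0.30
    motif_offset_sd: float = 50.0
    motif_offset_max: int = 90
    de_frac_bound: float = 0.36
    de_frac_unbound: float = 0.08
    de_up_bias_bound: float = 0.62
    de_up_bias_unbound: float = 0.50
    de_fc_cutoff: float = 1.25
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if abs(sum(self.location_mix) - 1.0) > 1e-9:
            raise ValueError("location_mix must sum to 1")
        for name, frac in self.cooccupancy.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"cooccupancy[{name}] out of [0,1]")
        if not 0.0 <= self.replicate_dropout < 1.0:
            raise ValueError("replicate_dropout must be in [0,1)")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """What was planted, site by site and gene by gene."""

    config: SyntheticConfig
    sites: dict[str, list[tuple[str, int, int, float]]]
    signatures: list[tuple[str, ...]]        # per reference site
    location_bins: list[str]                 # per reference site
    states: list[str]                        # promoter / enhancer
    motif_planted: list[bool]                # per reference site
    motif_offsets: list[int | None]          # hit-start offset vs center
    bound_genes: dict[str, list[str]]
    de_direction: dict[str, str]             # gene -> up/down/unchanged

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "sites": self.sites,
            "signatures": [list(s) for s in self.signatures],
            "location_bins": self.location_bins,
            "states": self.states,
            "motif_planted": self.motif_planted,
            "motif_offsets": self.motif_offsets,
            "bound_genes": self.bound_genes,
            "de_direction": self.de_direction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=None, separators=(",", ":"))


@dataclass
class SyntheticBundle:
    """Paths of the emitted files plus the planted truth."""

    outdir: Path
    genome_fasta: Path
    gene_table: Path
    peak_beds: dict[str, Path]
    replicate_beds: dict[str, tuple[Path, Path]]
    signal_bedgraphs: dict[str, Path]
    de_table: Path
    truth_json: Path
    truth: GroundTruth


class _Registry:
    """Per-chromosome sorted site centers with a minimum-spacing check."""

    def __init__(self, chroms: list[str]):
        self._centers: dict[str, list[int]] = {c: [] for c in chroms}

    def fits(self, chrom: str, center: int, min_dist: int) -> bool:
        lst = self._centers[chrom]
        i = bisect.bisect_left(lst, center)
        for j in (i - 1, i):
            if 0 <= j < len(lst) and abs(lst[j] - center) < min_dist:
                return False
        return True

    def add(self, chrom: str, center: int) -> None:
        bisect.insort(self._centers[chrom], center)


def _exact_count(frac: float, n: int) -> int:
    return int(math.floor(frac * n + 0.5))


def _allocate_bins(mix, n: int) -> list[int]:
    """Largest-remainder allocation of n items to the mix fractions."""
    raw = [f * n for f in mix]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# gene models


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator):
    """Clustered gene placement leaving TSS deserts between clusters.

    Genes sit in 8 clusters per chromosome (sd 40 kb around evenly spaced
    centers) so that positions >100 kb from every TSS exist — without
    deserts, the most distal binding-site class could not be planted.
    """
    from .annotation import GeneModel

    n_clusters = 8
    margin = 400_000
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes - sum(per_chrom)):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(cfg.chrom_names):
        centers = np.linspace(margin, cfg.chrom_length - margin, n_clusters)
        for k in range(per_chrom[ci]):
            cluster = centers[k % n_clusters]
            tss = int(round(cluster + rng.normal(0.0, 40_000.0)))
            tss = int(np.clip(tss, 100_000, cfg.chrom_length - 100_000))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(5_000, 60_000))
            if strand == "+":
                tx_start = tss
                tx_end = min(tss + length, cfg.chrom_length)
            else:
                tx_end = tss + 1
                tx_start = max(tx_end - length, 0)
            n_ex = int(rng.integers(2, 9))
            span = tx_end - tx_start
            block = span // n_ex
            exons = []
            for e in range(n_ex):
                # short exons within long introns, as in real gene bodies
                b0 = tx_start + e * block
                s = b0 + int(rng.integers(0, max(block // 2, 1)))
                ln = int(rng.integers(100, 400))
                exons.append((s, min(s + ln, b0 + block)))
            gid += 1
            genes.append(
                GeneModel(f"G{gid:04d}", chrom, strand, tx_start, tx_end,
                          tuple(exons))
            )
    return genes


def _tss_arrays(genes) -> dict[str, tuple[np.ndarray, list[str]]]:
    from .annotation import tss_of

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((tss_of(g), g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([p for p, _ in pairs], dtype=np.int64),
            [gid for _, gid in pairs],
        )
    return out


def _nearest(tss_arrays, chrom: str, point: int) -> tuple[str, int] | None:
    entry = tss_arrays.get(chrom)
    if entry is None:
        return None
    pos, ids = entry
    i = int(np.searchsorted(pos, point))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(pos):
            d = abs(point - int(pos[j]))
            cand = (d, ids[j])
            if best is None or cand < best:
                best = cand
    return (best[1], best[0]) if best else None


# ---------------------------------------------------------------------------
# site planting


def _plant_reference_sites(cfg: SyntheticConfig, rng: np.random.Generator,
                           genes, registry: _Registry):
    """Plant reference sites with an exact TSS-distance bin allocation."""
    tss = _tss_arrays(genes)
    counts = _allocate_bins(cfg.location_mix, cfg.n_sites)
    all_tss = [
        (chrom, int(p))
        for chrom in cfg.chrom_names
        for p in tss.get(chrom, (np.empty(0),))[0]
    ]
    sites: list[tuple[str, int]] = []
    bins: list[str] = []
    margin = cfg.site_halfwidth + 10
    for bin_name, n_bin in zip(BIN_ORDER, counts):
        lo, hi = DISTANCE_BIN_RANGES[bin_name]
        for _ in range(n_bin):
            placed = False
            for _try in range(500):
                chrom, anchor = all_tss[int(rng.integers(0, len(all_tss)))]
                if lo == 0:
                    d = int(rng.integers(0, hi))
                else:
                    d = int(round(math.exp(
                        rng.uniform(math.log(lo), math.log(hi))
                    )))
                side = 1 if rng.random() < 0.5 else -1
                center = anchor + side * d
                if not margin <= center <= cfg.chrom_length - margin:
                    continue
                hit = _nearest(tss, chrom, center)
                realized = hit[1] if hit else None
                lo_r, hi_r = DISTANCE_BIN_RANGES[bin_name]
                if realized is None or not (
                    lo_r <= realized < (hi_r if bin_name != ">100kb"
                                        else 10**12)
                ):
                    continue
                if not registry.fits(chrom, center, cfg.ref_min_center_dist):
                    continue
                registry.add(chrom, center)
                sites.append((chrom, center))
                bins.append(bin_name)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {bin_name} site after 500 tries; "
                    "genome too crowded for the requested mix"
                )
    # shuffle so bin identity is not encoded in site order
    order = rng.permutation(len(sites))
    sites = [sites[i] for i in order]
    bins = [bins[i] for i in order]
    return sites, bins, tss


def plant_cooccupancy(ref_sites: list[tuple[str, int]],
                      cfg: SyntheticConfig, rng: np.random.Generator,
                      registry: _Registry):
    """Partner-factor site lists sharing exact fractions of the reference.

    Shared sites literally reuse reference coordinates (guaranteeing >=1 bp
    overlap); each partner is padded with unique sites placed away from
    every existing site, so each factor ends with ``n_sites`` sites and a
    realized directional sharing rate of round(p*n)/n.
    """
    n = len(ref_sites)
    factor_sites: dict[str, list[tuple[str, int]]] = {}
    shared_flags: dict[str, np.ndarray] = {}
    margin = cfg.site_halfwidth + 10
    for factor in cfg.factors[1:]:
        p = cfg.cooccupancy.get(factor, 0.0)
        k = _exact_count(p, n)
        chosen = rng.choice(n, size=k, replace=False) if k else np.empty(0, int)
        flags = np.zeros(n, dtype=bool)
        flags[np.asarray(chosen, dtype=int)] = True
        shared_flags[factor] = flags
        sites = [ref_sites[i] for i in np.flatnonzero(flags)]
        for _ in range(n - k):
            for _try in range(1000):
                chrom = cfg.chrom_names[int(rng.integers(0, cfg.n_chroms))]
                center = int(rng.integers(margin, cfg.chrom_length - margin))
                if registry.fits(chrom, center, cfg.min_center_dist):
                    registry.add(chrom, center)
                    sites.append((chrom, center))
                    break
            else:
                raise RuntimeError("could not place a unique partner site")
        factor_sites[factor] = sites
    signatures = [
        tuple(f for f in cfg.factors[1:] if shared_flags[f][i])
        for i in range(n)
    ]
    return factor_sites, signatures


def _sites_to_peakset(name: str, sites, scores, cfg: SyntheticConfig) -> PeakSet:
    intervals = [
        GenomicInterval(chrom, center - cfg.site_halfwidth,
                        center + cfg.site_halfwidth, score=float(s),
                        name=f"{name}_{i + 1}")
        for i, ((chrom, center), s) in enumerate(zip(sites, scores))
    ]
    return PeakSet(factor=name, intervals=intervals, genome_id=cfg.genome_id)


def _make_replicate(true_peaks: PeakSet, cfg: SyntheticConfig,
                    rng: np.random.Generator) -> PeakSet:
    """Drop an exact fraction of sites and jitter the scores."""
    n = len(true_peaks)
    n_drop = _exact_count(cfg.replicate_dropout, n)
    dropped = set(
        np.asarray(rng.choice(n, size=n_drop, replace=False), dtype=int)
    ) if n_drop else set()
    intervals = []
    for i, iv in enumerate(true_peaks):
        jitter = float(np.exp(rng.normal(0.0, cfg.replicate_score_sd)))
        if i in dropped:
            continue
        intervals.append(
            GenomicInterval(iv.chrom, iv.start, iv.end,
                            score=iv.score * jitter, name=iv.name)
        )
    return PeakSet(factor=true_peaks.factor, intervals=intervals,
                   genome_id=true_peaks.genome_id)


# ---------------------------------------------------------------------------
# signal


def simulate_signal(ref_sites, states, cfg: SyntheticConfig,
                    rng: np.random.Generator) -> dict[str, SignalTrack]:
    """Gaussian-bump coverage per histone mark over Poisson background.

    Promoter-state sites get promoter-mark (H3K4me3) bumps, enhancer-state
    sites H3K4me1/H3K27ac bumps; per-site amplitudes carry lognormal
    variation.  Tracks are discretized at ``signal_resolution`` bp.
    """
    res = cfg.signal_resolution
    n_bins = {c: cfg.chrom_length // res for c in cfg.chrom_names}
    arrays = {
        mark: {c: np.zeros(n_bins[c]) for c in cfg.chrom_names}
        for mark in cfg.marks
    }
    # Poisson background in coarse blocks
    block_bins = cfg.background_block // res
    for mark in cfg.marks:
        for chrom in cfg.chrom_names:
            n_blocks = n_bins[chrom] // block_bins
            vals = rng.poisson(cfg.background_rate, size=n_blocks).astype(float)
            arrays[mark][chrom][: n_blocks * block_bins] = np.repeat(
                vals, block_bins
            )
    # site bumps
    sd = cfg.signal_width
    reach = int(3 * sd)
    for (chrom, center), state in zip(ref_sites, states):
        mults = MARK_PROFILES[state]
        for mark in cfg.marks:
            amp_jitter = float(np.exp(rng.normal(0.0, cfg.signal_height_sd)))
            mult = mults.get(mark, 0.0)
            if mult == 0.0:
                continue
            amp = cfg.signal_height * mult * amp_jitter
            lo = max((center - reach) // res, 0)
            hi = min((center + reach) // res + 1, n_bins[chrom])
            x = (np.arange(lo, hi) * res + res / 2.0) - center
            arrays[mark][chrom][lo:hi] += amp * np.exp(
                -(x**2) / (2.0 * sd**2)
            )
    tracks = {}
    for mark in cfg.marks:
        segs = []
        for chrom in cfg.chrom_names:
            arr = np.round(arrays[mark][chrom], 3)
            change = np.nonzero(np.diff(arr))[0] + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v > 0:
                    segs.append((chrom, int(s) * res, int(e) * res, float(v)))
        tracks[mark] = SignalTrack.from_segments(mark, segs)
    return tracks


# ---------------------------------------------------------------------------
# genome sequence + motifs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _make_genome(cfg: SyntheticConfig, rng: np.random.Generator,
                 ref_sites) -> tuple[dict[str, np.ndarray], list[bool],
                                     list[int | None]]:
    codes = {
        chrom: rng.integers(0, 4, size=cfg.chrom_length, dtype=np.int8)
        for chrom in cfg.chrom_names
    }
    n = len(ref_sites)
    n_plant = _exact_count(cfg.motif_plant_fraction, n)
    chosen = set(
        np.asarray(rng.choice(n, size=n_plant, replace=False), dtype=int)
    ) if n_plant else set()
    consensus = cfg.motif_consensus.upper()
    length = len(consensus)
    planted = [False] * n
    offsets: list[int | None] = [None] * n
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, (chrom, center) in enumerate(ref_sites):
        if i not in chosen:
            continue
        raw = rng.normal(0.0, cfg.motif_offset_sd)
        off = int(np.clip(round(raw), -cfg.motif_offset_max,
                          cfg.motif_offset_max))
        instance = "".join(
            _IUPAC_CHOICES[ch][int(rng.integers(0, len(_IUPAC_CHOICES[ch])))]
            for ch in consensus
        )
        if rng.random() < 0.5:
            instance = "".join(_COMP[b] for b in reversed(instance))
        start = center + off - length // 2
        for k, b in enumerate(instance):
            codes[chrom][start + k] = base_idx[b]
        planted[i] = True
        offsets[i] = start - center
    return codes, planted, offsets


def _write_fasta(codes: dict[str, np.ndarray], path: Path,
                 width: int = 80) -> None:
    with open(path, "wb") as fh:
        for chrom in sorted(codes):
            fh.write(f">{chrom}\n".encode())
            seq = _BASES[codes[chrom].astype(np.intp)]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width].tobytes())
                fh.write(b"\n")


# ---------------------------------------------------------------------------
# differential expression


def _simulate_de(cfg: SyntheticConfig, rng: np.random.Generator,
                 gene_ids: list[str], bound: set[str]):
    """Assign exact DE fractions and direction biases, then emit
    (fold_change, q) pairs consistent with the planted direction."""
    bound_sorted = sorted(bound)
    unbound_sorted = sorted(set(gene_ids) - bound)
    direction: dict[str, str] = {g: "unchanged" for g in gene_ids}

    def assign(pool: list[str], frac_de: float, up_bias: float) -> None:
        n_de = _exact_count(frac_de, len(pool))
        if n_de == 0:
            return
        chosen = rng.choice(len(pool), size=n_de, replace=False)
        chosen = [pool[int(i)] for i in chosen]
        n_up = _exact_count(up_bias, n_de)
        for j, g in enumerate(chosen):
            direction[g] = "up" if j < n_up else "down"

    assign(bound_sorted, cfg.de_frac_bound, cfg.de_up_bias_bound)
    assign(unbound_sorted, cfg.de_frac_unbound, cfg.de_up_bias_unbound)

    records = []
    for g in gene_ids:
        d = direction[g]
        if d == "up":
            fc = cfg.de_fc_cutoff * math.exp(rng.exponential(0.4))
            q = 10.0 ** (-rng.uniform(4.05, 10.0))
        elif d == "down":
            fc = 1.0 / (cfg.de_fc_cutoff * math.exp(rng.exponential(0.4)))
            q = 10.0 ** (-rng.uniform(4.05, 10.0))
        else:
            fc = math.exp(rng.normal(0.0, 0.08))
            q = rng.uniform(0.0, 1.0)
        records.append((g, fc, q))
    return records, direction


# ---------------------------------------------------------------------------
# top-level generation


def generate(cfg: SyntheticConfig, outdir: str | Path) -> SyntheticBundle:
    """Write the full synthetic bundle and return paths plus ground truth.

    Emits: genome FASTA with planted motif instances, refFlat-style gene
    table, per-factor true/replicate BEDs, per-mark bedGraph signal, a DE
    TSV, and a ground-truth JSON.  Byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = _place_genes(cfg, rng)
    registry = _Registry(cfg.chrom_names)
    ref_sites, location_bins, tss = _plant_reference_sites(
        cfg, rng, genes, registry
    )
    states = ["promoter" if b == "<1kb" else "enhancer"
              for b in location_bins]
    factor_sites, signatures = plant_cooccupancy(ref_sites, cfg, rng, registry)

    ref_name = cfg.factors[0]
    all_sites = {ref_name: ref_sites, **factor_sites}
    peak_sets: dict[str, PeakSet] = {}
    for name in cfg.factors:
        scores = rng.lognormal(3.0, 1.0, size=len(all_sites[name]))
        peak_sets[name] = _sites_to_peakset(name, all_sites[name], scores, cfg)

    tracks = simulate_signal(ref_sites, states, cfg, rng)
    codes, motif_planted, motif_offsets = _make_genome(cfg, rng, ref_sites)

    # bound genes per factor: nearest gene of each true site
    bound_genes: dict[str, list[str]] = {}
    for name in cfg.factors:
        hit_genes = set()
        for chrom, center in all_sites[name]:
            hit = _nearest(tss, chrom, center)
            if hit is not None:
                hit_genes.add(hit[0])
        bound_genes[name] = sorted(hit_genes)

    gene_ids = [g.gene_id for g in genes]
    de_records, de_direction = _simulate_de(
        cfg, rng, gene_ids, set(bound_genes[ref_name])
    )

    # ------------------------------------------------------------------ write
    from .annotation import write_gene_table

    genome_fasta = outdir / "genome.fa"
    _write_fasta(codes, genome_fasta)
    gene_table = outdir / "genes.tsv"
    write_gene_table(genes, gene_table)

    peak_beds: dict[str, Path] = {}
    replicate_beds: dict[str, tuple[Path, Path]] = {}
    for name in cfg.factors:
        path = outdir / f"{name}.bed"
        write_bed(peak_sets[name].sorted_by_position(), path)
        peak_beds[name] = path
        rep_a = _make_replicate(peak_sets[name], cfg, rng)
        rep_b = _make_replicate(peak_sets[name], cfg, rng)
        pa = outdir / f"{name}_repA.bed"
        pb = outdir / f"{name}_repB.bed"
        write_bed(rep_a.sorted_by_position(), pa)
        write_bed(rep_b.sorted_by_position(), pb)
        replicate_beds[name] = (pa, pb)

    signal_bedgraphs: dict[str, Path] = {}
    for mark, track in tracks.items():
        path = outdir / f"{mark}.bedgraph"
        write_bedgraph(track, path)
        signal_bedgraphs[mark] = path

    de_table = outdir / "de_table.tsv"
    with open(de_table, "w") as fh:
        fh.write("gene_id\tfold_change\tfdr\n")
        for g, fc, q in de_records:
            fh.write(f"{g}\t{fc:.6g}\t{q:.6g}\n")

    truth = GroundTruth(
        config=cfg,
        sites={
            name: [
                (iv.chrom, iv.start, iv.end, iv.score)
                for iv in peak_sets[name]
            ]
            for name in cfg.factors
        },
        signatures=signatures,
        location_bins=location_bins,
        states=states,
        motif_planted=motif_planted,
        motif_offsets=motif_offsets,
        bound_genes=bound_genes,
        de_direction=de_direction,
    )
    truth_json = outdir / "ground_truth.json"
    truth.to_json(truth_json)

    return SyntheticBundle(
        outdir=outdir,
        genome_fasta=genome_fasta,
        gene_table=gene_table,
        peak_beds=peak_beds,
        replicate_beds=replicate_beds,
        signal_bedgraphs=signal_bedgraphs,
        de_table=de_table,
        truth_json=truth_json,
        truth=truth,
    )
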