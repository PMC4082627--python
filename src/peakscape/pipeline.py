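"""Config-driven orchestration of the full cistrome analysis.

Stages run in a fixed order — replicate QC -> merge -> location annotation
-> signal profiling / chromatin-state clustering -> motif analysis ->
co-association -> expression integration — each writing its own TSV/JSON
artifacts plus one versioned summary JSON.  A missing DE table downgrades
the integration stage to a logged warning; everything else still runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import annotation, coassociation, expression, intervals, motifs
from . import replicate_qc as qc
from . import signal as sig

log = logging.getLogger("peakscape")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Input manifest + stage parameters for one pipeline run."""

    outdir: Path
    peaks: dict[str, str]                   # factor -> BED path (merged/true)
    replicates: dict[str, tuple[str, str]] = field(default_factory=dict)
    signal_tracks: dict[str, str] = field(default_factory=dict)
    genome_fasta: str | None = None
    gene_table: str | None = None
    de_table: str | None = None
    reference_factor: str | None = None     # defaults to first peaks key
    motif_consensus: str = "TGASTCAY"
    seed: int = 0
    # stage parameters
    qc_top_fraction: float = 0.4
    qc_threshold: float = 0.8
    profile_w: int = 2000
    profile_b: int = 50
    promoter_mark: str = "H3K4me3"
    motif_window: int = 200
    motif_threshold_frac: float = 0.8
    motif_half_window: int = 500
    motif_density_bin: int = 20
    coassoc_mode: str = "overlap"
    coassoc_window: int = 1000
    fc_cutoff: float = 1.25
    fdr_cutoff: float = 1e-4
    top_n_regions: int = 5000

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.reference_factor is None and self.peaks:
            self.reference_factor = next(iter(self.peaks))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "replicates" in raw:
            raw["replicates"] = {
                k: tuple(v) for k, v in raw["replicates"].items()
            }
        return cls(**raw)


def validate(config: PipelineConfig) -> list[str]:
    """Collect configuration problems; an empty list means valid."""
    problems: list[str] = []
    if not config.peaks:
        problems.append("no peak sets configured")
    for factor, path in config.peaks.items():
        if not Path(path).exists():
            problems.append(f"peaks[{factor}]: missing file {path}")
    for factor, (pa, pb) in config.replicates.items():
        for p in (pa, pb):
            if not Path(p).exists():
                problems.append(f"replicates[{factor}]: missing file {p}")
    for mark, path in config.signal_tracks.items():
        if not Path(path).exists():
            problems.append(f"signal_tracks[{mark}]: missing file {path}")
    for name in ("genome_fasta", "gene_table", "de_table"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name}: missing file {path}")
    if not config.fc_cutoff > 1:
        problems.append(f"fc_cutoff must be > 1, got {config.fc_cutoff}")
    if not 0 < config.qc_top_fraction <= 1:
        problems.append("qc_top_fraction must be in (0, 1]")
    if not 0 < config.qc_threshold <= 1:
        problems.append("qc_threshold must be in (0, 1]")
    if (2 * config.profile_w) % config.profile_b != 0:
        problems.append("profile_b must divide 2 * profile_w")
    if config.gene_table and config.de_table:
        try:
            genes = {g.gene_id for g in
                     annotation.read_gene_table(config.gene_table)}
            de_genes = {r.gene_id for r in
                        expression.read_de_table(config.de_table)}
            if genes and de_genes and not (genes & de_genes):
                problems.append(
                    "gene_table and de_table share no gene identifiers"
                )
        except Exception as exc:  # validation reports, never raises
            problems.append(f"could not cross-check gene namespaces: {exc}")
    return problems


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the summary dict."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
    }

    peak_sets = {
        factor: intervals.read_bed(path, factor=factor)
        for factor, path in config.peaks.items()
    }
    ref = config.reference_factor

    # ------------------------------------------------------------ replicate QC
    if ref in config.replicates:
        stage = "replicate_qc"
        try:
            pa, pb = config.replicates[ref]
            rep_a = intervals.read_bed(pa, factor=f"{ref}_repA")
            rep_b = intervals.read_bed(pb, factor=f"{ref}_repB")
            report = qc.replicate_consistency(
                rep_a, rep_b, top_fraction=config.qc_top_fraction,
                threshold=config.qc_threshold,
            )
            merged = qc.merge_replicates(rep_a, rep_b)
            intervals.write_bed(merged, outdir / f"{ref}_merged.bed")
            with open(outdir / "qc_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            summary["replicate_qc"] = report.to_dict()
            log.info("replicate_qc: containments %.3f/%.3f passed=%s",
                     report.containment_a_in_b, report.containment_b_in_a,
                     report.passed)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    ref_peaks = peak_sets[ref]

    # ------------------------------------------------------------- annotation
    gene_index = None
    bound_sets: dict[str, set[str]] = {}
    if config.gene_table:
        stage = "annotate"
        try:
            genes = annotation.read_gene_table(config.gene_table)
            gene_index = annotation.GeneIndex(genes)
            loc = annotation.location_summary(ref_peaks, gene_index)
            summary["location"] = loc.to_dict()
            annos = annotation.annotate_peaks(ref_peaks, gene_index)
            distinct, multi = annotation.target_genes(annos)
            summary["target_genes"] = {
                "n_distinct": len(distinct),
                "n_multi_bound": len(multi),
            }
            top = annotation.top_regions(ref_peaks, config.top_n_regions)
            intervals.write_bed(top, outdir / f"{ref}_top_regions.bed")
            with open(outdir / "annotations.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tnearest_gene\t"
                         "signed_distance\tdistance_bin\tcontext\n")
                for a in annos:
                    fh.write(
                        f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
                        f"{a.nearest_gene or '.'}\t"
                        f"{a.signed_distance if a.signed_distance is not None else '.'}\t"
                        f"{a.distance_bin}\t{a.context}\n"
                    )
            for factor, pset in peak_sets.items():
                fannos = annotation.annotate_peaks(pset, gene_index)
                bound_sets[factor], _ = annotation.target_genes(fannos)
            log.info("annotate: %d peaks, %d target genes",
                     len(ref_peaks), len(distinct))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ------------------------------------------------------ profiles / states
    if config.signal_tracks:
        stage = "profile"
        try:
            matrices = {}
            for mark, path in config.signal_tracks.items():
                track = sig.read_bedgraph(path, track_id=mark)
                m = sig.profile_matrix(track, ref_peaks,
                                       w=config.profile_w, b=config.profile_b)
                m.to_tsv(outdir / f"profile_{mark}.tsv")
                matrices[mark] = m
            summary["average_profiles"] = {
                mark: [round(float(v), 4) for v in sig.average_profile(m)]
                for mark, m in matrices.items()
            }
            if config.promoter_mark in matrices:
                states = sig.cluster_states(
                    matrices, promoter_mark=config.promoter_mark,
                    seed=config.seed,
                )
                n_i = states.labels.count("I")
                summary["chromatin_states"] = {
                    "n_cluster_I": n_i,
                    "n_cluster_II": len(states.labels) - n_i,
                    "cluster_means": states.cluster_means,
                }
                with open(outdir / "state_labels.tsv", "w") as fh:
                    fh.write("peak_index\tlabel\n")
                    for i, lab in enumerate(states.labels):
                        fh.write(f"{i}\t{lab}\n")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ motif
    if config.genome_fasta:
        stage = "motif"
        try:
            genome = motifs.GenomeSource.from_fasta(config.genome_fasta)
            pwm = motifs.consensus_to_pwm(config.motif_consensus)
            frac = motifs.motif_fraction(
                ref_peaks, genome, pwm, window=config.motif_window,
                threshold_frac=config.motif_threshold_frac,
            )
            hits = motifs.scan_peaks(
                ref_peaks, genome, pwm,
                half_window=config.motif_half_window,
                threshold_frac=config.motif_threshold_frac,
            )
            density = motifs.motif_density(
                hits, half_window=config.motif_half_window,
                bin=config.motif_density_bin,
            )
            argmax_bin = int(np.argmax(density)) if density.sum() else None
            argmax_offset = (
                -config.motif_half_window
                + argmax_bin * config.motif_density_bin
                + config.motif_density_bin // 2
                if argmax_bin is not None else None
            )
            summary["motif"] = {
                "consensus": config.motif_consensus,
                "fraction_with_hit": frac,
                "n_hits": len(hits),
                "density_argmax_offset": argmax_offset,
            }
            with open(outdir / "motif_hits.tsv", "w") as fh:
                fh.write("peak_index\toffset\tstrand\tscore\n")
                for h in hits:
                    fh.write(f"{h.peak_index}\t{h.offset}\t{h.strand}\t"
                             f"{h.score:.4f}\n")
            log.info("motif: fraction=%.3f hits=%d", frac, len(hits))
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ coassociation
    if len(peak_sets) >= 2:
        stage = "coassoc"
        try:
            sets = [peak_sets[f] for f in config.peaks]
            matrix = coassociation.coassoc_matrix(
                sets, mode=config.coassoc_mode, window=config.coassoc_window
            )
            matrix.to_tsv(outdir / "coassociation.tsv")
            clust = coassociation.correlation_cluster(matrix)
            (outdir / "coassociation.nwk").write_text(clust.to_newick() + "\n")
            summary["coassociation"] = {
                "factors": matrix.factors,
                "matrix": [[round(float(v), 4) for v in row]
                           for row in matrix.values],
                "leaf_order": clust.leaf_order,
            }
            part = intervals.multiway_partition(sets)
            summary["multiway_partition"] = {
                "".join(map(str, sigt)): n for sigt, n in sorted(part.items())
            }
            intervals.write_partition_tsv(sets, outdir / "venn_partition.tsv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ------------------------------------------------------------- integration
    if config.de_table and bound_sets:
        stage = "integrate"
        try:
            records = expression.read_de_table(config.de_table)
            de = expression.filter_de(records, fc_cutoff=config.fc_cutoff,
                                      fdr_cutoff=config.fdr_cutoff)
            named = dict(bound_sets)
            others = [f for f in config.peaks if f != ref]
            if others:
                partner = others[0]
                named[f"{ref}+{partner}"] = expression.co_bound(
                    bound_sets, ref, partner
                )
            integration = expression.integrate(de, named)
            summary["integration"] = integration.to_dict()
            with open(outdir / "integration.json", "w") as fh:
                json.dump(integration.to_dict(), fh, indent=2)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    elif config.de_table is None:
        log.warning("integration skipped: no DE table configured")
        summary["integration"] = None

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
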