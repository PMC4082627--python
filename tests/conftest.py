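"""Shared fixtures: seeded synthetic bundles and small peak-set builders."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from peakscape.intervals import GenomicInterval, PeakSet
from peakscape.simulate import SyntheticConfig, generate


def make_peaks(factor: str, triples, genome_id: str = "genome") -> PeakSet:
    """PeakSet from (chrom, start, end[, score]) tuples."""
    intervals = []
    for t in triples:
        chrom, start, end = t[:3]
        score = t[3] if len(t) > 3 else 0.0
        intervals.append(GenomicInterval(chrom, start, end, score=score))
    return PeakSet(factor=factor, intervals=intervals, genome_id=genome_id)


def generation_order(peaks: PeakSet) -> list[int]:
    """Map BED row order back to the generator's site order via peak names."""
    return [int(iv.name.rsplit("_", 1)[1]) - 1 for iv in peaks]


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The full default synthetic study bundle (seed-fixed)."""
    outdir = tmp_path_factory.mktemp("bundle_default")
    cfg = SyntheticConfig(seed=1)
    return generate(cfg, outdir)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced bundle for fast pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("bundle_small")
    cfg = SyntheticConfig(
        seed=7, n_chroms=1, chrom_length=2_000_000, n_genes=80, n_sites=200
    )
    return generate(cfg, outdir)


@pytest.fixture(scope="session")
def default_truth(default_bundle):
    with open(default_bundle.truth_json) as fh:
        return json.load(fh)
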