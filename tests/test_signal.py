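"""bedGraph I/O, window binning, profile matrices, and state clustering."""

import numpy as np
import pytest

from peakscape.signal import (
    BedGraphParseError,
    SignalTrack,
    average_profile,
    cluster_states,
    profile_matrix,
    read_bedgraph,
    window_signal,
)

from conftest import make_peaks


def track_from(segs, track_id="t"):
    return SignalTrack.from_segments(track_id, segs)


def oracle_window(segs, chrom, center, w, b):
    """Per-base summation oracle for window_signal."""
    base = np.zeros(2 * w)
    for c, s, e, v in segs:
        if c != chrom:
            continue
        for pos in range(max(s, center - w), min(e, center + w)):
            base[pos - (center - w)] = v
    return base.reshape(-1, b).mean(axis=1)


class TestBedGraphIO:
    def test_read_two_segments(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t100\t2.5\nchr1\t100\t200\t1\n")
        track = read_bedgraph(path)
        assert track.n_segments() == 2

    def test_overlapping_segments_rejected(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t100\t2.5\nchr1\t50\t200\t1\n")
        with pytest.raises(BedGraphParseError, match="overlap"):
            read_bedgraph(path)

    def test_negative_value_rejected_with_line(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t100\t-1\n")
        with pytest.raises(BedGraphParseError, match=":1"):
            read_bedgraph(path)

    def test_uncovered_positions_are_zero(self):
        track = track_from([("chr1", 1000, 1100, 4.0)])
        vec = window_signal(track, "chr1", 500, w=100, b=50)
        assert np.all(vec == 0.0)


class TestWindowSignal:
    def test_constant_track(self):
        track = track_from([("chr1", 0, 10_000, 2.0)])
        vec = window_signal(track, "chr1", 5_000, w=2_000, b=50)
        assert vec.shape == (80,)
        assert np.allclose(vec, 2.0)

    def test_single_segment_fills_exactly_one_bin(self):
        # window [4000, 8000), B=50: bin 10 covers [4500, 4550)
        segs = [("chr1", 4_500, 4_550, 3.0)]
        vec = window_signal(track_from(segs), "chr1", 6_000, w=2_000, b=50)
        expected = oracle_window(segs, "chr1", 6_000, 2_000, 50)
        assert np.allclose(vec, expected)
        assert vec[10] == 3.0
        assert vec.sum() == 3.0

    def test_window_at_chromosome_start_left_padded(self):
        track = track_from([("chr1", 0, 10_000, 1.0)])
        vec = window_signal(track, "chr1", 100, w=1_000, b=100)
        # bins left of position 0 are zero-padded
        assert vec[0] == 0.0
        assert vec[-1] == 1.0

    def test_partial_bin_coverage_matches_per_base_oracle(self):
        rng = np.random.default_rng(13)
        pos = 0
        segs = []
        while pos < 6_000:
            length = int(rng.integers(10, 400))
            if rng.random() < 0.6:
                segs.append(("chr1", pos, pos + length,
                             float(rng.uniform(0, 5))))
            pos += length + int(rng.integers(0, 200))
        for center in (500, 2_000, 4_750):
            got = window_signal(track_from(segs), "chr1", center, w=500, b=25)
            want = oracle_window(segs, "chr1", center, 500, 25)
            assert np.allclose(got, want)

    def test_bin_must_divide_span(self):
        track = track_from([("chr1", 0, 100, 1.0)])
        with pytest.raises(ValueError):
            window_signal(track, "chr1", 50, w=100, b=30)


class TestProfileMatrix:
    def test_constant_track_identical_rows(self):
        track = track_from([("chr1", 0, 100_000, 1.5)])
        peaks = make_peaks("F", [("chr1", 20_000, 20_300),
                                 ("chr1", 40_000, 40_300),
                                 ("chr1", 60_000, 60_300)])
        m = profile_matrix(track, peaks)
        assert m.values.shape == (3, 80)
        assert np.allclose(m.values, 1.5)

    def test_empty_track_zero_matrix(self):
        track = track_from([])
        peaks = make_peaks("F", [("chr1", 20_000, 20_300)])
        m = profile_matrix(track, peaks)
        assert np.all(m.values == 0.0)

    def test_invariant_to_segment_order(self, tmp_path):
        segs = [("chr1", 1_000, 1_200, 2.0), ("chr1", 3_000, 3_500, 1.0),
                ("chr1", 2_000, 2_100, 4.0)]
        p1 = tmp_path / "a.bedgraph"
        p2 = tmp_path / "b.bedgraph"
        p1.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in segs))
        p2.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n"
                              for c, s, e, v in reversed(segs)))
        peaks = make_peaks("F", [("chr1", 2_000, 2_400)])
        m1 = profile_matrix(read_bedgraph(p1), peaks)
        m2 = profile_matrix(read_bedgraph(p2), peaks)
        assert np.array_equal(m1.values, m2.values)

    def test_planted_enrichment_peaks_centrally(self, default_bundle):
        """Average enhancer-mark profile peaks at a central bin."""
        from peakscape.intervals import read_bed

        cfg = default_bundle.truth.config
        peaks = read_bed(default_bundle.peak_beds[cfg.factors[0]])
        track = read_bedgraph(default_bundle.signal_bedgraphs["H3K4me1"])
        m = profile_matrix(track, peaks)
        avg = average_profile(m)
        assert int(np.argmax(avg)) in (39, 40)


class TestAverageProfile:
    def test_matrix_of_ones(self):
        from peakscape.signal import ProfileMatrix

        m = ProfileMatrix(values=np.ones((5, 8)), w=200, b=50, track_id="t")
        assert np.allclose(average_profile(m), 1.0)

    def test_single_row_is_identity(self):
        from peakscape.signal import ProfileMatrix

        row = np.arange(8, dtype=float)
        m = ProfileMatrix(values=row[None, :], w=200, b=50, track_id="t")
        assert np.array_equal(average_profile(m), row)

    def test_row_duplication_invariance(self):
        from peakscape.signal import ProfileMatrix

        rng = np.random.default_rng(19)
        vals = rng.uniform(0, 3, size=(6, 10))
        m1 = ProfileMatrix(values=vals, w=250, b=50, track_id="t")
        m2 = ProfileMatrix(values=np.vstack([vals, vals]), w=250, b=50,
                           track_id="t")
        assert np.allclose(average_profile(m1), average_profile(m2))

    def test_empty_matrix_rejected(self):
        from peakscape.signal import ProfileMatrix

        m = ProfileMatrix(values=np.zeros((0, 8)), w=200, b=50, track_id="t")
        with pytest.raises(ValueError):
            average_profile(m)


def synthetic_state_matrices(n_promoter, n_enhancer, seed=0):
    """Two planted populations: promoter-mark-high vs enhancer-mark-high."""
    from peakscape.signal import ProfileMatrix

    rng = np.random.default_rng(seed)
    n = n_promoter + n_enhancer
    mats = {}
    shapes = {"H3K4me3": (8.0, 0.3), "H3K4me1": (0.3, 8.0),
              "H3K27ac": (4.0, 6.0)}
    x = np.arange(80) - 39.5
    bump = np.exp(-(x**2) / (2 * 6.0**2))
    for mark, (h_prom, h_enh) in shapes.items():
        rows = []
        for i in range(n):
            h = h_prom if i < n_promoter else h_enh
            amp = h * float(np.exp(rng.normal(0, 0.2)))
            rows.append(amp * bump + rng.uniform(0, 0.1, size=80))
        mats[mark] = ProfileMatrix(values=np.vstack(rows), w=2000, b=50,
                                   track_id=mark)
    truth = ["promoter"] * n_promoter + ["enhancer"] * n_enhancer
    return mats, truth


class TestClusterStates:
    def test_recovers_planted_populations(self):
        mats, truth = synthetic_state_matrices(40, 160, seed=3)
        states = cluster_states(mats, seed=0)
        agree = np.mean([
            (lab == "I") == (t == "promoter")
            for lab, t in zip(states.labels, truth)
        ])
        assert agree >= 0.95

    def test_cluster_one_has_higher_promoter_mark(self):
        mats, _ = synthetic_state_matrices(40, 160, seed=4)
        states = cluster_states(mats, seed=0)
        assert (states.cluster_means["I"]["H3K4me3"]
                > states.cluster_means["II"]["H3K4me3"])

    def test_identical_rows_still_fully_labeled(self):
        from peakscape.signal import ProfileMatrix

        vals = np.ones((12, 80))
        mats = {m: ProfileMatrix(values=vals.copy(), w=2000, b=50, track_id=m)
                for m in ("H3K4me3", "H3K4me1")}
        states = cluster_states(mats, seed=0)
        assert len(states.labels) == 12
        assert set(states.labels) <= {"I", "II"}

    def test_mismatched_shapes_rejected(self):
        from peakscape.signal import ProfileMatrix

        mats = {
            "H3K4me3": ProfileMatrix(values=np.ones((5, 80)), w=2000, b=50,
                                     track_id="a"),
            "H3K4me1": ProfileMatrix(values=np.ones((6, 80)), w=2000, b=50,
                                     track_id="b"),
        }
        with pytest.raises(ValueError, match="shape"):
            cluster_states(mats, seed=0)

    def test_deterministic_for_fixed_seed(self):
        mats, _ = synthetic_state_matrices(30, 90, seed=5)
        s1 = cluster_states(mats, seed=11)
        s2 = cluster_states(mats, seed=11)
        assert s1.labels == s2.labels
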