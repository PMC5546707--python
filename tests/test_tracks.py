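"""Track algebra: binarization rules, smoothing, combination, proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsk.genome import CoordinateError, GenomeLayout
from gsk.tracks import (
    BinaryTrack,
    ScoreTrack,
    binarize_methylation,
    binarize_peaks,
    binarize_rnaseq,
    combine_tracks,
    count_functional_tracks,
    dichotomize,
    flank_regions,
    functional_proportion,
    quantile_binarize,
    smooth_windows,
)
from conftest import random_binary_track, random_score_track


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "p"])


class TestBinarizePeaks:
    def test_single_passing_peak(self, layout):
        track = binarize_peaks(layout, frame([("chr1", 100, 200, 0.001)]), 0.01)
        s, e = track.intervals("chr1")
        assert list(s) == [100] and list(e) == [200]

    def test_empty_peak_set(self, layout):
        track = binarize_peaks(layout, frame([]), 0.01)
        assert track.coverage_bp == 0

    def test_merged_union_coverage(self, layout):
        peaks = frame([("chr1", 100, 200, 0.001), ("chr1", 150, 300, 0.005),
                       ("chr1", 400, 450, 0.05)])
        track = binarize_peaks(layout, peaks, 0.01)
        assert track.coverage_bp == 200  # merged [100, 300)

    def test_out_of_bounds_rejected(self, layout):
        with pytest.raises(CoordinateError):
            binarize_peaks(layout, frame([("chr2", 0, 60_000, 0.001)]), 0.01)


class TestBinarizeMethylation:
    def make(self, fracs):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [1000 * i for i in range(len(fracs))],
            "end": [1000 * i + 500 for i in range(len(fracs))],
            "fraction": fracs,
        })

    def test_below_cutoff_included(self, layout):
        assert binarize_methylation(layout, self.make([0.4])).coverage_bp == 500

    def test_at_cutoff_excluded_strictly(self, layout):
        assert binarize_methylation(layout, self.make([0.5])).coverage_bp == 0

    def test_exactly_one_of_three_retained(self, layout):
        track = binarize_methylation(layout, self.make([0.1, 0.5, 0.9]))
        assert track.coverage_bp == 500

    def test_invalid_fraction_rejected(self, layout):
        with pytest.raises(ValueError):
            binarize_methylation(layout, self.make([1.2]))


class TestBinarizeRnaseq:
    def make(self, values, start=0):
        n = len(values)
        return pd.DataFrame({
            "chrom": "chr1",
            "start": start + 25 * np.arange(n),
            "end": start + 25 * np.arange(n) + 25,
            "value": values,
        })

    def test_threshold_is_inclusive(self, layout):
        track = binarize_rnaseq(layout, self.make([0.0, 0.5, 1.2]))
        assert track.coverage_bp == 50
        assert track.resolution == 25

    def test_all_below_cutoff(self, layout):
        assert binarize_rnaseq(layout, self.make([0.1, 0.2])).coverage_bp == 0

    def test_known_list_count(self, layout, rng):
        values = rng.random(100)
        expected = 25 * int((values >= 0.5).sum())
        assert binarize_rnaseq(layout, self.make(values)).coverage_bp == expected

    def test_off_grid_rejected(self, layout):
        bins = self.make([1.0])
        bins["start"] += 3
        bins["end"] += 3
        with pytest.raises(ValueError, match="grid"):
            binarize_rnaseq(layout, bins)


class TestDichotomize:
    def constant(self, layout, value):
        runs = {c: (np.array([0]), np.array([layout.lengths[c]]),
                    np.array([value])) for c in layout.chromosomes}
        return ScoreTrack(layout, runs)

    def test_constant_above(self, layout):
        track = dichotomize(self.constant(layout, 0.7))
        assert track.coverage_bp == layout.total_bp

    def test_tie_goes_functional(self, layout):
        track = dichotomize(self.constant(layout, 0.5))
        assert track.coverage_bp == layout.total_bp

    def test_runs_coverage(self, layout):
        runs = {"chr1": (np.arange(4) * 25, np.arange(4) * 25 + 25,
                         np.array([0.2, 0.6, 0.4, 0.9]))}
        assert dichotomize(ScoreTrack(layout, runs)).coverage_bp == 50


class TestSmoothWindows:
    def test_constant_invariant(self, layout):
        runs = {c: (np.array([0]), np.array([layout.lengths[c]]),
                    np.array([0.3])) for c in layout.chromosomes}
        track = ScoreTrack(layout, runs)
        sm = smooth_windows(track, 10_000)
        for c in layout.chromosomes:
            assert np.allclose(sm.runs(c)[2], 0.3)

    def test_half_window_mean(self, layout):
        runs = {"chr1": (np.array([0]), np.array([5000]), np.array([1.0]))}
        sm = smooth_windows(ScoreTrack(layout, runs), 10_000)
        s, e, v = sm.runs("chr1")
        assert s[0] == 0 and e[0] == 10_000 and v[0] == pytest.approx(0.5)

    def test_window_means_match_dense(self, layout, rng):
        track = random_score_track(layout, rng)
        sm = smooth_windows(track, 10_000)
        dense = track.to_dense("chr1")
        for w in range(10):
            expected = dense[w * 10_000:(w + 1) * 10_000].mean()
            got = sm.value_at("chr1", [w * 10_000])[0]
            assert got == pytest.approx(expected)

    def test_genome_mean_preserved(self, layout, rng):
        track = random_score_track(layout, rng)
        # chr2 length 50,000 is not a multiple of 30,000: partial window
        sm = smooth_windows(track, 30_000)
        assert sm.genome_mean == pytest.approx(track.genome_mean, abs=1e-12)

    def test_bad_window_rejected(self, layout, score_track):
        with pytest.raises(ValueError):
            smooth_windows(score_track, 0)


class TestCombine:
    def test_union_basic(self, layout):
        a = BinaryTrack(layout, {"chr1": ([0], [100])})
        b = BinaryTrack(layout, {"chr1": ([50], [150])})
        u = combine_tracks([a, b], "union")
        s, e = u.intervals("chr1")
        assert list(s) == [0] and list(e) == [150]

    def test_mean_of_constants(self, layout):
        def const(v):
            runs = {c: (np.array([0]), np.array([layout.lengths[c]]),
                        np.array([v])) for c in layout.chromosomes}
            return ScoreTrack(layout, runs)
        m = combine_tracks([const(0.2), const(0.8)], "mean")
        assert m.genome_mean == pytest.approx(0.5)

    def test_union_inclusion_exclusion(self, layout, rng):
        tracks = [random_binary_track(layout, rng) for _ in range(3)]
        u = combine_tracks(tracks, "union")
        dense = np.zeros(layout.lengths["chr1"], dtype=bool)
        for t in tracks:
            dense |= t.to_dense("chr1").astype(bool)
        s, e = u.intervals("chr1")
        assert (e - s).sum() == dense.sum()

    def test_layout_mismatch_rejected(self, layout):
        other = GenomeLayout(("chr1",), {"chr1": 10})
        a = BinaryTrack(layout, {})
        b = BinaryTrack(other, {})
        with pytest.raises(ValueError):
            combine_tracks([a, b], "union")

    def test_union_requires_binary(self, layout, score_track):
        with pytest.raises(TypeError):
            combine_tracks([score_track], "union")


class TestFunctionalProportion:
    def test_all_ones(self, layout):
        track = BinaryTrack(layout, {"chr1": ([0], [100_000])})
        el = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [500]})
        assert functional_proportion(track, el) == 1.0

    def test_all_zero(self, layout):
        track = ScoreTrack(layout, {})
        el = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [500]})
        assert functional_proportion(track, el) == 0.0

    def test_partial(self, layout):
        track = ScoreTrack(layout, {"chr1": ([0], [60], [0.8])})
        el = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        assert functional_proportion(track, el) == pytest.approx(0.30)

    def test_empty_elements_error(self, layout, score_track):
        with pytest.raises(ValueError):
            functional_proportion(score_track, pd.DataFrame(
                columns=["chrom", "start", "end"]))

    def test_strictly_above_cutoff(self, layout):
        # a run exactly at the cutoff does not count (strict >)
        track = ScoreTrack(layout, {"chr1": ([0], [100], [0.5])})
        el = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        assert functional_proportion(track, el, cutoff=0.5) == 0.0


class TestFlankRegions:
    def test_basic_extension(self, layout):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1100]})
        out = flank_regions(layout, el, 200)
        assert out.iloc[0].tolist() == ["chr1", 800, 1300]

    def test_clip_at_chromosome_start(self, layout):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [100]})
        out = flank_regions(layout, el, 200)
        assert out.iloc[0]["start"] == 0

    def test_nearby_elements_merge(self, layout):
        el = pd.DataFrame({"chrom": ["chr1", "chr1"],
                           "start": [1000, 1400], "end": [1100, 1500]})
        out = flank_regions(layout, el, 200)
        assert len(out) == 1
        assert out.iloc[0].tolist() == ["chr1", 800, 1700]


class TestCountFunctionalTracks:
    regions = pd.DataFrame({"chrom": ["chr1"] * 3,
                            "start": [0, 1000, 2000],
                            "end": [500, 1500, 2500]})

    def test_all_zero_tracks(self, layout):
        tracks = [BinaryTrack(layout, {}) for _ in range(5)]
        counts, hist = count_functional_tracks(tracks, self.regions)
        assert counts.tolist() == [0, 0, 0]
        assert hist[0] == 3

    def test_all_one_tracks(self, layout):
        tracks = [BinaryTrack(layout, {"chr1": ([0], [100_000])})
                  for _ in range(3)]
        counts, hist = count_functional_tracks(tracks, self.regions)
        assert counts.tolist() == [3, 3, 3]
        assert hist[3] == 3

    def test_known_overlaps(self, layout):
        tracks = [
            BinaryTrack(layout, {"chr1": ([0], [400])}),          # region 0
            BinaryTrack(layout, {"chr1": ([1200], [2100])}),      # 1 and 2
            BinaryTrack(layout, {"chr1": ([600], [900])}),        # none
            BinaryTrack(layout, {"chr1": ([100, 2400], [200, 2450])}),  # 0, 2
        ]
        counts, hist = count_functional_tracks(tracks, self.regions)
        assert counts.tolist() == [2, 1, 2]
        assert hist.tolist() == [0, 1, 2, 0, 0]


class TestQuantileBinarize:
    def test_nearest_rank_cutoff(self, layout):
        # scores 0.01..1.00 at 100 reference SNPs: 0.90 quantile -> 0.90
        starts = np.arange(100) * 1000
        track = ScoreTrack(layout, {"chr1": (starts, starts + 1000,
                                             (np.arange(100) + 1) / 100)})
        ref = pd.DataFrame({"chrom": "chr1", "pos": starts + 5})
        out = quantile_binarize(track, 0.90, ref)
        assert out.coverage_bp == 11_000  # runs at 0.90 .. 1.00

    def test_degenerate_constant_warns(self, layout):
        track = ScoreTrack(layout, {"chr1": ([0], [100_000], [0.4])})
        ref = pd.DataFrame({"chrom": "chr1", "pos": np.arange(10) * 100})
        with pytest.warns(UserWarning, match="identical"):
            out = quantile_binarize(track, 0.90, ref)
        assert out.coverage_bp == 100_000  # >= tie rule keeps everything

    def test_uniform_scores_tag_expected_fraction(self, layout, rng):
        n = 10_000
        lengths = {"chr1": 10 * n}
        big = GenomeLayout(("chr1",), lengths)
        starts = np.arange(n) * 10
        values = rng.random(n)
        track = ScoreTrack(big, {"chr1": (starts, starts + 10, values)})
        ref = pd.DataFrame({"chrom": "chr1", "pos": starts})
        out = quantile_binarize(track, 0.90, ref)
        tagged = out.contains("chr1", starts).mean()
        assert tagged == pytest.approx(0.10, abs=0.02)


class TestInvariantsProperties:
    """Spec-level invariants on randomized fixtures."""

    @given(seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_dichotomize_idempotent(self, seed):
        layout = GenomeLayout(("chr1",), {"chr1": 10_000})
        track = random_score_track(layout, np.random.default_rng(seed), 20)
        once = dichotomize(track)
        twice = dichotomize(once.as_score_track())
        assert once == twice

    @given(seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_union_coverage_bound_and_mean_range(self, seed):
        layout = GenomeLayout(("chr1",), {"chr1": 10_000})
        rng = np.random.default_rng(seed)
        tracks = [random_binary_track(layout, rng, 10) for _ in range(3)]
        u = combine_tracks(tracks, "union")
        assert u.coverage_bp >= max(t.coverage_bp for t in tracks)
        m = combine_tracks(tracks, "mean")
        for c in layout.chromosomes:
            _, _, v = m.runs(c)
            assert np.all((v >= 0) & (v <= 1))

    @given(seed=st.integers(0, 200), window=st.sampled_from([100, 300, 1000]))
    @settings(max_examples=20, deadline=None)
    def test_smoothing_preserves_mean(self, seed, window):
        layout = GenomeLayout(("chr1",), {"chr1": 10_000})
        track = random_score_track(layout, np.random.default_rng(seed), 20)
        sm = smooth_windows(track, window)
        assert sm.genome_mean == pytest.approx(track.genome_mean, abs=1e-12)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_proportion_of_union_dominates(self, seed):
        layout = GenomeLayout(("chr1",), {"chr1": 10_000})
        rng = np.random.default_rng(seed)
        a = random_binary_track(layout, rng, 10)
        b = random_binary_track(layout, rng, 10)
        el = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        pu = functional_proportion(combine_tracks([a, b], "union"), el)
        assert pu >= max(functional_proportion(a, el),
                         functional_proportion(b, el)) - 1e-12
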