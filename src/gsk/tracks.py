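"""Run-length genome tracks and the algebra used to build annotations.

Two containers cover everything downstream:

``BinaryTrack``
    per-base presence/absence, stored as sorted disjoint one-intervals.
``ScoreTrack``
    per-base values in [0, 1], stored as sorted disjoint scored runs;
    gaps between runs carry an implicit score of 0.

Both declare a resolution (1 bp for chromatin/methylation, 25 bp for
binned RNA-seq signal) and validate against a :class:`~gsk.genome.GenomeLayout`.

The module also provides the binarization rules used to turn raw signals
into tracks: ChIP-seq peaks pass at an enrichment p-value below 0.01,
CpG islands count when their methylation fraction is below 0.5, and RNA
signal passes at an rpkm of at least 0.5 in 25-bp bins. Continuous scores
are dichotomized at 0.5 with ties going to the functional side.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import (
    CoordinateError,
    GenomeLayout,
    _covered_before,
    flank_intervals,
    intervals_from_frame,
    merge_intervals,
    total_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryTrack",
    "ScoreTrack",
    "binarize_peaks",
    "binarize_methylation",
    "binarize_rnaseq",
    "dichotomize",
    "smooth_windows",
    "combine_tracks",
    "functional_proportion",
    "flank_regions",
    "count_functional_tracks",
    "quantile_binarize",
]


def _normalize_runs(starts, ends, values, length):
    """Validate, sort, and compress scored runs for one chromosome.

    Runs must be disjoint; touching runs with equal value are merged and
    zero-valued runs dropped (gaps are implicit zeros).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if not (starts.size == ends.size == values.size):
        raise ValueError("starts, ends, values must have equal length")
    if starts.size == 0:
        return starts, ends, values
    if np.any(starts >= ends):
        raise ValueError("runs must satisfy start < end")
    if np.any(starts < 0) or np.any(ends > length):
        raise CoordinateError(f"run outside chromosome bounds [0,{length})")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("scores must lie in [0, 1]")
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("runs must be disjoint")
    keep = values != 0.0
    starts, ends, values = starts[keep], ends[keep], values[keep]
    if starts.size == 0:
        return starts, ends, values
    # merge touching runs of equal value
    new = np.empty(starts.size, dtype=bool)
    new[0] = True
    new[1:] = (starts[1:] != ends[:-1]) | (values[1:] != values[:-1])
    block = np.cumsum(new) - 1
    out_s = starts[new]
    out_v = values[new]
    out_e = np.zeros(out_s.size, dtype=np.int64)
    np.maximum.at(out_e, block, ends)
    return out_s, out_e, out_v


class ScoreTrack:
    """Piecewise-constant [0, 1] scores over a genome."""

    binary = False

    def __init__(self, layout: GenomeLayout, runs: Mapping[str, tuple] | None = None,
                 resolution: int = 1):
        self.layout = layout
        self.resolution = int(resolution)
        norm = {}
        runs = runs or {}
        for chrom, triple in runs.items():
            if chrom not in layout:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            s, e, v = triple
            norm[chrom] = _normalize_runs(s, e, v, layout.length(chrom))
        self._runs = norm

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dense(cls, layout: GenomeLayout, dense: Mapping[str, np.ndarray],
                   resolution: int = 1) -> "ScoreTrack":
        runs = {}
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size != layout.length(chrom):
                raise ValueError("dense array length must match chromosome")
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            bounds = np.concatenate(([0], change, [arr.size]))
            runs[chrom] = (bounds[:-1], bounds[1:], arr[bounds[:-1]])
        return cls(layout, runs, resolution=resolution)

    # -- accessors --------------------------------------------------------
    def runs(self, chrom: str):
        s, e, v = self._runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
        return s, e, v

    def to_dense(self, chrom: str) -> np.ndarray:
        out = np.zeros(self.layout.length(chrom))
        s, e, v = self.runs(chrom)
        for a, b, x in zip(s, e, v):
            out[a:b] = x
        return out

    def value_at(self, chrom: str, positions) -> np.ndarray:
        """Score at 0-based positions; implicit 0 in gaps."""
        positions = np.asarray(positions, dtype=np.int64)
        n = self.layout.length(chrom)
        if positions.size and (positions.min() < 0 or positions.max() >= n):
            raise CoordinateError("position outside chromosome bounds")
        s, e, v = self.runs(chrom)
        out = np.zeros(positions.size)
        if s.size:
            i = np.searchsorted(s, positions, side="right") - 1
            ok = (i >= 0) & (positions < e[np.maximum(i, 0)])
            out[ok] = v[i[ok]]
        return out

    def integral_before(self, chrom: str, x) -> np.ndarray:
        """Integral of the score over ``[0, x)`` for each x."""
        s, e, v = self.runs(chrom)
        x = np.asarray(x, dtype=np.int64)
        cum = np.concatenate(([0.0], np.cumsum((e - s) * v)))
        i = np.searchsorted(s, x, side="right")
        out = cum[i]
        if s.size:
            prev = np.maximum(i - 1, 0)
            over = np.clip(e[prev] - x, 0, None) * v[prev]
            out = out - np.where(i > 0, over, 0.0)
        return out

    @property
    def total_integral(self) -> float:
        return float(sum(((e - s) * v).sum() for s, e, v in self._runs.values()))

    @property
    def genome_mean(self) -> float:
        return self.total_integral / self.layout.total_bp

    def __eq__(self, other):
        if not isinstance(other, ScoreTrack) or self.layout != other.layout:
            return NotImplemented
        chroms = set(self._runs) | set(other._runs)
        for c in chroms:
            for a, b in zip(self.runs(c), other.runs(c)):
                if a.size != b.size or not np.allclose(a, b):
                    return False
        return True


class BinaryTrack:
    """Per-base 0/1 presence track stored as disjoint one-intervals."""

    binary = True

    def __init__(self, layout: GenomeLayout, intervals: Mapping[str, tuple] | None = None,
                 resolution: int = 1):
        self.layout = layout
        self.resolution = int(resolution)
        norm = {}
        for chrom, (s, e) in (intervals or {}).items():
            if chrom not in layout:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            if s.size:
                if s.min() < 0 or e.max() > layout.length(chrom):
                    raise CoordinateError(
                        f"interval outside {chrom} bounds "
                        f"[0,{layout.length(chrom)})"
                    )
                s, e = merge_intervals(s, e)
            norm[chrom] = (s, e)
        self._iv = norm

    @classmethod
    def from_frame(cls, layout: GenomeLayout, df: pd.DataFrame,
                   resolution: int = 1) -> "BinaryTrack":
        return cls(layout, intervals_from_frame(df, layout), resolution=resolution)

    def intervals(self, chrom: str):
        return self._iv.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def interval_dict(self) -> dict:
        return dict(self._iv)

    @property
    def coverage_bp(self) -> int:
        return total_length(self._iv)

    @property
    def coverage_fraction(self) -> float:
        return self.coverage_bp / self.layout.total_bp

    def contains(self, chrom: str, positions) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        s, e = self.intervals(chrom)
        out = np.zeros(positions.size, dtype=bool)
        if s.size:
            i = np.searchsorted(s, positions, side="right") - 1
            out = (i >= 0) & (positions < e[np.maximum(i, 0)])
        return out

    def overlap_bp(self, chrom: str, starts, ends) -> np.ndarray:
        """Overlap in bp between this track and each query interval."""
        s, e = self.intervals(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if s.size == 0:
            return np.zeros(starts.size, dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum(e - s)))
        return (_covered_before(ends, s, e, cum)
                - _covered_before(starts, s, e, cum))

    def to_dense(self, chrom: str) -> np.ndarray:
        out = np.zeros(self.layout.length(chrom), dtype=np.uint8)
        s, e = self.intervals(chrom)
        for a, b in zip(s, e):
            out[a:b] = 1
        return out

    def as_score_track(self) -> ScoreTrack:
        runs = {c: (s, e, np.ones(s.size)) for c, (s, e) in self._iv.items()}
        return ScoreTrack(self.layout, runs, resolution=self.resolution)

    def union(self, other: "BinaryTrack") -> "BinaryTrack":
        if other.layout != self.layout:
            raise ValueError("layout mismatch")
        out = {}
        for chrom in set(self._iv) | set(other._iv):
            s1, e1 = self.intervals(chrom)
            s2, e2 = other.intervals(chrom)
            out[chrom] = merge_intervals(np.concatenate([s1, s2]),
                                         np.concatenate([e1, e2])) \
                if s1.size + s2.size else (s1, e1)
        return BinaryTrack(self.layout, out,
                           resolution=min(self.resolution, other.resolution))

    def __eq__(self, other):
        if not isinstance(other, BinaryTrack) or self.layout != other.layout:
            return NotImplemented
        for c in set(self._iv) | set(other._iv):
            for a, b in zip(self.intervals(c), other.intervals(c)):
                if a.size != b.size or not np.array_equal(a, b):
                    return False
        return True


# -- binarizations --------------------------------------------------------

def binarize_peaks(layout: GenomeLayout, peaks: pd.DataFrame,
                   p_threshold: float = 0.01) -> BinaryTrack:
    """Union of peak intervals whose enrichment p-value is below threshold.

    ``peaks`` needs columns chrom/start/end/p. Intervals beyond chromosome
    ends are rejected.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if len(peaks) == 0:
        return BinaryTrack(layout, {})
    passing = peaks[peaks["p"].to_numpy() < p_threshold]
    if len(passing) == 0:
        return BinaryTrack(layout, {})
    return BinaryTrack(layout, intervals_from_frame(passing, layout))


def binarize_methylation(layout: GenomeLayout, islands: pd.DataFrame,
                         cutoff: float = 0.5) -> BinaryTrack:
    """Unmethylated CpG islands: fraction strictly below the cutoff.

    ``islands`` needs chrom/start/end/fraction, one fraction per island.
    """
    frac = islands["fraction"].to_numpy(float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    keep = islands[frac < cutoff]
    if len(keep) == 0:
        return BinaryTrack(layout, {})
    return BinaryTrack(layout, intervals_from_frame(keep, layout))


def binarize_rnaseq(layout: GenomeLayout, bins: pd.DataFrame,
                    rpkm_cutoff: float = 0.5, bin_bp: int = 25) -> BinaryTrack:
    """Dichotomize binned RNA signal: bins with rpkm >= cutoff become 1.

    Bins must sit on the ``bin_bp`` grid (the final bin may be clipped at the
    chromosome end).
    """
    start = bins["start"].to_numpy(np.int64)
    end = bins["end"].to_numpy(np.int64)
    chrom_len = bins["chrom"].map(layout.lengths).to_numpy()
    on_grid = (start % bin_bp == 0) & (
        (end - start == bin_bp) | ((end == chrom_len) & (end - start <= bin_bp))
    )
    if not on_grid.all():
        bad = bins[~on_grid].iloc[0]
        raise ValueError(
            f"bin {bad['chrom']}:[{bad['start']},{bad['end']}) not on the "
            f"{bin_bp}-bp grid"
        )
    keep = bins[bins["value"].to_numpy(float) >= rpkm_cutoff]
    if len(keep) == 0:
        return BinaryTrack(layout, {}, resolution=bin_bp)
    return BinaryTrack(layout, intervals_from_frame(keep, layout),
                       resolution=bin_bp)


def dichotomize(track: ScoreTrack, cutoff: float = 0.5) -> BinaryTrack:
    """Binary track of bases with score >= cutoff (ties go functional)."""
    if cutoff <= 0:
        # degenerate: every base (implicit zeros included) passes
        iv = {c: (np.array([0], np.int64),
                  np.array([track.layout.length(c)], np.int64))
              for c in track.layout.chromosomes}
        return BinaryTrack(track.layout, iv, resolution=track.resolution)
    out = {}
    for chrom in track.layout.chromosomes:
        s, e, v = track.runs(chrom)
        keep = v >= cutoff
        out[chrom] = merge_intervals(s[keep], e[keep]) if keep.any() else \
            (np.empty(0, np.int64), np.empty(0, np.int64))
    return BinaryTrack(track.layout, out, resolution=track.resolution)


def _threshold_strict(track: ScoreTrack, cutoff: float) -> dict:
    out = {}
    for chrom in track.layout.chromosomes:
        s, e, v = track.runs(chrom)
        keep = v > cutoff
        out[chrom] = merge_intervals(s[keep], e[keep]) if keep.any() else \
            (np.empty(0, np.int64), np.empty(0, np.int64))
    return out


def smooth_windows(track: ScoreTrack, window_bp: int = 10_000) -> ScoreTrack:
    """Tile each chromosome into fixed windows and assign the window mean.

    The last, possibly partial window is averaged over its actual length, so
    the genome-wide mean score is preserved exactly.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if window_bp % track.resolution != 0:
        raise ValueError("window_bp must be a multiple of the track resolution")
    runs = {}
    for chrom in track.layout.chromosomes:
        n = track.layout.length(chrom)
        edges = np.arange(0, n, window_bp, dtype=np.int64)
        edges = np.append(edges, n)
        integ = track.integral_before(chrom, edges)
        means = np.diff(integ) / np.diff(edges)
        runs[chrom] = (edges[:-1], edges[1:], means)
    return ScoreTrack(track.layout, runs, resolution=track.resolution)


def combine_tracks(tracks, mode: str = "union"):
    """Combine tracks across samples: bitwise-OR union or per-base mean.

    ``union`` requires binary inputs; ``mean`` accepts binary and score
    tracks (binary counted as 0/1 scores). Layouts must match.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    layout = tracks[0].layout
    if any(t.layout != layout for t in tracks):
        raise ValueError("all tracks must share one layout")
    if mode == "union":
        if not all(isinstance(t, BinaryTrack) for t in tracks):
            raise TypeError("union requires binary tracks")
        out = tracks[0]
        for t in tracks[1:]:
            out = out.union(t)
        return out
    if mode != "mean":
        raise ValueError("mode must be 'union' or 'mean'")
    score_tracks = [t.as_score_track() if isinstance(t, BinaryTrack) else t
                    for t in tracks]
    runs = {}
    res = min(t.resolution for t in tracks)
    for chrom in layout.chromosomes:
        bounds = [np.array([0, layout.length(chrom)], np.int64)]
        for t in score_tracks:
            s, e, _ = t.runs(chrom)
            bounds.extend((s, e))
        cut = np.unique(np.concatenate(bounds))
        seg_s, seg_e = cut[:-1], cut[1:]
        if seg_s.size == 0:
            continue
        acc = np.zeros(seg_s.size)
        for t in score_tracks:
            acc += t.value_at(chrom, seg_s)
        runs[chrom] = (seg_s, seg_e, acc / len(score_tracks))
    return ScoreTrack(layout, runs, resolution=res)


def functional_proportion(track, elements: pd.DataFrame,
                          cutoff: float = 0.5) -> float:
    """Fraction of element bases called functional.

    For a :class:`ScoreTrack` a base counts when its score is strictly above
    the cutoff; for a :class:`BinaryTrack` every one-base counts.
    """
    if len(elements) == 0:
        raise ValueError("element set is empty")
    per_chrom = intervals_from_frame(elements, track.layout)
    total = total_length(per_chrom)
    if total == 0:
        raise ValueError("element set covers zero bases")
    if isinstance(track, BinaryTrack):
        functional = track
    else:
        functional = BinaryTrack(track.layout, _threshold_strict(track, cutoff),
                                 resolution=track.resolution)
    hit = 0
    for chrom, (s, e) in per_chrom.items():
        hit += int(functional.overlap_bp(chrom, s, e).sum())
    return hit / total


def flank_regions(layout: GenomeLayout, elements: pd.DataFrame,
                  flank_bp: int = 200) -> pd.DataFrame:
    """Extend elements by ``flank_bp`` both sides, clip to bounds, merge."""
    per_chrom = intervals_from_frame(elements, layout)
    flanked = flank_intervals(per_chrom, layout, flank_bp)
    rows = []
    for chrom in layout.chromosomes:
        if chrom not in flanked:
            continue
        s, e = flanked[chrom]
        rows.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_functional_tracks(tracks, regions: pd.DataFrame):
    """Per-region count of tracks with at least one functional base.

    Returns ``(counts, histogram)``: counts align with ``regions`` rows and
    the histogram tallies regions by count (length ``len(tracks) + 1``).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    counts = np.zeros(len(regions), dtype=np.int64)
    chrom = regions["chrom"].to_numpy()
    start = regions["start"].to_numpy(np.int64)
    end = regions["end"].to_numpy(np.int64)
    for t in tracks:
        binary = t if isinstance(t, BinaryTrack) else dichotomize(t)
        for c in np.unique(chrom):
            sel = chrom == c
            counts[sel] += binary.overlap_bp(str(c), start[sel], end[sel]) > 0
    hist = np.bincount(counts, minlength=len(tracks) + 1)
    return counts, hist


def quantile_binarize(track: ScoreTrack, quantile: float = 0.90,
                      reference_positions: pd.DataFrame | None = None) -> BinaryTrack:
    """Dichotomize at the nearest-rank quantile of scores at reference SNPs.

    ``reference_positions`` needs chrom/pos (0-based) columns. The cutoff is
    the nearest-rank ``quantile`` of the reference scores; bases scoring at
    or above the cutoff become 1.
    """
    if reference_positions is None or len(reference_positions) == 0:
        raise ValueError("reference positions must be non-empty")
    scores = []
    for chrom, grp in reference_positions.groupby("chrom", sort=False):
        scores.append(track.value_at(str(chrom), grp["pos"].to_numpy(np.int64)))
    scores = np.sort(np.concatenate(scores))
    if scores[0] == scores[-1]:
        warnings.warn(
            "all reference scores identical; quantile cutoff is degenerate",
            stacklevel=2,
        )
    k = int(np.ceil(quantile * scores.size))
    cutoff = float(scores[max(k, 1) - 1])
    return dichotomize(track, cutoff) if cutoff > 0 else dichotomize(track, 0.0)
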