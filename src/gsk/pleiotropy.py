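"""Window-based test for annotation-localized pleiotropy between two traits.

The autosomes are tiled into fixed windows (default 1 Mb). For each study a
window is labelled 1 when (condition 1) it contains a SNP with p below 1e-3
and (condition 2) at least one such sub-threshold SNP lies inside the
tissue's functional annotation; windows without SNPs are dropped. Windows
labelled 1 for both traits are candidate pleiotropic regions. Their excess
over chance is assessed two ways:

* an upper-tail hypergeometric test treating one study's labels as draws
  from the retained windows, and
* a permutation test that shuffles the per-SNP annotation-membership
  indicator (preserving the total annotated proportion), recomputes
  condition-2 labels for both studies, and compares the observed joint
  count to the permutation distribution. The permutation design also
  absorbs bias from shared control samples between the two studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout
from .sumstats import SumStats
from .tracks import BinaryTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowGrid:
    """Fixed windows tiling the autosomes, anchored at position 0."""

    layout: GenomeLayout
    window_bp: int = 1_000_000

    def windows(self) -> pd.DataFrame:
        rows = []
        for chrom in self.layout.autosomes():
            n = self.layout.length(chrom)
            starts = np.arange(0, n, self.window_bp, dtype=np.int64)
            ends = np.minimum(starts + self.window_bp, n)
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df.index.name = "window"
        return df

    def window_of(self, chroms, bp) -> np.ndarray:
        """Window index per SNP (1-based bp); -1 off the autosomal grid."""
        chroms = np.asarray(chroms).astype(str)
        bp = np.asarray(bp, dtype=np.int64)
        offset = {}
        acc = 0
        for c in self.layout.autosomes():
            offset[c] = acc
            acc += -(-self.layout.length(c) // self.window_bp)
        out = np.full(bp.size, -1, dtype=np.int64)
        for c, off in offset.items():
            sel = chroms == c
            if sel.any():
                out[sel] = off + (bp[sel] - 1) // self.window_bp
        return out


@dataclass
class WindowLabels:
    """Per-window binary labels for one study on a retained window set."""

    grid: WindowGrid
    retained: np.ndarray         # indices of retained windows
    labels: np.ndarray           # 0/1 per retained window

    @property
    def k(self) -> int:
        return int(self.labels.sum())

    @property
    def n_windows(self) -> int:
        return int(self.retained.size)


def snp_annotation_status(stats: SumStats, track: BinaryTrack) -> np.ndarray:
    """Boolean: SNP position (1-based bp) inside the annotation track."""
    chroms = stats.table["chrom"].to_numpy().astype(str)
    bp = stats.table["bp"].to_numpy(np.int64)
    out = np.zeros(bp.size, dtype=bool)
    for c in np.unique(chroms):
        sel = chroms == c
        if c in track.layout:
            out[sel] = track.contains(c, bp[sel] - 1)
    return out


def _labels_from_status(stats: SumStats, status: np.ndarray, grid: WindowGrid,
                        p_cut: float, retained=None, win_idx=None):
    if win_idx is None:
        win_idx = grid.window_of(stats.table["chrom"], stats.table["bp"])
    on_grid = win_idx >= 0
    if retained is None:
        retained = np.unique(win_idx[on_grid])
        if retained.size == 0:
            raise ValueError("no SNPs fall on the window grid")
    labels = np.zeros(retained.size, dtype=np.int8)
    p = stats.table["p"].to_numpy(float)
    hit_windows = win_idx[on_grid & (p < p_cut) & status]
    idx = np.searchsorted(retained, hit_windows)
    ok = (idx < retained.size) & (retained[np.minimum(idx, retained.size - 1)]
                                  == hit_windows)
    labels[idx[ok]] = 1
    return retained, labels


def label_windows(stats: SumStats, annot_track: BinaryTrack, grid: WindowGrid,
                  p_cut: float = 1e-3, retained=None) -> WindowLabels:
    """Label retained windows 1 when an annotated SNP passes the p cut.

    ``retained`` fixes the retained-window set externally (needed when two
    studies must share one population of windows); by default windows with
    at least one SNP of this study are retained.
    """
    if len(stats) == 0:
        raise ValueError("summary statistics are empty")
    status = snp_annotation_status(stats, annot_track)
    retained, labels = _labels_from_status(stats, status, grid, p_cut,
                                           retained)
    return WindowLabels(grid, retained, labels)


def joint_retained(stats_a: SumStats, stats_b: SumStats,
                   grid: WindowGrid) -> np.ndarray:
    """Windows containing at least one SNP from each study."""
    wa = grid.window_of(stats_a.table["chrom"], stats_a.table["bp"])
    wb = grid.window_of(stats_b.table["chrom"], stats_b.table["bp"])
    retained = np.intersect1d(np.unique(wa[wa >= 0]), np.unique(wb[wb >= 0]))
    if retained.size == 0:
        raise ValueError("no windows contain SNPs from both studies")
    return retained


def hypergeom_overlap(labels_a: WindowLabels, labels_b: WindowLabels) -> float:
    """Upper-tail hypergeometric p of the joint-window overlap."""
    if labels_a.grid != labels_b.grid or \
            not np.array_equal(labels_a.retained, labels_b.retained):
        raise ValueError("labels must share one retained window set")
    n = labels_a.n_windows
    k_a, k_b = labels_a.k, labels_b.k
    overlap = int((labels_a.labels & labels_b.labels).sum())
    return float(sps.hypergeom.sf(overlap - 1, n, k_a, k_b))


def permutation_test(stats_a: SumStats, stats_b: SumStats,
                     annot_track: BinaryTrack, grid: WindowGrid,
                     p_cut: float = 1e-3, n_perm: int = 1000,
                     seed: int | None = 0):
    """Annotation-status permutation test of the joint-window count.

    The per-SNP membership indicator is defined on the union of SNP
    positions of both studies and permuted uniformly, preserving the total
    annotated count; condition-2 labels are recomputed each round. Returns
    ``(p_value, observed_count, null_counts)`` with the add-one estimator
    ``p = (1 + #{null >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    retained = joint_retained(stats_a, stats_b, grid)
    positions = pd.concat([
        stats_a.table[["chrom", "bp"]], stats_b.table[["chrom", "bp"]]
    ]).drop_duplicates().reset_index(drop=True)
    chroms = positions["chrom"].to_numpy().astype(str)
    bp = positions["bp"].to_numpy(np.int64)
    status_u = np.zeros(bp.size, dtype=bool)
    for c in np.unique(chroms):
        sel = chroms == c
        if c in annot_track.layout:
            status_u[sel] = annot_track.contains(c, bp[sel] - 1)
    key = pd.MultiIndex.from_frame(positions)
    ka = key.get_indexer(pd.MultiIndex.from_frame(stats_a.table[["chrom", "bp"]]))
    kb = key.get_indexer(pd.MultiIndex.from_frame(stats_b.table[["chrom", "bp"]]))
    wa = grid.window_of(stats_a.table["chrom"], stats_a.table["bp"])
    wb = grid.window_of(stats_b.table["chrom"], stats_b.table["bp"])

    def joint_count(status):
        _, la = _labels_from_status(stats_a, status[ka], grid, p_cut,
                                    retained, win_idx=wa)
        _, lb = _labels_from_status(stats_b, status[kb], grid, p_cut,
                                    retained, win_idx=wb)
        return int((la & lb).sum())

    observed = joint_count(status_u)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = joint_count(rng.permutation(status_u))
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return p, observed, null


def candidate_loci(stats_a: SumStats, stats_b: SumStats,
                   annot_track: BinaryTrack, grid: WindowGrid,
                   p_cut: float = 1e-3) -> pd.DataFrame:
    """Report windows labelled for both studies, ranked by combined min p.

    Each row carries the window coordinates, the per-study minimum p-value
    and its peak SNP, and the count of annotated sub-threshold SNPs.
    """
    retained = joint_retained(stats_a, stats_b, grid)
    la = label_windows(stats_a, annot_track, grid, p_cut, retained)
    lb = label_windows(stats_b, annot_track, grid, p_cut, retained)
    joint = retained[(la.labels & lb.labels).astype(bool)]
    if joint.size == 0:
        logger.warning("no joint windows found")
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "min_p_a", "peak_snp_a", "min_p_b",
            "peak_snp_b", "n_annotated_hits",
        ])
    windows = grid.windows()
    rows = []
    for study_stats in (stats_a, stats_b):
        study_stats.table["_win"] = grid.window_of(
            study_stats.table["chrom"], study_stats.table["bp"]
        )
    status_a = snp_annotation_status(stats_a, annot_track)
    status_b = snp_annotation_status(stats_b, annot_track)
    for w in joint:
        win = windows.loc[w]
        sub_a = stats_a.table[stats_a.table["_win"] == w]
        sub_b = stats_b.table[stats_b.table["_win"] == w]
        peak_a = sub_a.loc[sub_a["p"].idxmin()]
        peak_b = sub_b.loc[sub_b["p"].idxmin()]
        n_hits = int(
            ((sub_a["p"] < p_cut) & status_a[sub_a.index]).sum()
            + ((sub_b["p"] < p_cut) & status_b[sub_b.index]).sum()
        )
        rows.append((win["chrom"], win["start"], win["end"],
                     peak_a["p"], peak_a["snp"], peak_b["p"], peak_b["snp"],
                     n_hits))
    for study_stats in (stats_a, stats_b):
        study_stats.table.drop(columns="_win", inplace=True)
    out = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "min_p_a", "peak_snp_a", "min_p_b",
        "peak_snp_b", "n_annotated_hits",
    ])
    out["combined_min_p"] = out[["min_p_a", "min_p_b"]].min(axis=1)
    return out.sort_values("combined_min_p").reset_index(drop=True)
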