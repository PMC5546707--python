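"""Genome coordinate system and low-level interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` internally, matching
the BED convention used at every text interface. Interval sets are kept as
parallel numpy arrays of starts and ends, sorted and disjoint; helper
functions here normalise arbitrary input into that form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CoordinateError(ValueError):
    """An interval or position falls outside the declared chromosome bounds."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; every track validates against one.

    Parameters
    ----------
    chromosomes : ordered chromosome names (unique).
    lengths : mapping name -> length in bp (> 0).
    assembly : free-text assembly tag, e.g. ``"hg19"`` or ``"synthetic"``.
    """

    chromosomes: tuple
    lengths: Mapping[str, int]
    assembly: str = "custom"

    def __post_init__(self):
        chroms = tuple(self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if len(set(chroms)) != len(chroms):
            raise ValueError("chromosome names must be unique")
        for c in chroms:
            if c not in self.lengths:
                raise ValueError(f"missing length for chromosome {c!r}")
            if int(self.lengths[c]) <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")
        object.__setattr__(
            self, "lengths", {c: int(self.lengths[c]) for c in chroms}
        )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def autosomes(self) -> tuple:
        """Chromosome names excluding sex chromosomes (X/Y, chrX/chrY)."""
        sex = {"X", "Y", "chrX", "chrY"}
        return tuple(c for c in self.chromosomes if c not in sex)

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        n = self.length(chrom)
        if not (0 <= start < end <= n):
            raise CoordinateError(
                f"interval {chrom}:[{start},{end}) outside [0,{n})"
            )


def merge_intervals(starts, ends):
    """Sort and merge overlapping or touching ``[start, end)`` intervals.

    Returns (starts, ends) as int64 arrays, sorted and strictly disjoint
    (``end_i < start_{i+1}``).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("intervals must satisfy start < end")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # a new merged block begins wherever the start exceeds the running max end
    run_end = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_end[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out_starts = starts[new_block]
    out_ends = np.zeros(n_blocks, dtype=np.int64)
    np.maximum.at(out_ends, block_id, ends)
    return out_starts, out_ends


def intervals_from_frame(df: pd.DataFrame, layout: GenomeLayout | None = None,
                         merge: bool = True) -> dict:
    """Convert a (chrom, start, end) DataFrame into per-chromosome arrays."""
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        if layout is not None:
            n = layout.length(str(chrom))
            if np.any(s < 0) or np.any(e > n) or np.any(s >= e):
                bad = grp[(s < 0) | (e > n) | (s >= e)].iloc[0]
                raise CoordinateError(
                    f"interval {chrom}:[{bad['start']},{bad['end']}) outside "
                    f"[0,{n})"
                )
        out[str(chrom)] = merge_intervals(s, e) if merge else (s, e)
    return out


def frame_from_intervals(per_chrom: Mapping[str, tuple]) -> pd.DataFrame:
    rows = []
    for chrom, (s, e) in per_chrom.items():
        for a, b in zip(s, e):
            rows.append((chrom, int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def total_length(per_chrom: Mapping[str, tuple]) -> int:
    return int(sum((e - s).sum() for s, e in per_chrom.values()))


def flank_intervals(per_chrom: Mapping[str, tuple], layout: GenomeLayout,
                    flank_bp: int) -> dict:
    """Extend each interval by ``flank_bp`` on both sides, clip, and merge."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    out = {}
    for chrom, (s, e) in per_chrom.items():
        n = layout.length(chrom)
        s2 = np.clip(s - flank_bp, 0, n)
        e2 = np.clip(e + flank_bp, 0, n)
        out[chrom] = merge_intervals(s2, e2)
    return out


def _covered_before(x, starts, ends, cumlen):
    """Total covered bp strictly below each position in ``x``.

    ``cumlen`` is the 0-prefixed cumulative length of the (disjoint, sorted)
    intervals.
    """
    x = np.asarray(x, dtype=np.int64)
    i = np.searchsorted(starts, x, side="right")
    cov = cumlen[i]
    if starts.size:
        prev = np.maximum(i - 1, 0)
        over = np.clip(ends[prev] - x, 0, None)
        cov = cov - np.where(i > 0, over, 0)
    return cov


def overlap_bp(set_a: Mapping[str, tuple], set_b: Mapping[str, tuple]) -> int:
    """Total overlap in bp between two merged interval sets."""
    total = 0
    for chrom, (sa, ea) in set_a.items():
        if chrom not in set_b or sa.size == 0:
            continue
        sb, eb = set_b[chrom]
        if sb.size == 0:
            continue
        cum = np.concatenate(([0], np.cumsum(eb - sb)))
        total += int(
            (_covered_before(ea, sb, eb, cum)
             - _covered_before(sa, sb, eb, cum)).sum()
        )
    return total


def positions_in(per_chrom: Mapping[str, tuple], chroms, positions) -> np.ndarray:
    """Boolean membership of 0-based positions in a merged interval set."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(positions.size, dtype=bool)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        if str(chrom) not in per_chrom:
            continue
        s, e = per_chrom[str(chrom)]
        if s.size == 0:
            continue
        pos = positions[sel]
        i = np.searchsorted(s, pos, side="right") - 1
        ok = (i >= 0) & (pos < e[np.maximum(i, 0)])
        out[sel] = ok
    return out
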