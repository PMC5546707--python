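"""Plain-text readers and writers for the track formats.

Supported: chrom.sizes layout files, BED (binary tracks, masks, elements),
narrowPeak (peaks with -log10 p-values), bedGraph (scored runs and binned
RNA signal). All files use the BED convention of 0-based half-open
intervals, which matches the in-memory representation directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeLayout, intervals_from_frame
from .tracks import BinaryTrack, ScoreTrack

logger = logging.getLogger(__name__)


def read_chrom_sizes(path, assembly: str = "custom") -> GenomeLayout:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return GenomeLayout(tuple(df["chrom"]),
                        dict(zip(df["chrom"], df["length"].astype(int))),
                        assembly=assembly)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for c in layout.chromosomes:
            fh.write(f"{c}\t{layout.lengths[c]}\n")


def read_bed(path) -> pd.DataFrame:
    """Read the first 3-4 BED columns (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     dtype={0: str})
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a narrowPeak file, converting -log10 p to a ``p`` column."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "neglog10p", "neglog10q", "summit"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = cols[: df.shape[1]]
    if "neglog10p" in df:
        df["p"] = 10.0 ** (-df["neglog10p"].astype(float))
    elif df.shape[1] >= 4:
        # fall back on BED+p: fourth column is a plain p-value
        df = df.rename(columns={"name": "p"})
        df["p"] = df["p"].astype(float)
    return df


def read_bed_values(path, value_name: str = "value") -> pd.DataFrame:
    """BED with a numeric fourth column (methylation fraction, rpkm, ...)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", value_name],
                     dtype={"chrom": str})
    df[value_name] = df[value_name].astype(float)
    return df


def read_bedgraph(path) -> pd.DataFrame:
    return read_bed_values(path, "value")


def write_bed(track: BinaryTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.layout.chromosomes:
            s, e = track.intervals(chrom)
            for a, b in zip(s, e):
                fh.write(f"{chrom}\t{a}\t{b}\n")


def write_bedgraph(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.layout.chromosomes:
            s, e, v = track.runs(chrom)
            for a, b, x in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{x:.6g}\n")


def track_from_bed(layout: GenomeLayout, path, resolution: int = 1) -> BinaryTrack:
    df = read_bed(path)
    if len(df) == 0:
        return BinaryTrack(layout, {}, resolution=resolution)
    return BinaryTrack(layout, intervals_from_frame(df, layout),
                       resolution=resolution)


def track_from_bedgraph(layout: GenomeLayout, path, resolution: int = 1) -> ScoreTrack:
    df = read_bedgraph(path)
    runs = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        runs[str(chrom)] = (grp["start"].to_numpy(np.int64),
                            grp["end"].to_numpy(np.int64),
                            grp["value"].to_numpy(float))
    return ScoreTrack(layout, runs, resolution=resolution)
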