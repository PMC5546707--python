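"""Tissue-specificity index (TSI) and element-set validation workflows.

The TSI of an element j over N tissues is

    TSI_j = sum_i (1 - x_{j,i}) / (N - 1)

where x_{j,i} is the expression of tissue i divided by the row maximum.
TSI is 1 when the element is expressed in exactly one tissue and 0 when
expression is uniform. Elements above a TSI threshold (default 0.75,
strict) are assigned to their maximally expressed tissue and their genomic
footprints are scored against each tissue's functionality track: a
well-calibrated annotation should give the matched tissue the largest
functional proportion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .tracks import flank_regions, functional_proportion

logger = logging.getLogger(__name__)


def compute_tsi(expr: pd.DataFrame) -> pd.Series:
    """Per-element TSI in [0, 1] from an elements-by-tissues matrix.

    Raises on rows with no positive expression (TSI undefined there).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    values = expr.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression intensities must be non-negative")
    row_max = values.max(axis=1)
    dead = row_max <= 0
    if dead.any():
        name = expr.index[np.flatnonzero(dead)[0]]
        raise ValueError(f"element {name!r} has all-zero expression")
    x = values / row_max[:, None]
    tsi = (1.0 - x).sum(axis=1) / (expr.shape[1] - 1)
    return pd.Series(tsi, index=expr.index, name="tsi")


def select_specific(expr: pd.DataFrame, tsi_threshold: float = 0.75) -> pd.DataFrame:
    """Elements with TSI strictly above the threshold, with argmax tissue.

    Argmax ties resolve to the lowest-index tissue and are logged.
    """
    tsi = compute_tsi(expr)
    keep = tsi > tsi_threshold
    sub = expr.loc[keep]
    values = sub.to_numpy(dtype=float)
    arg = values.argmax(axis=1)
    n_tied = int((values == values.max(axis=1)[:, None]).sum(axis=1).max()) \
        if len(sub) else 1
    if n_tied > 1:
        logger.info("argmax ties resolved to the lowest-index tissue")
    return pd.DataFrame({
        "tsi": tsi[keep],
        "tissue": [expr.columns[i] for i in arg],
    }, index=sub.index)


def validate_elements(elements_by_tissue: dict, tracks: dict,
                      cutoff: float = 0.5) -> pd.DataFrame:
    """Functional proportion of each element set under each track.

    ``elements_by_tissue`` maps set name -> (chrom, start, end) DataFrame;
    ``tracks`` maps track name -> Binary/ScoreTrack. Returns a matrix with
    one row per element set and one column per track, plus a ``best_track``
    column naming the argmax.
    """
    rows = {}
    for set_name, elements in elements_by_tissue.items():
        if elements is None or len(elements) == 0:
            raise ValueError(f"element set {set_name!r} is empty")
        rows[set_name] = {
            track_name: functional_proportion(track, elements, cutoff=cutoff)
            for track_name, track in tracks.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["best_track"] = out.idxmax(axis=1)
    return out


def cns_flank_profile(layout: GenomeLayout, cns_sites: pd.DataFrame,
                      tracks: dict, flank_bp: int = 200,
                      cutoff: float = 0.5) -> pd.Series:
    """Per-track functional proportion over conserved sites plus flanks.

    Sites are extended by ``flank_bp`` both sides, clipped, and merged
    before scoring, mirroring the conserved-noncoding-sequence analysis of
    locus control regions.
    """
    flanked = flank_regions(layout, cns_sites, flank_bp=flank_bp)
    return pd.Series({
        name: functional_proportion(track, flanked, cutoff=cutoff)
        for name, track in tracks.items()
    }, name="functional_proportion")
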