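"""GWAS summary statistics: parsing, region masks, and two-stage z algebra.

A :class:`SumStats` wraps a per-SNP table (id, chromosome, 1-based bp,
z-score, two-sided p-value, sample size). Named genomic masks remove SNPs
in regions with atypical LD or outsized effects (the MHC in heritability
analyses; the APOE region, chr19:45,147,340-45,594,595 on hg19, in
Alzheimer SNP reprioritization).

For a two-stage study reporting stage-I and combined meta-analysis
z-scores, the unpublished stage-II z is recovered from the sample-size
weighted meta-analysis model:

    z_meta = (z1 * sqrt(n1) + z2 * sqrt(n2)) / sqrt(n1 + n2)
    z2     = z_meta * sqrt(n1 + n2) / sqrt(n2) - z1 * sqrt(n1) / sqrt(n2)

which are exact mutual inverses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout

logger = logging.getLogger(__name__)

REQUIRED = ("snp", "chrom", "bp")

#: APOE region, 1-based inclusive hg19 coordinates.
APOE_REGION = ("chr19", 45_147_340, 45_594_595)


def p_to_z(p, sign=None):
    """Two-sided p to |z|; optional effect sign restores direction."""
    z = sps.norm.isf(np.asarray(p, float) / 2.0)
    if sign is not None:
        z = z * np.sign(sign)
    return z


def z_to_p(z):
    p = 2.0 * sps.norm.sf(np.abs(np.asarray(z, float)))
    # extreme z underflows the two-sided p to 0; keep it representable
    return np.maximum(p, 1e-300)


@dataclass
class SumStats:
    """Per-SNP association records for one study."""

    table: pd.DataFrame
    study: str = "study"

    def __post_init__(self):
        df = self.table
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df["snp"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        if "z" not in df.columns and "p" not in df.columns:
            raise ValueError("need a z or p column")
        if "p" in df.columns:
            p = df["p"].to_numpy(float)
            if np.any((p <= 0) | (p > 1)):
                raise ValueError("p-values must lie in (0, 1]")
        if "z" not in df.columns:
            sign = df["beta"] if "beta" in df.columns else None
            df = df.assign(z=p_to_z(df["p"], sign))
            if sign is None:
                logger.warning(
                    "no z or effect column; z magnitudes derived from p "
                    "without sign"
                )
        if "p" not in df.columns:
            df = df.assign(p=z_to_p(df["z"]))
        else:
            # two-sided consistency between z and p
            implied = z_to_p(df["z"])
            if not np.allclose(implied, df["p"].to_numpy(float),
                               rtol=1e-3, atol=1e-6):
                raise ValueError("z and p columns are inconsistent (two-sided)")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chisq(self) -> np.ndarray:
        return self.table["z"].to_numpy(float) ** 2

    def validate_layout(self, layout: GenomeLayout) -> None:
        for chrom, grp in self.table.groupby("chrom"):
            n = layout.length(str(chrom))
            bp = grp["bp"].to_numpy()
            if bp.min() < 1 or bp.max() > n:
                raise ValueError(f"bp outside {chrom} bounds")


@dataclass
class GenomicMask:
    """Named excluded regions; bp coordinates are 1-based inclusive."""

    regions: list = field(default_factory=list)  # (name, chrom, start, end)

    @classmethod
    def from_bed(cls, path) -> "GenomicMask":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "name"],
                         dtype={"chrom": str})
        # BED is 0-based half-open; convert to 1-based inclusive bp
        return cls([(str(r["name"]), str(r["chrom"]),
                     int(r["start"]) + 1, int(r["end"]))
                    for _, r in df.iterrows()])

    @classmethod
    def apoe(cls) -> "GenomicMask":
        chrom, s, e = APOE_REGION
        return cls([("APOE", chrom, s, e)])

    def add(self, name: str, chrom: str, start_1based: int, end_1based: int):
        if start_1based > end_1based or start_1based < 1:
            raise ValueError("invalid mask interval")
        self.regions.append((name, chrom, start_1based, end_1based))
        return self

    def covers(self, chroms, bp) -> np.ndarray:
        chroms = np.asarray(chroms).astype(str)
        bp = np.asarray(bp, dtype=np.int64)
        hit = np.zeros(bp.size, dtype=bool)
        for _, chrom, s, e in self.regions:
            hit |= (chroms == chrom) & (bp >= s) & (bp <= e)
        return hit


def exclude_regions(stats: SumStats, mask: GenomicMask) -> SumStats:
    """Drop SNPs whose position falls in any masked region."""
    if not mask.regions:
        return stats
    hit = mask.covers(stats.table["chrom"], stats.table["bp"])
    n_removed = int(hit.sum())
    logger.info("mask removed %d of %d SNPs", n_removed, len(stats))
    remaining = stats.table.loc[~hit].reset_index(drop=True)
    if len(remaining) == 0:
        raise ValueError("mask removed every SNP")
    return SumStats(remaining, study=stats.study)


def meta_z(z1, z2, n1, n2):
    """Sample-size weighted meta-analysis z of two independent stages."""
    if np.any(np.asarray(n1) <= 0) or np.any(np.asarray(n2) <= 0):
        raise ValueError("sample sizes must be positive")
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    out = (z1 * np.sqrt(n1) + z2 * np.sqrt(n2)) / np.sqrt(n1 + n2)
    return float(out) if out.ndim == 0 else out


def infer_stage2_z(z1, z12, n1, n2):
    """Invert the meta-analysis: stage-II z from stage-I and combined z."""
    if np.any(np.asarray(n2) <= 0) or np.any(np.asarray(n1) <= 0):
        raise ValueError("sample sizes must be positive")
    z1, z12 = np.asarray(z1, float), np.asarray(z12, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    out = z12 * np.sqrt(n1 + n2) / np.sqrt(n2) - z1 * np.sqrt(n1) / np.sqrt(n2)
    return float(out) if out.ndim == 0 else out


_ALIASES = {
    "snp": {"snp", "rsid", "rs", "id", "markername"},
    "chrom": {"chr", "chrom", "chromosome"},
    "bp": {"bp", "pos", "position", "base_pair_location"},
    "z": {"z", "zscore", "z_score", "stat"},
    "p": {"p", "pval", "pvalue", "p_value"},
    "n": {"n", "nsum", "samplesize", "n_total"},
    "beta": {"beta", "b", "effect", "log_odds"},
}


def read_sumstats(path, study: str | None = None) -> SumStats:
    """Read a whitespace/tab-delimited summary file with header detection.

    Recognised (case-insensitive) columns: SNP/RSID, CHR, BP/POS, Z, P,
    N, BETA. When Z is absent it is derived from P and the effect sign.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "chr": str})
    rename = {}
    for col in df.columns:
        low = col.lower()
        for canon, names in _ALIASES.items():
            if low in names:
                rename[col] = canon
    df = df.rename(columns=rename)
    df["chrom"] = df["chrom"].astype(str)
    return SumStats(df, study=study or str(path))


def write_sumstats(stats: SumStats, path) -> None:
    cols = [c for c in ("snp", "chrom", "bp", "z", "p", "n")
            if c in stats.table.columns]
    stats.table[cols].rename(columns=str.upper).to_csv(
        path, sep="\t", index=False
    )
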