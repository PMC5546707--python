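"""Synthetic fixtures with planted ground truth for every module.

The generators emulate the statistical shape of the real inputs — binary
annotation tracks from the two-class Bernoulli mixture, a genotype
reference panel with local LD, paired GWAS summary statistics with
per-category heritability and optional shared association windows, and an
elements-by-tissues expression matrix — at a scale where planted
parameters can be recovered on a laptop. Each generator is deterministic
given its spec's seed and returns a machine-readable truth record.

Key default conditions: functional prior 0.1 with strongly informative
activating marks (odds ratios well above 1) and a reversed H3K9me3 effect;
adjacent-SNP r-squared near 0.5 from first-order haplotype copying; cM
positions linear in bp at 1 cM/Mb; GWAS chi-square statistics drawn with
exact panel LD so that the expected chi-square is 1 + N * sum_c tau_c *
l(j, c).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout
from .heritability import GenotypePanel, make_annot
from .model import ANNOTATIONS, MixtureParams
from .sumstats import SumStats, z_to_p
from .tracks import BinaryTrack

__all__ = [
    "SyntheticSpec",
    "default_mixture_params",
    "sample_patterns",
    "gen_annotation_tracks",
    "gen_genotype_panel",
    "gen_gwas_pair",
    "gen_expression",
    "write_truth",
]


def default_mixture_params() -> MixtureParams:
    """Planted mixture: sparse functionality, informative activating marks.

    H3K4me3, H3K9ac and DNase carry the largest odds ratios; H3K9me3 is
    mildly depleted in functional regions (reversed effect); the rest are
    moderately informative.
    """
    p1 = np.array([0.60, 0.85, 0.40, 0.20, 0.04, 0.55, 0.80, 0.75, 0.35, 0.50])
    p0 = np.array([0.08, 0.03, 0.06, 0.10, 0.08, 0.05, 0.03, 0.04, 0.04, 0.10])
    return MixtureParams(0.1, np.column_stack([p0, p1]))


@dataclass
class SyntheticSpec:
    """Reproducible description of one synthetic dataset."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    assembly: str = "synthetic"
    # annotation tracks
    mixture: MixtureParams = field(default_factory=default_mixture_params)
    segment_bp: int = 25
    # genotype panel + GWAS
    n_snps: int = 20_000
    n_individuals: int = 500
    gwas_n: float = 50_000.0
    h2_total: float = 0.5
    category_coverage: float = 0.10
    category_enrichment: float = 5.0
    n_shared_windows: int = 0
    shared_effect_z: float = 7.0
    window_bp: int = 1_000_000
    copy_low: float = 0.45
    copy_high: float = 0.92
    maf_low: float = 0.2
    maf_high: float = 0.4
    # expression matrix
    n_elements: int = 200
    n_tissues: int = 6
    specific_fraction: float = 0.5
    element_bp: int = 200

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))
        return GenomeLayout(names,
                            {c: self.chromosome_length for c in names},
                            assembly=self.assembly)


def sample_patterns(params: MixtureParams, n: int, rng) -> tuple:
    """Draw ``n`` latent states and annotation 10-vectors from the mixture."""
    z = rng.random(n) < params.pi
    probs = np.where(z[:, None], params.p[:, 1], params.p[:, 0])
    a = (rng.random((n, params.p.shape[0])) < probs).astype(np.uint8)
    return a, z.astype(np.uint8)


def gen_annotation_tracks(spec: SyntheticSpec):
    """Planted-mixture annotation tracks plus the latent truth track.

    The genome is tiled into segments of ``segment_bp``; each segment draws
    one latent state and one annotation pattern. Returns
    ``(tracks, truth_track, truth)`` where ``tracks`` maps annotation name
    to BinaryTrack and ``truth`` records the planted parameters.
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed)
    params = spec.mixture
    names = params.annotations
    track_iv = {name: {} for name in names}
    truth_iv = {}
    n_func = 0
    n_seg_total = 0
    for chrom in layout.chromosomes:
        n = layout.length(chrom)
        starts = np.arange(0, n, spec.segment_bp, dtype=np.int64)
        ends = np.minimum(starts + spec.segment_bp, n)
        a, z = sample_patterns(params, starts.size, rng)
        n_func += int(z.sum())
        n_seg_total += starts.size
        truth_iv[chrom] = (starts[z == 1], ends[z == 1])
        for i, name in enumerate(names):
            on = a[:, i] == 1
            track_iv[name][chrom] = (starts[on], ends[on])
    tracks = {name: BinaryTrack(layout, iv) for name, iv in track_iv.items()}
    truth_track = BinaryTrack(layout, truth_iv)
    truth = {
        "seed": spec.seed,
        "pi": params.pi,
        "p0": params.p[:, 0].tolist(),
        "p1": params.p[:, 1].tolist(),
        "annotations": list(names),
        "segment_bp": spec.segment_bp,
        "functional_segment_fraction": n_func / n_seg_total,
    }
    return tracks, truth_track, truth


@dataclass
class _LdModel:
    """Markov LD model shared by the panel and the summary statistics.

    Within a chromosome, haplotype alleles copy their left neighbour with a
    per-SNP probability ``c_k`` (drawn per SNP, emulating variable LD
    blocks) and otherwise redraw from the chromosome's allele frequency.
    The chain is stationary, so the true genotype correlation between SNPs
    j < k is exactly ``prod_{i=j+1..k} c_i``; adjacent r-squared averages
    near 0.5 under the default copy range.
    """

    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray
    maf: np.ndarray              # one frequency per SNP (constant per chrom)
    copy_p: np.ndarray           # c_k; c of the first SNP per chrom is 0

    def corr_apply(self, beta: np.ndarray) -> np.ndarray:
        """Exact O(M) product R @ beta for the Markov correlation matrix.

        Uses the forward/backward recursions S_j = c_j S_{j-1} + beta_j and
        T_j = c_{j+1} T_{j+1} + beta_j, giving (R beta)_j = S_j + T_j -
        beta_j.
        """
        c = self.copy_p
        s = np.empty_like(beta)
        t = np.empty_like(beta)
        m = beta.size
        s[0] = beta[0]
        for j in range(1, m):
            s[j] = c[j] * s[j - 1] + beta[j]
        t[m - 1] = beta[m - 1]
        for j in range(m - 2, -1, -1):
            t[j] = c[j + 1] * t[j + 1] + beta[j]
        return s + t - beta

    def draw_correlated_noise(self, rng) -> np.ndarray:
        """One draw of e ~ N(0, R) via the AR recursion."""
        g = rng.normal(size=self.copy_p.size)
        e = np.empty_like(g)
        c = self.copy_p
        e[0] = g[0]
        for j in range(1, g.size):
            e[j] = c[j] * e[j - 1] + np.sqrt(1.0 - c[j] ** 2) * g[j]
        return e

    def true_ld_scores(self) -> np.ndarray:
        """Analytic base-category LD scores sum_k r2_jk (untruncated)."""
        ones = np.ones(self.copy_p.size)
        model2 = _LdModel(self.chrom, self.bp, self.cm, self.maf,
                          self.copy_p ** 2)
        return model2.corr_apply(ones)


def _build_ld_model(spec: SyntheticSpec, rng) -> _LdModel:
    layout = spec.layout()
    per_chrom = max(2, spec.n_snps // spec.n_chromosomes)
    chrom_l, bp_l, cm_l, maf_l, copy_l = [], [], [], [], []
    for chrom in layout.chromosomes:
        n = layout.length(chrom)
        pos = np.sort(rng.choice(np.arange(1, n + 1), size=per_chrom,
                                 replace=False))
        maf = np.full(per_chrom, rng.uniform(spec.maf_low, spec.maf_high))
        c = rng.uniform(spec.copy_low, spec.copy_high, size=per_chrom)
        c[0] = 0.0  # chromosomes are independent
        chrom_l.extend([chrom] * per_chrom)
        bp_l.append(pos)
        cm_l.append(pos * 1e-6)
        maf_l.append(maf)
        copy_l.append(c)
    return _LdModel(np.array(chrom_l), np.concatenate(bp_l),
                    np.concatenate(cm_l), np.concatenate(maf_l),
                    np.concatenate(copy_l))


def gen_genotype_panel(spec: SyntheticSpec, rng=None,
                       model: _LdModel | None = None) -> GenotypePanel:
    """Reference panel drawn from the Markov LD model.

    Haplotypes follow the stationary copying chain; genotypes are sums of
    two independent haplotypes, so the panel's population LD is exactly the
    model's ``prod c_i`` correlation. cM positions are linear in bp at
    1 cM/Mb.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    if model is None:
        model = _build_ld_model(spec, rng)
    n_hap = 2 * spec.n_individuals
    m = model.copy_p.size
    hap = np.empty((n_hap, m), dtype=np.int8)
    maf, c = model.maf, model.copy_p
    fresh = rng.random((n_hap, m)) < maf
    copy = rng.random((n_hap, m)) < c
    hap[:, 0] = fresh[:, 0]
    for k in range(1, m):
        hap[:, k] = np.where(copy[:, k], hap[:, k - 1], fresh[:, k])
    g = hap[: spec.n_individuals] + hap[spec.n_individuals:]
    # repair the (rare) monomorphic column by flipping one genotype
    for k in np.flatnonzero(g.std(axis=0) == 0):
        g[0, k] = 1 if g[0, k] != 1 else 0
    return GenotypePanel(
        g,
        np.array([f"rs{i}" for i in range(m)]),
        model.chrom,
        model.bp,
        model.cm,
    )


def _plant_variances(spec: SyntheticSpec, member: np.ndarray):
    """Per-SNP effect variances realising the planted enrichment.

    In-category SNPs carry ``E`` times the genome-average per-SNP
    heritability; outside SNPs absorb the remainder so the total is
    ``h2_total``.
    """
    m = member.size
    cov = member.mean()
    v_bar = spec.h2_total / m
    e = spec.category_enrichment
    v_in = e * v_bar
    v_out = (1 - e * cov) / (1 - cov) * v_bar
    if v_out < 0:
        raise ValueError("planted enrichment and coverage imply negative "
                         "background variance")
    return np.where(member, v_in, v_out), v_in, v_out


@dataclass
class GwasPair:
    panel: GenotypePanel
    annot: pd.DataFrame
    functional_track: BinaryTrack
    stats_a: SumStats
    stats_b: SumStats
    truth: dict


def gen_gwas_pair(spec: SyntheticSpec) -> GwasPair:
    """Panel, annotation, and two GWAS with planted architecture.

    z-scores are drawn as ``z = sqrt(N) R beta + e`` with ``e ~ N(0, R)``,
    where R is the exact Markov-model LD matrix (the population LD of the
    panel), so that ``E[chi2_j] = 1 + N sum_k r2_jk v_k`` and the panel's
    adjusted-r2 LD scores estimate the matching ``l(j, c)`` without bias.
    A ``functional`` category covers
    ``category_coverage`` of SNPs with ``category_enrichment``-fold
    per-SNP heritability. When ``n_shared_windows > 0``, that many windows
    receive a large fixed effect at one annotated SNP in both traits
    (planted pleiotropy).
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed + 2)
    model = _build_ld_model(spec, rng)
    panel = gen_genotype_panel(spec, rng, model=model)
    m = panel.n_snps
    member = rng.random(m) < spec.category_coverage
    if not member.any():
        member[rng.integers(m)] = True
    v, v_in, v_out = _plant_variances(spec, member)

    # annotation track: small intervals around member SNPs, clipped at the
    # midpoints to neighbouring SNPs so each interval contains exactly its
    # member SNP (keeps the per-SNP membership indicator exchangeable, the
    # null the permutation test assumes)
    iv = {}
    for chrom in layout.chromosomes:
        on_chrom = panel.chrom == chrom
        pos_all = panel.bp[on_chrom] - 1
        sel = member[on_chrom]
        pos0 = pos_all[sel]
        n = layout.length(chrom)
        left_mid = np.full(pos_all.size, 0, dtype=np.int64)
        right_mid = np.full(pos_all.size, n, dtype=np.int64)
        left_mid[1:] = (pos_all[:-1] + pos_all[1:]) // 2 + 1
        right_mid[:-1] = (pos_all[:-1] + pos_all[1:]) // 2 + 1
        s = np.clip(pos0 - 50, left_mid[sel], None)
        e = np.clip(pos0 + 51, None, np.maximum(right_mid[sel], pos0 + 1))
        iv[chrom] = (s, e)
    functional_track = BinaryTrack(layout, iv)
    annot = make_annot(panel.snp, panel.chrom, panel.bp,
                       {"functional": member})

    # shared pleiotropic windows
    shared_windows, shared_snps = [], []
    if spec.n_shared_windows > 0:
        win = (panel.bp - 1) // spec.window_bp
        win_key = pd.MultiIndex.from_arrays([panel.chrom, win])
        candidates = np.flatnonzero(member)
        rng.shuffle(candidates)
        chosen = {}
        for j in candidates:
            key = (panel.chrom[j], int(win[j]))
            if key not in chosen:
                chosen[key] = j
            if len(chosen) == spec.n_shared_windows:
                break
        shared_windows = sorted(chosen)
        shared_snps = [int(chosen[k]) for k in shared_windows]

    sqrt_n = np.sqrt(spec.gwas_n)

    def draw_stats(study: str) -> SumStats:
        if spec.h2_total > 0:
            beta = rng.normal(0.0, np.sqrt(v))
        else:
            beta = np.zeros(m)
        for j in shared_snps:
            beta[j] += spec.shared_effect_z / sqrt_n
        z = sqrt_n * model.corr_apply(beta) + model.draw_correlated_noise(rng)
        table = pd.DataFrame({
            "snp": panel.snp, "chrom": panel.chrom, "bp": panel.bp,
            "z": z, "p": z_to_p(z), "n": spec.gwas_n,
        })
        return SumStats(table, study=study)

    stats_a = draw_stats("trait_A")
    stats_b = draw_stats("trait_B")
    truth = {
        "seed": spec.seed,
        "n_snps": m,
        "n_individuals": panel.n_individuals,
        "gwas_n": spec.gwas_n,
        "h2_total": spec.h2_total,
        "category_coverage": float(member.mean()),
        "category_enrichment": spec.category_enrichment,
        "tau_base": float(v_out),
        "tau_functional": float(v_in - v_out),
        "shared_windows": [[c, int(w)] for c, w in shared_windows],
        "shared_snps": [panel.snp[j] for j in shared_snps],
    }
    return GwasPair(panel, annot, functional_track, stats_a, stats_b, truth)


def gen_expression(spec: SyntheticSpec):
    """Expression matrix with planted tissue-specific elements and tracks.

    A ``specific_fraction`` of elements is exactly one-hot (TSI = 1); the
    rest are near-uniform. Each tissue owns a contiguous genomic block;
    specific elements sit inside their tissue's block with probability 0.8
    and each tissue's track covers its own block plus a thin random
    background, so the matched track maximises the functional proportion
    by construction.

    Returns ``(expr, coords, tracks, truth)``.
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed + 3)
    n_el, n_ti = spec.n_elements, spec.n_tissues
    tissues = [f"tissue{t}" for t in range(n_ti)]
    n_specific = int(round(spec.specific_fraction * n_el))
    expr = np.empty((n_el, n_ti))
    owner = np.full(n_el, -1)
    for j in range(n_el):
        if j < n_specific:
            t = rng.integers(n_ti)
            owner[j] = t
            row = np.zeros(n_ti)
            row[t] = rng.uniform(5.0, 50.0)
        else:
            row = rng.uniform(1.0, 2.0) * rng.uniform(0.8, 1.25, size=n_ti)
        expr[j] = row
    expr_df = pd.DataFrame(expr, columns=tissues,
                           index=[f"el{j}" for j in range(n_el)])

    # one genomic block per tissue on chromosome 1
    chrom = layout.chromosomes[0]
    n = layout.length(chrom)
    block = n // n_ti
    coords_rows = []
    for j in range(n_el):
        t = owner[j]
        if t >= 0 and rng.random() < 0.8:
            start = int(rng.integers(t * block, (t + 1) * block - spec.element_bp))
        else:
            start = int(rng.integers(0, n - spec.element_bp))
        coords_rows.append((chrom, start, start + spec.element_bp))
    coords = pd.DataFrame(coords_rows, columns=["chrom", "start", "end"],
                          index=expr_df.index)

    tracks = {}
    for t, name in enumerate(tissues):
        s = [t * block]
        e = [(t + 1) * block]
        # thin random background outside the block (~10% of the rest)
        n_bg = 20
        for _ in range(n_bg):
            a = int(rng.integers(0, n - 2000))
            if not (t * block <= a < (t + 1) * block):
                s.append(a)
                e.append(a + int(0.1 * block // n_bg) + 100)
        iv = {chrom: (np.clip(np.array(s), 0, n), np.clip(np.array(e), 0, n))}
        tracks[name] = BinaryTrack(layout, iv)
    truth = {
        "seed": spec.seed,
        "n_specific": n_specific,
        "owner": {expr_df.index[j]: tissues[owner[j]]
                  for j in range(n_el) if owner[j] >= 0},
    }
    return expr_df, coords, tracks, truth


def write_truth(truth: dict, path) -> None:
    """Persist a generator's planted-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
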