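"""Two-class Bernoulli mixture over binary annotations and posterior scoring.

The genome is modelled as a mixture of functional (Z = 1) and non-functional
(Z = 0) nucleotides. At each position a vector A of ten binary annotations
(histone marks, DNase hypersensitivity, unmethylated CpG islands, RNA signal)
is observed; annotations are conditionally independent given Z, each
Bernoulli with class-conditional probability ``p_ic``. Together with the
functional prior ``pi`` this gives 21 free parameters. The per-nucleotide
posterior P(Z = 1 | A) is the tissue's functionality score.

Parameters are estimated by EM from training regions (1-kb intervals centred
on trait-associated SNPs). After fitting, the latent classes are relabelled
so that the activating marks H3K4me3, H3K9ac and DNase jointly predict
functionality positively, which resolves the label-switching ambiguity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, merge_intervals, total_length
from .tracks import BinaryTrack, ScoreTrack

logger = logging.getLogger(__name__)

#: Fixed annotation order for all 10-vector inputs.
ANNOTATIONS = (
    "H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3", "H3K9me3",
    "H3K27ac", "H3K9ac", "DNase", "CpG_unmethylated", "RNA",
)
#: Marks used to anchor class labels: strongest positive predictors.
ACTIVATING_MARKS = ("H3K4me3", "H3K9ac", "DNase")

_EPS = 1e-6


class DegenerateDataError(ValueError):
    """Training data carries no information (a single annotation pattern)."""


@dataclass
class MixtureParams:
    """Mixture parameters: prior ``pi`` and Bernoulli matrix ``p`` (10 x 2).

    Column 0 of ``p`` holds p_{i,0} (non-functional class), column 1 holds
    p_{i,1} (functional class). All entries are clamped to (0, 1).
    """

    pi: float
    p: np.ndarray
    annotations: tuple = ANNOTATIONS

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (len(self.annotations), 2):
            raise ValueError(f"p must be {len(self.annotations)} x 2")
        if not (0 < self.pi < 1):
            raise ValueError("pi must lie strictly in (0, 1)")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("all p_ic must lie strictly in (0, 1)")

    @property
    def n_parameters(self) -> int:
        """Free parameter count: the prior plus one Bernoulli rate per
        annotation and class."""
        return 1 + self.p.size

    def odds_ratio(self, i: int) -> float:
        """OR of annotation i for predicting functionality:
        [p_i1/(1-p_i1)] / [p_i0/(1-p_i0)]."""
        p1, p0 = self.p[i, 1], self.p[i, 0]
        return float((p1 / (1 - p1)) / (p0 / (1 - p0)))

    def swap_labels(self) -> "MixtureParams":
        return MixtureParams(1 - self.pi, self.p[:, ::-1].copy(),
                             self.annotations)

    # -- serialization ---------------------------------------------------
    def to_json(self, path, **meta) -> None:
        payload = {
            "format_version": 1,
            "pi": self.pi,
            "p0": self.p[:, 0].tolist(),
            "p1": self.p[:, 1].tolist(),
            "annotations": list(self.annotations),
            **meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MixtureParams":
        with open(path) as fh:
            d = json.load(fh)
        p = np.column_stack([d["p0"], d["p1"]])
        return cls(d["pi"], p, tuple(d["annotations"]))


@dataclass
class FitResult:
    params: MixtureParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class TrainingRegions:
    """Merged 1-kb training intervals around trait-associated SNPs."""

    intervals: dict  # chrom -> (starts, ends)
    total_bp: int
    n_snps: int


def build_training_regions(layout: GenomeLayout, snp_positions,
                           flank_total_bp: int = 1000) -> TrainingRegions:
    """Expand SNPs into centred intervals of ``flank_total_bp`` and merge.

    ``snp_positions`` is an iterable of (chrom, 0-based bp). Duplicates are
    deduplicated with a log message; overlapping intervals merge.
    """
    half = flank_total_bp // 2
    seen = set()
    per_chrom: dict = {}
    n_dup = 0
    for chrom, bp in snp_positions:
        if (chrom, bp) in seen:
            n_dup += 1
            continue
        seen.add((chrom, bp))
        n = layout.length(chrom)
        s = max(0, bp - half)
        e = min(n, bp - half + flank_total_bp)
        per_chrom.setdefault(chrom, []).append((s, e))
    if n_dup:
        logger.info("deduplicated %d duplicate SNP positions", n_dup)
    intervals = {}
    for chrom, pairs in per_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        intervals[chrom] = merge_intervals(arr[:, 0], arr[:, 1])
    return TrainingRegions(intervals, total_length(intervals), len(seen))


def extract_patterns(tracks, regions: TrainingRegions):
    """Annotation patterns and base counts over the training regions.

    Every base of the merged regions is one observation; bases sharing a
    pattern are aggregated into (pattern, count) pairs, which leaves the
    likelihood unchanged.
    """
    tracks = list(tracks)
    layout = tracks[0].layout
    pat_counts: dict = {}
    for chrom, (rs, re) in regions.intervals.items():
        bounds = [rs, re]
        for t in tracks:
            s, e = t.intervals(chrom)
            bounds.extend((s, e))
        cut = np.unique(np.concatenate(bounds))
        seg_s, seg_e = cut[:-1], cut[1:]
        # keep only segments inside the training regions
        idx = np.searchsorted(rs, seg_s, side="right") - 1
        inside = (idx >= 0) & (seg_s < re[np.maximum(idx, 0)])
        seg_s, seg_e = seg_s[inside], seg_e[inside]
        if seg_s.size == 0:
            continue
        pat = np.column_stack([t.contains(chrom, seg_s) for t in tracks])
        lengths = seg_e - seg_s
        for row, w in zip(pat.astype(np.uint8), lengths):
            key = tuple(row)
            pat_counts[key] = pat_counts.get(key, 0) + int(w)
    patterns = np.array(list(pat_counts.keys()), dtype=np.uint8)
    counts = np.array(list(pat_counts.values()), dtype=np.int64)
    return patterns, counts


def _log_bernoulli(patterns, p_col):
    logp = np.log(p_col)
    log1p = np.log1p(-p_col)
    return patterns @ logp + (1 - patterns) @ log1p


def fit_em(data, weights=None, init: MixtureParams | None = None,
           seed: int | None = 0, tol: float = 1e-6, max_iter: int = 1000,
           annotations: tuple = ANNOTATIONS) -> FitResult:
    """Fit the two-class Bernoulli mixture by EM.

    Parameters
    ----------
    data : (n, k) binary matrix of annotation observations, or already
        aggregated unique patterns when ``weights`` is given.
    weights : optional per-row counts for aggregated patterns.
    init : explicit starting parameters; otherwise a data-driven start with
        a small seeded jitter.
    tol : relative log-likelihood change declaring convergence.

    The log-likelihood is non-decreasing across iterations; estimated
    probabilities are clamped to ``[1e-6, 1 - 1e-6]`` with a warning when a
    boundary is hit. Classes are relabelled so that the activating marks
    (H3K4me3, H3K9ac, DNase, where present) jointly have positive log odds.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D binary matrix")
    k = data.shape[1]
    if weights is None:
        patterns, counts = np.unique(data, axis=0, return_counts=True)
    else:
        patterns, counts = data, np.asarray(weights, dtype=np.float64)
    if patterns.shape[0] < 2:
        raise DegenerateDataError(
            "training data must contain at least two distinct patterns"
        )
    counts = counts.astype(np.float64)
    n = counts.sum()

    if init is not None:
        pi = init.pi
        p = init.p.copy()
    else:
        rng = np.random.default_rng(seed)
        pi = 0.5
        pos = patterns.sum(axis=1) > 0
        w_pos = counts * pos
        w_neg = counts * ~pos
        freq_pos = (patterns * w_pos[:, None]).sum(0) / max(w_pos.sum(), 1.0)
        freq_neg = (patterns * w_neg[:, None]).sum(0) / max(w_neg.sum(), 1.0)
        p = np.column_stack([freq_neg, freq_pos])
        p = p + rng.uniform(-0.02, 0.02, size=p.shape)
        p = np.clip(p, 0.02, 0.98)

    clamped = False
    trace = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        l1 = np.log(pi) + _log_bernoulli(patterns, p[:, 1])
        l0 = np.log1p(-pi) + _log_bernoulli(patterns, p[:, 0])
        m = np.maximum(l0, l1)
        denom = m + np.log(np.exp(l0 - m) + np.exp(l1 - m))
        ll = float((counts * denom).sum())
        trace.append(ll)
        r = np.exp(l1 - denom)  # responsibility of class 1
        # M-step
        w1 = counts * r
        w0 = counts * (1 - r)
        pi = float(w1.sum() / n)
        pi = min(max(pi, _EPS), 1 - _EPS)
        p1 = (patterns * w1[:, None]).sum(0) / max(w1.sum(), _EPS)
        p0 = (patterns * w0[:, None]).sum(0) / max(w0.sum(), _EPS)
        p_new = np.column_stack([p0, p1])
        if np.any((p_new < _EPS) | (p_new > 1 - _EPS)):
            clamped = True
        p = np.clip(p_new, _EPS, 1 - _EPS)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
    if clamped:
        warnings.warn(
            "some Bernoulli estimates hit the boundary and were clamped to "
            "[1e-6, 1 - 1e-6]",
            stacklevel=2,
        )
    if not converged:
        warnings.warn("EM did not converge within max_iter", stacklevel=2)

    annotations = tuple(annotations[:k]) if len(annotations) >= k else tuple(
        f"A{i}" for i in range(k)
    )
    params = MixtureParams(pi, p, annotations)
    anchor = [annotations.index(a) for a in ACTIVATING_MARKS
              if a in annotations]
    if anchor:
        log_or = sum(np.log(params.odds_ratio(i)) for i in anchor)
        if log_or < 0:
            params = params.swap_labels()
            logger.info("relabelled mixture classes to orient activating marks")
    return FitResult(params, np.asarray(trace), converged, len(trace), seed)


def posterior_score(params: MixtureParams, a) -> np.ndarray | float:
    """Posterior probability of functionality for annotation vector(s) ``a``.

    Implements Bayes' rule for the conditionally independent Bernoulli
    likelihoods; accepts a single 10-vector or an (n, 10) matrix.
    """
    arr = np.asarray(a, dtype=np.float64)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    l1 = np.log(params.pi) + _log_bernoulli(arr, params.p[:, 1])
    l0 = np.log1p(-params.pi) + _log_bernoulli(arr, params.p[:, 0])
    post = 1.0 / (1.0 + np.exp(l0 - l1))
    return float(post[0]) if single else post


def score_genome(params: MixtureParams, tracks) -> ScoreTrack:
    """Apply the posterior base-by-base, yielding a run-length score track.

    Runs are the maximal segments over which the joint annotation pattern is
    constant; the value of a run equals :func:`posterior_score` of its
    pattern (including the all-zero pattern in unannotated gaps).
    """
    tracks = list(tracks)
    if len(tracks) != params.p.shape[0]:
        raise ValueError(
            f"expected {params.p.shape[0]} tracks, got {len(tracks)}"
        )
    layout = tracks[0].layout
    if any(t.layout != layout for t in tracks):
        raise ValueError("tracks must share one layout")
    runs = {}
    for chrom in layout.chromosomes:
        bounds = [np.array([0, layout.length(chrom)], dtype=np.int64)]
        for t in tracks:
            s, e = t.intervals(chrom)
            bounds.extend((s, e))
        cut = np.unique(np.concatenate(bounds))
        seg_s, seg_e = cut[:-1], cut[1:]
        pat = np.column_stack([t.contains(chrom, seg_s) for t in tracks])
        scores = posterior_score(params, pat.astype(np.float64))
        runs[chrom] = (seg_s, seg_e, scores)
    return ScoreTrack(layout, runs, resolution=min(t.resolution for t in tracks))


def annotation_odds_ratio(params: MixtureParams, i: int) -> float:
    """Odds ratio of annotation ``i`` for predicting functionality."""
    return params.odds_ratio(i)
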