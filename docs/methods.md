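# Methods

This note documents the statistical models implemented in `gsk`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about behaviour on real data.

## The functionality mixture model

Each nucleotide carries a latent binary state Z (functional in the given
tissue or not) and an observed vector **A** of ten binary annotations, in
fixed order: H3K4me1, H3K4me3, H3K36me3, H3K27me3, H3K9me3, H3K27ac,
H3K9ac, DNase, unmethylated CpG island, RNA. Annotations are conditionally
independent given Z, each Bernoulli with class-conditional rate p_ic, so
the model has 21 free parameters (the prior π plus a 10 × 2 rate matrix).
The tissue's score at a nucleotide is the posterior

    P(Z = 1 | A) = π Π_i f_i(A_i|1) / [π Π_i f_i(A_i|1) + (1−π) Π_i f_i(A_i|0)].

**Input binarization.** ChIP-seq peaks pass at an enrichment p-value
below 0.01; CpG islands count as unmethylated below a 0.5 methylation
fraction (strict); RNA signal passes at rpkm ≥ 0.5 in 25-bp bins.
Continuous scores are dichotomized at 0.5 with ties going to the
functional side — the score distribution is strongly bimodal, so the tie
rule and the exact cutoff matter little, but one convention (≥) is fixed
globally.

**Training.** SNPs curated as trait-associated are expanded into 1-kb
intervals centred on the SNP ([bp−500, bp+500)); overlapping intervals
merge and duplicate SNPs deduplicate. Every base of the merged regions is
one observation; identical annotation patterns aggregate into
(pattern, count) pairs, which leaves the likelihood unchanged and bounds
the E-step at 1,024 distinct patterns.

**EM details.** Initialisation: π₀ = 0.5; class rates start from the
empirical annotation frequencies among pattern-positive versus all-zero
rows, plus a small seeded jitter. Convergence: relative log-likelihood
change below 1e-6, or 1,000 iterations (non-convergence warns, never
errors). Rates are clamped to [1e-6, 1−1e-6] with a warning on boundary
hits. Label switching is resolved after fitting: classes are relabelled so
that the summed log odds ratios of H3K4me3, H3K9ac and DNase — the marks
that should predict functionality most strongly, with H3K9me3 expected to
reverse — are positive. When the planted rates are equal across classes
the likelihood is flat in the split and the fitted odds ratios are only
near 1 (tests bound them by a factor, not an ε).

## Tracks

Tracks are run-length encoded: sorted disjoint `[start, end)` runs per
chromosome, 0-based half-open (BED convention end to end), strandless.
Score-track gaps are implicit zeros. Window smoothing (default 10 kb,
used for the general-functionality tier) assigns each window its mean
score; the final partial window averages over its actual length, which
preserves the genome-wide mean exactly. Multi-donor samples are averaged
per base *before* dichotomization. The nearest-rank (no interpolation)
quantile defines the top-90%-quantile dichotomizer used to compare
external scoring tools on an equal footing. Mixed-resolution combinations
resolve to the finest input resolution.

## Tissue-specificity validation

TSI_j = Σ_i (1 − x_{j,i}) / (N − 1) with x row-normalised by the row
maximum (not the row sum): 1 means expression in exactly one tissue, 0
uniform. Elements with TSI strictly above 0.75 are assigned to their
maximally expressed tissue (ties → lowest-index tissue, logged) and their
merged genomic footprints are scored as the fraction of bases with score
strictly above 0.5 under each tissue's track; a sound annotation makes
the matched tissue the argmax. The conserved-noncoding-sequence profile
extends sites by 200 bp each side before scoring.

## Stratified heritability enrichment

LD scores: ℓ(j, c) = Σ_{k ∈ c, |cM_j − cM_k| ≤ 1} r̃²_{jk} with the
small-sample adjustment r̃² = r² − (1 − r²)/(n − 2) estimated from a
reference panel; the self term contributes exactly 1. Because null pairs
contribute slightly negative adjusted terms, a subcategory score can
exceed the base score by sampling noise — dominance holds in expectation,
and tests assert it with a noise tolerance.

The regression is weighted least squares of χ²_j on N·ℓ(j, c) with a free
intercept, after removing SNPs with χ² > 80 (configurable) and any
masked regions (MHC in all heritability analyses). Weights are
1/max(ℓ_base, 1) in a single pass — a deliberate simplification of the
reference method's iterative heteroskedasticity weighting, ample at the
package's scale. Uncertainty comes from a delete-one block jackknife over
contiguous SNP blocks (default 200).

Enrichment per category is the heritability share over the SNP coverage
share, with per-SNP heritability the additive h²_j = Σ_c τ_c a_{cj}
floored at zero when forming shares (negative τ can otherwise produce
negative per-SNP values; the flooring is recorded in output). The p-value
is a two-sided normal test of (enrichment − 1)/SE_jackknife. Per-SNP h²
also drives the per-chromosome partition, optionally restricted to SNPs
inside a functional mask.

On the synthetic conditions (20,000 SNPs, 500 panel individuals, planted
5× enrichment at 10% coverage) the recovered enrichment averages ~5.7
over 20 seeds: noise in the estimated LD scores acts as errors in
variables and attenuates the base coefficient slightly more than the
category coefficient, inflating the ratio. The effect shrinks with panel
size and stays inside the ±20% recovery band; the null false-positive
rate at α = 0.05 is ~4%.

## Pleiotropy scan

Autosomes are tiled into 1-Mb windows (windows without SNPs dropped, sex
chromosomes excluded; the last partial window is kept when it has SNPs).
A window is labelled for a study when it holds a SNP with p < 1e-3 that
lies inside the tissue annotation. Overlap between two studies' labels is
tested two ways: an upper-tail hypergeometric test with the retained
windows (those containing SNPs of both studies) as the population — one
reading of an under-specified test, recorded as such — and a permutation
test that shuffles the per-SNP membership indicator over the union of
both studies' positions, preserving the total annotated count, with the
add-one estimator p = (1 + #{null ≥ obs})/(n_perm + 1). The permutation
design also absorbs bias from shared control samples between studies.
The add-one estimator is conservative in the presence of ties, so its
null distribution sits slightly above uniform; the calibration fixture
uses 40 windows and ~300 SNPs per window so that the count statistic is
fine-grained enough for approximate uniformity. The synthetic functional
track clips each member SNP's interval at the midpoints to its
neighbours so the per-SNP membership indicator is exactly exchangeable —
the null the permutation assumes; real functional annotations cluster
spatially, which is precisely why the permutation (not the
hypergeometric) test is the primary inference on real data.

## SNP reprioritization

Three disjoint cases: (1) phenotype- and tissue-functional, (2)
tissue-functional only, (3) not tissue-functional. Case priors come from
splitting SNPs at a functionality-score threshold of 0.1 (the tissue
score is the annotation score at the SNP base; the general score is the
10-kb-smoothed general-functionality value — the point-score convention
is stated and configurable). Null p-value densities are 500-bin
equal-width histograms on (0, 1] over the low-score subgroups, with empty
bins floored at 1e-8 and renormalised; density evaluation uses the same
edge arithmetic as the estimating histogram. The high-tissue-score
p-values follow w·Beta(α, 1) + (1 − w)·f(p|Z=0) with α ∈ (0, 1); EM uses
the closed form α = −Σ r_j / Σ r_j log p_j, projected into
[1e-4, 1−1e-4]. As α → 1 the signal component degenerates to the uniform
and w is unidentified along a flat likelihood ridge; when the fitted
mixture improves on the pure null by less than an AIC-scale margin (4
log-likelihood units for the two extra parameters) the equivalent
no-signal fit w = 0 is reported. High-posterior SNPs (> 0.95) cluster
into loci within a 1-Mb merge window. For late-onset Alzheimer-like
phenotypes the APOE region (chr19:45,147,340–45,594,595, hg19, 1-based
inclusive) is masked before fitting.

## Two-stage z algebra

meta_z and infer_stage2_z implement the sample-size weighted
meta-analysis and its exact inverse. Note that equal per-stage z-scores
do *not* combine to themselves: z(√n1 + √n2)/√(n1 + n2) > z. The n₂ → 0
limit recovers the stage-I z, and the two functions are exact mutual
inverses for all finite inputs.

## Synthetic conditions

Annotation tracks: the genome is tiled into 25-bp segments; each segment
draws one latent state (π = 0.1) and one annotation pattern from the
planted rates (activating marks strongly informative, H3K9me3 mildly
reversed). EM recovery runs at 100,000 observations over 20 seeds.

GWAS architecture: a Markov LD model assigns each SNP a copy probability
c_k ∈ [0.45, 0.92] (adjacent r² averages near 0.5, emulating variable LD
blocks), one allele frequency per chromosome in [0.2, 0.4], and cM
positions linear at 1 cM/Mb. The true LD correlation between SNPs j < k
is exactly Π c_i, so summary statistics can be drawn from the exact model,
z = √N·Rβ + e with e ~ N(0, R), via O(M) recursions, giving
E[χ²_j] = 1 + N·Σ_c τ_c ℓ(j, c); the genotype panel is an independent
draw of the same process, so the package's adjusted-r² LD scores estimate
the matching ℓ without bias. Per-SNP effect variances realise a requested
coverage and fold-enrichment exactly; planted pleiotropy adds a fixed
effect at one annotated SNP per shared window in both traits. Default
study sizes: 20,000 SNPs, 500 panel individuals, N = 50,000, h² = 0.5.

What the fixtures do not emulate: realistic human allele-frequency
spectra, long-range LD and population structure, non-uniform SNP density,
annotation spatial clustering, and case/control ascertainment. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to the violations real data
present.

## Known limitations

- The stratified regression is single-pass weighted; no constrained
  intercept, no genetic-correlation machinery, no sample-overlap
  correction in the regression itself (the permutation design covers the
  pleiotropy use case).
- Enrichment recovery carries a mild upward bias from LD-score
  measurement noise at small panel sizes (see above).
- The hypergeometric window-test parameterisation is one reading of an
  under-specified design and is cross-checked by the permutation test.
- Histogram null densities assume enough low-score SNPs; with fewer than
  10 observations per bin the binning coarsens with a warning.
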