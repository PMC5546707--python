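# gsk — tissue-specific functional genome annotation

`gsk` scores every nucleotide of a genome for *tissue-specific functional
potential* by integrating binary epigenomic and transcriptomic annotations
— histone ChIP-seq peaks, DNase hypersensitivity, unmethylated CpG
islands, and binned RNA-seq signal — and carries those scores through the
downstream analyses that make them useful for complex-trait genetics:

- **Mixture model** (`gsk.model`): a two-class Bernoulli mixture over ten
  binary annotations. With prior π of functionality and class-conditional
  rates p_ic (21 free parameters), the per-nucleotide score is the
  posterior P(Z=1 | A) under conditional independence given Z. Parameters
  are estimated by EM on 1-kb regions around trait-associated SNPs.
- **Track algebra** (`gsk.tracks`, `gsk.io`): run-length binary and
  score tracks over a declared genome layout, with the binarization rules
  (peak p < 0.01, methylation fraction < 0.5, rpkm ≥ 0.5 at 25 bp),
  dichotomization at 0.5, 10-kb window smoothing, union/mean combination,
  functional proportions, and quantile-based dichotomization of external
  scores. BED/bedGraph/narrowPeak/chrom.sizes text formats throughout.
- **Specificity validation** (`gsk.specificity`): the tissue-specificity
  index TSI = Σ(1−x)/(N−1) with max-normalised expression, selection of
  highly specific elements (TSI > 0.75), and functional-proportion
  matrices that check whether each element set is maximised by its
  matched tissue track.
- **Heritability enrichment** (`gsk.heritability`):
  annotation-stratified LD scores (1-cM window, small-sample adjusted
  r²), a weighted regression of GWAS χ² on N·ℓ(j,c) with block-jackknife
  uncertainty, and per-category enrichment
  `%h² explained / %SNPs covered`, plus per-chromosome heritability
  partitions.
- **Pleiotropy scan** (`gsk.pleiotropy`): 1-Mb windows labelled when a
  sub-threshold SNP (p < 1e-3) falls inside the tissue annotation;
  cross-trait overlap tested by hypergeometric tail and by an
  annotation-status permutation test robust to shared controls.
- **SNP reprioritization** (`gsk.reprioritize`): the three-case Bayesian
  posterior P(phenotype- and tissue-functional | p) combining a
  Beta(α,1) signal component (closed-form EM) with histogram null
  densities from low-score SNP subgroups.
- **Two-stage algebra** (`gsk.sumstats`): summary-statistic parsing,
  MHC/APOE masks, and exact inversion of sample-size weighted
  meta-analysis z-scores to recover unpublished replication-stage
  results.
- **Synthetic fixtures** (`gsk.synth`): generators with planted ground
  truth for every chain — mixture tracks, an exact Markov-LD GWAS
  architecture, and expression matrices — so each estimator is tested
  against known parameters.

## Worked example

Fit the mixture on a synthetic tissue with planted π = 0.1 and score the
genome:

```python
import numpy as np
from gsk.synth import SyntheticSpec, gen_annotation_tracks
from gsk.model import (ANNOTATIONS, build_training_regions,
                       extract_patterns, fit_em, score_genome)
from gsk.tracks import dichotomize

spec = SyntheticSpec(seed=7, n_chromosomes=1, chromosome_length=500_000)
tracks, truth, info = gen_annotation_tracks(spec)
layout = spec.layout()
rng = np.random.default_rng(7)
snps = [("chr1", int(x)) for x in rng.integers(1000, 499_000, 200)]
regions = build_training_regions(layout, snps)
patterns, counts = extract_patterns([tracks[a] for a in ANNOTATIONS], regions)
fit = fit_em(patterns, weights=counts, seed=7)
print(f"pi = {fit.params.pi:.3f}  (planted 0.100)")
print(f"n_parameters = {fit.params.n_parameters}")
print(f"OR(H3K4me3) = {fit.params.odds_ratio(1):.1f}")
print(f"OR(H3K9me3) = {fit.params.odds_ratio(4):.2f}")
score = score_genome(fit.params, [tracks[a] for a in ANNOTATIONS])
called = dichotomize(score, 0.5)
print(f"functional fraction called = {called.coverage_fraction:.3f}")
```

prints

```
pi = 0.098  (planted 0.100)
n_parameters = 21
OR(H3K4me3) = 198.5
OR(H3K9me3) = 0.56
functional fraction called = 0.097
```

The estimated prior matches the planted functional fraction; the
activating promoter mark H3K4me3 has a large odds ratio for predicting
functionality while the repressive mark H3K9me3 has a reversed (below-1)
effect; and dichotomizing the posterior at 0.5 calls ~10% of the genome
functional, in line with the planted truth (precision 0.97, recall 0.95
against the latent state on this seed).

The enrichment arithmetic is equally direct: a category covering 24.4%
of SNPs that explains 98.7% of trait heritability has enrichment

```python
from gsk.heritability import enrichment_from_shares
round(enrichment_from_shares(98.7, 24.4), 1)   # 4.0
```

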