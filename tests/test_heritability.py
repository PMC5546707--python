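"""LD scores, stratified regression, enrichment, and file dialects."""

import numpy as np
import pandas as pd
import pytest

from gsk.genome import GenomeLayout
from gsk.heritability import (
    GenotypePanel,
    RankDeficientError,
    compute_ld_scores,
    enrichment,
    enrichment_from_shares,
    fit_stratified_regression,
    make_annot,
    partition_heritability_by_chrom,
    per_snp_h2,
    read_annot,
    read_ldscore,
    write_annot,
    write_ldscore,
)
from gsk.sumstats import SumStats, z_to_p
from gsk.synth import SyntheticSpec, gen_genotype_panel, gen_gwas_pair
from gsk.tracks import BinaryTrack


def tiny_panel(genotypes, cm=None, chrom=None):
    genotypes = np.asarray(genotypes)
    m = genotypes.shape[1]
    return GenotypePanel(
        genotypes,
        np.array([f"rs{i}" for i in range(m)]),
        np.array(chrom if chrom is not None else ["chr1"] * m),
        np.arange(m, dtype=np.int64) * 1000 + 1,
        np.asarray(cm if cm is not None else np.arange(m) * 1e-3),
    )


def base_annot(panel, **categories):
    return make_annot(panel.snp, panel.chrom, panel.bp, categories)


class TestLdScores:
    def test_isolated_snp_scores_one(self, rng):
        g = rng.integers(0, 3, size=(50, 3))
        g[:, 0] = rng.integers(0, 2, 50) + rng.integers(0, 2, 50)
        panel = tiny_panel(g, cm=np.array([0.0, 10.0, 20.0]))  # far apart
        ld = compute_ld_scores(panel, base_annot(panel))
        assert np.allclose(ld["base"], 1.0)

    def test_duplicated_snps_score_two(self, rng):
        col = rng.integers(0, 2, 80) + rng.integers(0, 2, 80)
        g = np.column_stack([col, col])
        panel = tiny_panel(g, cm=np.array([0.0, 0.001]))
        ld = compute_ld_scores(panel, base_annot(panel))
        assert np.allclose(ld["base"], 2.0, atol=1e-12)

    def test_independent_snps_average_near_one(self):
        spec = SyntheticSpec(seed=8, n_chromosomes=2,
                             chromosome_length=1_000_000, n_snps=2000,
                             n_individuals=500, copy_low=0.0, copy_high=0.0)
        panel = gen_genotype_panel(spec)
        annot = base_annot(panel)
        ld = compute_ld_scores(panel, annot)
        assert ld["base"].mean() == pytest.approx(1.0, abs=0.05)

    def test_too_few_individuals_rejected(self, rng):
        g = np.array([[0, 1], [2, 0]])
        panel = tiny_panel(g)
        with pytest.raises(ValueError, match="individuals"):
            compute_ld_scores(panel, base_annot(panel))

    def test_subcategory_dominated_by_base(self, rng):
        # the base score dominates each subcategory score up to the noise
        # the small-sample adjustment introduces (null pairs contribute
        # slightly negative adjusted r-squared terms)
        spec = SyntheticSpec(seed=9, n_chromosomes=2,
                             chromosome_length=500_000, n_snps=1000,
                             n_individuals=100)
        pair = gen_gwas_pair(spec)
        ld = compute_ld_scores(pair.panel, pair.annot)
        assert (ld["base"] + 0.5 >= ld["functional"]).all()
        assert ld["base"].mean() > ld["functional"].mean()

    def test_mask_locality(self):
        # dropping far-away SNPs leaves other SNPs' scores untouched
        spec = SyntheticSpec(seed=10, n_chromosomes=2,
                             chromosome_length=500_000, n_snps=600,
                             n_individuals=80)
        panel = gen_genotype_panel(spec)
        annot = base_annot(panel)
        full = compute_ld_scores(panel, annot)
        keep = panel.chrom == "chr1"
        sub_panel = GenotypePanel(panel.genotypes[:, keep], panel.snp[keep],
                                  panel.chrom[keep], panel.bp[keep],
                                  panel.cm[keep])
        sub = compute_ld_scores(sub_panel, annot.loc[keep])
        assert np.allclose(sub["base"], full["base"][keep])


class TestStratifiedRegression:
    def make_noiseless(self, seed=0, tau=(2e-4, 8e-4), intercept=1.0):
        spec = SyntheticSpec(seed=seed, n_chromosomes=4,
                             chromosome_length=500_000, n_snps=2000,
                             n_individuals=150)
        pair = gen_gwas_pair(spec)
        ld = compute_ld_scores(pair.panel, pair.annot)
        n = 10_000.0
        chi2 = n * (ld["base"] * tau[0] + ld["functional"] * tau[1]) + intercept
        z = np.sqrt(chi2.to_numpy())
        stats = SumStats(pd.DataFrame({
            "snp": pair.panel.snp, "chrom": pair.panel.chrom,
            "bp": pair.panel.bp, "z": z, "n": n,
        }))
        return stats, ld, pair

    def test_noiseless_recovery_machine_precision(self):
        stats, ld, pair = self.make_noiseless()
        res = fit_stratified_regression(stats, ld, n_blocks=50,
                                        chisq_max=np.inf)
        assert res.tau[0] == pytest.approx(2e-4, abs=1e-12)
        assert res.tau[1] == pytest.approx(8e-4, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)

    def test_snp_order_invariance_of_estimates(self):
        stats, ld, pair = self.make_noiseless(seed=1)
        res = fit_stratified_regression(stats, ld, n_blocks=50,
                                        chisq_max=np.inf)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(stats.table))
        stats2 = SumStats(stats.table.iloc[perm].reset_index(drop=True))
        res2 = fit_stratified_regression(stats2, ld, n_blocks=50,
                                         chisq_max=np.inf)
        assert np.allclose(res.tau, res2.tau)

    def test_duplicate_category_rejected(self):
        stats, ld, pair = self.make_noiseless(seed=2)
        ld2 = ld.copy()
        ld2["dup"] = ld2["functional"]
        with pytest.raises(RankDeficientError):
            fit_stratified_regression(stats, ld2, n_blocks=50,
                                      chisq_max=np.inf)

    def test_chisq_filter_drops_outliers(self):
        stats, ld, pair = self.make_noiseless(seed=3)
        t = stats.table.copy()
        t.loc[0, "z"] = 100.0
        t.loc[0, "p"] = z_to_p(100.0)
        stats2 = SumStats(t)
        res = fit_stratified_regression(stats2, ld, n_blocks=50)
        assert "rs0" not in res.snps

    def test_jackknife_se_shrinks_with_snp_count(self):
        ses = []
        for n_snps in (2000, 8000):
            spec = SyntheticSpec(seed=20, n_chromosomes=4,
                                 chromosome_length=1_000_000, n_snps=n_snps,
                                 n_individuals=200, gwas_n=20_000)
            pair = gen_gwas_pair(spec)
            ld = compute_ld_scores(pair.panel, pair.annot)
            res = fit_stratified_regression(pair.stats_a, ld, n_blocks=100)
            ses.append(res.tau_se[1])
        # 4x the SNPs: SE should drop roughly 2x; allow a loose band
        ratio = ses[0] / ses[1]
        assert 1.2 < ratio < 3.5


class TestEnrichment:
    def test_full_coverage_category_is_unenriched(self, rng):
        # any category covering every SNP explains exactly its share
        from gsk.heritability import _enrichment_from_tau
        m = 200
        member = rng.random(m) < 0.25
        A = np.column_stack([np.ones(m), np.ones(m), member])
        enr, share, cov = _enrichment_from_tau(np.array([1e-4, 5e-5, 2e-4]), A)
        assert enr[1] == pytest.approx(1.0)   # the full-coverage column
        assert enr[0] == pytest.approx(1.0)   # base itself

    def test_printed_percentage_worked_example(self):
        value = enrichment_from_shares(98.7, 24.4)
        assert round(value, 1) == 4.0

    def test_planted_five_fold_recovery_single_seed(self):
        spec = SyntheticSpec(seed=6, n_chromosomes=10,
                             chromosome_length=2_000_000, n_snps=20_000,
                             n_individuals=500)
        pair = gen_gwas_pair(spec)
        ld = compute_ld_scores(pair.panel, pair.annot)
        res = fit_stratified_regression(pair.stats_a, ld, n_blocks=200)
        enr = enrichment(res, pair.annot)
        row = enr.table.loc["functional"]
        assert row["enrichment"] == pytest.approx(5.0, rel=0.5)
        assert row["p"] < 0.05
        assert enr.table.loc["base", "enrichment"] == 1.0

    def test_total_nonpositive_h2_rejected(self):
        spec = SyntheticSpec(seed=7, n_chromosomes=2,
                             chromosome_length=500_000, n_snps=1000,
                             n_individuals=100)
        pair = gen_gwas_pair(spec)
        ld = compute_ld_scores(pair.panel, pair.annot)
        res = fit_stratified_regression(pair.stats_a, ld, n_blocks=50)
        res.tau = np.array([-1e-4, -1e-4])
        with pytest.raises(ValueError):
            enrichment(res, pair.annot)


class TestChromPartition:
    def test_single_chromosome_fraction_one(self):
        h2 = pd.Series([0.1, 0.2, 0.3])
        out = partition_heritability_by_chrom(h2, ["chr1"] * 3)
        assert out["chr1"] == pytest.approx(1.0)

    def test_equal_h2_splits_by_snp_count(self):
        h2 = pd.Series(np.ones(400))
        chrom = ["chr1"] * 100 + ["chr2"] * 300
        out = partition_heritability_by_chrom(h2, chrom)
        assert out["chr1"] == pytest.approx(0.25)
        assert out["chr2"] == pytest.approx(0.75)

    def test_fractions_sum_to_one(self, rng):
        h2 = pd.Series(rng.random(100))
        chrom = rng.choice(["chr1", "chr2", "chr3"], 100)
        out = partition_heritability_by_chrom(h2, chrom)
        assert out.sum() == pytest.approx(1.0)

    def test_mask_restriction(self):
        layout = GenomeLayout(("chr1", "chr2"), {"chr1": 10_000,
                                                 "chr2": 10_000})
        mask = BinaryTrack(layout, {"chr1": ([0], [10_000])})
        h2 = pd.Series([1.0, 1.0, 1.0, 1.0])
        chrom = ["chr1", "chr1", "chr2", "chr2"]
        bp = [100, 200, 100, 200]
        out = partition_heritability_by_chrom(h2, chrom, bp,
                                              restrict_mask=mask)
        assert out["chr1"] == pytest.approx(1.0)
        assert "chr2" not in out.index

    def test_empty_mask_errors(self):
        layout = GenomeLayout(("chr1",), {"chr1": 10_000})
        mask = BinaryTrack(layout, {})
        with pytest.raises(ValueError):
            partition_heritability_by_chrom(
                pd.Series([1.0]), ["chr1"], [100], restrict_mask=mask)


class TestFileDialects:
    def make_annot_frame(self, rng, m=1000):
        return make_annot(
            [f"rs{i}" for i in range(m)],
            np.repeat(["chr1", "chr2"], m // 2),
            np.arange(m) * 997 + 1,
            {"catA": rng.random(m) < 0.3, "catB": rng.random(m) < 0.1},
        )

    def test_annot_round_trip(self, tmp_path, rng):
        annot = self.make_annot_frame(rng)
        path = tmp_path / "test.annot"
        write_annot(annot, path)
        back = read_annot(path)
        pd.testing.assert_frame_equal(
            back.astype(annot.dtypes), annot, check_dtype=False
        )

    def test_gzip_and_plain_identical(self, tmp_path, rng):
        annot = self.make_annot_frame(rng)
        write_annot(annot, tmp_path / "a.annot")
        write_annot(annot, tmp_path / "a.annot.gz")
        plain = read_annot(tmp_path / "a.annot")
        gz = read_annot(tmp_path / "a.annot.gz")
        pd.testing.assert_frame_equal(plain, gz)

    def test_base_column_validated_on_read(self, tmp_path):
        path = tmp_path / "bad.annot"
        path.write_text("CHR\tBP\tSNP\tbase\nchr1\t100\trs0\t0\n")
        with pytest.raises(ValueError, match="base"):
            read_annot(path)

    def test_malformed_header_named_error(self, tmp_path):
        path = tmp_path / "bad2.annot"
        path.write_text("FOO\tBAR\nx\ty\n")
        with pytest.raises(ValueError, match="missing"):
            read_annot(path)

    def test_ldscore_round_trip(self, tmp_path, rng):
        m = 500
        table = pd.DataFrame({
            "chrom": "chr1", "bp": np.arange(m) * 10 + 1,
            "base": rng.random(m) * 5 + 1, "catA": rng.random(m),
        }, index=pd.Index([f"rs{i}" for i in range(m)], name="snp"))
        path = tmp_path / "test.l2.ldscore"
        write_ldscore(table, path)
        back = read_ldscore(path)
        assert list(back.columns) == ["chrom", "bp", "base", "catA"]
        assert np.allclose(back["base"], table["base"], atol=1e-6)
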