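import numpy as np
import pandas as pd
import pytest

from snipage.age import detect_age_tfs
from snipage.interaction import (PipelineConfig, TripletSkip,
                                 consistency_filter, consistency_pass,
                                 enumerate_candidates, llr_interaction_test,
                                 replication_rate, run_pipeline,
                                 shuffle_background)
from tests.conftest import make_covariates


def sim_triplet(rng, n=200, beta_int=0.0, beta_snp=0.3, beta_tf=0.2,
                maf=0.3, noise_sd=1.0):
    """One candidate triplet's data under the generative model."""
    cov = make_covariates(rng, n)
    d = rng.binomial(2, maf, n).astype(float)
    tf = 0.05 * cov.age.to_numpy() + rng.normal(0, 1, n)
    y = (beta_snp * d + beta_tf * tf + beta_int * d * tf
         + 0.02 * cov.age.to_numpy() + rng.normal(0, noise_sd, n))
    return y, d, tf, cov.design()


class TestEnumerateCandidates:
    ANN = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                        "tss": [600_000, 2_700_000, 100_000]},
                       index=pd.Index(["gA", "gB", "gC"], name="gene_id"))

    def call(self, pos):
        return pd.DataFrame([{"tf": "t1", "snp": "rs1", "chrom": "chr1",
                              "pos": pos, "binding_allele": "alt"}])

    def test_cis_window_filtering(self):
        cands = enumerate_candidates(self.call(1_500_000), self.ANN)
        assert [(c.gene_id, c.snp_to_tss_distance) for c in cands] == \
            [("gA", 900_000)]

    def test_exact_window_boundary_included(self):
        cands = enumerate_candidates(self.call(1_600_000), self.ANN)
        assert "gA" in [c.gene_id for c in cands]   # exactly 1 Mbp

    def test_product_over_calls_and_genes(self):
        calls = pd.DataFrame([
            {"tf": "t1", "snp": "rs1", "chrom": "chr1", "pos": 600_500},
            {"tf": "t2", "snp": "rs2", "chrom": "chr1", "pos": 700_000}])
        ann = pd.DataFrame({"chrom": "chr1",
                            "tss": [600_000, 650_000, 800_000]},
                           index=pd.Index(["g1", "g2", "g3"],
                                          name="gene_id"))
        assert len(enumerate_candidates(calls, ann)) == 6


class TestLLRTest:
    def test_matches_statsmodels_likelihood_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(31)
        for _ in range(50):
            y, d, tf, cov = sim_triplet(rng, n=120,
                                        beta_int=rng.uniform(0, 0.5))
            res = llr_interaction_test(y, d, tf, cov)
            X0 = sm.add_constant(np.column_stack([cov, d, tf]))
            X1 = np.column_stack([X0, d * tf])
            ll0 = sm.OLS(y, X0).fit().llf
            ll1 = sm.OLS(y, X1).fit().llf
            assert res.llr == pytest.approx(2 * (ll1 - ll0), rel=1e-8,
                                            abs=1e-8)
            fit1 = sm.OLS(y, X1).fit()
            assert res.beta_interaction == pytest.approx(fit1.params[-1],
                                                         rel=1e-8)

    def test_null_calibration(self):
        rng = np.random.default_rng(32)
        reps = 400
        hits = 0
        for _ in range(reps):
            y, d, tf, cov = sim_triplet(rng, n=200, beta_int=0.0)
            hits += llr_interaction_test(y, d, tf, cov).p_llr < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 0.035

    def test_power_matches_independent_simulation(self):
        # same scenario, one path through the package, one through a
        # brute-force statsmodels LR comparison
        import statsmodels.api as sm
        reps = 200

        def rejection_rate(fit_fn, seed):
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(reps):
                y, d, tf, cov = sim_triplet(rng, n=300, beta_int=0.5,
                                            maf=0.3)
                hits += fit_fn(y, d, tf, cov) < 0.05
            return hits / reps

        def package_p(y, d, tf, cov):
            return llr_interaction_test(y, d, tf, cov).p_llr

        def oracle_p(y, d, tf, cov):
            X0 = sm.add_constant(np.column_stack([cov, d, tf]))
            X1 = np.column_stack([X0, d * tf])
            alt = sm.OLS(y, X1).fit()
            return alt.compare_lr_test(sm.OLS(y, X0).fit())[1]

        assert abs(rejection_rate(package_p, 7)
                   - rejection_rate(oracle_p, 8)) < 0.05

    def test_nesting_llr_nonnegative(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            y, d, tf, cov = sim_triplet(rng, n=80)
            assert llr_interaction_test(y, d, tf, cov).llr >= -1e-8

    def test_allele_recoding_invariance(self):
        rng = np.random.default_rng(34)
        y, d, tf, cov = sim_triplet(rng, n=150, beta_int=0.4)
        a = llr_interaction_test(y, d, tf, cov)
        b = llr_interaction_test(y, 2.0 - d, tf, cov)
        assert a.p_llr == pytest.approx(b.p_llr, abs=1e-8)
        assert a.beta_interaction == pytest.approx(-b.beta_interaction,
                                                   rel=1e-6)

    def test_missing_dosage_dropped(self):
        rng = np.random.default_rng(35)
        y, d, tf, cov = sim_triplet(rng, n=100)
        d[:5] = np.nan
        assert llr_interaction_test(y, d, tf, cov).n_used == 95

    def test_monomorphic_skipped(self):
        rng = np.random.default_rng(36)
        y, d, tf, cov = sim_triplet(rng, n=100)
        with pytest.raises(TripletSkip, match="monomorphic"):
            llr_interaction_test(y, np.ones_like(d), tf, cov)

    def test_too_few_samples_skipped(self):
        rng = np.random.default_rng(37)
        y, d, tf, cov = sim_triplet(rng, n=20)
        with pytest.raises(TripletSkip, match="too_few"):
            llr_interaction_test(y, d, tf, cov)


class TestConsistency:
    def test_reported_example_passes(self):
        # genotype-stratified correlations of the MAX-rs2295079-MTOR
        # style example: het and binding-homozygote groups significant,
        # non-binding homozygotes not, homB stronger with matching sign
        passed, reason = consistency_pass(
            r_het=-0.24, p_het=5.8e-3, r_homB=-0.3, p_homB=4e-4,
            r_homNB=-0.03, p_homNB=0.79)
        assert passed and reason == ""

    def test_magnitude_rule(self):
        passed, reason = consistency_pass(0.3, 0.01, 0.2, 0.01, 0.01, 0.9)
        assert not passed and reason == "homB_not_stronger"

    def test_nonbinding_exclusion_rule(self):
        passed, reason = consistency_pass(-0.24, 5.8e-3, -0.3, 4e-4,
                                          0.4, 0.001)
        assert not passed and reason == "homNB_significant"

    def test_sign_rule(self):
        passed, reason = consistency_pass(0.3, 0.001, -0.5, 0.001,
                                          0.0, 0.9)
        assert not passed and reason == "sign_mismatch"

    def test_filter_on_planted_data(self):
        rng = np.random.default_rng(38)
        n = 300
        d = rng.binomial(2, 0.4, n).astype(float)
        tf = rng.normal(0, 2, n)
        y = 1.0 * d * tf + rng.normal(0, 0.5, n)
        res = consistency_filter(y, tf, d)
        assert res.passed
        assert res.p_het < 0.05 and res.p_homB < 0.05
        assert abs(res.r_homB) > abs(res.r_het)

    def test_small_group_fails_with_reason(self):
        rng = np.random.default_rng(39)
        d = np.repeat([0.0, 1.0, 2.0], [140, 155, 5])
        tf = rng.normal(size=300)
        y = d * tf + rng.normal(0, 0.3, 300)
        res = consistency_filter(y, tf, d, min_group=10)
        assert not res.passed and res.reason == "group_too_small"

    def test_degenerate_group_fails(self):
        rng = np.random.default_rng(40)
        d = np.repeat([0.0, 1.0, 2.0], 40)
        tf = rng.normal(size=120)
        y = np.where(d == 2, 1.0, rng.normal(size=120))  # constant in homB
        res = consistency_filter(y, tf, d)
        assert not res.passed


class TestPipeline:
    def test_empty_candidates_gives_empty_table(self, small_bundle):
        from snipage.age import detect_age_tfs
        b = small_bundle
        age_set = detect_age_tfs(b.cohort, b.tf_panel)
        empty_calls = pd.DataFrame(columns=["tf", "snp", "chrom", "pos",
                                            "binding_allele"])
        table = run_pipeline(b.cohort, age_set, empty_calls, b.annotations)
        assert len(table) == 0 and "p_llr" in table.columns

    def test_planted_triplets_detected_on_small_fixture(self, small_bundle):
        from snipage import motif
        b = small_bundle
        calls = motif.filter_open_chromatin(
            motif.call_asb_table(b.pwms, b.cohort.genotypes.snps, b.genome),
            b.dhs)
        age_set = detect_age_tfs(b.cohort, b.tf_panel)
        table = run_pipeline(b.cohort, age_set, calls, b.annotations)
        truth = set(map(tuple, b.truth[["tf", "snp", "gene"]].to_numpy()))
        sel = set(map(tuple, table.loc[table["selected"],
                                       ["tf", "snp", "gene"]].to_numpy()))
        assert len(sel & truth) >= 0.5 * len(truth)
        assert len(sel - truth) <= 1

    def test_shuffle_preserves_gene_gene_covariance(self, small_bundle):
        cohort = small_bundle.cohort
        shuffled = shuffle_background(cohort, seed=5)
        c0 = np.corrcoef(cohort.expression.to_numpy())
        c1 = np.corrcoef(shuffled.expression.to_numpy())
        np.testing.assert_allclose(c0, c1, atol=1e-12)
        # covariates/genotypes keep their original labels
        pd.testing.assert_frame_equal(cohort.covariates.df,
                                      shuffled.covariates.df)

    def test_shuffle_is_a_column_permutation(self, small_bundle):
        cohort = small_bundle.cohort
        shuffled = shuffle_background(cohort, seed=6)
        orig = {tuple(col) for col in cohort.expression.to_numpy().T}
        perm = {tuple(col) for col in shuffled.expression.to_numpy().T}
        assert orig == perm

    def test_replication_identity_fraction(self, small_bundle):
        from snipage import motif
        b = small_bundle
        calls = motif.filter_open_chromatin(
            motif.call_asb_table(b.pwms, b.cohort.genotypes.snps, b.genome),
            b.dhs)
        rates = replication_rate(b.cohort, b.tf_panel, calls, b.annotations,
                                 fractions=(1.0,), n_reps=1, seed=0)
        assert rates["rate_age_tfs"].iloc[0] == pytest.approx(100.0)
        assert rates["rate_triplets"].iloc[0] == pytest.approx(100.0)
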