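import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twostepmr.estimators import tsls_estimate
from twostepmr.simulate import (
    SimParams,
    disease_gwas_from_study,
    mediator_gwas_from_study,
    simulate_cohort,
    simulate_disease_gwas,
    simulate_genotypes,
    simulate_study,
    simulate_two_sample_gwas,
)


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs, msg",
        [
            ({"n_individuals": (1,)}, "n_individuals"),
            ({"maf_range": (0.0, 0.5)}, "maf_range"),
            ({"maf_range": (0.1, 0.6)}, "maf_range"),
            ({"ld_within_block_r2": 1.0}, "ld_within_block_r2"),
            ({"exposure_h2": 1.0}, "exposure_h2"),
            ({"zero_inflation": 1.0}, "zero_inflation"),
            ({"case_fraction": 0.0}, "case_fraction"),
            ({"exposure_h2": 0.5, "confounder_effect_on_exposure": 0.9}, "must be < 1"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimParams(**kwargs)

    def test_theta_broadcast(self):
        p = SimParams(n_mediators=4, theta=0.2)
        np.testing.assert_array_equal(p.thetas(), [0.2] * 4)
        with pytest.raises(ValueError, match="theta length"):
            SimParams(n_mediators=4, theta=(0.1, 0.2)).thetas()


class TestSimulateGenotypes:
    def test_seeded_determinism(self):
        p = SimParams(seed=5, ld_block_size=4, ld_within_block_r2=0.3)
        a = simulate_genotypes(p, n_individuals=500)
        b = simulate_genotypes(p, n_individuals=500)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.ld_r2 == b.ld_r2

    def test_independent_columns_when_no_ld(self):
        p = SimParams(seed=1, ld_within_block_r2=0.0)
        panel = simulate_genotypes(p, n_individuals=5000, n_snps=40)
        corr = np.corrcoef(panel.dosages.astype(float), rowvar=False)
        off_diag = corr[np.triu_indices(40, k=1)]
        assert np.max(off_diag**2) < 0.05

    def test_dosage_mean_tracks_maf(self):
        p = SimParams(seed=2, maf_range=(0.5, 0.5))
        panel = simulate_genotypes(p, n_individuals=10_000, n_snps=20)
        means = panel.dosages.mean(axis=0)
        assert np.all((means >= 0.96) & (means <= 1.04))

    def test_block_ld_near_target(self):
        p = SimParams(
            seed=3, ld_block_size=5, ld_within_block_r2=0.4, maf_range=(0.2, 0.4)
        )
        panel = simulate_genotypes(p, n_individuals=8000, n_snps=20)
        realized = np.array(list(panel.ld_r2.values()))
        assert len(realized) == 4 * 10  # 4 blocks x C(5,2) pairs
        assert abs(realized.mean() - 0.4) < 0.08

    def test_ld_map_symmetric_semantics(self):
        p = SimParams(seed=3, ld_block_size=3, ld_within_block_r2=0.5)
        panel = simulate_genotypes(p, n_individuals=2000, n_snps=6)
        from twostepmr.instruments import ld_lookup

        (a, b), r2 = next(iter(panel.ld_r2.items()))
        assert ld_lookup(panel.ld_r2, b, a) == r2
        assert ld_lookup(panel.ld_r2, a, a) == 1.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_genotypes(SimParams(), n_individuals=0)


class TestSimulateCohort:
    def _cohort(self, **kw):
        defaults = dict(
            n_individuals=(5000,), n_mediators=2, n_mediator_snps=0, mediator_h2=0.0, seed=4
        )
        defaults.update(kw)
        p = SimParams(**defaults)
        panel = simulate_genotypes(p, n_individuals=p.n_individuals[0])
        return p, simulate_cohort(p, panel)

    def test_null_mediator_independent_of_exposure(self):
        _, cohort = self._cohort(
            theta=0.0,
            confounder_effect_on_exposure=0.0,
            confounder_effect_on_mediator=0.0,
            zero_inflation=0.0,
            missing_fraction=0.0,
        )
        x = cohort.exposure.to_numpy()
        for col in cohort.mediators.columns:
            m = np.log(cohort.mediators[col].to_numpy())
            assert abs(np.corrcoef(x, m)[0, 1]) < 0.05

    def test_zero_inflation_fraction(self):
        _, cohort = self._cohort(zero_inflation=0.1, missing_fraction=0.0)
        for col in cohort.mediators.columns:
            frac = (cohort.mediators[col] == 0.0).mean()
            assert frac == pytest.approx(0.10, abs=0.02)

    def test_missingness_fraction(self):
        _, cohort = self._cohort(missing_fraction=0.05)
        frac = cohort.mediators.isna().mean().mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_exposure_scale_matches_cohort_description(self):
        _, cohort = self._cohort()
        bmi = cohort.exposure.to_numpy()
        assert bmi.mean() == pytest.approx(27.0, abs=0.5)
        assert bmi.std() == pytest.approx(4.5, rel=0.1)

    def test_causal_calibration_at_large_n(self):
        # confounder-adjusted regression recovers theta within 3 SE
        p = SimParams(
            n_individuals=(50_000,), n_mediators=1, theta=0.2,
            n_mediator_snps=0, mediator_h2=0.0, zero_inflation=0.0,
            missing_fraction=0.0, seed=6,
        )
        panel = simulate_genotypes(p, n_individuals=50_000)
        cohort = simulate_cohort(p, panel)
        m = np.log(cohort.mediators["cyt_001"].to_numpy())
        x = cohort.truth["x_standardized"]
        u = cohort.truth["U"]
        # adjust for every shared cause: the scalar confounder plus the
        # auxiliary covariates that load on both exposure and mediator
        cov = cohort.covariates.to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x, u, cov])
        beta = np.linalg.lstsq(X, m, rcond=None)[0]
        resid = m - X @ beta
        se = np.sqrt(
            resid @ resid / (len(m) - X.shape[1]) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert beta[1] == pytest.approx(0.2, abs=3 * se)

    def test_iv_recovers_theta_while_ols_biased(self):
        # strong GRS (h2=0.3) so the IV sampling error is well inside +/-0.02;
        # confounder path 0.5 x 0.2 biases OLS upward by ~0.1
        p = SimParams(
            n_individuals=(50_000,), n_mediators=1, theta=0.2, exposure_h2=0.3,
            confounder_effect_on_exposure=0.5, confounder_effect_on_mediator=0.2,
            n_mediator_snps=0, mediator_h2=0.0, zero_inflation=0.0,
            missing_fraction=0.0, seed=8,
        )
        panel = simulate_genotypes(p, n_individuals=50_000)
        cohort = simulate_cohort(p, panel)
        m = np.log(cohort.mediators["cyt_001"].to_numpy())
        x = cohort.truth["x_standardized"]
        score = panel.dosages.astype(float) @ cohort.truth["instrument_weights"]
        iv = tsls_estimate(m, x, score)
        ols = np.polyfit(x, m, 1)[0]
        assert iv.beta == pytest.approx(0.2, abs=0.02)
        assert ols == pytest.approx(0.2 + 0.5 * 0.2, abs=0.03)

    def test_determinism(self):
        p = SimParams(n_individuals=(300,), n_mediators=2, seed=10)
        panel = simulate_genotypes(p, n_individuals=300)
        a = simulate_cohort(p, panel)
        b = simulate_cohort(p, panel)
        pd.testing.assert_frame_equal(a.mediators, b.mediators)
        pd.testing.assert_series_equal(a.exposure, b.exposure)


class TestTwoSampleGwas:
    def _panel_and_trait(self, n=5000, effect=0.1, seed=12):
        p = SimParams(seed=seed)
        panel = simulate_genotypes(p, n_individuals=n, n_snps=10)
        rng = np.random.default_rng(seed + 1)
        g = panel.dosages[:, 0].astype(float)
        gz = (g - g.mean()) / g.std()
        trait = effect * gz + rng.normal(size=n) * np.sqrt(1 - effect**2)
        return panel, trait

    def test_effect_recovered_within_3se(self):
        panel, trait = self._panel_and_trait()
        t1, t2 = simulate_two_sample_gwas(panel, trait, (2500, 2500), seed=1)
        g = panel.dosages[:, 0].astype(float)
        per_allele = 0.1 / g.std()  # standardized effect back to per-allele
        for t in (t1, t2):
            row = t.iloc[0]
            assert row["BETA"] == pytest.approx(per_allele, abs=3 * row["SE"])

    def test_null_pvalues_uniform(self):
        p = SimParams(seed=13)
        panel = simulate_genotypes(p, n_individuals=4000, n_snps=500)
        rng = np.random.default_rng(14)
        trait = rng.normal(size=4000)
        t1, _ = simulate_two_sample_gwas(panel, trait, (2000, 2000), seed=2)
        ks = stats.kstest(t1["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_determinism_and_disjointness(self):
        panel, trait = self._panel_and_trait(n=1000)
        a1, a2 = simulate_two_sample_gwas(panel, trait, (400, 600), seed=3)
        b1, b2 = simulate_two_sample_gwas(panel, trait, (400, 600), seed=3)
        pd.testing.assert_frame_equal(a1, b1)
        pd.testing.assert_frame_equal(a2, b2)
        assert a1["N"].iloc[0] == 400 and a2["N"].iloc[0] == 600

    def test_overlapping_split_rejected(self):
        panel, trait = self._panel_and_trait(n=1000)
        with pytest.raises(ValueError, match="overlap"):
            simulate_two_sample_gwas(panel, trait, (600, 600), seed=3)

    def test_linear_gwas_matches_statsmodels(self):
        import statsmodels.api as sm

        panel, trait = self._panel_and_trait(n=800)
        t1, _ = simulate_two_sample_gwas(panel, trait, (790, 10), seed=4)
        # refit SNP 0 on the same subsample by reproducing the permutation
        from twostepmr.simulate import _rng

        perm = _rng(4, 3).permutation(800)
        idx = np.sort(perm[:790])
        g = panel.dosages[idx, 0].astype(float)
        ref = sm.OLS(trait[idx], sm.add_constant(g)).fit()
        assert t1["BETA"].iloc[0] == pytest.approx(ref.params[1], abs=1e-10)
        assert t1["SE"].iloc[0] == pytest.approx(ref.bse[1], abs=1e-10)
        assert t1["P"].iloc[0] == pytest.approx(ref.pvalues[1], abs=1e-10)


class TestDiseaseGwas:
    def test_null_log_ors_center_on_zero(self):
        p = SimParams(seed=20)
        panel = simulate_genotypes(p, n_individuals=6000, n_snps=30)
        rng = np.random.default_rng(21)
        med = rng.normal(size=6000)
        tab = simulate_disease_gwas(panel, med, 0.0, 0.33, seed=22)
        z = tab["BETA"] / tab["SE"]
        assert abs(z.mean()) < 3 / np.sqrt(30)
        assert np.all(np.exp(np.abs(tab["BETA"])) < 1.5)

    def test_path_product_alpha_times_lambda(self):
        # SNP -> mediator (alpha) and mediator -> disease (lambda) compose
        n = 50_000
        p = SimParams(seed=23)
        panel = simulate_genotypes(p, n_individuals=n, n_snps=5)
        rng = np.random.default_rng(24)
        g = panel.dosages[:, 0].astype(float)
        gz = (g - g.mean()) / g.std()
        alpha = 0.3
        med = alpha * gz + rng.normal(size=n) * np.sqrt(1 - alpha**2)
        lam = 0.4
        tab = simulate_disease_gwas(panel, med, lam, 0.33, seed=25)
        per_allele_alpha = alpha / g.std()
        row = tab.iloc[0]
        assert row["BETA"] == pytest.approx(per_allele_alpha * lam, abs=3 * row["SE"])

    def test_case_fraction_calibrated(self):
        p = SimParams(seed=26)
        panel = simulate_genotypes(p, n_individuals=5000, n_snps=3)
        rng = np.random.default_rng(27)
        tab = simulate_disease_gwas(panel, rng.normal(size=5000), 0.1, 0.25, seed=28)
        assert tab["N"].iloc[0] == 5000

    def test_logistic_gwas_matches_statsmodels(self):
        import statsmodels.api as sm

        from twostepmr.simulate import _logistic_gwas

        rng = np.random.default_rng(29)
        g = rng.binomial(2, 0.3, size=(2000, 2)).astype(float)
        y = (rng.random(2000) < 1 / (1 + np.exp(-(-0.5 + 0.2 * g[:, 0])))).astype(float)
        beta, se, p = _logistic_gwas(g, y)
        for j in range(2):
            ref = sm.Logit(y, sm.add_constant(g[:, j])).fit(disp=0)
            assert beta[j] == pytest.approx(ref.params[1], abs=1e-6)
            assert se[j] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_degenerate_outcome_rejected(self):
        p = SimParams(seed=30)
        panel = simulate_genotypes(p, n_individuals=200, n_snps=2)
        rng = np.random.default_rng(31)
        with pytest.raises(ValueError, match="degenerate outcome"):
            simulate_disease_gwas(
                panel, rng.normal(size=200), 0.0, 1 - 1e-12, seed=32
            )

    def test_determinism(self):
        p = SimParams(seed=33)
        panel = simulate_genotypes(p, n_individuals=1000, n_snps=4)
        rng = np.random.default_rng(34)
        med = rng.normal(size=1000)
        a = simulate_disease_gwas(panel, med, 0.2, 0.3, seed=35)
        b = simulate_disease_gwas(panel, med, 0.2, 0.3, seed=35)
        pd.testing.assert_frame_equal(a, b)


class TestStudyLevel:
    def test_study_structure(self, small_study):
        s = small_study
        assert [c.n for c in s.cohorts] == [300, 400, 250]
        assert s.outcome_cohort.n == 3000
        assert s.grs_weights.shape[0] == s.params.n_instrument_snps
        # outcome sample disjoint by construction: generated from rows beyond
        # the cohort span of the shared panel
        assert s.panel.n_individuals == 300 + 400 + 250 + 3000

    def test_mediator_gwas_in_sd_units(self, small_study):
        tab = mediator_gwas_from_study(small_study, "cyt_001")
        assert set(tab.columns) == {"SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"}
        assert tab["N"].iloc[0] <= 950
        # strongest mediator SNPs should show signal with h2=0.3 over 12 SNPs
        assert tab["P"].min() < 1e-4

    def test_disease_gwas_two_sample_recovery(self, small_study):
        # Wald/IVW over the mediator SNPs recovers log_or_per_sd within 3 SE
        from twostepmr.estimators import ivw_combine, wald_ratio
        from twostepmr.instruments import harmonize_pair

        out = disease_gwas_from_study(small_study, "cyt_001")
        exp = mediator_gwas_from_study(small_study, "cyt_001")
        pair = harmonize_pair(exp, out)
        walds = [
            wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out)
            for r in pair.table.itertuples(index=False)
        ]
        est = ivw_combine(walds)
        assert est.n_snps == len(exp)
        assert est.beta == pytest.approx(np.log(1.3), abs=3 * est.se)

    def test_study_determinism(self, small_study):
        again = simulate_study(small_study.params)
        pd.testing.assert_frame_equal(again.grs_weights, small_study.grs_weights)
        pd.testing.assert_frame_equal(
            again.cohorts[1].mediators, small_study.cohorts[1].mediators
        )
        np.testing.assert_array_equal(
            again.outcome_cohort.dosages.to_numpy(),
            small_study.outcome_cohort.dosages.to_numpy(),
        )
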