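"""REML variance components, GEBVs, z-score, SE-weighted summaries."""

import numpy as np
import pandas as pd
import pytest

import ovinet
from ovinet.traits import two_trait_architecture, default_assaf_architecture
from ovinet.varcomp import (fit_univariate_reml, fit_bivariate_reml,
                            compute_gebv, gebv_table, variance_fraction,
                            zscore_summary, se_weighted_h2, reml_grid_search,
                            build_fixed_design, fit_all_traits)


class TestUnivariate:
    def test_pure_genetic_signal_h2_near_one(self):
        # y equals the TBV with every SNP causal, so the phenotypic
        # covariance is exactly proportional to the GRM: h2_hat -> 1
        G = ovinet.simulate_genotypes(300, 150, seed=21)
        arch = two_trait_architecture("A", "B", 1.0, 1.0, 0.3)
        pheno, truth = ovinet.simulate_phenotypes(G, arch, n_causal=150,
                                                  seed=22, fixed_effect_sd=0.0)
        grm = ovinet.compute_grm(G)
        y = truth.tbv["A"].to_numpy()
        fit = fit_univariate_reml(y, np.ones((300, 1)), grm)
        assert fit.h2 >= 0.98

    def test_pure_noise_h2_near_zero(self):
        G = ovinet.simulate_genotypes(400, 400, seed=23)
        grm = ovinet.compute_grm(G)
        h2s = []
        rng = np.random.default_rng(0)
        X = np.ones((400, 1))
        for _ in range(20):
            y = rng.standard_normal(400)
            h2s.append(fit_univariate_reml(y, X, grm).h2)
        assert np.mean(h2s) <= 0.05

    def test_recovery_default_architecture_reduced_scale(self):
        # h2 recovery across traits spanning the architecture's range,
        # averaged over seeds (reduced-scale version of the full recovery
        # study run by the acceptance suite)
        arch = default_assaf_architecture()
        traits = ["pH", "A60", "MY"]
        errs = {t: [] for t in traits}
        for seed in range(6):
            G = ovinet.simulate_genotypes(500, 1000, seed=seed)
            pheno, _ = ovinet.simulate_phenotypes(G, arch, n_causal=150,
                                                  seed=seed + 50)
            grm = ovinet.compute_grm(G)
            X = build_fixed_design(pheno)
            cache = {}
            for t in traits:
                fit = fit_univariate_reml(pheno[t].to_numpy(), X, grm,
                                          eig_cache=cache)
                errs[t].append(fit.h2 - arch.h2[t])
        for t in traits:
            assert abs(np.mean(errs[t])) <= 0.08

    def test_matches_grid_search(self):
        # 1-D profile optimum vs a 200-point log-spaced lambda grid
        rng = np.random.default_rng(3)
        for seed in range(20):
            G = ovinet.simulate_genotypes(100, 300, seed=seed)
            arch = two_trait_architecture("A", "B", 0.5, 0.2, 0.0)
            pheno, _ = ovinet.simulate_phenotypes(G, arch, n_causal=50,
                                                  seed=seed,
                                                  fixed_effect_sd=0.0)
            grm = ovinet.compute_grm(G)
            X = np.ones((100, 1))
            y = pheno["A"].to_numpy()
            fit = fit_univariate_reml(y, X, grm)
            h2_grid = reml_grid_search(y, X, grm, n_grid=200)
            assert abs(fit.h2 - h2_grid) <= 0.01

    def test_loglik_history_monotone(self, small_study):
        fit = fit_univariate_reml(small_study["pheno"]["T1"].to_numpy(),
                                  small_study["X"], small_study["grm"])
        hist = np.array(fit.loglik_history)
        assert (np.diff(hist) >= 0).all()

    def test_warm_start_matches_cold_start(self, small_study):
        y = small_study["pheno"]["T1"].to_numpy()
        cold = fit_univariate_reml(y, small_study["X"], small_study["grm"])
        warm = fit_univariate_reml(y, small_study["X"], small_study["grm"],
                                   lambda_hint=cold.lambda_ * 3)
        assert abs(warm.h2 - cold.h2) < 1e-4

    def test_missing_phenotypes_casewise_deleted(self, small_study):
        y = small_study["pheno"]["T1"].to_numpy().copy()
        y[:30] = np.nan
        fit = fit_univariate_reml(y, small_study["X"], small_study["grm"])
        assert fit.n_used == len(y) - 30
        assert 0.0 <= fit.h2 <= 1.0

    def test_reports_se_from_ai_matrix(self, small_study):
        fit = fit_univariate_reml(small_study["pheno"]["T1"].to_numpy(),
                                  small_study["X"], small_study["grm"])
        assert fit.se_h2 > 0
        assert fit.se_sigma_a2 > 0


class TestBivariate:
    def test_same_trait_twice_rg_near_one(self, small_study):
        y = small_study["pheno"]["T1"].to_numpy()
        fit = fit_bivariate_reml(y, y, small_study["X"], small_study["grm"])
        assert fit.r_g >= 0.99

    def test_independent_traits_rg_near_zero(self):
        rgs = []
        for seed in range(20):
            G = ovinet.simulate_genotypes(250, 500, seed=seed)
            arch = two_trait_architecture("A", "B", 0.4, 0.4, 0.0)
            pheno, _ = ovinet.simulate_phenotypes(G, arch, n_causal=60,
                                                  seed=seed + 7,
                                                  fixed_effect_sd=0.0)
            grm = ovinet.compute_grm(G)
            X = np.ones((250, 1))
            fit = fit_bivariate_reml(pheno["A"].to_numpy(),
                                     pheno["B"].to_numpy(), X, grm)
            rgs.append(fit.r_g)
        assert abs(np.mean(rgs)) <= 0.1

    def test_zero_covariance_constraint_matches_univariates(self, small_study):
        # with r_g constrained to ~0 (independent traits fit), the genetic
        # variances agree with the univariate fits
        pheno, grm, X = (small_study["pheno"], small_study["grm"],
                         small_study["X"])
        y1 = pheno["T1"].to_numpy()
        y2 = pheno["T2"].to_numpy()
        biv = fit_bivariate_reml(y1, y2, X, grm)
        u1 = fit_univariate_reml(y1, X, grm)
        u2 = fit_univariate_reml(y2, X, grm)
        # bivariate variance components stay in the neighbourhood of the
        # univariate ones (exact only at r_g = 0)
        assert biv.gen_cov[0, 0] == pytest.approx(u1.sigma_a2, rel=0.5, abs=0.05)
        assert biv.gen_cov[1, 1] == pytest.approx(u2.sigma_a2, rel=0.5, abs=0.05)

    def test_moderate_rg_recovered_reduced_scale(self):
        rgs = []
        for seed in range(8):
            G = ovinet.simulate_genotypes(600, 600, seed=seed)
            arch = two_trait_architecture("A", "B", 0.4, 0.3, 0.6)
            pheno, _ = ovinet.simulate_phenotypes(G, arch, n_causal=300,
                                                  seed=seed + 3,
                                                  fixed_effect_sd=0.0)
            grm = ovinet.compute_grm(G)
            X = np.ones((600, 1))
            fit = fit_bivariate_reml(pheno["A"].to_numpy(),
                                     pheno["B"].to_numpy(), X, grm)
            rgs.append(fit.r_g)
        assert np.mean(rgs) == pytest.approx(0.6, abs=0.12)

    def test_too_few_overlapping_animals_raises(self, small_study):
        y1 = small_study["pheno"]["T1"].to_numpy().copy()
        y2 = small_study["pheno"]["T2"].to_numpy().copy()
        y1[: len(y1) - 20] = np.nan
        with pytest.raises(ValueError, match="50"):
            fit_bivariate_reml(y1, y2, small_study["X"], small_study["grm"])


class TestGebv:
    def test_zero_genetic_variance_gives_zero_gebv(self, small_study):
        fit = fit_univariate_reml(small_study["pheno"]["T1"].to_numpy(),
                                  small_study["X"], small_study["grm"])
        object.__setattr__(fit, "sigma_a2", 0.0)
        a = compute_gebv(small_study["pheno"]["T1"].to_numpy(),
                         small_study["X"], small_study["grm"], fit)
        np.testing.assert_array_equal(a, 0.0)

    def test_mean_near_zero(self, small_study):
        y = small_study["pheno"]["T1"].to_numpy()
        fit = fit_univariate_reml(y, small_study["X"], small_study["grm"])
        a = compute_gebv(y, small_study["X"], small_study["grm"], fit)
        assert abs(a.mean()) < 1e-6 * max(a.std(), 1e-12)

    def test_accuracy_increases_with_h2(self):
        cors = {}
        for h2 in (0.1, 0.8):
            cc = []
            for seed in range(5):
                G = ovinet.simulate_genotypes(250, 500, seed=seed)
                arch = two_trait_architecture("A", "B", h2, 0.3, 0.0)
                pheno, truth = ovinet.simulate_phenotypes(
                    G, arch, n_causal=80, seed=seed + 11,
                    fixed_effect_sd=0.0)
                grm = ovinet.compute_grm(G)
                X = np.ones((250, 1))
                y = pheno["A"].to_numpy()
                fit = fit_univariate_reml(y, X, grm)
                a = compute_gebv(y, X, grm, fit)
                cc.append(np.corrcoef(a, truth.tbv["A"])[0, 1])
            cors[h2] = np.mean(cc)
        assert cors[0.8] > cors[0.1]

    def test_missing_animals_predicted_via_grm(self, small_study):
        y = small_study["pheno"]["T1"].to_numpy().copy()
        y[:10] = np.nan
        fit = fit_univariate_reml(y, small_study["X"], small_study["grm"])
        a = compute_gebv(y, small_study["X"], small_study["grm"], fit)
        assert np.isfinite(a[:10]).all()
        assert a[:10].std() > 0


class TestVarianceFraction:
    def test_full_subset_fraction_one(self, small_study):
        G, pheno, X = small_study["G"], small_study["pheno"], small_study["X"]
        traits = ["T1", "T2"]
        fits = fit_all_traits(pheno, traits, X, small_study["grm"])
        full = {t: f.sigma_a2 for t, f in fits.items()}
        fracs, mean_frac = variance_fraction(G.snp_ids, G, pheno, traits, X,
                                             full)
        for t in traits:
            assert fracs[t] == pytest.approx(1.0, abs=1e-6)
        assert mean_frac == pytest.approx(1.0, abs=1e-6)

    def test_causal_subset_beats_random(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            G = ovinet.simulate_genotypes(200, 400, seed=seed)
            arch = two_trait_architecture("A", "B", 0.5, 0.4, 0.3)
            pheno, truth = ovinet.simulate_phenotypes(G, arch, n_causal=40,
                                                      seed=seed + 5,
                                                      fixed_effect_sd=0.0)
            grm = ovinet.compute_grm(G)
            X = pd.DataFrame({"intercept": np.ones(200)})
            traits = ["A", "B"]
            fits = fit_all_traits(pheno, traits, X, grm)
            full = {t: f.sigma_a2 for t, f in fits.items()}
            _, f_causal = variance_fraction(truth.causal_snps, G, pheno,
                                            traits, X, full)
            rng = np.random.default_rng(seed)
            rand = [G.snp_ids[i] for i in
                    rng.choice(G.n_snps, size=40, replace=False)]
            _, f_rand = variance_fraction(rand, G, pheno, traits, X, full)
            wins += f_causal > f_rand
        assert wins >= 0.95 * n_seeds

    def test_single_uncorrelated_snp_low_fraction(self, small_study):
        G, pheno, X = small_study["G"], small_study["pheno"], small_study["X"]
        fits = fit_all_traits(pheno, ["T1"], X, small_study["grm"])
        full = {"T1": fits["T1"].sigma_a2}
        causal = set(small_study["truth"].causal_snps)
        snp = next(s for s in G.snp_ids if s not in causal)
        # single-SNP GRM needs >= 2 SNPs; use two neutral SNPs
        snp2 = next(s for s in reversed(G.snp_ids) if s not in causal)
        fracs, _ = variance_fraction([snp, snp2], G, pheno, ["T1"], X, full)
        assert fracs["T1"] <= 0.1

    def test_empty_subset_raises(self, small_study):
        with pytest.raises(ValueError):
            variance_fraction([], small_study["G"], small_study["pheno"],
                              ["T1"], small_study["X"], {"T1": 1.0})


class TestZscore:
    @staticmethod
    def make_gebv(arch, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.standard_normal((n, len(arch.traits))),
                            columns=arch.traits)

    def test_mean_exactly_zero_sd_one(self, assaf_arch):
        z = zscore_summary(self.make_gebv(assaf_arch), assaf_arch)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_identical_columns_no_inversion(self, assaf_arch):
        arch = default_assaf_architecture()
        for t in arch.traits:
            arch.invert_for_zscore[t] = False
        col = np.arange(20, dtype=float)
        gebv = pd.DataFrame({t: col for t in arch.traits})
        z = zscore_summary(gebv, arch)
        expected = (col - col.mean()) / col.std(ddof=0)
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12)

    def test_inversion_flag_symmetry(self, assaf_arch):
        gebv = self.make_gebv(assaf_arch, seed=4)
        z_base = zscore_summary(gebv, assaf_arch)
        flipped = gebv.copy()
        flipped["RCT"] = -flipped["RCT"]
        arch_flipped = default_assaf_architecture()
        arch_flipped.invert_for_zscore["RCT"] = (
            not arch_flipped.invert_for_zscore["RCT"])
        z_both = zscore_summary(flipped, arch_flipped)
        np.testing.assert_allclose(z_base.to_numpy(), z_both.to_numpy(),
                                   atol=1e-12)
        z_only_data = zscore_summary(flipped, assaf_arch)
        assert not np.allclose(z_base.to_numpy(), z_only_data.to_numpy())

    def test_zero_variance_column_contributes_zero(self, assaf_arch):
        gebv = self.make_gebv(assaf_arch, seed=5)
        gebv["MY"] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_summary(gebv, assaf_arch)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


class TestSeWeightedH2:
    def test_single_estimate_unchanged(self):
        assert se_weighted_h2([(0.42, 0.1)]) == pytest.approx(0.42)

    def test_equal_ses_arithmetic_mean(self):
        assert se_weighted_h2([(0.2, 0.1), (0.4, 0.1)]) == pytest.approx(0.3)

    def test_hand_weighted_example(self):
        # weights 1/0.1 = 10 and 1/0.2 = 5 -> (10*0.30 + 5*0.40)/15
        assert se_weighted_h2([(0.30, 0.1), (0.40, 0.2)]) == pytest.approx(
            1 / 3, abs=1e-4)

    def test_zero_se_capped_not_infinite(self):
        val = se_weighted_h2([(0.3, 0.0), (0.9, 0.1)])
        assert 0.3 <= val < 0.31
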