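"""Probe/SNP/conditional model fits and the vectorized scan engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cnvscan.association import (
    ModelSpec,
    build_design,
    fit_conditional_model,
    fit_probe_model,
    fit_snp_model,
    ols_scan_tstats,
    scan_probes,
)
from cnvscan.io import IntensityPanel

from conftest import make_phenotypes, make_probe_map


class TestOrdinaryModel:
    def test_vectorized_engine_matches_statsmodels(self):
        """FWL-residualized t-statistics equal joint-model OLS to 1e-8."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = rng.integers(12, 21)
            pheno = make_phenotypes(int(n), seed=trial)
            y, X, _, _ = build_design(pheno)
            L = rng.normal(0, 0.3, (n, 3))
            beta, se, t = ols_scan_tstats(L, y, X)
            for j in range(3):
                ref = sm.OLS(y, np.column_stack([X, L[:, j]])).fit()
                assert abs(beta[j] - ref.params[-1]) < 1e-8
                assert abs(t[j] - ref.tvalues[-1]) < 1e-8

    def test_zero_variance_probe_degenerate_not_exception(self):
        pheno = make_phenotypes(30, seed=1)
        stat = fit_probe_model(np.zeros(30), pheno)
        assert stat.degenerate
        assert stat.t_statistic == 0.0

    def test_exact_collinearity_flagged(self):
        """sqrt(PD) an exact linear function of LRR: zero-residual path flagged."""
        n = 12
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, n)
        sqrt_pd = 4.0 + 0.5 * x
        pheno = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "percent_density": sqrt_pd**2,
                "age": 0.0,
                "bmi": 25.0,
                "menopausal": 0,
                "family_id": "f1",
                "plate_id": "P1",
            }
        )
        stat = fit_probe_model(x, pheno)
        assert stat.degenerate

    def test_missing_values_complete_case(self):
        pheno = make_phenotypes(40, seed=3)
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        x[:5] = np.nan
        stat = fit_probe_model(x, pheno)
        assert stat.n_used == 35


class TestMixedModel:
    def test_single_family_collapses_to_ols(self):
        pheno = make_phenotypes(25, seed=4)
        pheno["family_id"] = "f1"
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        mixed = fit_probe_model(x, pheno, ModelSpec(use_family_random_intercept=True))
        ols = fit_probe_model(x, pheno, ModelSpec())
        assert mixed.coefficient == pytest.approx(ols.coefficient, rel=1e-6)

    def test_mixed_coefficient_equals_gls_closed_form(self):
        """At the ML solution, the fixed effects are GLS given the fitted
        variance components; verify the closed form on a balanced two-family toy."""
        rng = np.random.default_rng(5)
        n_fam, fam_size = 8, 6
        n = n_fam * fam_size
        fam = np.repeat(np.arange(n_fam), fam_size)
        x = rng.normal(0, 1, n)
        sqrt_pd = 5.0 + 0.8 * x + rng.normal(0, 1, n_fam)[fam] + rng.normal(0, 0.7, n)
        pheno = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "percent_density": np.clip(sqrt_pd, 0, 10) ** 2,
                "age": rng.normal(57, 10, n),
                "bmi": np.maximum(rng.normal(27, 4, n), 15),
                "menopausal": rng.integers(0, 2, n),
                "family_id": [f"f{g}" for g in fam],
                "plate_id": "P1",
            }
        )
        stat = fit_probe_model(x, pheno, ModelSpec(use_family_random_intercept=True))
        assert "mixed_fallback" not in stat.flags
        y, X, _, _ = build_design(pheno)
        design = np.column_stack([X, x])
        res = sm.MixedLM(y, design, groups=fam).fit(reml=False, method="lbfgs")
        tau2 = float(np.asarray(res.cov_re)[0, 0])  # already on the data scale
        sigma2 = res.scale
        blocks = []
        for _ in range(n_fam):
            V = np.full((fam_size, fam_size), tau2) + sigma2 * np.eye(fam_size)
            blocks.append(np.linalg.inv(V))
        Vinv = np.zeros((n, n))
        for g, B in enumerate(blocks):
            sl = slice(g * fam_size, (g + 1) * fam_size)
            Vinv[sl, sl] = B
        gls = np.linalg.solve(design.T @ Vinv @ design, design.T @ Vinv @ y)
        assert abs(stat.coefficient - gls[-1]) < 1e-6


class TestScan:
    def test_null_scan_t_distribution(self):
        """Phenotype independent of LRR: mean t near 0, SD near 1."""
        rng = np.random.default_rng(6)
        n, m = 500, 1000
        pm = make_probe_map(m)
        pheno = make_phenotypes(n, seed=6)
        panel = IntensityPanel(
            sample_ids=list(pheno["sample_id"]),
            plate_ids=["P1"] * n,
            lrr=rng.normal(0, 0.2, (n, m)),
            baf=np.full((n, m), 0.5),
            probe_map=pm,
        )
        stats = scan_probes(panel, pheno)
        t = stats["t"].to_numpy()
        assert abs(t.mean()) < 3 / np.sqrt(m)
        assert abs(t.std() - 1.0) < 0.1
        frac = (stats["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_embedded_region_elevates_abs_t(self, effect_cohort, effect_panel):
        stats = scan_probes(effect_panel, effect_cohort.phenotypes)
        t = np.abs(stats["t"].to_numpy())
        assert np.median(t[200:210]) > np.median(np.delete(t, np.arange(200, 210)))

    def test_empty_probe_set_empty_result(self):
        pm = make_probe_map(1)
        pheno = make_phenotypes(20, seed=7)
        panel = IntensityPanel(
            sample_ids=list(pheno["sample_id"]),
            plate_ids=["P1"] * 20,
            lrr=np.zeros((20, 1)),
            baf=np.full((20, 1), 0.5),
            probe_map=pm,
        )
        stats = scan_probes(panel, pheno)
        assert len(stats) == 1  # single degenerate probe, not an exception
        assert stats.iloc[0]["t"] == 0

    def test_scan_invariant_to_sample_order(self, effect_cohort, effect_panel):
        pheno = effect_cohort.phenotypes
        order = list(reversed(effect_panel.sample_ids))
        panel_r = effect_panel.subset_samples(order)
        a = scan_probes(effect_panel, pheno)
        b = scan_probes(panel_r, pheno)
        np.testing.assert_allclose(a["t"].to_numpy(), b["t"].to_numpy(), atol=1e-10)


class TestSnpModels:
    def test_additive_effect_recovered(self):
        rng = np.random.default_rng(8008)  # distinct from the phenotype stream
        n = 500
        pheno = make_phenotypes(n, seed=8)
        g = rng.binomial(2, 0.3, n).astype(float)
        sqrt_pd = np.sqrt(pheno["percent_density"].to_numpy()) * 0 + 4.0 + 1.0 * g
        sqrt_pd += rng.normal(0, 1, n)
        pheno["percent_density"] = np.clip(sqrt_pd, 0, 10) ** 2
        stat = fit_snp_model(g, pheno)
        assert abs(stat.coefficient - 1.0) < 3 * stat.std_error

    def test_monomorphic_snp_degenerate(self):
        pheno = make_phenotypes(30, seed=9)
        stat = fit_snp_model(np.zeros(30), pheno)
        assert stat.degenerate

    def test_recoding_symmetry(self):
        rng = np.random.default_rng(10)
        pheno = make_phenotypes(100, seed=10)
        g = rng.binomial(2, 0.4, 100).astype(float)
        a = fit_snp_model(g, pheno)
        b = fit_snp_model(2 - g, pheno)
        assert a.coefficient == pytest.approx(-b.coefficient, rel=1e-9)
        assert abs(a.t_statistic) == pytest.approx(abs(b.t_statistic), rel=1e-9)

    def test_invalid_coding_rejected(self):
        pheno = make_phenotypes(30, seed=11)
        with pytest.raises(Exception, match="0/1/2"):
            fit_snp_model(np.full(30, 3.0), pheno)


class TestConditionalModel:
    def _ld_data(self, seed, n=300, r=0.9, driver="snp"):
        rng = np.random.default_rng(seed * 7 + 10_001)  # decouple from pheno stream
        g = rng.binomial(1, 0.3, n).astype(float)
        lrr = -0.45 * g + rng.normal(0, 0.2, n)
        noise_mask = rng.random(n) < (1 - r)
        g_obs = g.copy()
        g_obs[noise_mask] = rng.permutation(g)[noise_mask]
        pheno = make_phenotypes(n, seed=seed)
        base = 4.0 + rng.normal(0, 1, n)
        if driver == "snp":
            sqrt_pd = base + 1.0 * g_obs
        else:
            sqrt_pd = base + 2.0 * lrr
        pheno["percent_density"] = np.clip(sqrt_pd, 0, 10) ** 2
        return lrr, g_obs, pheno

    def test_snp_driven_signal_attenuated_by_adjustment(self):
        hits = 0
        for rep in range(20):
            lrr, g, pheno = self._ld_data(100 + rep, driver="snp")
            unadj = fit_probe_model(lrr, pheno)
            adj, _ = fit_conditional_model(lrr, g, pheno)
            if abs(adj.t_statistic) < abs(unadj.t_statistic):
                hits += 1
        assert hits >= 19

    def test_lrr_driven_signal_survives_adjustment(self):
        lrr, g, pheno = self._ld_data(200, driver="lrr")
        unadj = fit_probe_model(lrr, pheno)
        adj, _ = fit_conditional_model(lrr, g, pheno)
        assert abs(adj.t_statistic) > 0.5 * abs(unadj.t_statistic)
        assert adj.p_value < 0.01

    def test_constant_genotype_reduces_to_unconditional(self):
        rng = np.random.default_rng(12)
        pheno = make_phenotypes(50, seed=12)
        lrr = rng.normal(0, 0.3, 50)
        adj, snp_stat = fit_conditional_model(lrr, np.zeros(50), pheno)
        unadj = fit_probe_model(lrr, pheno)
        assert adj.t_statistic == pytest.approx(unadj.t_statistic, rel=1e-12)
        assert snp_stat.degenerate

    def test_perfect_collinearity_degenerate_pair(self):
        rng = np.random.default_rng(13)
        pheno = make_phenotypes(50, seed=13)
        g = rng.binomial(2, 0.5, 50).astype(float)
        adj, snp_stat = fit_conditional_model(g.copy(), g, pheno)
        assert adj.degenerate and snp_stat.degenerate
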