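"""Region permutation machinery: statistic, p-value convention, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from cnvscan.permutation import (
    PermutationError,
    conditional_region_test,
    permutation_pvalue,
    permute_region,
    region_statistic,
    select_top_snp,
)
from cnvscan.qc import median_normalize_by_plate
from cnvscan.segmentation import CBSParams, ExpandedRegion, Segment, expand_segment
from cnvscan.simulate import (
    SimulationConfig,
    TrueRegion,
    simulate_cohort,
    simulate_linked_snp,
    shift_sqrt_density,
)

FAST_CBS = CBSParams(n_split_permutations=100)


class TestRegionStatistic:
    def test_mean_of_two_values(self):
        assert region_statistic(np.array([2.0, 4.0])) == 3.0

    def test_single_value(self):
        assert region_statistic(np.array([1.7])) == pytest.approx(1.7)

    def test_empty_errors(self):
        with pytest.raises(PermutationError):
            region_statistic(np.array([]))

    def test_matches_recomputation_from_scan(self, effect_cohort, effect_panel):
        from cnvscan.association import scan_probes

        stats = scan_probes(effect_panel, effect_cohort.phenotypes)
        vals = np.abs(stats["t"].to_numpy()[200:210])
        assert region_statistic(vals) == pytest.approx(np.abs(stats["t"][200:210]).mean())


class TestPvalueConvention:
    def test_no_exceedances_gives_floor(self):
        n_exceed, p = permutation_pvalue(5.0, np.zeros(10_000))
        assert n_exceed == 0
        assert p == 1.0 / 10_001

    def test_all_exceedances_gives_one(self):
        _, p = permutation_pvalue(1.0, np.full(10_000, 2.0))
        assert p == 1.0

    def test_ties_count_as_exceedances(self):
        n_exceed, p = permutation_pvalue(3.0, np.array([3.0, 1.0, 2.0]))
        assert n_exceed == 1
        assert p == 2.0 / 4.0

    def test_monotone_nonincreasing_in_observed(self):
        rng = np.random.default_rng(0)
        draw = rng.normal(0, 1, 500)
        ps = [permutation_pvalue(o, draw)[1] for o in np.linspace(-3, 3, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.fixture(scope="module")
def strong_region_setup(effect_cohort, effect_panel):
    seg = Segment("chr1", 200, 210, mean_abs_t=0.0)
    bounds = effect_cohort.probe_map.chromosome_bounds()["chr1"]
    er = expand_segment(seg, bounds)
    return er, effect_panel, effect_cohort.phenotypes


class TestPermuteRegion:
    def test_strong_effect_reaches_floor(self, strong_region_setup):
        er, panel, pheno = strong_region_setup
        res = permute_region(er, panel, pheno, B=200, seed=1, cbs_params=FAST_CBS)
        assert res.p_value == pytest.approx(1.0 / 201)
        assert res.n_exceed == 0
        assert res.significant_replication

    def test_bit_reproducible_with_seed(self, strong_region_setup):
        er, panel, pheno = strong_region_setup
        a = permute_region(er, panel, pheno, B=50, seed=9, cbs_params=FAST_CBS)
        b = permute_region(er, panel, pheno, B=50, seed=9, cbs_params=FAST_CBS)
        assert a.p_value == b.p_value
        assert a.observed_stat == b.observed_stat
        assert a.n_exceed == b.n_exceed

    def test_seed_insensitivity_for_strong_region(self, strong_region_setup):
        er, panel, pheno = strong_region_setup
        ps = [
            permute_region(er, panel, pheno, B=99, seed=s, cbs_params=FAST_CBS).p_value
            for s in (11, 12)
        ]
        assert ps[0] == ps[1] == pytest.approx(1.0 / 100)

    def test_invalid_B_rejected(self, strong_region_setup):
        er, panel, pheno = strong_region_setup
        with pytest.raises(PermutationError):
            permute_region(er, panel, pheno, B=0)

    def test_null_pvalues_close_to_uniform(self):
        """Fixed 10-probe windows on a null cohort: p approximately U(0,1)."""
        cfg = SimulationConfig(
            n_families=30, family_size_range=(4, 6), n_probes=400, n_chromosomes=1, seed=33
        )
        cohort = simulate_cohort(cfg)
        panel = median_normalize_by_plate(cohort.panel)
        ps = []
        for k in range(40):
            seg = Segment("chr1", k * 10, k * 10 + 10, 0.0)
            er = ExpandedRegion(seg, k * 10, k * 10 + 10)
            r = permute_region(
                er,
                panel,
                cohort.phenotypes,
                B=99,
                seed=1000 + k,
                cbs_params=FAST_CBS,
                observed_segment_stat="best",
            )
            ps.append(r.p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def ld_cohort():
    """Phenotype driven by a SNP in strong LD with a deletion region."""
    cfg = SimulationConfig(
        n_families=60,
        family_size_range=(4, 6),
        n_probes=1000,
        n_chromosomes=2,
        cnv_regions=(TrueRegion("chr1", 200, 210, deletion_freq=0.3),),
        seed=44,
    )
    cohort = simulate_cohort(cfg)
    region = cohort.truth.regions[0]
    geno, snp_id, _ = simulate_linked_snp(
        None, cohort.truth, region, 0.8, cohort.probe_map, seed=45
    )
    g = geno[snp_id].reindex(cohort.phenotypes["sample_id"]).to_numpy(dtype=float)
    pheno = shift_sqrt_density(cohort.phenotypes, g, 0.9)
    return cohort, geno, snp_id, g, pheno


class TestConditionalRegionTest:
    def test_snp_adjustment_removes_snp_driven_signal(self, ld_cohort):
        cohort, geno, snp_id, g, pheno = ld_cohort
        panel = median_normalize_by_plate(cohort.panel)
        seg = Segment("chr1", 200, 210, 0.0)
        er = expand_segment(seg, cohort.probe_map.chromosome_bounds()["chr1"])
        unadj = permute_region(er, panel, pheno, B=99, seed=5, cbs_params=FAST_CBS)
        adj = conditional_region_test(er, panel, pheno, g, B=99, seed=5, cbs_params=FAST_CBS)
        assert unadj.p_value <= 0.05
        assert adj.p_value > 0.05

    def test_constant_genotype_equals_unadjusted(self, strong_region_setup):
        er, panel, pheno = strong_region_setup
        plain = permute_region(er, panel, pheno, B=50, seed=6, cbs_params=FAST_CBS)
        adj = conditional_region_test(
            er, panel, pheno, np.zeros(panel.n_samples), B=50, seed=6, cbs_params=FAST_CBS
        )
        assert adj.p_value == plain.p_value
        assert adj.observed_stat == plain.observed_stat

    def test_lrr_driven_signal_survives_adjustment(self, strong_region_setup, effect_cohort):
        """Adjusting for an independent SNP leaves a real CNV signal intact."""
        er, panel, pheno = strong_region_setup
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, panel.n_samples).astype(float)
        adj = conditional_region_test(er, panel, pheno, g, B=99, seed=7, cbs_params=FAST_CBS)
        assert adj.p_value == pytest.approx(1.0 / 100)

    def test_select_top_snp_finds_linked_snp(self, ld_cohort):
        cohort, geno, snp_id, g, pheno = ld_cohort
        seg = Segment("chr1", 200, 210, 0.0)
        er = expand_segment(seg, cohort.probe_map.chromosome_bounds()["chr1"])
        found, stat = select_top_snp(geno, pheno, er, cohort.probe_map)
        assert found == snp_id
        assert stat.p_value < 0.001
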