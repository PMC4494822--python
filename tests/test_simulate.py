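"""Generator contracts: null behaviour, frequencies, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cnvscan.qc import apply_qc_exclusions, compute_qc_metrics, median_normalize_by_plate
from cnvscan.simulate import (
    PhenoCoeffs,
    SimulationConfig,
    SimulationError,
    TrueRegion,
    simulate_cohort,
    simulate_linked_snp,
    simulate_qc_failures,
    with_effect,
)


class TestSimulateCohort:
    def test_null_configuration_lrr_centered_at_zero(self, null_cohort):
        """No regions and no effect: two copies everywhere, probe means near 0."""
        assert null_cohort.truth.copy_numbers.shape[1] == 0
        probe_means = null_cohort.panel.lrr.mean(axis=0)
        # per-probe mean is noise/sqrt(n) plus wave (0.02) and plate shifts (0.03)
        assert np.abs(probe_means).max() < 0.2
        assert abs(null_cohort.panel.lrr.mean()) < 0.05

    def test_deletion_carrier_fraction_matches_binomial(self):
        cfg = SimulationConfig(
            n_families=100,
            family_size_range=(4, 6),
            n_probes=400,
            n_chromosomes=1,
            cnv_regions=(TrueRegion("chr1", 50, 60, deletion_freq=0.3),),
            seed=5,
        )
        cohort = simulate_cohort(cfg)
        cn = cohort.truth.copy_numbers.iloc[:, 0]
        n = len(cn)
        frac = (cn < 2).mean()
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < 3 * sd

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_families=10, n_probes=300, n_chromosomes=1, seed=7)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.panel.lrr, b.panel.lrr)
        np.testing.assert_array_equal(a.panel.baf, b.panel.baf)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(SimulationError, match="overlap"):
            SimulationConfig(
                n_probes=400,
                n_chromosomes=1,
                cnv_regions=(
                    TrueRegion("chr1", 10, 30, deletion_freq=0.1),
                    TrueRegion("chr1", 25, 40, deletion_freq=0.1),
                ),
            )

    def test_region_invariants_enforced(self):
        with pytest.raises(SimulationError):
            TrueRegion("chr1", 10, 20, deletion_freq=0.7, duplication_freq=0.5)
        with pytest.raises(SimulationError):
            TrueRegion(
                "chr1", 10, 20, copy_number_lrr_means={0: -3.5, 1: -0.45, 2: 0.1, 3: 0.4, 4: 0.7}
            )

    def test_percent_density_in_range(self, null_cohort):
        pdense = null_cohort.phenotypes["percent_density"]
        assert pdense.between(0, 100).all()

    def test_phenotype_coefficients_recovered_from_true_design(self):
        """OLS of sqrt(PD) on the generating design recovers the coefficients."""
        cfg = with_effect(
            SimulationConfig(
                n_families=100,
                family_size_range=(4, 6),
                n_probes=300,
                n_chromosomes=1,
                cnv_regions=(TrueRegion("chr1", 50, 60, deletion_freq=0.3),),
                seed=13,
            ),
            -0.5,
        )
        cohort = simulate_cohort(cfg)
        ph = cohort.phenotypes
        y = np.sqrt(ph["percent_density"].to_numpy())
        dosage = cohort.truth.copy_numbers.iloc[:, 0].to_numpy() - 2
        X = np.column_stack(
            [
                np.ones(len(ph)),
                ph["age"],
                1.0 / ph["bmi"],
                ph["menopausal"],
                dosage,
            ]
        )
        fit = sm.OLS(y, X).fit()
        truth = cfg.pheno_coeffs
        for k, expected in enumerate(truth):
            assert abs(fit.params[k] - expected) < 3 * fit.bse[k], (
                f"coefficient {k}: {fit.params[k]} vs {expected}"
            )


class TestQCFailureInjection:
    def test_each_failure_kind_trips_its_threshold(self, null_cohort):
        panel = null_cohort.panel
        s = panel.sample_ids
        spec = {
            s[0]: {"kind": "noisy_lrr", "sd": 0.5},
            s[1]: {"kind": "baf_drift", "fraction": 0.01},
        }
        broken = simulate_qc_failures(panel, spec, seed=3)
        norm = median_normalize_by_plate(broken)
        metrics = apply_qc_exclusions(compute_qc_metrics(norm))
        assert metrics.loc[s[0], "lrr_sd"] > 0.35
        assert metrics.loc[s[1], "baf_drift"] > 0.0015
        # untouched samples unchanged
        i = panel.sample_index(s[2])
        np.testing.assert_array_equal(broken.lrr[i], panel.lrr[i])

    def test_empty_spec_is_identity(self, null_cohort):
        out = simulate_qc_failures(null_cohort.panel, {})
        np.testing.assert_array_equal(out.lrr, null_cohort.panel.lrr)

    def test_unknown_sample_errors(self, null_cohort):
        with pytest.raises(KeyError):
            simulate_qc_failures(null_cohort.panel, {"nope": {"kind": "wave", "amplitude": 1}})


@pytest.fixture(scope="module")
def carrier_cohort():
    cfg = SimulationConfig(
        n_families=100,
        family_size_range=(5, 6),
        n_probes=300,
        n_chromosomes=1,
        cnv_regions=(TrueRegion("chr1", 100, 110, deletion_freq=0.3),),
        seed=17,
    )
    return simulate_cohort(cfg)


class TestLinkedSnp:
    def test_perfect_linkage_is_deterministic(self, carrier_cohort):
        co = carrier_cohort
        region = co.truth.regions[0]
        geno, snp_id, r2 = simulate_linked_snp(None, co.truth, region, 1.0, co.probe_map, seed=1)
        carrier = co.truth.carriers(region.label).to_numpy()
        np.testing.assert_array_equal(geno[snp_id].to_numpy(), carrier.astype(int))
        assert r2 == pytest.approx(1.0)

    def test_zero_target_gives_near_independence(self, carrier_cohort):
        co = carrier_cohort
        region = co.truth.regions[0]
        geno, snp_id, _ = simulate_linked_snp(None, co.truth, region, 0.0, co.probe_map, seed=2)
        carrier = co.truth.carriers(region.label).to_numpy().astype(float)
        r = np.corrcoef(geno[snp_id].to_numpy(dtype=float), carrier)[0, 1]
        assert abs(r) < 0.1

    def test_intermediate_r2_realized(self, carrier_cohort):
        co = carrier_cohort
        region = co.truth.regions[0]
        _, _, realized = simulate_linked_snp(None, co.truth, region, 0.8, co.probe_map, seed=3)
        assert abs(realized - 0.8) < 0.1

    def test_no_carriers_errors(self):
        cfg = SimulationConfig(
            n_families=10,
            n_probes=300,
            n_chromosomes=1,
            cnv_regions=(TrueRegion("chr1", 100, 110, deletion_freq=0.0),),
            seed=4,
        )
        co = simulate_cohort(cfg)
        with pytest.raises(SimulationError, match="carrier"):
            simulate_linked_snp(None, co.truth, co.truth.regions[0], 0.8, co.probe_map)


def test_pheno_coeffs_defaults_are_null_effect():
    assert PhenoCoeffs().gamma_cnv == 0.0
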