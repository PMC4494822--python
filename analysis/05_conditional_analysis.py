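#!/usr/bin/env python
"""SNP-conditional analysis of a deletion region.

Builds the confounded scenario in which a SNP in LD (r^2 ~ 0.8) with the
deletion drives the phenotype, then contrasts the region's permutation
p-value before and after including the top SNP as a covariate in every probe
model.  A SNP-driven signal should lose significance after adjustment; a
genuinely copy-number-driven signal should survive it.
"""

from pathlib import Path

import pandas as pd

from cnvscan.permutation import conditional_region_test, permute_region, select_top_snp
from cnvscan.qc import median_normalize_by_plate
from cnvscan.segmentation import CBSParams, Segment, expand_segment
from cnvscan.simulate import (
    SimulationConfig,
    TrueRegion,
    shift_sqrt_density,
    simulate_cohort,
    simulate_linked_snp,
    with_effect,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FAST_CBS = CBSParams(n_split_permutations=100)
B = 999


def scenario(name: str, snp_driven: bool, seed: int) -> dict:
    cfg = SimulationConfig(
        n_families=60,
        family_size_range=(4, 4),
        n_probes=1000,
        n_chromosomes=2,
        cnv_regions=(TrueRegion("chr1", 200, 210, deletion_freq=0.3),),
        seed=seed,
    )
    if not snp_driven:
        cfg = with_effect(cfg, -1.2)
    cohort = simulate_cohort(cfg)
    region = cohort.truth.regions[0]
    geno, snp_id, r2 = simulate_linked_snp(
        None, cohort.truth, region, 0.8, cohort.probe_map, seed=seed + 1
    )
    pheno = cohort.phenotypes
    if snp_driven:
        g_for_pheno = geno[snp_id].reindex(pheno["sample_id"]).to_numpy(dtype=float)
        pheno = shift_sqrt_density(pheno, g_for_pheno, 0.9)
    panel = median_normalize_by_plate(cohort.panel)
    seg = Segment("chr1", 200, 210, 0.0)
    er = expand_segment(seg, cohort.probe_map.chromosome_bounds()["chr1"])
    top_snp, snp_stat = select_top_snp(geno, pheno, er, cohort.probe_map)
    g = geno[top_snp].reindex(pheno["sample_id"]).to_numpy(dtype=float)
    unadj = permute_region(er, panel, pheno, B=B, seed=seed + 2, cbs_params=FAST_CBS)
    adj = conditional_region_test(er, panel, pheno, g, B=B, seed=seed + 2, cbs_params=FAST_CBS)
    return dict(
        scenario=name,
        linked_snp=top_snp,
        realized_r2=round(r2, 3),
        snp_pvalue=f"{snp_stat.p_value:.3g}",
        region_p_unadjusted=f"{unadj.p_value:.6g}",
        region_p_snp_adjusted=f"{adj.p_value:.6g}",
    )


def main() -> None:
    rows = [
        scenario("snp_driven", snp_driven=True, seed=51),
        scenario("cnv_driven", snp_driven=False, seed=61),
    ]
    tab = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    tab.to_csv(RESULTS / "conditional_analysis.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))
    print(
        "\nsnp_driven: adjustment should remove significance; "
        "cnv_driven: the region should stay at/near the floor."
    )


if __name__ == "__main__":
    main()
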