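#!/usr/bin/env python
"""Simulate the discovery and replication cohorts.

Generates two family-structured SNP-array cohorts sharing one embedded
10-probe deletion region (carrier frequency 0.30).  The discovery cohort
carries a strong negative per-copy effect on sqrt(percent density); the
replication cohort carries the CNV but no phenotype effect — the situation
in which a CNV replicates while its association does not.

Bulky per-sample signal files go to scratch/cohorts/; small summaries to
results/.
"""

from pathlib import Path

import numpy as np

from cnvscan import io as cio
from cnvscan.simulate import SimulationConfig, TrueRegion, simulate_cohort, with_effect

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

REGION = TrueRegion("chr1", 200, 210, deletion_freq=0.3)

DISCOVERY = with_effect(
    SimulationConfig(
        n_families=50,
        family_size_range=(4, 5),
        n_probes=2000,
        n_chromosomes=4,
        cnv_regions=(REGION,),
        seed=11,
    ),
    -1.2,
)
REPLICATION = SimulationConfig(
    n_families=40,
    family_size_range=(4, 5),
    n_probes=2000,
    n_chromosomes=4,
    cnv_regions=(REGION,),
    seed=12,
)


def write_cohort(name: str, cfg: SimulationConfig) -> None:
    cohort = simulate_cohort(cfg)
    out = SCRATCH / name
    out.mkdir(parents=True, exist_ok=True)
    cio.write_probe_map(cohort.probe_map, out / "probemap.tsv")
    cio.write_phenotypes(cohort.phenotypes, out / "phenotypes.csv")
    cio.write_panel(cohort.panel, out / "signals")
    cohort.truth.copy_numbers.to_csv(out / "ground_truth.tsv", sep="\t")
    cn = cohort.truth.copy_numbers.iloc[:, 0]
    print(
        f"{name}: {cohort.panel.n_samples} samples, {cohort.probe_map.n_probes} probes, "
        f"deletion carriers {(cn < 2).mean():.1%} "
        f"(copy 0: {(cn == 0).sum()}, copy 1: {(cn == 1).sum()})"
    )
    RESULTS.mkdir(exist_ok=True)
    summary = out / "ground_truth.tsv"
    print(f"  data under {out}, truth at {summary}")


def main() -> None:
    np.set_printoptions(precision=3)
    write_cohort("discovery", DISCOVERY)
    write_cohort("replication", REPLICATION)


if __name__ == "__main__":
    main()
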