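import numpy as np
import pandas as pd
import pytest

from cnvscan.io import ProbeMap
from cnvscan.qc import median_normalize_by_plate
from cnvscan.simulate import (
    SimulationConfig,
    TrueRegion,
    simulate_cohort,
    with_effect,
)


@pytest.fixture(scope="session")
def null_cohort():
    """~200 women in 40 families, 1,000 probes, no CNV regions, no effect."""
    cfg = SimulationConfig(
        n_families=40,
        family_size_range=(4, 6),
        n_probes=1000,
        n_chromosomes=2,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """One strong 10-probe deletion region (chr1 probes 200..210) on 2,000 probes."""
    cfg = with_effect(
        SimulationConfig(
            n_families=50,
            family_size_range=(3, 5),
            n_probes=2000,
            n_chromosomes=4,
            cnv_regions=(TrueRegion("chr1", 200, 210, deletion_freq=0.3),),
            seed=21,
        ),
        -1.2,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_panel(effect_cohort):
    return median_normalize_by_plate(effect_cohort.panel)


def make_probe_map(n_probes: int, n_chrom: int = 1) -> ProbeMap:
    per = n_probes // n_chrom
    chroms = np.repeat([f"chr{i+1}" for i in range(n_chrom)], per)
    chroms = np.concatenate([chroms, [f"chr{n_chrom}"] * (n_probes - len(chroms))])
    pos = np.concatenate(
        [np.arange(np.sum(chroms == c)) * 5000 + 1 for c in pd.unique(chroms)]
    )
    return ProbeMap(
        pd.DataFrame(
            {
                "probe_id": [f"p{i:05d}" for i in range(n_probes)],
                "chromosome": chroms,
                "position": pos,
                "is_snp": True,
            }
        )
    )


def make_phenotypes(n: int, seed: int = 0, n_families: int | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    fam = (
        np.repeat([f"f{i}" for i in range((n_families or n) + 1)], max(1, n // (n_families or n)))[:n]
        if n_families
        else [f"f{i}" for i in range(n)]
    )
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "percent_density": rng.uniform(5, 60, n),
            "age": rng.normal(57, 11, n),
            "bmi": np.maximum(rng.normal(27, 5, n), 15),
            "menopausal": rng.integers(0, 2, n),
            "family_id": list(fam),
            "plate_id": ["P1"] * n,
        }
    )
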