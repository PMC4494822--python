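#!/usr/bin/env python
"""Per-plate median normalization and sample QC for both cohorts.

Reads the signal files written by 01_simulate_cohorts.py, recentres LRR per
plate, computes the four QC metrics (LRR SD, BAF drift, wave factor, CNV
interval count) and applies the exclusion thresholds 0.35 / 0.0015 / 0.05 /
500.  Writes per-sample QC tables to results/.
"""

from pathlib import Path

from cnvscan import io as cio
from cnvscan.qc import apply_qc_exclusions, compute_qc_metrics, median_normalize_by_plate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def qc_cohort(name: str) -> None:
    d = SCRATCH / name
    probe_map = cio.read_probe_map(d / "probemap.tsv")
    pheno = cio.read_phenotypes(d / "phenotypes.csv")
    plates = dict(zip(pheno["sample_id"], pheno["plate_id"]))
    panel = cio.read_signal_files(sorted((d / "signals").glob("*.signal.tsv")), probe_map, plates)
    panel = median_normalize_by_plate(panel)
    metrics = apply_qc_exclusions(compute_qc_metrics(panel))
    RESULTS.mkdir(exist_ok=True)
    metrics.to_csv(RESULTS / f"qc_{name}.tsv", sep="\t", index_label="sample_id")
    n_exc = int(metrics["excluded"].sum())
    print(
        f"{name}: {len(metrics)} samples, {n_exc} excluded "
        f"({', '.join(r for r in metrics.loc[metrics['excluded'], 'exclusion_reasons']) or 'none'})"
    )


def main() -> None:
    for name in ("discovery", "replication"):
        qc_cohort(name)


if __name__ == "__main__":
    main()
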