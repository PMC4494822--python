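#!/usr/bin/env python
"""Probe-level association scan and CBS segmentation, both cohorts.

Fits sqrt(percent density) ~ LRR + age + 1/BMI + menopausal status at every
probe on the QC-passing samples, applies circular binary segmentation to the
|t| track per chromosome, filters to segments of >= 3 probes with mean |t|
> 1, and expands candidates by six times their probe count on each side.
Writes the probe statistic tracks and candidate-region tables to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cnvscan import io as cio
from cnvscan.association import scan_probes, write_probe_stats
from cnvscan.qc import apply_qc_exclusions, compute_qc_metrics, median_normalize_by_plate, passing_samples
from cnvscan.segmentation import expand_segment, identify_candidate_segments

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def scan_cohort(name: str, seed: int) -> None:
    d = SCRATCH / name
    probe_map = cio.read_probe_map(d / "probemap.tsv")
    pheno = cio.read_phenotypes(d / "phenotypes.csv")
    plates = dict(zip(pheno["sample_id"], pheno["plate_id"]))
    panel = cio.read_signal_files(sorted((d / "signals").glob("*.signal.tsv")), probe_map, plates)
    panel = median_normalize_by_plate(panel)
    metrics = apply_qc_exclusions(compute_qc_metrics(panel))
    keep = passing_samples(metrics)
    panel = panel.subset_samples(keep)
    pheno = pheno.set_index("sample_id").loc[keep].reset_index()

    stats = scan_probes(panel, pheno)
    # full per-probe tracks are bulky; keep them with the cohort data
    write_probe_stats(stats, SCRATCH / name / "probe_stats.tsv")
    track = np.abs(stats["t"].to_numpy())
    segments = identify_candidate_segments(track, probe_map, seed=seed)
    bounds = probe_map.chromosome_bounds()
    pos = probe_map.table["position"].to_numpy()
    rows = []
    for seg in segments:
        er = expand_segment(seg, bounds[seg.chromosome])
        rows.append(
            dict(
                chromosome=seg.chromosome,
                start_pos=int(pos[seg.start_idx]),
                end_pos=int(pos[seg.end_idx - 1]),
                n_probes=seg.n_probes,
                mean_abs_t=round(seg.mean_abs_t, 4),
                exp_start_pos=int(pos[er.exp_start_idx]),
                exp_end_pos=int(pos[er.exp_end_idx - 1]),
                n_total_probes=er.n_total_probes,
            )
        )
    tab = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start_pos", "end_pos", "n_probes", "mean_abs_t",
            "exp_start_pos", "exp_end_pos", "n_total_probes",
        ],
    )
    tab.to_csv(RESULTS / f"segments_{name}.tsv", sep="\t", index=False)
    print(f"{name}: {len(keep)} samples analyzed, {len(tab)} candidate segments")
    if len(tab):
        print(tab.to_string(index=False))


def main() -> None:
    scan_cohort("discovery", seed=31)
    scan_cohort("replication", seed=32)


if __name__ == "__main__":
    main()
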