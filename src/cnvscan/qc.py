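"""Per-plate median normalization and sample-level quality control.

QC metrics are desk-scale analogues of the conventional array QC summaries:

* ``lrr_sd`` — standard deviation of a sample's non-missing autosomal LRR;
* ``baf_drift`` — fraction of non-missing BAF values strictly inside the
  drift windows (0.2, 0.25) ∪ (0.75, 0.8), where no genotype cluster should
  place mass;
* ``wave_factor`` — SD across 1,000-probe windows of the per-window median
  LRR (long-range "genomic wave" oscillation);
* ``n_cnv_intervals`` — number of maximal runs of ≥3 consecutive probes whose
  3-probe running-mean LRR deviates from 0 by more than 0.25 (a fragmented,
  CNV-call-rich profile indicates a failed sample).

Default exclusion thresholds: lrr_sd > 0.35, baf_drift > 0.0015,
wave_factor > 0.05, n_cnv_intervals > 500 (all strict).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import IntensityPanel


class QCThresholds(NamedTuple):
    lrr_sd: float = 0.35
    baf_drift: float = 0.0015
    wave_factor: float = 0.05
    n_cnv_intervals: int = 500


METRIC_NAMES = ["lrr_sd", "baf_drift", "wave_factor", "n_cnv_intervals"]

#: Minimum non-missing probes for metrics to be defined.
MIN_PROBES = 100


class QCError(ValueError):
    pass


def median_normalize_by_plate(panel: IntensityPanel) -> IntensityPanel:
    """Subtract each plate's pooled LRR median; BAF is untouched.

    After normalization every plate's pooled non-missing LRR median is 0.
    Idempotent.  A plate with no non-missing LRR values is an error.
    """
    out = panel.copy()
    plate_arr = np.asarray(out.plate_ids, dtype=object)
    for plate in pd.unique(plate_arr):
        rows = np.nonzero(plate_arr == plate)[0]
        vals = out.lrr[rows]
        if not np.isfinite(vals).any():
            raise QCError(f"plate {plate!r} has no non-missing LRR values")
        out.lrr[rows] -= np.nanmedian(vals)
    return out


def _running_mean3(x: np.ndarray) -> np.ndarray:
    """Centered 3-probe running mean, NaN-aware, defined at the edges."""
    return (
        pd.Series(x).rolling(3, center=True, min_periods=1).mean().to_numpy()
    )


def _count_cnv_intervals(
    lrr: np.ndarray, chrom_codes: np.ndarray, threshold: float = 0.25
) -> int:
    """Maximal runs of >=3 consecutive probes with |running-mean LRR| > threshold."""
    total = 0
    for chrom in np.unique(chrom_codes):
        x = lrr[chrom_codes == chrom]
        sm = _running_mean3(x)
        flag = np.abs(sm) > threshold
        flag &= np.isfinite(sm)
        # run-length encode
        padded = np.concatenate([[False], flag, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]
        total += int(np.sum((ends - starts) >= 3))
    return total


def _wave_factor(lrr: np.ndarray, window: int = 1000) -> float:
    """SD of per-window median LRR over consecutive probe windows."""
    m = len(lrr)
    n_full = m // window
    edges = [(i * window, (i + 1) * window) for i in range(n_full)]
    rem = m - n_full * window
    if rem >= window // 2:
        edges.append((n_full * window, m))
    if len(edges) < 2:
        return 0.0
    with np.errstate(all="ignore"):
        medians = np.array([np.nanmedian(lrr[a:b]) for a, b in edges])
    medians = medians[np.isfinite(medians)]
    if len(medians) < 2:
        return 0.0
    return float(np.std(medians, ddof=1))


def compute_qc_metrics(
    panel: IntensityPanel, window: int = 1000, interval_threshold: float = 0.25
) -> pd.DataFrame:
    """Per-sample QC metric table (computed on the normalized panel).

    Samples with fewer than 100 non-missing LRR probes get NaN metrics and
    are pre-excluded with reason ``insufficient probes``.
    """
    chrom_codes = pd.factorize(panel.probe_map.table["chromosome"])[0]
    rows = []
    for i, sample in enumerate(panel.sample_ids):
        lrr = panel.lrr[i]
        baf = panel.baf[i]
        ok = np.isfinite(lrr)
        if ok.sum() < MIN_PROBES:
            rows.append(
                dict(
                    sample_id=sample,
                    lrr_sd=np.nan,
                    baf_drift=np.nan,
                    wave_factor=np.nan,
                    n_cnv_intervals=np.nan,
                    excluded=True,
                    exclusion_reasons="insufficient probes",
                )
            )
            continue
        lrr_sd = float(np.std(lrr[ok], ddof=1))
        bok = np.isfinite(baf)
        if bok.any():
            b = baf[bok]
            in_window = ((b > 0.2) & (b < 0.25)) | ((b > 0.75) & (b < 0.8))
            baf_drift = float(in_window.mean())
        else:
            baf_drift = 0.0
        wave = _wave_factor(lrr, window=window)
        n_intervals = _count_cnv_intervals(lrr, chrom_codes, threshold=interval_threshold)
        rows.append(
            dict(
                sample_id=sample,
                lrr_sd=lrr_sd,
                baf_drift=baf_drift,
                wave_factor=wave,
                n_cnv_intervals=n_intervals,
                excluded=False,
                exclusion_reasons="",
            )
        )
    return pd.DataFrame(rows).set_index("sample_id")


def apply_qc_exclusions(
    metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """Mark samples whose metrics strictly exceed any threshold.

    A sample sitting exactly at a threshold is retained (strict inequality).
    Pre-existing exclusions (insufficient probes) are preserved.
    """
    out = metrics.copy()
    for idx in out.index:
        row = out.loc[idx]
        reasons = [r for r in [row["exclusion_reasons"]] if r]
        for name, thr in zip(METRIC_NAMES, thresholds):
            v = row[name]
            if np.isfinite(v) and v > thr:
                reasons.append(name)
        out.loc[idx, "exclusion_reasons"] = ",".join(reasons)
        out.loc[idx, "excluded"] = bool(reasons)
    return out


def passing_samples(metrics: pd.DataFrame) -> list[str]:
    return list(metrics.index[~metrics["excluded"].astype(bool)])


def write_qc_report(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index_label="sample_id")
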