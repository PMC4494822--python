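"""Forced integer copy-number calls in predefined regions.

For a fixed genomic window the de-novo segmentation problem disappears and
calling reduces to a per-sample decision among five copy-number states.  Each
state contributes a Gaussian likelihood for every probe's LRR around the
state's displacement (0 at two copies, strongly negative at zero copies) and
a mixture likelihood for every SNP probe's BAF around the state's cluster
pattern (uniform at zero copies, clusters {k/c} with binomial weights at c
copies).  The call is the state maximizing the summed log-likelihood; the
call score is the log-likelihood margin over the runner-up state.

Deletion carriers (called copy number < 2) are then contrasted against
non-carriers in the usual density model; a duplication contrast is available
symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import ModelSpec, ProbeStat, fit_probe_model
from .io import IntensityPanel
from .simulate import DEFAULT_CN_LRR_MEANS

logger = logging.getLogger(__name__)

STATES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class CallingParams:
    """Likelihood parameters shared by default with the simulator's physics."""

    lrr_means: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CN_LRR_MEANS)
    )
    lrr_sd: float = 0.2
    baf_cluster_sd: float = 0.04
    baf_outlier_weight: float = 0.02
    het_allele_freq: float = 0.5  # binomial weight parameter for BAF clusters


@dataclass
class CNVCall:
    sample_id: str
    region: str
    copy_number: int | None
    call_score: float
    is_deletion_carrier: bool

    def __post_init__(self) -> None:
        if self.copy_number is not None and self.copy_number not in STATES:
            raise ValueError("copy number must be in {0..4}")
        expected = self.copy_number is not None and self.copy_number < 2
        if self.is_deletion_carrier != expected:
            raise ValueError("carrier flag inconsistent with copy number")


class CallingError(ValueError):
    pass


def _baf_loglik(baf: np.ndarray, state: int, params: CallingParams) -> float:
    """Log-likelihood of observed BAF values under a copy-number state."""
    if baf.size == 0:
        return 0.0
    if state == 0:
        return 0.0  # uniform on [0, 1]: log-density 0 per probe
    k = np.arange(state + 1)
    weights = sps.binom.pmf(k, state, params.het_allele_freq)
    centers = k / state
    dens = np.zeros_like(baf)
    for w, c in zip(weights, centers):
        dens += w * sps.norm.pdf(baf, loc=c, scale=params.baf_cluster_sd)
    dens = (1 - params.baf_outlier_weight) * dens + params.baf_outlier_weight * 1.0
    return float(np.sum(np.log(dens)))


def call_region_copy_number(
    panel: IntensityPanel,
    region: tuple[str, int, int],
    params: CallingParams = CallingParams(),
) -> list[CNVCall]:
    """Force a copy-number call (0–4) for every sample in a genomic window.

    ``region`` is (chromosome, start_position, end_position), inclusive in
    basepairs.  The window must contain at least three probes.  A sample with
    no non-missing measurement in the window gets its call withheld
    (``copy_number`` None, logged).  Calls are deterministic and independent
    across samples.
    """
    chrom, start_pos, end_pos = region
    idx = panel.probe_map.probes_in_interval(chrom, start_pos, end_pos)
    if len(idx) < 3:
        raise CallingError(f"region {chrom}:{start_pos}-{end_pos} has <3 probes")
    label = f"{chrom}:{start_pos}-{end_pos}"
    is_snp = panel.probe_map.table["is_snp"].to_numpy()[idx]
    calls: list[CNVCall] = []
    for i, sample in enumerate(panel.sample_ids):
        lrr = panel.lrr[i, idx]
        baf = panel.baf[i, idx]
        lrr_ok = np.isfinite(lrr)
        baf_ok = np.isfinite(baf) & is_snp
        if not lrr_ok.any() and not baf_ok.any():
            logger.info("call withheld for %s in %s: all probes missing", sample, label)
            calls.append(CNVCall(sample, label, None, 0.0, False))
            continue
        logliks = np.empty(len(STATES))
        for s_i, state in enumerate(STATES):
            ll = float(
                np.sum(
                    sps.norm.logpdf(
                        lrr[lrr_ok], loc=params.lrr_means[state], scale=params.lrr_sd
                    )
                )
            )
            ll += _baf_loglik(baf[baf_ok], state, params)
            logliks[s_i] = ll
        order = np.argsort(logliks)[::-1]
        best, runner = int(order[0]), int(order[1])
        cn = STATES[best]
        calls.append(
            CNVCall(
                sample_id=sample,
                region=label,
                copy_number=cn,
                call_score=float(logliks[best] - logliks[runner]),
                is_deletion_carrier=cn < 2,
            )
        )
    return calls


def calls_table(calls: Sequence[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=c.sample_id,
                region=c.region,
                copy_number=c.copy_number,
                call_score=c.call_score,
                is_deletion_carrier=c.is_deletion_carrier,
            )
            for c in calls
        ]
    )


def carrier_association(
    calls: Sequence[CNVCall],
    phenotypes: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    contrast: str = "deletion",
) -> ProbeStat:
    """Density model with carrier status (0/1) replacing the LRR.

    ``contrast`` selects deletion carriers (called copy number < 2) or
    duplication carriers (> 2).  Requires at least two carriers and two
    non-carriers among samples with calls and phenotypes.
    """
    if contrast not in ("deletion", "duplication"):
        raise CallingError("contrast must be 'deletion' or 'duplication'")
    tab = calls_table(list(calls)).dropna(subset=["copy_number"])
    if contrast == "deletion":
        tab["carrier"] = tab["copy_number"] < 2
    else:
        tab["carrier"] = tab["copy_number"] > 2
    merged = phenotypes.merge(tab[["sample_id", "carrier"]], on="sample_id", how="inner")
    n_car = int(merged["carrier"].sum())
    n_non = len(merged) - n_car
    if n_car < 2:
        raise CallingError(
            f"no usable {contrast} carriers ({n_car} found; need >= 2)"
        )
    if n_non < 2:
        raise CallingError(
            f"nearly all samples are {contrast} carriers ({n_non} non-carriers; need >= 2)"
        )
    region = calls[0].region if calls else ""
    return fit_probe_model(
        merged["carrier"].astype(float).to_numpy(),
        merged,
        spec,
        probe_id=f"{region}:{contrast}",
    )
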