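"""Synthetic SNP-array cohorts with known embedded copy-number regions.

The generator emulates the structure of a family-based mammographic-density
GWAS cohort: a few hundred women in multigenerational families, genotyped on
plates that each carry a shared LRR batch shift, with long-range "genomic
wave" oscillation in LRR, embedded deletion/duplication regions (copy numbers
0–4), and percent density driven by age, inverse BMI, menopausal status and
copy number on the square-root scale with a per-family random intercept.

Copy-number states displace a probe's LRR by a state-specific mean (defaults
match conventional array cluster positions) and reshape the BAF cluster
pattern: 0 copies give uninformative uniform BAF, c >= 1 copies cluster at
{k/c : k = 0..c}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import IntensityPanel, ProbeMap, validate_phenotypes

logger = logging.getLogger(__name__)

#: Default LRR displacement per copy-number state (2 copies = reference 0).
DEFAULT_CN_LRR_MEANS: dict[int, float] = {0: -3.5, 1: -0.45, 2: 0.0, 3: 0.4, 4: 0.68}

#: Maximum representable square-root percent density (sqrt(100)).
_SQRT_PD_MAX = 10.0


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


class PhenoCoeffs(NamedTuple):
    """Coefficients of the phenotype model on the sqrt(percent density) scale."""

    intercept: float = 6.1
    beta_age: float = -0.04  # per year
    beta_invbmi: float = 40.0  # per (kg/m^2)^-1
    beta_meno: float = -0.6  # post- vs pre-menopausal
    gamma_cnv: float = 0.0  # per copy relative to the 2-copy reference


@dataclass(frozen=True)
class TrueRegion:
    """An embedded CNV region, in chromosome-local probe indices (half-open)."""

    chromosome: str
    start_probe_index: int
    end_probe_index: int
    deletion_freq: float = 0.0  # P(carrier with copy number < 2)
    duplication_freq: float = 0.0  # P(carrier with copy number > 2)
    copy_number_lrr_means: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CN_LRR_MEANS)
    )

    def __post_init__(self) -> None:
        if self.end_probe_index <= self.start_probe_index:
            raise SimulationError("region end must exceed start")
        if self.start_probe_index < 0:
            raise SimulationError("region start must be >= 0")
        for f in (self.deletion_freq, self.duplication_freq):
            if not 0.0 <= f <= 1.0:
                raise SimulationError("region frequencies must be in [0, 1]")
        if self.deletion_freq + self.duplication_freq > 1.0:
            raise SimulationError("deletion_freq + duplication_freq must be <= 1")
        means = self.copy_number_lrr_means
        if set(means) != {0, 1, 2, 3, 4}:
            raise SimulationError("copy_number_lrr_means must cover states 0..4")
        if means[2] != 0.0:
            raise SimulationError("copy_number_lrr_means[2] must be 0")
        vals = [means[c] for c in range(5)]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise SimulationError("copy_number_lrr_means must increase with copy number")

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.start_probe_index}-{self.end_probe_index}"

    @property
    def n_probes(self) -> int:
        return self.end_probe_index - self.start_probe_index


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 89
    family_size_range: tuple[int, int] = (4, 9)
    n_probes: int = 5000
    n_chromosomes: int = 5
    plate_size: int = 96
    cnv_regions: tuple[TrueRegion, ...] = ()
    lrr_noise_sd: float = 0.15
    wave_amplitude: float = 0.02
    wave_period: int = 1500  # probes per wave cycle
    plate_shift_sd: float = 0.03
    pheno_coeffs: PhenoCoeffs = PhenoCoeffs()
    family_sd: float = 0.6
    residual_sd: float = 1.1
    baf_noise_sd: float = 0.03
    snp_probe_fraction: float = 0.9
    n_background_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_families=self.n_families,
            n_probes=self.n_probes,
            n_chromosomes=self.n_chromosomes,
            plate_size=self.plate_size,
            wave_period=self.wave_period,
        )
        for name, v in counts.items():
            if v < 1:
                raise SimulationError(f"{name} must be >= 1")
        lo, hi = self.family_size_range
        if lo < 1 or hi < lo:
            raise SimulationError("family_size_range must satisfy 1 <= min <= max")
        for name in ("lrr_noise_sd", "family_sd", "residual_sd", "baf_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not isinstance(self.pheno_coeffs, PhenoCoeffs):
            object.__setattr__(self, "pheno_coeffs", PhenoCoeffs(*self.pheno_coeffs))
        object.__setattr__(self, "cnv_regions", tuple(self.cnv_regions))
        self._validate_regions()

    def _validate_regions(self) -> None:
        per_chrom = self.n_probes // self.n_chromosomes
        by_chrom: dict[str, list[TrueRegion]] = {}
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for r in self.cnv_regions:
            if r.chromosome not in chroms:
                raise SimulationError(f"region chromosome {r.chromosome!r} not simulated")
            n_on_chrom = per_chrom + (
                self.n_probes % self.n_chromosomes
                if r.chromosome == f"chr{self.n_chromosomes}"
                else 0
            )
            if r.end_probe_index > n_on_chrom:
                raise SimulationError(f"region {r.label} extends past the chromosome")
            by_chrom.setdefault(r.chromosome, []).append(r)
        for regions in by_chrom.values():
            regions = sorted(regions, key=lambda r: r.start_probe_index)
            for a, b in zip(regions, regions[1:]):
                if b.start_probe_index < a.end_probe_index:
                    raise SimulationError(f"regions {a.label} and {b.label} overlap")


@dataclass
class GroundTruth:
    """Per-sample true copy numbers plus the generating coefficients."""

    copy_numbers: pd.DataFrame  # index sample_id, one column per region label
    regions: tuple[TrueRegion, ...]
    pheno_coeffs: PhenoCoeffs
    family_id: pd.Series
    plate_id: pd.Series

    def carriers(self, region_label: str, kind: str = "deletion") -> pd.Series:
        cn = self.copy_numbers[region_label]
        return cn < 2 if kind == "deletion" else cn > 2


@dataclass
class Cohort:
    probe_map: ProbeMap
    panel: IntensityPanel
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame | None
    truth: GroundTruth


def _make_probe_map(config: SimulationConfig, rng: np.random.Generator) -> ProbeMap:
    per = config.n_probes // config.n_chromosomes
    rows = []
    left = config.n_probes
    for i in range(config.n_chromosomes):
        n = per if i < config.n_chromosomes - 1 else left
        left -= n
        chrom = f"chr{i + 1}"
        positions = 10_000 + 5_000 * np.arange(n)
        for j in range(n):
            rows.append((f"{chrom}_p{j:05d}", chrom, int(positions[j])))
    df = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])
    df["is_snp"] = rng.random(len(df)) < config.snp_probe_fraction
    return ProbeMap(df)


def _global_region_slice(probe_map: ProbeMap, region: TrueRegion) -> slice:
    start, _ = probe_map.chromosome_bounds()[region.chromosome]
    return slice(start + region.start_probe_index, start + region.end_probe_index)


def _draw_copy_numbers(
    region: TrueRegion, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Carrier state by region frequency; a third of carriers are homozygous.

    The 1/3 homozygous : 2/3 hemizygous split mirrors the ratio reported for
    catalogued common deletion regions; the same split is used for
    duplications (copy 4 vs copy 3).
    """
    u = rng.random(n)
    zyg = rng.random(n)
    cn = np.full(n, 2, dtype=int)
    deleted = u < region.deletion_freq
    duplicated = (~deleted) & (u < region.deletion_freq + region.duplication_freq)
    cn[deleted] = np.where(zyg[deleted] < 1 / 3, 0, 1)
    cn[duplicated] = np.where(zyg[duplicated] < 1 / 3, 4, 3)
    return cn


def _baf_for_state(
    cn: int,
    p_b: np.ndarray,
    size: tuple[int, ...],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """BAF draws under copy-number state ``cn`` with per-probe B-allele freq."""
    if cn == 0:
        return rng.random(size)
    k = rng.binomial(cn, np.broadcast_to(p_b, size))
    vals = k / cn + rng.normal(0.0, noise_sd, size)
    return np.clip(vals, 0.0, 1.0)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort (probe map, intensities, phenotypes, truth).

    Identical configuration (including seed) yields bit-identical output.  A
    per-stage seed sequence is derived from ``config.seed`` so that each
    component (family structure, copy numbers, intensities, phenotypes,
    genotypes) consumes an independent, reproducible stream.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_map, s_fam, s_cnv, s_lrr, s_baf, s_pheno, s_geno) = ss.spawn(7)
    rng_map = np.random.default_rng(s_map)
    probe_map = _make_probe_map(config, rng_map)
    m = probe_map.n_probes

    # family / plate structure
    rng_fam = np.random.default_rng(s_fam)
    lo, hi = config.family_size_range
    sizes = rng_fam.integers(lo, hi + 1, size=config.n_families)
    n = int(sizes.sum())
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    family_id = np.repeat([f"F{i + 1:03d}" for i in range(config.n_families)], sizes)
    plate_id = np.array(
        [f"P{(i // config.plate_size) + 1:02d}" for i in range(n)], dtype=object
    )

    # copy numbers per region
    rng_cnv = np.random.default_rng(s_cnv)
    cn_cols: dict[str, np.ndarray] = {}
    for region in config.cnv_regions:
        cn_cols[region.label] = _draw_copy_numbers(region, n, rng_cnv)
    copy_numbers = pd.DataFrame(cn_cols, index=pd.Index(sample_ids, name="sample_id"))

    # LRR: state means + wave + plate shift + noise
    rng_lrr = np.random.default_rng(s_lrr)
    lrr = rng_lrr.normal(0.0, config.lrr_noise_sd, size=(n, m))
    phases = rng_lrr.uniform(0.0, 2 * np.pi, size=n)
    wave = config.wave_amplitude * np.sin(
        2 * np.pi * np.arange(m)[None, :] / config.wave_period + phases[:, None]
    )
    lrr += wave
    plates = pd.unique(plate_id)
    shifts = rng_lrr.normal(0.0, config.plate_shift_sd, size=len(plates))
    plate_shift = pd.Series(shifts, index=plates)
    lrr += plate_shift[plate_id].to_numpy()[:, None]
    for region in config.cnv_regions:
        sl = _global_region_slice(probe_map, region)
        means = np.array([region.copy_number_lrr_means[c] for c in range(5)])
        lrr[:, sl] += means[copy_numbers[region.label].to_numpy()][:, None]

    # BAF: cluster pattern by copy-number state; non-SNP probes uninformative
    rng_baf = np.random.default_rng(s_baf)
    is_snp = probe_map.table["is_snp"].to_numpy()
    p_b = rng_baf.uniform(0.1, 0.9, size=m)
    baf = _baf_for_state(2, p_b[None, :], (n, m), config.baf_noise_sd, rng_baf)
    for region in config.cnv_regions:
        sl = _global_region_slice(probe_map, region)
        cn_vec = copy_numbers[region.label].to_numpy()
        for state in (0, 1, 3, 4):
            rows = np.nonzero(cn_vec == state)[0]
            if len(rows) == 0:
                continue
            sub = _baf_for_state(
                state,
                p_b[None, sl],
                (len(rows), sl.stop - sl.start),
                config.baf_noise_sd,
                rng_baf,
            )
            baf[np.ix_(rows, np.arange(sl.start, sl.stop))] = sub
    baf[:, ~is_snp] = np.nan

    panel = IntensityPanel(
        sample_ids=sample_ids,
        plate_ids=list(plate_id),
        lrr=lrr,
        baf=baf,
        probe_map=probe_map,
    )

    # phenotype
    rng_pheno = np.random.default_rng(s_pheno)
    age = rng_pheno.normal(57.2, 11.6, size=n)
    bmi = np.maximum(rng_pheno.normal(27.1, 5.7, size=n), 15.0)
    meno = ((age > 51.0) ^ (rng_pheno.random(n) < 0.1)).astype(int)
    fam_codes = pd.factorize(family_id)[0]
    fam_eff = rng_pheno.normal(0.0, config.family_sd, size=config.n_families)
    resid = rng_pheno.normal(0.0, config.residual_sd, size=n)
    c = config.pheno_coeffs
    dosage = np.zeros(n)
    for region in config.cnv_regions:
        dosage += copy_numbers[region.label].to_numpy() - 2
    sqrt_pd = (
        c.intercept
        + c.beta_age * age
        + c.beta_invbmi / bmi
        + c.beta_meno * meno
        + c.gamma_cnv * dosage
        + fam_eff[fam_codes]
        + resid
    )
    n_clamped = int(np.sum((sqrt_pd < 0) | (sqrt_pd > _SQRT_PD_MAX)))
    if n_clamped:
        logger.warning(
            "sqrt(PD) outside [0, %.0f] for %d samples; clamping", _SQRT_PD_MAX, n_clamped
        )
    sqrt_pd = np.clip(sqrt_pd, 0.0, _SQRT_PD_MAX)
    phenotypes = validate_phenotypes(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "percent_density": sqrt_pd**2,
                "age": age,
                "bmi": bmi,
                "menopausal": meno,
                "family_id": family_id,
                "plate_id": plate_id,
            }
        )
    )

    # optional background SNP genotypes, named after SNP probes
    genotypes = None
    if config.n_background_snps > 0:
        rng_geno = np.random.default_rng(s_geno)
        snp_probes = probe_map.table.loc[is_snp, "probe_id"].to_numpy()
        k = min(config.n_background_snps, len(snp_probes))
        chosen = rng_geno.choice(snp_probes, size=k, replace=False)
        mafs = rng_geno.uniform(0.1, 0.5, size=k)
        geno = rng_geno.binomial(2, np.broadcast_to(mafs, (n, k)))
        genotypes = pd.DataFrame(
            geno, index=pd.Index(sample_ids, name="sample_id"), columns=list(chosen)
        )

    truth = GroundTruth(
        copy_numbers=copy_numbers,
        regions=config.cnv_regions,
        pheno_coeffs=c,
        family_id=pd.Series(family_id, index=sample_ids),
        plate_id=pd.Series(plate_id, index=sample_ids),
    )
    return Cohort(probe_map, panel, phenotypes, genotypes, truth)


# ---------------------------------------------------------------------------
# QC failure injection


def simulate_qc_failures(
    panel: IntensityPanel,
    failure_spec: Mapping[str, Mapping[str, float]],
    seed: int = 0,
) -> IntensityPanel:
    """Degrade designated samples so they violate specific QC thresholds.

    ``failure_spec`` maps sample id to ``{"kind": ..., **params}`` where kind
    is one of:

    * ``noisy_lrr`` (``sd``): extra white noise on the LRR;
    * ``baf_drift`` (``fraction``): move that fraction of BAF values into the
      drift windows (0.2, 0.25) and (0.75, 0.8);
    * ``wave`` (``amplitude``): add a strong long-range sinusoid;
    * ``fragmented`` (``n_intervals``): inject that many short ±0.4 LRR blocks.

    Unnamed samples are returned unchanged.
    """
    out = panel.copy()
    rng = np.random.default_rng(seed)
    m = panel.probe_map.n_probes
    for sample, spec in failure_spec.items():
        i = out.sample_index(sample)  # KeyError for unknown samples
        kind = spec["kind"]
        if kind == "noisy_lrr":
            out.lrr[i] += rng.normal(0.0, float(spec["sd"]), size=m)
        elif kind == "baf_drift":
            frac = float(spec["fraction"])
            observed = np.nonzero(np.isfinite(out.baf[i]))[0]
            k = int(round(frac * len(observed)))
            idx = rng.choice(observed, size=k, replace=False)
            lo_window = rng.random(k) < 0.5
            vals = np.where(
                lo_window,
                rng.uniform(0.205, 0.245, size=k),
                rng.uniform(0.755, 0.795, size=k),
            )
            out.baf[i, idx] = vals
        elif kind == "wave":
            # period of two QC windows so the per-window medians alternate sign
            amp = float(spec["amplitude"])
            out.lrr[i] += amp * np.sin(2 * np.pi * np.arange(m) / 2000.0)
        elif kind == "fragmented":
            k = int(spec["n_intervals"])
            block = 5
            spacing = m // k
            if spacing < block + 3:
                raise SimulationError(f"cannot fit {k} intervals into {m} probes")
            for b in range(k):
                start = b * spacing
                sign = 1.0 if b % 2 == 0 else -1.0
                out.lrr[i, start : start + block] += sign * 0.4
        else:
            raise SimulationError(f"unknown failure kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# linked-SNP generation and phenotype perturbation helpers


def simulate_linked_snp(
    genotypes: pd.DataFrame | None,
    truth: GroundTruth,
    region: TrueRegion,
    r2_target: float,
    probe_map: ProbeMap,
    seed: int = 0,
) -> tuple[pd.DataFrame, str, float]:
    """Add one SNP in LD with a region's carrier status.

    The SNP starts as a copy of the 0/1 carrier indicator and a fraction
    ``1 - sqrt(r2_target)`` of samples are re-drawn from the permuted marginal
    (copy-then-perturb), so that the squared correlation with carrier status
    is approximately ``r2_target``.  The realized r² is returned and logged.
    The SNP is named after the SNP probe closest to the region midpoint so
    that positional SNP selection can find it.
    """
    if not 0.0 <= r2_target <= 1.0:
        raise SimulationError("r2_target must be in [0, 1]")
    carrier = truth.carriers(region.label).to_numpy().astype(float)
    if carrier.sum() == 0:
        raise SimulationError("region has no carriers; correlation undefined")
    rng = np.random.default_rng(seed)
    g = carrier.copy()
    pi = 1.0 - float(np.sqrt(r2_target))
    mask = rng.random(len(g)) < pi
    if mask.any():
        g[mask] = rng.permutation(carrier)[mask]
    if np.std(g) > 0 and np.std(carrier) > 0:
        realized = float(np.corrcoef(g, carrier)[0, 1] ** 2)
    else:
        realized = 0.0
    logger.info("linked SNP realized r^2 = %.3f (target %.3f)", realized, r2_target)

    sl = _global_region_slice(probe_map, region)
    sub = probe_map.table.iloc[sl.start : sl.stop]
    snp_rows = sub[sub["is_snp"]]
    if len(snp_rows) == 0:  # fall back to nearest SNP probe on the chromosome
        chrom_tab = probe_map.table[probe_map.table["chromosome"] == region.chromosome]
        snp_rows = chrom_tab[chrom_tab["is_snp"]]
        if len(snp_rows) == 0:
            raise SimulationError("no SNP probes available to anchor the linked SNP")
    mid = (sl.start + sl.stop) // 2
    snp_id = snp_rows.iloc[(snp_rows.index - mid).to_numpy().__abs__().argmin()]["probe_id"]

    col = pd.Series(g.astype(int), index=truth.copy_numbers.index, name=snp_id)
    if genotypes is None:
        genotypes = pd.DataFrame(index=truth.copy_numbers.index)
    genotypes = genotypes.copy()
    genotypes[snp_id] = col
    return genotypes, str(snp_id), realized


def shift_sqrt_density(
    phenotypes: pd.DataFrame, covariate: np.ndarray | pd.Series, beta: float
) -> pd.DataFrame:
    """Add ``beta * covariate`` to sqrt(percent density), re-square and clamp.

    Utility for constructing phenotypes driven by a SNP or carrier status on
    the model's own (square-root) scale.
    """
    out = phenotypes.copy()
    x = np.asarray(covariate, dtype=float)
    sqrt_pd = np.sqrt(out["percent_density"].to_numpy()) + beta * x
    out["percent_density"] = np.clip(sqrt_pd, 0.0, _SQRT_PD_MAX) ** 2
    return validate_phenotypes(out)


def null_config(**overrides) -> SimulationConfig:
    """A convenience null configuration (no CNV effect, no regions)."""
    return SimulationConfig(**overrides)


def with_effect(config: SimulationConfig, gamma: float) -> SimulationConfig:
    """Copy of ``config`` with the per-copy phenotype effect set to ``gamma``."""
    return replace(config, pheno_coeffs=config.pheno_coeffs._replace(gamma_cnv=gamma))
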