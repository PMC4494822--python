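"""End-to-end orchestration: simulate/read → QC → scan → segment → permute → call.

A single :class:`PipelineConfig` carries every stage parameter, defaulting to
the method's standard constants (QC thresholds 0.35 / 0.0015 / 0.05 / 500;
candidate filter >= 3 probes with mean |t| > 1; 6× expansion; 10,000
permutations; discovery significance p < 1/10,000; replication significance
p < 0.05).  One global seed drives a per-stage seed sequence so any stage can
be re-run reproducibly.  Reruns with an identical config produce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import ModelSpec, ProbeStat, scan_probes, write_probe_stats
from .calling import CallingParams, CNVCall, call_region_copy_number, calls_table, carrier_association
from .permutation import (
    RegionResult,
    conditional_region_test,
    permute_region,
    region_results_table,
    select_top_snp,
)
from .qc import QCThresholds, apply_qc_exclusions, compute_qc_metrics, median_normalize_by_plate, passing_samples
from .segmentation import CBSParams, ExpandedRegion, Segment, expand_segment, identify_candidate_segments
from .simulate import Cohort, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    signals_dir: str | None = None
    probemap_path: str | None = None
    pheno_path: str | None = None
    geno_path: str | None = None

    qc_thresholds: QCThresholds = QCThresholds()
    model: ModelSpec = ModelSpec()
    cbs: CBSParams = CBSParams()
    perm_cbs: CBSParams = CBSParams(n_split_permutations=100)
    min_probes: int = 3
    min_mean_t: float = 1.0
    expansion: int = 6
    B: int = 10_000
    snp_significance: float = 0.05
    calling: CallingParams = CallingParams()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "cnv_regions" in sim:
                from .simulate import TrueRegion

                sim["cnv_regions"] = tuple(TrueRegion(**r) for r in sim["cnv_regions"])
            if "pheno_coeffs" in sim:
                from .simulate import PhenoCoeffs

                sim["pheno_coeffs"] = PhenoCoeffs(*sim["pheno_coeffs"])
            if "family_size_range" in sim:
                sim["family_size_range"] = tuple(sim["family_size_range"])
            kwargs["simulation"] = SimulationConfig(**sim)
        for key in ("signals_dir", "probemap_path", "pheno_path", "geno_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "qc_thresholds" in raw:
            kwargs["qc_thresholds"] = QCThresholds(**raw["qc_thresholds"])
        if "model" in raw:
            kwargs["model"] = ModelSpec(**raw["model"])
        for key in ("cbs", "perm_cbs"):
            if key in raw:
                kwargs[key] = CBSParams(**raw[key])
        for key in ("min_probes", "min_mean_t", "expansion", "B", "snp_significance", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = cls(**kwargs)
        defaults = cls()
        for key in ("qc_thresholds", "min_probes", "min_mean_t", "expansion", "B"):
            if getattr(cfg, key) != getattr(defaults, key):
                logger.info("config override: %s = %r", key, getattr(cfg, key))
        return cfg

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    qc_metrics: pd.DataFrame
    n_samples_in: int
    n_excluded: int
    probe_stats: pd.DataFrame
    segments: list[Segment]
    expanded: list[ExpandedRegion]
    region_results: list[RegionResult]
    conditional: dict[int, tuple[str, ProbeStat, RegionResult]] = field(default_factory=dict)
    calls: dict[str, list[CNVCall]] = field(default_factory=dict)
    carrier_stats: dict[str, ProbeStat] = field(default_factory=dict)
    recovery: pd.DataFrame | None = None
    report_text: str = ""

    @property
    def region_table(self) -> pd.DataFrame:
        return region_results_table(self.region_results, self.cohort.probe_map)


def _load_inputs(config: PipelineConfig) -> Cohort:
    if config.simulation is not None:
        return simulate_cohort(config.simulation)
    if not (config.signals_dir and config.probemap_path and config.pheno_path):
        raise PipelineError(
            "either a simulation block or signals_dir/probemap_path/pheno_path is required"
        )
    probe_map = cio.read_probe_map(config.probemap_path)
    phenotypes = cio.read_phenotypes(config.pheno_path)
    plates = dict(zip(phenotypes["sample_id"], phenotypes["plate_id"]))
    paths = sorted(Path(config.signals_dir).glob("*.signal.tsv"))
    panel = cio.read_signal_files(paths, probe_map, plates)
    genotypes = cio.read_genotypes(config.geno_path) if config.geno_path else None
    return Cohort(probe_map, panel, phenotypes, genotypes, truth=None)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order; any stage error aborts with its name."""
    ss = np.random.SeedSequence(config.seed)
    s_seg, s_perm, s_cond = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    stage = "input"
    try:
        cohort = _load_inputs(config)
        n_in = cohort.panel.n_samples

        stage = "normalization"
        panel = median_normalize_by_plate(cohort.panel)

        stage = "qc"
        metrics = apply_qc_exclusions(compute_qc_metrics(panel), config.qc_thresholds)
        keep = passing_samples(metrics)
        n_excluded = n_in - len(keep)
        panel = panel.subset_samples(keep)
        phenotypes = (
            cohort.phenotypes.set_index("sample_id").loc[keep].reset_index()
        )

        stage = "probe-association"
        probe_stats = scan_probes(panel, phenotypes, config.model)

        stage = "segmentation"
        track = np.abs(probe_stats["t"].to_numpy())
        segments = identify_candidate_segments(
            track,
            cohort.probe_map,
            params=config.cbs,
            min_probes=config.min_probes,
            min_mean_t=config.min_mean_t,
            seed=s_seg,
        )
        bounds = cohort.probe_map.chromosome_bounds()
        expanded = [
            expand_segment(seg, bounds[seg.chromosome], config.expansion)
            for seg in segments
        ]

        stage = "permutation"
        region_results = [
            permute_region(
                er,
                panel,
                phenotypes,
                spec=config.model,
                B=config.B,
                seed=s_perm + k,
                cbs_params=config.perm_cbs,
                min_probes=config.min_probes,
            )
            for k, er in enumerate(expanded)
        ]

        stage = "conditional"
        conditional: dict[int, tuple[str, ProbeStat, RegionResult]] = {}
        if cohort.genotypes is not None:
            for k, er in enumerate(expanded):
                try:
                    snp_id, snp_stat = select_top_snp(
                        cohort.genotypes, phenotypes, er, cohort.probe_map, config.model
                    )
                except Exception:
                    continue
                if snp_stat.p_value >= config.snp_significance:
                    continue
                geno = (
                    cohort.genotypes[snp_id]
                    .reindex(phenotypes["sample_id"])
                    .to_numpy(dtype=float)
                )
                adj = conditional_region_test(
                    er,
                    panel,
                    phenotypes,
                    geno,
                    spec=config.model,
                    B=config.B,
                    seed=s_cond + k,
                    cbs_params=config.perm_cbs,
                    min_probes=config.min_probes,
                )
                conditional[k] = (snp_id, snp_stat, adj)

        stage = "forced-calling"
        calls: dict[str, list[CNVCall]] = {}
        carrier_stats: dict[str, ProbeStat] = {}
        recovery = None
        if cohort.truth is not None and cohort.truth.regions:
            pos = cohort.probe_map.table["position"].to_numpy()
            cbounds = cohort.probe_map.chromosome_bounds()
            rec_rows = []
            for region in cohort.truth.regions:
                g0 = cbounds[region.chromosome][0]
                start_pos = int(pos[g0 + region.start_probe_index])
                end_pos = int(pos[g0 + region.end_probe_index - 1])
                call_list = call_region_copy_number(
                    panel, (region.chromosome, start_pos, end_pos), config.calling
                )
                calls[region.label] = call_list
                try:
                    carrier_stats[region.label] = carrier_association(
                        call_list, phenotypes, config.model
                    )
                except Exception as exc:
                    logger.info("carrier association skipped for %s: %s", region.label, exc)
                g_start = g0 + region.start_probe_index
                g_end = g0 + region.end_probe_index
                hit = any(
                    seg.chromosome == region.chromosome
                    and seg.start_idx < g_end
                    and seg.end_idx > g_start
                    for seg in segments
                )
                truth_cn = cohort.truth.copy_numbers[region.label].reindex(keep)
                called_cn = pd.Series(
                    {c.sample_id: c.copy_number for c in call_list}
                ).reindex(keep)
                ok = (called_cn == truth_cn).mean() if len(keep) else np.nan
                rec_rows.append(
                    dict(
                        region=region.label,
                        recovered_by_segmentation=hit,
                        call_accuracy=float(ok),
                    )
                )
            recovery = pd.DataFrame(rec_rows)
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        config=config,
        cohort=Cohort(cohort.probe_map, panel, phenotypes, cohort.genotypes, cohort.truth),
        qc_metrics=metrics,
        n_samples_in=n_in,
        n_excluded=n_excluded,
        probe_stats=probe_stats,
        segments=segments,
        expanded=expanded,
        region_results=region_results,
        conditional=conditional,
        calls=calls,
        carrier_stats=carrier_stats,
        recovery=recovery,
    )
    result.report_text = _render_report(result)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _render_report(res: PipelineResult) -> str:
    lines = [
        "cnvscan pipeline report",
        f"config hash: {res.config.config_hash()}",
        f"samples in: {res.n_samples_in}",
        f"samples excluded by QC: {res.n_excluded}",
        f"samples analyzed: {res.n_samples_in - res.n_excluded}",
        f"probes scanned: {len(res.probe_stats)}",
        f"candidate segments: {len(res.segments)}",
    ]
    tab = res.region_table
    if len(tab):
        lines.append("regions (chrom start end n_probes observed_stat p sig_discovery):")
        for _, r in tab.iterrows():
            lines.append(
                f"  {r.chromosome} {r.start_pos} {r.end_pos} {r.n_probes} "
                f"{r.observed_stat:.4f} {r.p:.6g} {bool(r.sig_discovery)}"
            )
    for k, (snp_id, snp_stat, adj) in sorted(res.conditional.items()):
        lines.append(
            f"conditional region {k}: top SNP {snp_id} (p={snp_stat.p_value:.3g}), "
            f"adjusted region p={adj.p_value:.6g}"
        )
    for label, stat in sorted(res.carrier_stats.items()):
        lines.append(
            f"carrier association {label}: beta={stat.coefficient:.4f} "
            f"se={stat.std_error:.4f} p={stat.p_value:.4g}"
        )
    if res.recovery is not None:
        for _, r in res.recovery.iterrows():
            lines.append(
                f"truth region {r.region}: segmentation recovered={bool(r.recovered_by_segmentation)} "
                f"call accuracy={r.call_accuracy:.4f}"
            )
    return "\n".join(lines) + "\n"


def write_outputs(res: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.qc_metrics.to_csv(outdir / "qc_metrics.tsv", sep="\t", index_label="sample_id")
    write_probe_stats(res.probe_stats, outdir / "probe_stats.tsv")
    tab = res.region_table
    tab.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    _write_bed(res, outdir / "regions.bed")
    if res.calls:
        pd.concat([calls_table(c) for c in res.calls.values()]).to_csv(
            outdir / "forced_calls.tsv", sep="\t", index=False
        )
    if res.recovery is not None:
        res.recovery.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(res.report_text)


def _write_bed(res: PipelineResult, path: Path) -> None:
    pos = res.cohort.probe_map.table["position"].to_numpy()
    with open(path, "w") as fh:
        for r in res.region_results:
            seg = r.region.segment
            # BED is 0-based half-open on genomic coordinates
            fh.write(
                f"{seg.chromosome}\t{int(pos[seg.start_idx]) - 1}\t"
                f"{int(pos[seg.end_idx - 1])}\tmean_abs_t={seg.mean_abs_t:.4f};"
                f"p={r.p_value:.6g}\n"
            )


def compare_cohorts(
    discovery: PipelineResult,
    replication: PipelineResult,
    B: int = 500,
    seed: int = 0,
    carrier_min: int = 2,
) -> pd.DataFrame:
    """Region-by-region concordance between a discovery and a replication run.

    Distinguishes replicating the CNV (forced calling in the replication
    panel finds carriers in the window) from replicating the association
    (the region's permutation p in the replication cohort is < 0.05).
    """
    ids_a = set(discovery.cohort.probe_map.table["probe_id"])
    ids_b = set(replication.cohort.probe_map.table["probe_id"])
    if not ids_a & ids_b:
        raise PipelineError("probe maps are disjoint; cohorts cannot be compared")
    pos_a = discovery.cohort.probe_map.table["position"].to_numpy()
    rep_map = replication.cohort.probe_map
    rep_bounds = rep_map.chromosome_bounds()
    rows = []
    for k, r in enumerate(discovery.region_results):
        seg = r.region.segment
        start_pos = int(pos_a[seg.start_idx])
        end_pos = int(pos_a[seg.end_idx - 1])
        idx = rep_map.probes_in_interval(seg.chromosome, start_pos, end_pos)
        present = False
        replicated = False
        if len(idx) >= 3:
            call_list = call_region_copy_number(
                replication.cohort.panel,
                (seg.chromosome, start_pos, end_pos),
                discovery.config.calling,
            )
            n_carriers = sum(
                1
                for c in call_list
                if c.copy_number is not None and c.copy_number != 2
            )
            present = n_carriers >= carrier_min
            rep_seg = Segment(
                chromosome=seg.chromosome,
                start_idx=int(idx[0]),
                end_idx=int(idx[-1]) + 1,
                mean_abs_t=0.0,
            )
            er = expand_segment(
                rep_seg, rep_bounds[seg.chromosome], discovery.config.expansion
            )
            rep_res = permute_region(
                er,
                replication.cohort.panel,
                replication.cohort.phenotypes,
                spec=ModelSpec(),  # replication cohorts use the ordinary model
                B=B,
                seed=seed + k,
                cbs_params=discovery.config.perm_cbs,
                min_probes=discovery.config.min_probes,
                observed_segment_stat="best",
            )
            replicated = rep_res.p_value < 0.05
        rows.append(
            dict(
                chromosome=seg.chromosome,
                start_pos=start_pos,
                end_pos=end_pos,
                discovery_p=r.p_value,
                cnv_present_in_replication=present,
                association_replicated=replicated,
            )
        )
    return pd.DataFrame(rows)
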