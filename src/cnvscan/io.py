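"""Containers and readers/writers for SNP-array signal data.

File dialects follow the prevailing array-signal export conventions:

* signal files — one tab-delimited file per sample with columns
  ``Name  Chr  Position  <sample>.Log R Ratio  <sample>.B Allele Freq``;
* probe map — TSV with ``probe_id  chromosome  position  is_snp``;
* phenotypes — CSV with ``sample_id, percent_density, age, bmi, menopausal,
  family_id, plate_id``;
* genotypes — TSV, samples as rows, SNP probe ids as columns, values 0/1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "sample_id",
    "percent_density",
    "age",
    "bmi",
    "menopausal",
    "family_id",
    "plate_id",
]


class SignalFormatError(ValueError):
    """Raised when a signal/probe-map/phenotype file violates its contract."""


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe coordinates with SNP/CNV-probe flags.

    Probes are kept in genome order: chromosomes form contiguous blocks and
    positions increase strictly within a chromosome.  All downstream matrices
    use this probe order for their columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chromosome", "position", "is_snp"}
        missing = required - set(self.table.columns)
        if missing:
            raise SignalFormatError(f"probe map missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise SignalFormatError("duplicate probe ids in probe map")
        if (self.table["position"] < 1).any():
            raise SignalFormatError("probe positions must be >= 1")
        chrom = self.table["chromosome"].to_numpy()
        # chromosome blocks must be contiguous
        change = np.nonzero(chrom[1:] != chrom[:-1])[0]
        seen = pd.unique(chrom)
        if len(change) + 1 != len(seen):
            raise SignalFormatError("chromosome blocks are not contiguous")
        pos = self.table["position"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise SignalFormatError("positions not strictly increasing within chromosome")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.table["chromosome"]))

    def chromosome_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open global index range occupied by each chromosome."""
        bounds: dict[str, tuple[int, int]] = {}
        grouped = self.table.groupby("chromosome", sort=False)
        for name, g in grouped:
            bounds[str(name)] = (int(g.index[0]), int(g.index[-1]) + 1)
        return bounds

    def probes_in_interval(self, chromosome: str, start_pos: int, end_pos: int) -> np.ndarray:
        """Global indices of probes with start_pos <= position <= end_pos."""
        t = self.table
        mask = (
            (t["chromosome"] == chromosome)
            & (t["position"] >= start_pos)
            & (t["position"] <= end_pos)
        )
        return np.nonzero(mask.to_numpy())[0]


@dataclass
class IntensityPanel:
    """Samples × probes LRR and BAF matrices with plate assignment.

    Missing measurements are NaN.  Row order matches ``sample_ids``, column
    order matches ``probe_map``.
    """

    sample_ids: list[str]
    plate_ids: list[str]
    lrr: np.ndarray
    baf: np.ndarray
    probe_map: ProbeMap = field(repr=False)

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), self.probe_map.n_probes
        if len(set(self.sample_ids)) != n:
            raise SignalFormatError("duplicate sample ids")
        if len(self.plate_ids) != n:
            raise SignalFormatError("plate_ids length mismatch")
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != (n, m) or self.baf.shape != (n, m):
            raise SignalFormatError(
                f"matrix shape mismatch: expected {(n, m)}, "
                f"got lrr {self.lrr.shape}, baf {self.baf.shape}"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.baf < 0) | (self.baf > 1))
        if bad:
            raise SignalFormatError("BAF values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset_samples(self, keep: Sequence[str]) -> "IntensityPanel":
        idx = [self.sample_index(s) for s in keep]
        return IntensityPanel(
            sample_ids=list(keep),
            plate_ids=[self.plate_ids[i] for i in idx],
            lrr=self.lrr[idx].copy(),
            baf=self.baf[idx].copy(),
            probe_map=self.probe_map,
        )

    def copy(self) -> "IntensityPanel":
        return IntensityPanel(
            sample_ids=list(self.sample_ids),
            plate_ids=list(self.plate_ids),
            lrr=self.lrr.copy(),
            baf=self.baf.copy(),
            probe_map=self.probe_map,
        )


# ---------------------------------------------------------------------------
# probe map / phenotype / genotype files


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    df["is_snp"] = df["is_snp"].astype(bool)
    return ProbeMap(df)


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise SignalFormatError(f"phenotype table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise SignalFormatError("duplicate sample ids in phenotype table")
    if (df["bmi"] <= 0).any():
        raise SignalFormatError("bmi must be positive")
    pdense = df["percent_density"]
    if ((pdense < 0) | (pdense > 100)).any():
        raise SignalFormatError("percent_density outside [0, 100]")
    return df.reset_index(drop=True)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "family_id": str, "plate_id": str})
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# per-sample signal files

_SIGNAL_FIXED = ["Name", "Chr", "Position"]


def signal_file_columns(sample_id: str) -> list[str]:
    return _SIGNAL_FIXED + [f"{sample_id}.Log R Ratio", f"{sample_id}.B Allele Freq"]


def write_signal_file(
    path: str | Path,
    probe_map: ProbeMap,
    sample_id: str,
    lrr: np.ndarray,
    baf: np.ndarray,
) -> None:
    df = pd.DataFrame(
        {
            "Name": probe_map.table["probe_id"],
            "Chr": probe_map.table["chromosome"],
            "Position": probe_map.table["position"],
            f"{sample_id}.Log R Ratio": lrr,
            f"{sample_id}.B Allele Freq": baf,
        }
    )
    # full float precision so a write-read round trip is lossless
    df.to_csv(path, sep="\t", index=False)


def _parse_signal_file(path: Path) -> tuple[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str}, float_precision="round_trip")
    lrr_cols = [c for c in df.columns if c.endswith(".Log R Ratio")]
    baf_cols = [c for c in df.columns if c.endswith(".B Allele Freq")]
    if len(lrr_cols) != 1 or len(baf_cols) != 1:
        raise SignalFormatError(f"{path}: expected one LRR and one BAF column")
    sample = lrr_cols[0][: -len(".Log R Ratio")]
    if baf_cols[0][: -len(".B Allele Freq")] != sample:
        raise SignalFormatError(f"{path}: LRR/BAF sample names disagree")
    if df["Name"].duplicated().any():
        dupes = df.loc[df["Name"].duplicated(), "Name"].iloc[0]
        raise SignalFormatError(f"{path}: duplicate probe {dupes!r}")
    out = df.rename(columns={lrr_cols[0]: "lrr", baf_cols[0]: "baf"})
    return sample, out[["Name", "lrr", "baf"]]


def read_signal_files(
    paths: Iterable[str | Path],
    probe_map: ProbeMap,
    plates: Mapping[str, str] | None = None,
) -> IntensityPanel:
    """Read per-sample signal files into a panel aligned to ``probe_map``.

    Probes absent from a file become NaN (count logged); a file covering fewer
    than half the probe map is rejected.  Plate assignment is taken from
    ``plates`` when given, else every sample lands on plate "P1".
    """
    probe_index = pd.Index(probe_map.table["probe_id"])
    sample_ids: list[str] = []
    lrr_rows: list[np.ndarray] = []
    baf_rows: list[np.ndarray] = []
    for p in paths:
        sample, df = _parse_signal_file(Path(p))
        aligned = df.set_index("Name").reindex(probe_index)
        n_present = aligned["lrr"].notna().sum() + 0  # unknown probes dropped by reindex
        known = df["Name"].isin(probe_index).sum()
        if known < 0.5 * len(probe_index):
            raise SignalFormatError(
                f"{p}: only {known}/{len(probe_index)} probes present (<50%)"
            )
        n_missing = len(probe_index) - known
        if n_missing:
            logger.info("%s: %d probes missing from file", p, n_missing)
        del n_present
        sample_ids.append(sample)
        lrr_rows.append(aligned["lrr"].to_numpy(dtype=float))
        baf_rows.append(aligned["baf"].to_numpy(dtype=float))
    plate_ids = [plates.get(s, "P1") if plates else "P1" for s in sample_ids]
    return IntensityPanel(
        sample_ids=sample_ids,
        plate_ids=plate_ids,
        lrr=np.vstack(lrr_rows) if lrr_rows else np.empty((0, probe_map.n_probes)),
        baf=np.vstack(baf_rows) if baf_rows else np.empty((0, probe_map.n_probes)),
        probe_map=probe_map,
    )


def write_panel(panel: IntensityPanel, outdir: str | Path) -> list[Path]:
    """Write one signal file per sample under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sample in enumerate(panel.sample_ids):
        path = outdir / f"{sample}.signal.tsv"
        write_signal_file(path, panel.probe_map, sample, panel.lrr[i], panel.baf[i])
        paths.append(path)
    return paths
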