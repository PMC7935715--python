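"""File formats and the in-memory count container.

Formats (all plain text):
  * manifest  — CSV, header
    ``sample_id,batch_id,bmi,karyotype,fetal_sex,protocol,true_ff,control_type``
  * counts    — TSV, BED3 (chrom, start, end; 0-based half-open) followed by
    one integer column per sample (wide format, human-inspectable)
  * regions   — BED4 (chrom, start, end, name)
  * results   — CSV, ``sample_id,region,depth_ratio,z_score,ff_positive,call``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

MANIFEST_COLUMNS = [
    "sample_id", "batch_id", "bmi", "karyotype", "fetal_sex",
    "protocol", "true_ff", "control_type",
]

VALID_CONTROL_TYPES = {"none", "ntc", "pooled_xx", "pooled_xy"}


class FormatError(ValueError):
    """An input file violates its declared format."""


@dataclass
class BinCounts:
    """Per-sample fragment counts per genome bin.

    ``total`` has shape (n_bins, n_samples).  For simulated data the
    compartment-resolved ``fetal``/``maternal`` matrices are retained
    (``fetal + maternal == total``); they never leave the simulation except
    through the explicitly-named sidecar files.
    """

    genome: GenomeModel
    sample_ids: list[str]
    total: np.ndarray
    fetal: np.ndarray | None = None
    maternal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total)
        if self.total.shape != (self.genome.n_bins, len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.total.shape} does not match "
                f"({self.genome.n_bins} bins, {len(self.sample_ids)} samples)"
            )
        if np.any(self.total < 0):
            raise FormatError("negative count")

    @property
    def has_compartments(self) -> bool:
        return self.fetal is not None and self.maternal is not None

    def column(self, sample_id: str) -> np.ndarray:
        return self.total[:, self.sample_ids.index(sample_id)]

    def depths(self) -> np.ndarray:
        """Total fragments per sample."""
        return self.total.sum(axis=0)

    def to_frame(self, which: str = "total") -> pd.DataFrame:
        mat = getattr(self, which)
        if mat is None:
            raise FormatError(f"no {which!r} counts available")
        coords = pd.DataFrame({
            "chrom": self.genome.bin_chrom,
            "start": self.genome.bin_start,
            "end": self.genome.bin_end,
        })
        samples = pd.DataFrame(mat, columns=self.sample_ids)
        return pd.concat([coords, samples], axis=1)


def write_bin_counts(counts: BinCounts, path: str | Path, which: str = "total") -> None:
    counts.to_frame(which).to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path, genome: GenomeModel) -> BinCounts:
    """Read a wide counts TSV, validating the bin set against the genome."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) != genome.n_bins:
        raise FormatError(
            f"{path}: {len(df)} bins, genome has {genome.n_bins}"
        )
    mismatch = (
        (df["chrom"].to_numpy() != genome.bin_chrom)
        | (df["start"].to_numpy() != genome.bin_start)
        | (df["end"].to_numpy() != genome.bin_end)
    )
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise FormatError(
            f"{path}: bin {i} is {df['chrom'][i]}:{df['start'][i]}-{df['end'][i]}, "
            f"expected {genome.bin_chrom[i]}:{genome.bin_start[i]}-{genome.bin_end[i]}"
        )
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end")]
    mat = df[sample_ids].to_numpy() if sample_ids else np.zeros((genome.n_bins, 0), dtype=np.int64)
    if sample_ids and not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat == np.floor(mat)):
            raise FormatError(f"{path}: non-integer count")
        mat = mat.astype(np.int64)
    if np.any(mat < 0):
        j, k = map(int, np.argwhere(mat < 0)[0])
        raise FormatError(f"{path}: negative count for sample {sample_ids[k]!r} in bin {j}")
    return BinCounts(genome=genome, sample_ids=sample_ids, total=mat)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str})
    if list(df.columns) != MANIFEST_COLUMNS:
        raise FormatError(
            f"{path}: header must be exactly {','.join(MANIFEST_COLUMNS)}"
        )
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(subset=["sample_id", "protocol"])
    if dup.any():
        sid = df.loc[dup, "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {sid!r} within a protocol arm")
    bmi = df["bmi"].dropna()
    if (bmi <= 0).any():
        raise FormatError("bmi must be > 0 where present")
    ff = df["true_ff"].dropna()
    if ((ff < 0) | (ff > 1)).any():
        raise FormatError("true_ff must lie in [0, 1] where present")
    ctl = df["control_type"].fillna("none")
    bad = ~ctl.isin(VALID_CONTROL_TYPES)
    if bad.any():
        raise FormatError(f"unknown control_type {ctl[bad].iloc[0]!r}")
    is_control = ctl != "none"
    if df.loc[is_control, "karyotype"].notna().any():
        raise FormatError("control rows must not carry a karyotype")
    return df


def write_regions_bed(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (chrom, start, end) in genome.regions.items():
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_regions_bed(path: str | Path) -> dict[str, tuple[str, int, int]]:
    regions: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected BED4")
            chrom, start, end, name = parts[:4]
            regions[name] = (chrom, int(start), int(end))
    return regions


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "region", "depth_ratio", "z_score", "ff_positive", "call"]
    results[cols].to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    return pd.read_csv(path, dtype={"sample_id": str})
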