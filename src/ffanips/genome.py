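"""Scaled genome model: chromosomes, fixed-width bins, and named regions.

The simulated genome is a 1/1000-scale replica of GRCh38 (per chromosome),
binned at a 50 kb-equivalent width.  Keeping the relative chromosome sizes
preserves the per-region count totals that drive z-score variance, while a
desk-scale fragment budget (1e5-1e7 fragments/sample) yields per-bin
statistics comparable to production sequencing depth.

All coordinates are 0-based half-open.  Trailing partial bins are dropped, so
the binned span of a chromosome is ``n_bins * bin_width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# GRCh38 primary-assembly chromosome lengths (bp).
GRCH38_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("chrX", "chrY")

# Default microdeletion panel: the five common syndromic microdeletions, at
# their approximate GRCh38 locations, sized 3-6 Mb (true scale).
DEFAULT_MICRODELETIONS = {
    "22q11.2": ("chr22", 18_900_000, 21_900_000),   # DiGeorge, ~3 Mb
    "5p15": ("chr5", 100_000, 6_100_000),           # cri du chat, ~6 Mb
    "1p36": ("chr1", 100_000, 5_500_000),
    "4p16.3": ("chr4", 100_000, 4_500_000),         # Wolf-Hirschhorn
    "15q11.2": ("chr15", 22_800_000, 28_200_000),   # Prader-Willi/Angelman
}


class GenomeConfigError(ValueError):
    """A region or bin specification is inconsistent with the genome."""


@dataclass(frozen=True)
class GenomeModel:
    """Binned genome with named regions.

    Attributes
    ----------
    chromosomes : list of (name, length) in scaled bp, fixed order.
    bin_width : scaled bp per bin.
    bins : (n_bins, 2) start/end array plus parallel ``bin_chrom`` labels.
    regions : name -> (chrom, start, end); ``region_bins`` maps each region
        to the indices of the bins fully contained in it.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int
    bin_chrom: np.ndarray = field(repr=False)
    bin_start: np.ndarray = field(repr=False)
    bin_end: np.ndarray = field(repr=False)
    regions: dict[str, tuple[str, int, int]] = field(repr=False)
    region_bins: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.bin_start.size

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.bin_chrom == chrom

    @property
    def autosomal_mask(self) -> np.ndarray:
        return ~np.isin(self.bin_chrom, ("chrX", "chrY"))

    def region_widths(self) -> dict[str, int]:
        return {name: idx.size * self.bin_width for name, idx in self.region_bins.items()}


def build_genome(
    scale: int = 1000,
    bin_width: int = 50,
    microdeletions: dict[str, tuple[str, int, int]] | None = None,
    extra_regions: dict[str, tuple[str, int, int]] | None = None,
) -> GenomeModel:
    """Construct the scaled, binned genome with the default region table.

    Parameters
    ----------
    scale : divisor applied to true chromosome lengths and region coordinates.
    bin_width : bin width in scaled bp (50 = 50 kb-equivalent at scale 1000).
    microdeletions : true-scale (chrom, start, end) map; defaults to the five
        common syndromic microdeletions.  A region's bin set is the bins
        fully contained in it; each region must retain at least one whole bin.
    extra_regions : additional true-scale named regions.

    The region table always contains one whole-chromosome region per
    chromosome (named after the chromosome) — chr13/18/21 for the common
    trisomies, the remaining autosomes for RAAs, and chrX/chrY for the sex
    karyotype analysis.
    """
    if scale < 1 or bin_width < 1:
        raise GenomeConfigError("scale and bin_width must be positive integers")

    chroms = tuple((name, GRCH38_LENGTHS[name] // scale) for name in CHROMOSOMES)
    starts, ends, labels = [], [], []
    for name, length in chroms:
        n = length // bin_width
        if n == 0:
            raise GenomeConfigError(f"{name}: no whole bin fits (length {length})")
        s = np.arange(n, dtype=np.int64) * bin_width
        starts.append(s)
        ends.append(s + bin_width)
        labels.append(np.full(n, name, dtype=object))
    bin_start = np.concatenate(starts)
    bin_end = np.concatenate(ends)
    bin_chrom = np.concatenate(labels)

    regions: dict[str, tuple[str, int, int]] = {}
    for name, length in chroms:
        regions[name] = (name, 0, (length // bin_width) * bin_width)

    named = dict(DEFAULT_MICRODELETIONS if microdeletions is None else microdeletions)
    if extra_regions:
        named.update(extra_regions)
    chrom_len = dict(chroms)
    for rname, (chrom, true_start, true_end) in named.items():
        if chrom not in chrom_len:
            raise GenomeConfigError(f"region {rname!r}: unknown chromosome {chrom!r}")
        start, end = true_start // scale, true_end // scale
        if start < 0 or end > chrom_len[chrom]:
            raise GenomeConfigError(
                f"region {rname!r} ({chrom}:{start}-{end}) outside chromosome "
                f"bounds [0, {chrom_len[chrom]})"
            )
        regions[rname] = (chrom, start, end)

    region_bins: dict[str, np.ndarray] = {}
    for rname, (chrom, start, end) in regions.items():
        on_chrom = bin_chrom == chrom
        inside = on_chrom & (bin_start >= start) & (bin_end <= end)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            raise GenomeConfigError(
                f"region {rname!r} ({chrom}:{start}-{end}) contains no whole bin "
                f"at bin width {bin_width}"
            )
        region_bins[rname] = idx

    return GenomeModel(
        chromosomes=chroms,
        bin_width=bin_width,
        bin_chrom=bin_chrom,
        bin_start=bin_start,
        bin_end=bin_end,
        regions=regions,
        region_bins=region_bins,
    )
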