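"""Genomic bin grids, gene catalog and binned read-count containers.

Everything downstream of alignment works on a fixed partition of the autosomes
into non-overlapping bins (500 kb for genome-wide copy-number inference, 50 kb
for focal-amplification detection).  :class:`BinGrid` is the shared coordinate
frame: an ordered set of 0-based half-open bins, each annotated with a GC
fraction and a mappability score used by the bias correction.

Only the 22 autosomes are modelled; instability metrics such as the weighted
genomic instability index are defined over autosomes and sex chromosomes are
excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HG19_AUTOSOMES",
    "HG19_CENTROMERES",
    "BinGrid",
    "BinCounts",
    "GeneAnnotation",
    "build_bin_grid",
    "driver_gene_catalog",
]

#: hg19 (GRCh37) autosome lengths in bp, chr1..chr22.
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
}

#: Approximate hg19 centromere midpoints (bp); used as p/q arm boundaries.
HG19_CENTROMERES: dict[str, int] = {
    "chr1": 125_000_000,
    "chr2": 93_300_000,
    "chr3": 91_000_000,
    "chr4": 50_400_000,
    "chr5": 48_400_000,
    "chr6": 61_000_000,
    "chr7": 59_900_000,
    "chr8": 45_600_000,
    "chr9": 49_000_000,
    "chr10": 40_200_000,
    "chr11": 53_700_000,
    "chr12": 35_800_000,
    "chr13": 17_900_000,
    "chr14": 17_600_000,
    "chr15": 19_000_000,
    "chr16": 36_600_000,
    "chr17": 24_000_000,
    "chr18": 17_200_000,
    "chr19": 26_500_000,
    "chr20": 27_500_000,
    "chr21": 13_200_000,
    "chr22": 14_700_000,
}

# Approximate hg19 loci of recurrently amplified/aberrant driver genes in
# oesophagogastric adenocarcinoma.  (symbol, chrom, start, end), 0-based
# half-open; coordinates are approximate gene footprints, adequate for
# overlap annotation at 50 kb resolution.
_DRIVER_GENES: list[tuple[str, str, int, int]] = [
    ("EGFR", "chr7", 55_086_725, 55_324_313),
    ("ERBB2", "chr17", 37_844_393, 37_884_915),
    ("KRAS", "chr12", 25_358_180, 25_403_854),
    ("MET", "chr7", 116_312_444, 116_438_440),
    ("MYC", "chr8", 128_748_315, 128_753_680),
    ("MAPK1", "chr22", 22_113_947, 22_221_970),
    ("CCND1", "chr11", 69_455_873, 69_469_242),
    ("GATA4", "chr8", 11_561_717, 11_617_509),
    ("CCNE1", "chr19", 30_302_805, 30_315_215),
    ("CDK6", "chr7", 92_234_235, 92_465_908),
    ("CDK4", "chr12", 58_141_510, 58_149_796),
    ("FGFR2", "chr10", 123_237_844, 123_357_972),
    ("VEGFA", "chr6", 43_737_946, 43_754_224),
    ("FBXW7", "chr4", 153_242_410, 153_457_253),
    ("MCPH1", "chr8", 6_264_113, 6_501_140),
    ("ERBB4", "chr2", 212_240_442, 213_403_352),
    ("PIK3CA", "chr3", 178_866_311, 178_952_497),
    ("CCND3", "chr6", 41_902_671, 42_018_254),
    ("FGFR1", "chr8", 38_268_656, 38_326_352),
    ("CDK12", "chr17", 37_617_739, 37_690_800),
]


class CoordinateMismatchError(ValueError):
    """Raised when records do not tile / match the declared bin grid."""


@dataclass
class BinGrid:
    """Fixed-width partition of a set of chromosomes into genomic bins.

    Bins are 0-based half-open, tile each chromosome without overlap in
    genome order, and the last bin of a chromosome may be shorter than
    ``bin_width``.  ``gc`` and ``mappability`` are per-bin annotations in
    [0, 1] consumed by the bias correction.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    bin_width: int
    chrom_index: np.ndarray  # int per bin, index into chrom_names
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.start)
        for name, arr in (
            ("chrom_index", self.chrom_index),
            ("end", self.end),
            ("gc", self.gc),
            ("mappability", self.mappability),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if np.any(~np.isfinite(self.gc)) or np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc fractions must be finite and in [0, 1]")
        if np.any(~np.isfinite(self.mappability)) or np.any(
            (self.mappability < 0) | (self.mappability > 1)
        ):
            raise ValueError("mappability must be finite and in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        """Bin lengths in bp."""
        return self.end - self.start

    @property
    def bin_chrom(self) -> np.ndarray:
        """Chromosome name per bin."""
        return np.asarray(self.chrom_names, dtype=object)[self.chrom_index]

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous slice of the bin arrays covered by each chromosome."""
        out: dict[str, slice] = {}
        for ci, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.chrom_index == ci)
            if idx.size:
                out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def same_frame(self, other: "BinGrid") -> bool:
        """True when two grids define identical bin coordinates."""
        return (
            self.chrom_names == other.chrom_names
            and self.bin_width == other.bin_width
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.array_equal(self.chrom_index, other.chrom_index)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bin_chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "mappability": self.mappability,
            }
        )

    def with_annotations(self, gc: np.ndarray, mappability: np.ndarray) -> "BinGrid":
        """Return a copy of the grid with new GC/mappability annotations."""
        return BinGrid(
            chrom_names=list(self.chrom_names),
            chrom_lengths=dict(self.chrom_lengths),
            bin_width=self.bin_width,
            chrom_index=self.chrom_index.copy(),
            start=self.start.copy(),
            end=self.end.copy(),
            gc=np.asarray(gc, dtype=float).copy(),
            mappability=np.asarray(mappability, dtype=float).copy(),
        )


def build_bin_grid(
    chrom_lengths: Mapping[str, int],
    bin_width: int,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
) -> BinGrid:
    """Partition chromosomes into non-overlapping fixed-width bins.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping chromosome name -> length in bp.  Iteration order
        defines genome order (conventionally chr1..chr22).
    bin_width
        Bin width in bp (500,000 genome-wide; 50,000 for focal calls).
    gc, mappability
        Optional per-bin annotations.  Default to 0.5 / 1.0 (unannotated).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if not chrom_lengths:
        raise ValueError("at least one chromosome is required")
    names = list(chrom_lengths)
    chrom_idx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    for ci, name in enumerate(names):
        length = int(chrom_lengths[name])
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {length}")
        pos = 0
        while pos < length:
            chrom_idx.append(ci)
            starts.append(pos)
            ends.append(min(pos + bin_width, length))
            pos += bin_width
    n = len(starts)
    if gc is None:
        gc = np.full(n, 0.5)
    if mappability is None:
        mappability = np.ones(n)
    return BinGrid(
        chrom_names=names,
        chrom_lengths={k: int(v) for k, v in chrom_lengths.items()},
        bin_width=int(bin_width),
        chrom_index=np.asarray(chrom_idx, dtype=np.int64),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        gc=np.asarray(gc, dtype=float),
        mappability=np.asarray(mappability, dtype=float),
    )


@dataclass
class BinCounts:
    """Read counts per bin for one sample."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class GeneAnnotation:
    """A catalog of gene intervals (symbol, chrom, start, end), half-open."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        if self.records["gene"].duplicated().any():
            dupes = self.records.loc[self.records["gene"].duplicated(), "gene"]
            raise ValueError(f"duplicate gene symbols: {sorted(set(dupes))}")
        if (self.records["end"] <= self.records["start"]).any():
            raise ValueError("gene intervals must satisfy start < end")

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Symbols of genes whose interval overlaps [start, end) on chrom."""
        recs = self.records
        hit = (recs["chrom"] == chrom) & (recs["start"] < end) & (recs["end"] > start)
        return recs.loc[hit, "gene"].tolist()


def driver_gene_catalog() -> GeneAnnotation:
    """Built-in catalog of ~20 OGA driver-gene loci (approximate hg19).

    Static fixture used to annotate focal amplification calls; no external
    annotation source is consulted.
    """
    df = pd.DataFrame(_DRIVER_GENES, columns=["gene", "chrom", "start", "end"])
    return GeneAnnotation(records=df)
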