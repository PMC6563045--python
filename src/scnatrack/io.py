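"""File formats: SEG segment files, bedGraph-like bin counts, metadata tables.

Coordinates are 0-based half-open in memory everywhere.  SEG files follow the
IGV convention (1-based inclusive) and are converted on write and read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bins import BinCounts, BinGrid, CoordinateMismatchError
from .profiles import SEGMENT_COLUMNS, SegmentProfile

__all__ = [
    "write_seg",
    "read_seg",
    "write_bin_counts",
    "read_bin_counts",
    "write_metadata",
    "read_metadata",
    "SegParseError",
]

SEG_HEADER = [
    "Sample",
    "Chromosome",
    "Start",
    "End",
    "Num_Probes",
    "Segment_Mean",
    "Copy_Number",
]


class SegParseError(ValueError):
    """Malformed SEG content; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def write_seg(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    """Write segment profiles to an IGV SEG file.

    Sample-level parameters (tumour fraction, ploidy, the model's
    normalisation ploidy, the zero-ctDNA flag and log-likelihood) go into
    ``#profile`` comment lines so that the file round-trips.
    """
    path = Path(path)
    with path.open("w") as fh:
        for p in profiles:
            fh.write(
                "#profile\t"
                f"sample={p.sample_id}\t"
                f"tumour_fraction={p.tumour_fraction:.6f}\t"
                f"ploidy={p.ploidy:.6f}\t"
                f"norm_ploidy={p.norm_ploidy:.6f}\t"
                f"zero_ctdna={int(p.zero_ctdna)}\t"
                f"loglik={p.loglik:.6f}\n"
            )
        fh.write("\t".join(SEG_HEADER) + "\n")
        for p in profiles:
            for rec in p.segments.itertuples(index=False):
                fh.write(
                    f"{p.sample_id}\t{rec.chrom}\t{rec.start + 1}\t{rec.end}\t"
                    f"{rec.n_bins}\t{rec.mean_log2:.6f}\t{rec.cn}\n"
                )


def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG file written by :func:`write_seg` back into profiles."""
    path = Path(path)
    meta: dict[str, dict] = {}
    order: list[str] = []
    rows: dict[str, list[dict]] = {}
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#profile"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split("\t")[1:] if "=" in kv
                )
                try:
                    sid = fields["sample"]
                    meta[sid] = {
                        "tumour_fraction": float(fields["tumour_fraction"]),
                        "ploidy": float(fields["ploidy"]),
                        "norm_ploidy": float(fields["norm_ploidy"]),
                        "zero_ctdna": bool(int(fields["zero_ctdna"])),
                        "loglik": float(fields["loglik"]),
                    }
                except (KeyError, ValueError) as exc:
                    raise SegParseError(f"bad #profile header: {exc}", lineno)
                order.append(sid)
                rows[sid] = []
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[: len(SEG_HEADER)] != SEG_HEADER:
                    raise SegParseError(
                        f"expected SEG column header, got {parts!r}", lineno
                    )
                header_seen = True
                continue
            if len(parts) != len(SEG_HEADER):
                raise SegParseError(
                    f"expected {len(SEG_HEADER)} columns, got {len(parts)}", lineno
                )
            try:
                sid = parts[0]
                rec = {
                    "chrom": parts[1],
                    "start": int(parts[2]) - 1,
                    "end": int(parts[3]),
                    "n_bins": int(parts[4]),
                    "mean_log2": float(parts[5]),
                    "cn": int(parts[6]),
                }
            except ValueError as exc:
                raise SegParseError(str(exc), lineno)
            if sid not in rows:
                order.append(sid)
                rows[sid] = []
                meta.setdefault(sid, {})
            rows[sid].append(rec)
    profiles = []
    for sid in order:
        m = meta.get(sid, {})
        seg = pd.DataFrame(rows[sid], columns=["chrom", "start", "end", "n_bins", "mean_log2", "cn"])
        profiles.append(
            SegmentProfile(
                sample_id=sid,
                tumour_fraction=m.get("tumour_fraction", float("nan")),
                ploidy=m.get("ploidy", float("nan")),
                norm_ploidy=m.get("norm_ploidy", float("nan")),
                segments=seg[SEGMENT_COLUMNS],
                loglik=m.get("loglik", float("nan")),
                zero_ctdna=m.get("zero_ctdna", False),
            )
        )
    return profiles


def write_bin_counts(counts: BinCounts, path: str | Path) -> None:
    """Write bin counts as 4-column tab-separated (chrom, start, end, count)."""
    df = pd.DataFrame(
        {
            "chrom": counts.grid.bin_chrom,
            "start": counts.grid.start,
            "end": counts.grid.end,
            "count": counts.counts,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bin_counts(path: str | Path, grid: BinGrid, sample_id: str | None = None) -> BinCounts:
    """Read a 4-column count file and align it to ``grid``.

    Rows may appear in any order but must cover exactly the grid's bins; the
    first bin that cannot be matched is reported.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "count"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "count": np.int64},
    )
    index = {
        (c, int(s)): i
        for i, (c, s) in enumerate(zip(grid.bin_chrom, grid.start))
    }
    counts = np.full(grid.n_bins, -1, dtype=np.int64)
    for rec in df.itertuples(index=False):
        key = (rec.chrom, int(rec.start))
        i = index.get(key)
        if i is None or int(grid.end[i]) != int(rec.end):
            raise CoordinateMismatchError(
                f"bin {rec.chrom}:{rec.start}-{rec.end} does not match the grid"
            )
        if counts[i] >= 0:
            raise CoordinateMismatchError(
                f"bin {rec.chrom}:{rec.start}-{rec.end} appears more than once"
            )
        counts[i] = rec.count
    if np.any(counts < 0):
        j = int(np.flatnonzero(counts < 0)[0])
        raise CoordinateMismatchError(
            f"grid bin {grid.bin_chrom[j]}:{grid.start[j]}-{grid.end[j]} "
            "missing from file"
        )
    return BinCounts(sample_id=sample_id or path.stem, grid=grid, counts=counts)


def write_grid(grid: BinGrid, path: str | Path) -> None:
    """Write a bin grid (with GC/mappability annotations) as TSV."""
    df = grid.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_grid(path: str | Path) -> BinGrid:
    """Read a grid TSV written by :func:`write_grid`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    names = list(dict.fromkeys(df["chrom"]))
    lengths = {c: int(df.loc[df["chrom"] == c, "end"].max()) for c in names}
    widths = (df["end"] - df["start"]).to_numpy()
    bin_width = int(np.max(widths))
    name_idx = {c: i for i, c in enumerate(names)}
    grid = BinGrid(
        chrom_names=names,
        chrom_lengths=lengths,
        bin_width=bin_width,
        chrom_index=df["chrom"].map(name_idx).to_numpy(dtype=np.int64),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy(dtype=float),
        mappability=df["mappability"].to_numpy(dtype=float),
    )
    return grid


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
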