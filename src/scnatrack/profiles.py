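"""Per-sample copy-number profile containers.

A :class:`SegmentProfile` is the central result of the genome-wide inference:
one sample's tumour fraction, ploidy and ordered integer copy-number segments.
It is what gets written to SEG files, what the instability metrics consume and
what the cohort-level analyses compare across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinGrid

__all__ = ["SegmentProfile", "segments_from_bin_cn"]

SEGMENT_COLUMNS = ["chrom", "start", "end", "cn", "mean_log2", "n_bins"]


@dataclass
class SegmentProfile:
    """Inferred copy-number profile of one sample.

    Parameters
    ----------
    sample_id : str
    tumour_fraction : float
        Estimated fraction of cfDNA derived from tumour cells ("ctDNA
        content").  Reported as 0 when ``zero_ctdna`` is set.
    ploidy : float
        Mean tumour copy number (length-weighted mean of the called integer
        copy numbers) — the quantity usually plotted as "ploidy".
    norm_ploidy : float
        The normalisation ploidy of the fitted mixture model (the copy number
        whose expected log2 ratio is zero); kept separately because
        median-centred ratios identify the modal rather than the mean copy
        number.  Needed to convert log2 ratios back to absolute copy number.
    segments : pandas.DataFrame
        Ordered segments with columns chrom, start, end, cn (integer),
        mean_log2, n_bins.  Segments partition the valid bins of each
        chromosome; adjacent segments on a chromosome differ in cn.
    loglik : float
        Log-likelihood of the selected model fit.
    zero_ctdna : bool
        True when no tumour-derived signal was detected; the profile is then
        flat at copy number 2.
    bin_cn : numpy.ndarray or None
        Optional per-bin integer copy number (-1 for masked bins), aligned to
        the grid the profile was fitted on.  Not serialised to SEG; excluded
        from equality.
    """

    sample_id: str
    tumour_fraction: float
    ploidy: float
    norm_ploidy: float
    segments: pd.DataFrame
    loglik: float = float("nan")
    zero_ctdna: bool = False
    bin_cn: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(SEGMENT_COLUMNS) - set(self.segments.columns)
        if missing:
            raise ValueError(f"segments missing columns: {sorted(missing)}")
        self.segments = self.segments.reset_index(drop=True)
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ValueError(f"segments on {chrom} are not sorted")
            if (sub["end"].values[:-1] > sub["start"].values[1:]).any():
                raise ValueError(f"segments on {chrom} overlap")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentProfile):
            return NotImplemented
        if self.sample_id != other.sample_id or self.zero_ctdna != other.zero_ctdna:
            return False
        for a, b in (
            (self.tumour_fraction, other.tumour_fraction),
            (self.ploidy, other.ploidy),
            (self.norm_ploidy, other.norm_ploidy),
        ):
            if round(a, 6) != round(b, 6):
                return False
        sa, sb = self.segments, other.segments
        if len(sa) != len(sb):
            return False
        if len(sa) == 0:
            return True
        return (
            sa["chrom"].tolist() == sb["chrom"].tolist()
            and sa["start"].tolist() == sb["start"].tolist()
            and sa["end"].tolist() == sb["end"].tolist()
            and sa["cn"].tolist() == sb["cn"].tolist()
            and sa["n_bins"].tolist() == sb["n_bins"].tolist()
            and np.allclose(
                np.round(sa["mean_log2"].astype(float), 6),
                np.round(sb["mean_log2"].astype(float), 6),
                equal_nan=True,
            )
        )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def merged_segments(self) -> pd.DataFrame:
        """Segments with adjacent equal-CN runs merged (per chromosome)."""
        rows = []
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            cur = None
            for rec in sub.itertuples(index=False):
                if cur is not None and rec.cn == cur["cn"]:
                    w_old = cur["n_bins"]
                    cur["mean_log2"] = (
                        cur["mean_log2"] * w_old + rec.mean_log2 * rec.n_bins
                    ) / (w_old + rec.n_bins)
                    cur["end"] = rec.end
                    cur["n_bins"] = w_old + rec.n_bins
                else:
                    if cur is not None:
                        rows.append(cur)
                    cur = {
                        "chrom": chrom,
                        "start": rec.start,
                        "end": rec.end,
                        "cn": rec.cn,
                        "mean_log2": rec.mean_log2,
                        "n_bins": rec.n_bins,
                    }
            if cur is not None:
                rows.append(cur)
        return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)

    def bin_copy_number(self, grid: BinGrid) -> np.ndarray:
        """Per-bin integer copy number on ``grid`` (-1 outside any segment).

        Uses the stored per-bin path when available, otherwise paints the
        segments onto the grid.
        """
        if self.bin_cn is not None and len(self.bin_cn) == grid.n_bins:
            return np.asarray(self.bin_cn)
        cn = np.full(grid.n_bins, -1, dtype=np.int64)
        chrom = grid.bin_chrom
        for rec in self.segments.itertuples(index=False):
            sel = (chrom == rec.chrom) & (grid.start < rec.end) & (grid.end > rec.start)
            cn[sel] = int(rec.cn)
        return cn


def segments_from_bin_cn(
    grid: BinGrid,
    bin_cn: np.ndarray,
    log2_ratio: np.ndarray | None = None,
) -> pd.DataFrame:
    """Merge a per-bin copy-number path into segments.

    Masked bins (cn < 0) are skipped; a segment spans from the first to the
    last valid bin of a constant-CN run, including any masked interior bins.
    """
    bin_cn = np.asarray(bin_cn)
    if log2_ratio is None:
        log2_ratio = np.full(grid.n_bins, np.nan)
    rows = []
    for ci, chrom in enumerate(grid.chrom_names):
        idx = np.flatnonzero((grid.chrom_index == ci) & (bin_cn >= 0))
        if idx.size == 0:
            continue
        run_start = 0
        for k in range(1, idx.size + 1):
            if k == idx.size or bin_cn[idx[k]] != bin_cn[idx[run_start]]:
                sel = idx[run_start:k]
                vals = np.asarray(log2_ratio)[sel]
                mean_l2 = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(grid.start[sel[0]]),
                        "end": int(grid.end[sel[-1]]),
                        "cn": int(bin_cn[sel[0]]),
                        "mean_log2": mean_l2,
                        "n_bins": int(sel.size),
                    }
                )
                run_start = k
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
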