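"""Plotting helpers for profiles, frequency tracks and survival curves."""

from __future__ import annotations

import numpy as np

from .cohort import FrequencyTrack, KmLogrankResult
from .normalize import NormalizedRatios
from .profiles import SegmentProfile

__all__ = ["plot_profile", "plot_frequency_track", "plot_km"]


def _genome_offsets(grid) -> tuple[dict[str, float], float]:
    offsets = {}
    pos = 0.0
    for name in grid.chrom_names:
        offsets[name] = pos
        pos += grid.chrom_lengths[name]
    return offsets, pos


def plot_profile(ratios: NormalizedRatios, profile: SegmentProfile, ax=None):
    """Genome-wide log2 ratios with the called segments overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3.5))
    grid = ratios.grid
    offsets, total = _genome_offsets(grid)
    x = np.array([offsets[c] for c in grid.bin_chrom]) + (grid.start + grid.end) / 2
    ax.scatter(x[ratios.valid], ratios.log2_ratio[ratios.valid], s=2, c="0.6", rasterized=True)
    for rec in profile.segments.itertuples(index=False):
        off = offsets[rec.chrom]
        color = "firebrick" if rec.cn > 2 else ("steelblue" if rec.cn < 2 else "black")
        ax.plot([off + rec.start, off + rec.end], [rec.mean_log2] * 2, color=color, lw=2)
    for name in grid.chrom_names[1:]:
        ax.axvline(offsets[name], color="0.85", lw=0.5)
    ax.set_xlim(0, total)
    ax.set_ylabel("log2 ratio")
    ax.set_title(
        f"{profile.sample_id}  f={profile.tumour_fraction:.2f}  "
        f"ploidy={profile.ploidy:.2f}"
    )
    return ax


def plot_frequency_track(track: FrequencyTrack, ax=None, title: str = ""):
    """Gain (up, red) and loss (down, blue) carrier counts per segment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 2.5))
    seg = track.segments
    chroms = list(dict.fromkeys(seg["chrom"]))
    offsets = {}
    pos = 0.0
    for c in chroms:
        offsets[c] = pos
        pos += float(seg.loc[seg["chrom"] == c, "end"].max())
    for i, rec in enumerate(seg.itertuples(index=False)):
        off = offsets[rec.chrom]
        ax.fill_between(
            [off + rec.start, off + rec.end], 0, track.gains[i], color="firebrick", lw=0
        )
        ax.fill_between(
            [off + rec.start, off + rec.end], 0, -track.losses[i], color="steelblue", lw=0
        )
    ax.axhline(0, color="black", lw=0.5)
    ax.set_ylabel("cases")
    ax.set_ylim(-track.group_size, track.group_size)
    if title:
        ax.set_title(title)
    return ax


def plot_km(result: KmLogrankResult, ax=None):
    """Kaplan-Meier curves with the log-rank p-values in the title."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for g in result.group_order:
        curve = result.curves[g]
        ax.step(curve["time"], curve["survival"], where="post", label=str(g))
    ax.set_xlabel("months")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(
        f"log-rank p={result.p_value:.3f} (trend p={result.trend_p_value:.3f})"
    )
    return ax
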