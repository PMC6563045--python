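"""Cohort-level and longitudinal copy-number statistics.

Group comparisons work on a common segment grid (the union of all samples'
segment boundaries): per-segment gain/loss calls relative to each sample's
own rounded ploidy, gain/loss frequency tracks per clinical group, regions
aberrant in one group and absent in the other, and the minimal consistent
region shared by all carriers of an aberration.  Longitudinal analysis
subtracts the pretreatment absolute copy number from the matched progression
sample; only pairs with tumour fraction above 10% at both timepoints and
similar tumour content are eligible, and a bin counts as changed only when
the absolute copy number difference exceeds 0.8 (strictly), enriching for
new aneuploidies in the dominant cell population.  Hypothesis tests are the
Mann-Whitney U (exact for small samples) and the log-rank test (k-group and
ordered-tertile trend).  No multiple-testing correction is applied; p-values
are reported raw.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinGrid, CoordinateMismatchError
from .hmm import absolute_copy_number, uniform_resegment
from .metrics import ploidy_reference
from .normalize import NormalizedRatios
from .profiles import SegmentProfile

__all__ = [
    "AberrationMatrix",
    "FrequencyTrack",
    "PairedChange",
    "PairedChangeConfig",
    "BinFrequencyTrack",
    "KmLogrankResult",
    "aberration_matrix",
    "group_frequency",
    "unique_regions",
    "minimal_consistent_region",
    "mann_whitney",
    "km_logrank",
    "paired_change",
    "change_recurrence",
]


# ---------------------------------------------------------------------- #
# aberration matrix and frequency tracks


@dataclass
class AberrationMatrix:
    """Per-sample, per-common-segment calls: -1 loss, 0 neutral, +1 gain.

    Calls are relative to each sample's own rounded ploidy; NaN marks
    segments without coverage for a sample.
    """

    segments: pd.DataFrame  # chrom, start, end, length
    calls: pd.DataFrame  # index sample_id, one column per segment

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)


@dataclass
class FrequencyTrack:
    """Per-segment gain/loss carrier counts for a named group."""

    segments: pd.DataFrame
    gains: np.ndarray
    losses: np.ndarray
    group_size: int

    def __post_init__(self) -> None:
        if np.any(self.gains > self.group_size) or np.any(self.losses > self.group_size):
            raise ValueError("carrier counts cannot exceed the group size")


def aberration_matrix(profiles: Sequence[SegmentProfile]) -> AberrationMatrix:
    """Ploidy-relative gain/loss calls on the common segment grid.

    Zero-ctDNA profiles are excluded (with a warning): their flat profiles
    carry no tumour signal.  A segment is a gain when its copy number exceeds
    the sample's rounded ploidy by at least 1, a loss when it is at least 1
    below.
    """
    usable = [p for p in profiles if not p.zero_ctdna]
    dropped = len(profiles) - len(usable)
    if dropped:
        warnings.warn(f"excluding {dropped} zero-ctDNA profile(s) from the matrix")
    if not usable:
        raise ValueError("no usable (non-zero-ctDNA) profiles")
    segments, cn = uniform_resegment(usable)
    refs = {p.sample_id: ploidy_reference(p.ploidy) for p in usable}
    calls = cn.copy()
    for sid in calls.index:
        diff = cn.loc[sid] - refs[sid]
        calls.loc[sid] = np.sign(diff).where(diff.abs() >= 1, 0.0)
    return AberrationMatrix(segments=segments, calls=calls)


def group_frequency(
    matrix: AberrationMatrix, members: Sequence[str] | Sequence[bool]
) -> FrequencyTrack:
    """Per-segment counts of group members carrying a gain / a loss."""
    if len(members) and isinstance(members[0], (bool, np.bool_)):
        ids = [sid for sid, m in zip(matrix.sample_ids, members) if m]
    else:
        ids = list(members)
    if not ids:
        raise ValueError("empty group")
    sub = matrix.calls.loc[ids]
    gains = (sub == 1).sum(axis=0).to_numpy()
    losses = (sub == -1).sum(axis=0).to_numpy()
    return FrequencyTrack(
        segments=matrix.segments, gains=gains, losses=losses, group_size=len(ids)
    )


def unique_regions(
    track_a: FrequencyTrack,
    track_b: FrequencyTrack,
    min_carriers: int = 1,
    min_length: int = 1_000_000,
    frequent_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Regions aberrant in group A and never aberrant (same direction) in B.

    Maximal runs of common segments (per chromosome and direction) where the
    group-A carrier count is >= ``min_carriers`` and the group-B count is 0,
    filtered to runs of at least ``min_length`` bp; each region reports its
    maximum carrier count and whether the carrier fraction exceeds
    ``frequent_fraction`` of group A.
    """
    seg_a, seg_b = track_a.segments, track_b.segments
    if not seg_a[["chrom", "start", "end"]].equals(seg_b[["chrom", "start", "end"]]):
        raise CoordinateMismatchError("tracks are not on the same segment grid")
    rows = []
    for direction, a_cnt, b_cnt in (
        ("gain", track_a.gains, track_b.gains),
        ("loss", track_a.losses, track_b.losses),
    ):
        cond = (a_cnt >= min_carriers) & (b_cnt == 0)
        for chrom, sub in seg_a.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            run: list[int] = []
            for pos, i in enumerate(idx):
                if cond[i]:
                    run.append(i)
                adjacent_next = (
                    pos + 1 < len(idx)
                    and cond[idx[pos + 1]]
                    and seg_a.loc[idx[pos + 1], "start"] == seg_a.loc[i, "end"]
                )
                if run and not (cond[i] and adjacent_next):
                    start = int(seg_a.loc[run[0], "start"])
                    end = int(seg_a.loc[run[-1], "end"])
                    carriers = int(max(a_cnt[j] for j in run))
                    if end - start >= min_length:
                        rows.append(
                            {
                                "chrom": chrom,
                                "start": start,
                                "end": end,
                                "direction": direction,
                                "carrier_count": carriers,
                                "frequent": carriers / track_a.group_size
                                > frequent_fraction,
                            }
                        )
                    run = []
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "carrier_count", "frequent"]
    )


def minimal_consistent_region(
    matrix: AberrationMatrix,
    region: tuple[str, int, int],
    direction: str,
) -> tuple[str, int, int, int] | None:
    """Core interval shared by all contributing carriers of an aberration.

    Within ``region`` = (chrom, start, end), the leftmost maximal contiguous
    run of common segments whose carrier count equals the maximum carrier
    count in the region.  Returns (chrom, start, end, carrier_count), or
    None when the region has no carriers.
    """
    chrom, start, end = region
    sign = {"gain": 1, "loss": -1}[direction]
    seg = matrix.segments
    sel = (seg["chrom"] == chrom) & (seg["start"] < end) & (seg["end"] > start)
    idx = seg.index[sel].to_numpy()
    if idx.size == 0:
        return None
    counts = (matrix.calls[idx] == sign).sum(axis=0).to_numpy()
    cmax = int(counts.max()) if counts.size else 0
    if cmax == 0:
        return None
    # maximal contiguous runs of segments at the maximum carrier count;
    # contiguity requires bp adjacency of consecutive common segments
    runs: list[tuple[int, int]] = []
    start_k = None
    for k in range(idx.size):
        adjacent = (
            k > 0 and seg.loc[idx[k], "start"] == seg.loc[idx[k - 1], "end"]
        )
        if counts[k] == cmax:
            if start_k is None or not adjacent:
                if start_k is not None:
                    runs.append((start_k, k))
                start_k = k
        elif start_k is not None:
            runs.append((start_k, k))
            start_k = None
    if start_k is not None:
        runs.append((start_k, idx.size))
    lo, hi = runs[0]  # leftmost maximal run
    return (
        chrom,
        int(seg.loc[idx[lo], "start"]),
        int(seg.loc[idx[hi - 1], "end"]),
        int(cmax),
    )


# ---------------------------------------------------------------------- #
# hypothesis tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2)


def _exact_p_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group labelings (tie-aware)."""
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    mu = nx * ny / 2
    u_obs = _u_statistic(x, y)
    dev = abs(u_obs - mu)
    hits = total = 0
    offset = nx * (nx + 1) / 2
    for comb in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def exact_u_distribution(nx: int, ny: int) -> np.ndarray:
    """Counts of labelings per U value for tie-free samples (recursion).

    ``out[u]`` is the number of ways to realise U = u; used as the exact
    reference for the large-sample approximation.
    """
    # c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)
    table = np.zeros((nx + 1, ny + 1, nx * ny + 1), dtype=np.float64)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for n in range(1, nx + 1):
        for m in range(1, ny + 1):
            for u in range(n * m + 1):
                val = table[n, m - 1, u]
                if u - m >= 0:
                    val += table[n - 1, m, u - m]
                table[n, m, u] = val
    return table[nx, ny]


def exact_p_no_ties(u_obs: float, nx: int, ny: int) -> float:
    """Two-sided exact p for tie-free data at any sample size."""
    dist = exact_u_distribution(nx, ny)
    mu = nx * ny / 2
    dev = abs(u_obs - mu)
    us = np.arange(dist.size)
    return float(dist[np.abs(us - mu) >= dev - 1e-9].sum() / dist.sum())


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact p by enumeration of all labelings when the combined sample size is
    at most 12 (handles ties by midranks); otherwise the normal
    approximation with tie and continuity correction.  Returns (U, p) with U
    the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    if len(x) + len(y) <= 12:
        return u, _exact_p_enumeration(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class KmLogrankResult:
    """Kaplan-Meier curves plus k-group and trend log-rank statistics."""

    curves: dict[str, pd.DataFrame]
    statistic: float
    df: int
    p_value: float
    trend_statistic: float
    trend_p_value: float
    group_order: list[str]


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    group_order: Sequence[str] | None = None,
) -> KmLogrankResult:
    """Product-limit survival curves and log-rank tests across groups.

    The k-group statistic is the usual observed-vs-expected chi-square with
    k-1 degrees of freedom.  For ordered groups (e.g. low/medium/high
    tertiles) the trend statistic weights groups by their rank scores
    (1 df).  Kaplan-Meier curves come from lifelines.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be coded 0/1")
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    else:
        group_order = list(group_order)
    k = len(group_order)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in group_order:
        if not np.any(groups == g):
            raise ValueError(f"group {g!r} is empty")
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined: no events in any group")

    curves = {}
    for g in group_order:
        sel = groups == g
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[sel], events[sel])
        curves[g] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(g): "survival"}
        )

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = int(np.sum((times == t) & (events == 1)))
        if n == 0 or d == 0:
            continue
        n_g = np.array([np.sum(at_risk & (groups == g)) for g in group_order], dtype=float)
        d_g = np.array(
            [np.sum((times == t) & (events == 1) & (groups == g)) for g in group_order],
            dtype=float,
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p_g = n_g / n
            V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    diff = O - E
    sub = slice(0, k - 1)
    V_sub = V[sub, sub]
    try:
        chi2 = float(diff[sub] @ np.linalg.solve(V_sub, diff[sub]))
    except np.linalg.LinAlgError:
        chi2 = float(diff[sub] @ np.linalg.pinv(V_sub) @ diff[sub])
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    scores = np.arange(k, dtype=float)
    denom = float(scores @ V @ scores)
    if denom > 0:
        trend = float((scores @ diff) ** 2 / denom)
    else:
        trend = 0.0
    trend_p = float(stats.chi2.sf(trend, 1))
    return KmLogrankResult(
        curves=curves,
        statistic=chi2,
        df=k - 1,
        p_value=p,
        trend_statistic=trend,
        trend_p_value=trend_p,
        group_order=group_order,
    )


# ---------------------------------------------------------------------- #
# paired pretreatment / progression differencing


@dataclass
class PairedChangeConfig:
    delta_threshold: float = 0.8
    f_min: float = 0.10
    similarity_ratio: float = 2.5
    ploidy_centred: bool = False


@dataclass
class PairedChange:
    """Per-bin copy-number differences of one matched sample pair."""

    patient_id: str
    sample_pre: str
    sample_prog: str
    eligible: bool
    reason: str = ""
    delta_cn: np.ndarray | None = field(default=None, repr=False)
    changed: np.ndarray | None = field(default=None, repr=False)
    joint_valid: np.ndarray | None = field(default=None, repr=False)
    percent_genome_changed: float | None = None


def _segment_painted_log2(
    profile: SegmentProfile, grid: BinGrid, fallback: np.ndarray
) -> np.ndarray:
    """Per-bin log2 ratios smoothed to segment means (caller's segmentation).

    Bins covered by a segment with a finite mean ratio take that mean; other
    bins keep their raw value.
    """
    out = np.array(fallback, dtype=float, copy=True)
    chrom = grid.bin_chrom
    for rec in profile.segments.itertuples(index=False):
        if np.isfinite(rec.mean_log2):
            sel = (chrom == rec.chrom) & (grid.start >= rec.start) & (grid.end <= rec.end)
            out[sel] = rec.mean_log2
    return out


def paired_change(
    profile_pre: SegmentProfile,
    profile_prog: SegmentProfile,
    ratios_pre: NormalizedRatios,
    ratios_prog: NormalizedRatios,
    config: PairedChangeConfig | None = None,
    patient_id: str = "",
) -> PairedChange:
    """Absolute-copy-number difference between matched timepoints.

    A pair is eligible only when the tumour fraction exceeds ``f_min``
    (strictly) at both timepoints and the two fractions are similar
    (max/min <= ``similarity_ratio``), avoiding artefacts from differences
    in tumour content.  Each sample's continuous absolute copy number is
    computed from its own *segmented* log2 ratios (each bin takes its
    segment's mean ratio, i.e. the caller's segmented output; bins without a
    finite segment mean fall back to their raw ratio) and the sample's own
    fitted parameters.  A bin changes when |delta| strictly exceeds
    ``delta_threshold``.
    """
    config = config or PairedChangeConfig()
    if not ratios_pre.grid.same_frame(ratios_prog.grid):
        raise CoordinateMismatchError("pre and progression samples use different grids")
    pc = PairedChange(
        patient_id=patient_id,
        sample_pre=profile_pre.sample_id,
        sample_prog=profile_prog.sample_id,
        eligible=False,
    )
    f1, f2 = profile_pre.tumour_fraction, profile_prog.tumour_fraction
    if f1 <= config.f_min or f2 <= config.f_min:
        pc.reason = f"tumour fraction <= {config.f_min:g} at one or both timepoints"
        return pc
    ratio = max(f1, f2) / min(f1, f2)
    if ratio > config.similarity_ratio:
        pc.reason = (
            f"tumour fractions dissimilar (ratio {ratio:.2f} > "
            f"{config.similarity_ratio:g})"
        )
        return pc
    grid = ratios_pre.grid
    joint = ratios_pre.valid & ratios_prog.valid
    log2_pre = _segment_painted_log2(profile_pre, grid, ratios_pre.log2_ratio)
    log2_prog = _segment_painted_log2(profile_prog, grid, ratios_prog.log2_ratio)
    cn_pre = np.full(grid.n_bins, np.nan)
    cn_prog = np.full(grid.n_bins, np.nan)
    cn_pre[joint] = absolute_copy_number(log2_pre[joint], f1, profile_pre.norm_ploidy)
    cn_prog[joint] = absolute_copy_number(
        log2_prog[joint], f2, profile_prog.norm_ploidy
    )
    if config.ploidy_centred:
        cn_pre -= profile_pre.ploidy
        cn_prog -= profile_prog.ploidy
    delta = cn_prog - cn_pre
    changed = np.where(joint, np.abs(delta) > config.delta_threshold, False)
    lengths = grid.lengths.astype(float)
    total = lengths[joint].sum()
    pc.eligible = True
    pc.delta_cn = delta
    pc.changed = changed
    pc.joint_valid = joint
    pc.percent_genome_changed = float(100.0 * lengths[changed].sum() / total)
    return pc


@dataclass
class BinFrequencyTrack:
    """Per-bin counts of pairs gaining / losing at progression."""

    grid: BinGrid
    gains: np.ndarray
    losses: np.ndarray
    n_pairs: int


def change_recurrence(
    changes: Sequence[PairedChange],
    grid: BinGrid,
    delta_threshold: float = 0.8,
) -> BinFrequencyTrack:
    """Count, per bin, how many eligible pairs gained or lost at progression."""
    eligible = [c for c in changes if c.eligible]
    gains = np.zeros(grid.n_bins, dtype=int)
    losses = np.zeros(grid.n_bins, dtype=int)
    if not eligible:
        warnings.warn("no eligible pairs; change recurrence track is empty")
        return BinFrequencyTrack(grid=grid, gains=gains, losses=losses, n_pairs=0)
    for c in eligible:
        d = np.where(c.joint_valid, c.delta_cn, 0.0)
        gains += (d > delta_threshold).astype(int)
        losses += (d < -delta_threshold).astype(int)
    return BinFrequencyTrack(grid=grid, gains=gains, losses=losses, n_pairs=len(eligible))
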