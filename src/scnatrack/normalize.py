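"""GC-content and mappability bias correction of binned read counts.

Low-coverage WGS depth per bin is biased by the bin's GC fraction (library
prep and sequencing chemistry favour mid-GC fragments) and by how uniquely
reads map there.  The correction here follows standard read-depth practice:
fit a smooth curve of count rate versus GC by local (lowess) regression,
divide it out together with the mappability score, and express each bin as a
log2 ratio against the sample's own median corrected depth.

The reference is the sample's own valid-bin median; a panel-of-normals hook
(`reference_rates`) is exposed but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .bins import BinCounts, BinGrid

__all__ = ["BiasCurve", "NormalizedRatios", "fit_gc_bias", "correct_counts"]

DEFAULT_MAPPABILITY_MIN = 0.9
MIN_VALID_BINS = 50
#: lowess is O(n^2); the curve is fitted on at most this many bins,
#: deterministically subsampled.
MAX_LOWESS_POINTS = 5000


class InsufficientDataError(ValueError):
    """Too few valid bins to normalise."""


@dataclass
class BiasCurve:
    """Smooth relative-rate curve over GC fraction, normalised to mean 1.

    Evaluated by linear interpolation between lowess knots; constant beyond
    the observed GC range; floored at a small positive value so corrected
    counts stay finite.
    """

    gc_knots: np.ndarray
    rate_knots: np.ndarray

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        vals = np.interp(np.asarray(gc, dtype=float), self.gc_knots, self.rate_knots)
        return np.maximum(vals, 1e-3)


def fit_gc_bias(
    counts: BinCounts,
    grid: BinGrid | None = None,
    span: float = 0.3,
    mappability_min: float = DEFAULT_MAPPABILITY_MIN,
) -> BiasCurve:
    """Fit the GC bias curve on count-per-unit-length versus GC fraction.

    Parameters
    ----------
    counts
        Raw bin counts.
    grid
        Bin grid (defaults to ``counts.grid``).
    span
        lowess fraction of points used per local fit.  The default was set by
        requiring the no-bias recovery property (flat simulated bias is
        refitted within a few percent of 1 across the central GC range).
    mappability_min
        Bins below this mappability are excluded from the fit.
    """
    grid = grid or counts.grid
    lengths = grid.lengths.astype(float)
    valid = (lengths > 0) & (grid.mappability >= mappability_min) & (counts.counts > 0)
    if valid.sum() < MIN_VALID_BINS:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid bins (< {MIN_VALID_BINS}) for GC fit"
        )
    gc = grid.gc[valid]
    rate = counts.counts[valid] / lengths[valid] / grid.mappability[valid]
    if np.ptp(gc) < 1e-9:
        warnings.warn("degenerate GC annotation (all equal); returning flat bias curve")
        return BiasCurve(gc_knots=np.array([0.0, 1.0]), rate_knots=np.array([1.0, 1.0]))
    if gc.size > MAX_LOWESS_POINTS:
        # deterministic thinning: evenly spaced ranks of the GC ordering keep
        # the full GC range represented
        order = np.argsort(gc, kind="stable")
        pick = order[np.linspace(0, gc.size - 1, MAX_LOWESS_POINTS).astype(int)]
        gc, rate = gc[pick], rate[pick]
    smoothed = lowess(rate, gc, frac=span, it=2, return_sorted=True)
    gc_knots, rate_knots = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate knots so np.interp sees strictly increasing x
    gc_knots, first = np.unique(gc_knots, return_index=True)
    rate_knots = rate_knots[first]
    rate_knots = np.maximum(rate_knots, 1e-12)
    # normalise so the curve has mean 1 over the bins used in the fit
    mean_rate = float(np.mean(np.interp(gc, gc_knots, rate_knots)))
    return BiasCurve(gc_knots=gc_knots, rate_knots=rate_knots / mean_rate)


@dataclass
class NormalizedRatios:
    """Median-centred log2 depth ratios for one sample.

    ``log2_ratio`` is NaN at masked bins; ``valid`` marks bins that enter all
    downstream likelihoods and length sums.  ``reference_median`` is the
    corrected-count scale the ratios are relative to.
    """

    sample_id: str
    grid: BinGrid
    log2_ratio: np.ndarray
    valid: np.ndarray
    reference_median: float

    def __post_init__(self) -> None:
        if len(self.log2_ratio) != self.grid.n_bins or len(self.valid) != self.grid.n_bins:
            raise ValueError("ratio arrays must match the grid")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def correct_counts(
    counts: BinCounts,
    curve: BiasCurve,
    grid: BinGrid | None = None,
    mappability_min: float = DEFAULT_MAPPABILITY_MIN,
    reference_rates: np.ndarray | None = None,
) -> NormalizedRatios:
    """Apply GC/mappability correction and median-centre to log2 ratios.

    corrected_i = count_i / (length_i * curve(gc_i) * mappability_i); bins
    with mappability below ``mappability_min``, zero length or zero count are
    masked.  ``log2_ratio_i = log2(corrected_i / median(corrected))`` over
    valid bins, optionally divided by ``reference_rates`` (panel-of-normals
    hook) first.
    """
    grid = grid or counts.grid
    if not 0 <= mappability_min <= 1:
        raise ValueError("mappability_min must be in [0, 1]")
    lengths = grid.lengths.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = lengths * curve(grid.gc) * grid.mappability
        corrected = np.where(denom > 0, counts.counts / denom, np.nan)
    valid = (
        (lengths > 0)
        & (grid.mappability >= mappability_min)
        & (counts.counts > 0)
        & np.isfinite(corrected)
    )
    if reference_rates is not None:
        ref = np.asarray(reference_rates, dtype=float)
        valid &= np.isfinite(ref) & (ref > 0)
        corrected = np.where(valid, corrected / np.where(valid, ref, 1.0), np.nan)
    if valid.sum() < MIN_VALID_BINS:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid bins (< {MIN_VALID_BINS}) after masking"
        )
    med = float(np.median(corrected[valid]))
    log2_ratio = np.full(grid.n_bins, np.nan)
    log2_ratio[valid] = np.log2(corrected[valid] / med)
    return NormalizedRatios(
        sample_id=counts.sample_id,
        grid=grid,
        log2_ratio=log2_ratio,
        valid=valid,
        reference_median=med,
    )


def normalize_sample(
    counts: BinCounts,
    span: float = 0.3,
    mappability_min: float = DEFAULT_MAPPABILITY_MIN,
) -> NormalizedRatios:
    """Convenience: fit the GC curve and correct in one call."""
    curve = fit_gc_bias(counts, span=span, mappability_min=mappability_min)
    return correct_counts(counts, curve, mappability_min=mappability_min)
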