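"""Shared fixtures: small annotated grids and profile builders."""

from __future__ import annotations

import numpy as np
import pytest

from scnatrack.bins import BinGrid, build_bin_grid
from scnatrack.normalize import NormalizedRatios
from scnatrack.profiles import SegmentProfile, segments_from_bin_cn
from scnatrack.simulate import annotate_grid


@pytest.fixture
def small_grid() -> BinGrid:
    """4 chromosomes x 10 Mb at 500 kb (80 bins), annotated."""
    lengths = {f"chr{i}": 10_000_000 for i in range(1, 5)}
    return annotate_grid(build_bin_grid(lengths, 500_000), seed=11)


@pytest.fixture
def equal22_grid() -> BinGrid:
    """22 equal-length chromosomes (11 Mb each) at 500 kb."""
    lengths = {f"chr{i}": 11_000_000 for i in range(1, 23)}
    return build_bin_grid(lengths, 500_000)


@pytest.fixture
def make_profile():
    """Build a SegmentProfile from a per-bin copy-number vector."""

    def _make(
        grid: BinGrid,
        bin_cn,
        sample_id: str = "s",
        tumour_fraction: float = 0.3,
        norm_ploidy: float = 2.0,
        zero_ctdna: bool = False,
    ) -> SegmentProfile:
        bin_cn = np.asarray(bin_cn, dtype=np.int64)
        lengths = grid.lengths.astype(float)
        v = bin_cn >= 0
        ploidy = float(np.sum(lengths[v] * bin_cn[v]) / np.sum(lengths[v]))
        return SegmentProfile(
            sample_id=sample_id,
            tumour_fraction=tumour_fraction,
            ploidy=2.0 if zero_ctdna else ploidy,
            norm_ploidy=norm_ploidy,
            segments=segments_from_bin_cn(grid, bin_cn),
            loglik=0.0,
            zero_ctdna=zero_ctdna,
            bin_cn=bin_cn,
        )

    return _make


@pytest.fixture
def make_ratios():
    """Build a NormalizedRatios object directly from per-bin log2 values."""

    def _make(grid: BinGrid, values, valid=None, sample_id: str = "s") -> NormalizedRatios:
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.isfinite(values)
        return NormalizedRatios(
            sample_id=sample_id,
            grid=grid,
            log2_ratio=values,
            valid=np.asarray(valid, dtype=bool),
            reference_median=1.0,
        )

    return _make
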