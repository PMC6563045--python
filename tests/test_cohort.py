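"""Cohort statistics: aberration matrix, regions, tests, paired changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnatrack.bins import build_bin_grid
from scnatrack.cohort import (
    aberration_matrix,
    change_recurrence,
    exact_p_no_ties,
    group_frequency,
    km_logrank,
    mann_whitney,
    minimal_consistent_region,
    paired_change,
    PairedChangeConfig,
    unique_regions,
)
from scnatrack.hmm import absolute_copy_number, emission_mean
from scnatrack.profiles import SegmentProfile, segments_from_bin_cn


def toy_grid(n_bins, n_chroms=1, bin_width=1_000_000):
    return build_bin_grid(
        {f"chr{i + 1}": n_bins * bin_width for i in range(n_chroms)}, bin_width
    )


def profile_from_cn(grid, cn, sid, f=0.3, norm=2.0, zero=False):
    cn = np.asarray(cn, dtype=np.int64)
    lengths = grid.lengths.astype(float)
    v = cn >= 0
    ploidy = float(np.sum(lengths[v] * cn[v]) / np.sum(lengths[v]))
    return SegmentProfile(
        sid, f, 2.0 if zero else ploidy, norm, segments_from_bin_cn(grid, cn),
        zero_ctdna=zero, bin_cn=cn,
    )


class TestAberrationMatrix:
    def test_all_neutral_cohort(self):
        grid = toy_grid(6)
        profiles = [profile_from_cn(grid, [2] * 6, f"s{k}") for k in range(3)]
        m = aberration_matrix(profiles)
        assert (m.calls.to_numpy() == 0).all()

    def test_ploidy_relative_semantics(self):
        grid = toy_grid(6)
        # near-triploid sample: CN 3 is neutral, CN 2 is a loss
        p = profile_from_cn(grid, [3, 3, 3, 3, 2, 2], "t")
        m = aberration_matrix([p, profile_from_cn(grid, [2] * 6, "d")])
        row = m.calls.loc["t"].to_numpy()
        assert row[0] == 0 and row[-1] == -1

    def test_zero_ctdna_excluded_with_warning(self):
        grid = toy_grid(4)
        good = profile_from_cn(grid, [2, 3, 3, 2], "a")
        flat = profile_from_cn(grid, [2] * 4, "z", zero=True)
        with pytest.warns(UserWarning, match="zero-ctDNA"):
            m = aberration_matrix([good, flat])
        assert m.sample_ids == ["a"]

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(20)
        grid = toy_grid(8, n_chroms=2)
        for _ in range(10):
            profiles = [
                profile_from_cn(grid, rng.choice([1, 2, 2, 3, 4], grid.n_bins), f"s{k}")
                for k in range(4)
            ]
            m = aberration_matrix(profiles)
            for p in profiles:
                ref = int(np.floor(p.ploidy + 0.5))
                for j in range(len(m.segments)):
                    seg = m.segments.iloc[j]
                    sel = (
                        (grid.bin_chrom == seg["chrom"])
                        & (grid.start >= seg["start"])
                        & (grid.end <= seg["end"])
                    )
                    cn = int(p.bin_cn[sel][0])
                    expected = 1 if cn - ref >= 1 else (-1 if cn - ref <= -1 else 0)
                    assert m.calls.loc[p.sample_id].iloc[j] == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            aberration_matrix([])


class TestGroupFrequency:
    def _matrix(self):
        grid = toy_grid(6)
        profiles = [
            profile_from_cn(grid, [3, 2, 4, 2, 1, 2], "a"),
            profile_from_cn(grid, [3, 2, 2, 3, 1, 2], "b"),
            profile_from_cn(grid, [2, 3, 4, 2, 2, 1], "c"),
        ]
        return aberration_matrix(profiles)

    def test_single_sample_track_is_indicator(self):
        m = self._matrix()
        track = group_frequency(m, ["a"])
        assert track.gains.tolist() == [1, 0, 1, 0, 0, 0]
        assert track.losses.tolist() == [0, 0, 0, 0, 1, 0]

    def test_counts_bounded_by_group_size(self):
        m = self._matrix()
        track = group_frequency(m, ["a", "b", "c"])
        assert track.gains.max() <= 3 and track.losses.max() <= 3

    def test_matches_brute_force_tally(self):
        m = self._matrix()
        track = group_frequency(m, ["a", "b"])
        sub = m.calls.loc[["a", "b"]].to_numpy()
        assert np.array_equal(track.gains, (sub == 1).sum(axis=0))
        assert np.array_equal(track.losses, (sub == -1).sum(axis=0))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_frequency(self._matrix(), [])


class TestUniqueRegions:
    def _tracks(self, cn_a, cn_b, grid=None):
        grid = grid or toy_grid(len(cn_a[0]))
        pa = [profile_from_cn(grid, cn, f"a{k}") for k, cn in enumerate(cn_a)]
        pb = [profile_from_cn(grid, cn, f"b{k}") for k, cn in enumerate(cn_b)]
        m = aberration_matrix(pa + pb)
        return (
            m,
            group_frequency(m, [p.sample_id for p in pa]),
            group_frequency(m, [p.sample_id for p in pb]),
        )

    def test_identical_tracks_no_unique_regions(self):
        cn = [[3, 3, 2, 2, 2, 2]]
        _, ta, tb = self._tracks(cn, cn)
        assert unique_regions(ta, tb, min_length=0).empty

    def test_unique_gain_reported_with_carrier_count(self):
        cn_a = [[3, 3, 2, 2, 2, 2], [3, 2, 2, 2, 2, 2], [2, 2, 2, 2, 2, 2]]
        cn_b = [[2, 2, 2, 2, 2, 2], [2, 2, 2, 3, 3, 2]]
        _, ta, tb = self._tracks(cn_a, cn_b)
        regions = unique_regions(ta, tb, min_length=0)
        gains = regions[regions["direction"] == "gain"]
        assert len(gains) == 1
        assert gains.iloc[0]["carrier_count"] == 2
        assert gains.iloc[0]["frequent"]  # 2/3 > 1/3

    def test_disjoint_between_group_orders(self):
        rng = np.random.default_rng(21)
        grid = toy_grid(10)
        cn_a = [rng.choice([2, 2, 3, 1], 10) for _ in range(3)]
        cn_b = [rng.choice([2, 2, 3, 1], 10) for _ in range(3)]
        _, ta, tb = self._tracks(cn_a, cn_b, grid)
        ab = unique_regions(ta, tb, min_length=0)
        ba = unique_regions(tb, ta, min_length=0)
        keys_ab = {(r.chrom, r.start, r.end, r.direction) for r in ab.itertuples()}
        keys_ba = {(r.chrom, r.start, r.end, r.direction) for r in ba.itertuples()}
        assert not (keys_ab & keys_ba)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            grid = toy_grid(8)
            cn_a = [rng.choice([1, 2, 2, 3], 8) for _ in range(3)]
            cn_b = [rng.choice([1, 2, 2, 3], 8) for _ in range(2)]
            m, ta, tb = self._tracks(cn_a, cn_b, grid)
            regions = unique_regions(ta, tb, min_length=0)
            for direction, a_cnt, b_cnt in (
                ("gain", ta.gains, tb.gains),
                ("loss", ta.losses, tb.losses),
            ):
                cond = (a_cnt > 0) & (b_cnt == 0)
                # brute-force: every maximal run of consecutive True segments
                expected = []
                k = 0
                n = len(cond)
                while k < n:
                    if cond[k]:
                        j = k
                        while j + 1 < n and cond[j + 1]:
                            j += 1
                        expected.append(
                            (
                                int(m.segments.iloc[k]["start"]),
                                int(m.segments.iloc[j]["end"]),
                                int(max(a_cnt[k : j + 1])),
                            )
                        )
                        k = j + 1
                    else:
                        k += 1
                got = regions[regions["direction"] == direction]
                assert [
                    (int(r.start), int(r.end), int(r.carrier_count))
                    for r in got.itertuples()
                ] == expected


class TestMinimalConsistentRegion:
    def test_staggered_intervals_intersect(self):
        # carriers aberrant on [2,10), [4,12), [6,14) Mb -> core [6,10)
        grid = toy_grid(30)
        profiles = []
        for k, (lo, hi) in enumerate([(2, 10), (4, 12), (6, 14)]):
            cn = np.full(30, 2)
            cn[lo:hi] = 3
            profiles.append(profile_from_cn(grid, cn, f"s{k}"))
        m = aberration_matrix(profiles)
        mcr = minimal_consistent_region(m, ("chr1", 0, 30_000_000), "gain")
        assert mcr == ("chr1", 6_000_000, 10_000_000, 3)

    def test_single_carrier_returns_its_interval(self):
        grid = toy_grid(10)
        cn = np.full(10, 2)
        cn[3:7] = 1
        m = aberration_matrix([profile_from_cn(grid, cn, "s"),
                               profile_from_cn(grid, [2] * 10, "t")])
        mcr = minimal_consistent_region(m, ("chr1", 0, 10_000_000), "loss")
        assert mcr == ("chr1", 3_000_000, 7_000_000, 1)

    def test_nested_intervals_give_innermost(self):
        grid = toy_grid(30)
        profiles = []
        for k, (lo, hi) in enumerate([(1, 13), (3, 11), (5, 9)]):
            cn = np.full(30, 2)
            cn[lo:hi] = 4
            profiles.append(profile_from_cn(grid, cn, f"s{k}"))
        m = aberration_matrix(profiles)
        mcr = minimal_consistent_region(m, ("chr1", 0, 30_000_000), "gain")
        assert mcr == ("chr1", 5_000_000, 9_000_000, 3)

    def test_no_carriers_returns_none(self):
        grid = toy_grid(5)
        m = aberration_matrix([profile_from_cn(grid, [2] * 5, "s"),
                               profile_from_cn(grid, [3] * 5 , "t")])
        assert minimal_consistent_region(m, ("chr1", 0, 5_000_000), "loss") is None


class TestMannWhitney:
    def test_enumerated_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_approximation_close_to_exact_at_n10(self):
        rng = np.random.default_rng(24)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            u, p_approx = mann_whitney(x, y)  # n=20 -> asymptotic branch
            p_exact = exact_p_no_ties(u, 10, 10)
            assert abs(p_approx - p_exact) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [3, 5, 8, 11, 3, 5, 8, 11]
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_km_reaches_zero_after_last_event(self):
        res = km_logrank([1, 2, 3, 1, 2, 4], [1] * 6, ["a"] * 3 + ["b"] * 3)
        for curve in res.curves.values():
            assert curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_two_group_toy_matches_hand_computation(self):
        # alternating event times 1..6, all observed; the observed-vs-expected
        # table is computed by hand below
        times = [1, 3, 5, 2, 4, 6]
        events = [1] * 6
        groups = ["a", "a", "a", "b", "b", "b"]
        e_a = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2 + 0
        var = (
            (3 * 3) / 36 + (2 * 3) / 25 + (2 * 2) / 16 + (1 * 2) / 9 + (1 * 1) / 4
        )
        expected_chi2 = (3 - e_a) ** 2 / var
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(expected_chi2, abs=1e-10)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(25)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        groups = np.array(["a", "b", "c", "d"] * 10)
        res = km_logrank(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_trend_detects_ordered_hazard(self):
        rng = np.random.default_rng(26)
        times, groups = [], []
        for g, med in (("low", 20), ("medium", 10), ("high", 5)):
            times.extend(rng.exponential(med / np.log(2), 30))
            groups.extend([g] * 30)
        res = km_logrank(times, [1] * 90, groups, ["low", "medium", "high"])
        assert res.trend_p_value < 0.01

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])


class TestPairedChange:
    def _ratios(self, grid, cn, f, make_ratios, norm=2.0):
        values = emission_mean(np.asarray(cn, dtype=float), f, norm)
        return make_ratios(grid, np.asarray(values))

    def test_identical_samples_zero_percent(self, make_ratios):
        grid = toy_grid(20)
        cn = [2] * 10 + [3] * 10
        pre = profile_from_cn(grid, cn, "pre", f=0.3)
        prog = profile_from_cn(grid, cn, "prog", f=0.3)
        pc = paired_change(
            pre, prog,
            self._ratios(grid, cn, 0.3, make_ratios),
            self._ratios(grid, cn, 0.3, make_ratios),
        )
        assert pc.eligible
        assert pc.percent_genome_changed == pytest.approx(0.0)

    def test_low_fraction_pair_ineligible(self, make_ratios):
        grid = toy_grid(10)
        cn = [2] * 10
        pre = profile_from_cn(grid, cn, "pre", f=0.12)
        prog = profile_from_cn(grid, cn, "prog", f=0.09)
        pc = paired_change(
            pre, prog,
            self._ratios(grid, cn, 0.12, make_ratios),
            self._ratios(grid, cn, 0.09, make_ratios),
        )
        assert not pc.eligible
        assert "0.1" in pc.reason

    def test_dissimilar_fractions_ineligible(self, make_ratios):
        grid = toy_grid(10)
        cn = [2] * 10
        pre = profile_from_cn(grid, cn, "pre", f=0.12)
        prog = profile_from_cn(grid, cn, "prog", f=0.45)
        pc = paired_change(
            pre, prog,
            self._ratios(grid, cn, 0.12, make_ratios),
            self._ratios(grid, cn, 0.45, make_ratios),
        )
        assert not pc.eligible
        assert "dissimilar" in pc.reason

    def test_delta_exactly_at_threshold_not_counted(self, make_ratios):
        # strict inequality: a change of exactly the threshold is not a change
        grid = toy_grid(10)
        pre_cn = [2] * 10
        prog_cn = [2] * 5 + [3] * 5
        f = 0.5
        pre = profile_from_cn(grid, pre_cn, "pre", f=f)
        prog = profile_from_cn(grid, prog_cn, "prog", f=f)
        r_pre = self._ratios(grid, pre_cn, f, make_ratios)
        r_prog = self._ratios(grid, prog_cn, f, make_ratios)
        probe = paired_change(pre, prog, r_pre, r_prog)
        realized = float(np.max(np.abs(probe.delta_cn[probe.joint_valid])))
        at = paired_change(
            pre, prog, r_pre, r_prog, PairedChangeConfig(delta_threshold=realized)
        )
        assert at.percent_genome_changed == pytest.approx(0.0)
        below = paired_change(
            pre, prog, r_pre, r_prog,
            PairedChangeConfig(delta_threshold=float(np.nextafter(realized, 0.0))),
        )
        assert below.percent_genome_changed == pytest.approx(50.0)

    def test_grid_mismatch_rejected(self, make_ratios):
        from scnatrack.bins import CoordinateMismatchError

        g1, g2 = toy_grid(10), toy_grid(12)
        cn1, cn2 = [2] * 10, [2] * 12
        with pytest.raises(CoordinateMismatchError):
            paired_change(
                profile_from_cn(g1, cn1, "pre"),
                profile_from_cn(g2, cn2, "prog"),
                self._ratios(g1, cn1, 0.3, make_ratios),
                self._ratios(g2, cn2, 0.3, make_ratios),
            )


class TestChangeRecurrence:
    def test_single_pair_track_equals_signed_mask(self, make_ratios):
        grid = toy_grid(12)
        pre_cn = [2] * 12
        prog_cn = [4] * 4 + [2] * 4 + [0] * 4
        f = 0.5
        pre = profile_from_cn(grid, pre_cn, "pre", f=f)
        prog = profile_from_cn(grid, prog_cn, "prog", f=f)
        values_pre = emission_mean(np.asarray(pre_cn, dtype=float), f, 2.0)
        values_prog = emission_mean(np.asarray(prog_cn, dtype=float), f, 2.0)
        pc = paired_change(
            pre, prog, make_ratios(grid, np.asarray(values_pre)),
            make_ratios(grid, np.asarray(values_prog)),
        )
        track = change_recurrence([pc], grid)
        assert track.gains.tolist() == [1] * 4 + [0] * 8
        assert track.losses.tolist() == [0] * 8 + [1] * 4
        assert track.n_pairs == 1

    def test_no_eligible_pairs_warns_empty(self, make_ratios):
        grid = toy_grid(10)
        cn = [2] * 10
        pre = profile_from_cn(grid, cn, "pre", f=0.05)
        prog = profile_from_cn(grid, cn, "prog", f=0.05)
        pc = paired_change(
            pre, prog,
            make_ratios(grid, np.zeros(10)),
            make_ratios(grid, np.zeros(10)),
        )
        with pytest.warns(UserWarning, match="no eligible"):
            track = change_recurrence([pc], grid)
        assert track.n_pairs == 0
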