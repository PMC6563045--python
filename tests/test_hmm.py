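"""Copy-number HMM: emissions, Viterbi vs enumeration, EM, resegmentation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from scnatrack.bins import build_bin_grid
from scnatrack.hmm import (
    CopyNumberHMM,
    FitSolution,
    HmmConfig,
    HmmParams,
    absolute_copy_number,
    emission_mean,
    select_solution,
    uniform_resegment,
    viterbi_states,
)
from scnatrack.profiles import SegmentProfile, segments_from_bin_cn


def toy_grid(n_bins, n_chroms=1, bin_width=500_000):
    return build_bin_grid(
        {f"chr{i + 1}": n_bins * bin_width for i in range(n_chroms)}, bin_width
    )


def brute_force_decode(obs, params):
    """Enumerate all state paths: best path, best score, total log-likelihood."""
    K = len(params.states)
    T = len(obs)
    mu = params.means()
    logb = (
        -0.5 * ((obs[:, None] - mu[None, :]) / params.sigma) ** 2
        - np.log(params.sigma)
        - 0.5 * np.log(2 * np.pi)
    )
    s, o = params.self_transition, (1 - params.self_transition) / (K - 1)
    log_pi = -np.log(K)
    best_score, best_path = -np.inf, None
    all_scores = []
    for path in itertools.product(range(K), repeat=T):
        score = log_pi + logb[0, path[0]]
        for t in range(1, T):
            score += logb[t, path[t]]
            score += np.log(s) if path[t] == path[t - 1] else np.log(o)
        all_scores.append(score)
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path), best_score, float(logsumexp(all_scores))


class TestEmissionMean:
    def test_no_tumour_signal_is_zero(self):
        assert emission_mean(5, 0.0, 2.0) == 0.0

    def test_pure_tumour_cn4_is_one(self):
        assert emission_mean(4, 1.0, 2.0) == pytest.approx(1.0)

    def test_half_mixture_cn3(self):
        # log2(2.5 / 2) evaluated directly
        assert emission_mean(3, 0.5, 2.0) == pytest.approx(np.log2(2.5 / 2), abs=1e-12)
        assert emission_mean(3, 0.5, 2.0) == pytest.approx(0.3219281, abs=1e-6)

    def test_zero_numerator_floored(self):
        assert emission_mean(0, 1.0, 2.0) == -8.0

    def test_means_increase_with_cn(self):
        mu = emission_mean(np.arange(6), 0.3, 2.0)
        assert np.all(np.diff(mu) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            emission_mean(2, -0.1, 2.0)
        with pytest.raises(ValueError):
            emission_mean(2, 0.5, 0.0)


class TestAbsoluteCopyNumber:
    def test_neutral_identity(self):
        for f in (0.1, 0.5, 1.0):
            assert absolute_copy_number(0.0, f, 2.0) == pytest.approx(2.0, abs=1e-12)

    def test_inverse_of_emission_mean(self):
        for c in range(6):
            for f in np.arange(0.1, 1.01, 0.1):
                for phi in (2.0, 3.0):
                    if c == 0 and f >= 1.0:
                        continue  # numerator 0: emission is floored, not invertible
                    r = emission_mean(c, float(f), phi)
                    assert absolute_copy_number(r, float(f), phi) == pytest.approx(
                        c, abs=1e-9
                    )

    def test_example_inverse(self):
        assert absolute_copy_number(np.log2(2.5 / 2), 0.5, 2.0) == pytest.approx(3.0)

    def test_zero_fraction_undefined(self):
        with pytest.raises(ValueError):
            absolute_copy_number(0.1, 0.0, 2.0)


class TestViterbi:
    def test_noiseless_states_recovered(self, make_ratios):
        params = HmmParams(f=0.4, phi=2.0, sigma=0.05)
        states = np.array([2, 2, 3, 3, 3, 1, 1, 2, 4, 4, 2, 2])
        grid = toy_grid(len(states))
        mu = params.means()
        ratios = make_ratios(grid, mu[states])
        path = viterbi_states(ratios, params)
        assert np.array_equal(path, states)

    def test_flat_ratios_all_neutral(self, make_ratios):
        grid = toy_grid(30)
        ratios = make_ratios(grid, np.zeros(30))
        path = viterbi_states(ratios, HmmParams(f=0.3, phi=2.0, sigma=0.1))
        assert np.all(path == 2)

    def test_matches_exhaustive_enumeration(self, make_ratios):
        rng = np.random.default_rng(0)
        for rep in range(20):
            T = int(rng.integers(4, 7))
            params = HmmParams(
                f=float(rng.uniform(0.1, 0.9)),
                phi=float(rng.uniform(1.8, 3.2)),
                sigma=float(rng.uniform(0.05, 0.4)),
                self_transition=float(rng.uniform(0.6, 0.999)),
            )
            obs = rng.normal(0, 0.6, T)
            grid = toy_grid(T)
            model = CopyNumberHMM(
                make_ratios(grid, obs),
                self_transition=params.self_transition,
            )
            path = model.viterbi(params)
            bf_path, bf_score, _ = brute_force_decode(obs, params)
            assert np.array_equal(path, bf_path)
            assert model.path_score(params, path) == pytest.approx(bf_score, abs=1e-8)

    def test_eight_bin_chain_matches_enumeration(self, make_ratios):
        rng = np.random.default_rng(7)
        obs = rng.normal(0, 0.5, 8)
        params = HmmParams(f=0.5, phi=2.0, sigma=0.15, self_transition=0.9)
        model = CopyNumberHMM(make_ratios(toy_grid(8), obs), self_transition=0.9)
        bf_path, bf_score, _ = brute_force_decode(obs, params)
        assert np.array_equal(model.viterbi(params), bf_path)

    def test_no_transitions_across_chromosomes(self, make_ratios):
        # a gain confined to chr2 does not leak into chr1
        params = HmmParams(f=0.5, phi=2.0, sigma=0.05)
        grid = toy_grid(5, n_chroms=2)
        mu = params.means()
        values = np.concatenate([np.full(5, mu[2]), np.full(5, mu[3])])
        path = viterbi_states(make_ratios(grid, values), params)
        assert np.all(path[:5] == 2) and np.all(path[5:] == 3)

    def test_nonfinite_valid_ratio_rejected(self, make_ratios):
        grid = toy_grid(5)
        values = np.array([0.0, np.nan, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="non-finite"):
            CopyNumberHMM(make_ratios(grid, values, valid=np.ones(5, bool)))


class TestForwardBackward:
    def test_posteriors_sum_to_one(self, make_ratios):
        rng = np.random.default_rng(1)
        obs = rng.normal(0, 0.3, 40)
        model = CopyNumberHMM(make_ratios(toy_grid(40), obs))
        _, gamma = model.forward_backward(HmmParams(f=0.3, phi=2.0, sigma=0.2))
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_matches_path_enumeration(self, make_ratios):
        rng = np.random.default_rng(2)
        obs = rng.normal(0, 0.4, 6)
        params = HmmParams(f=0.4, phi=2.0, sigma=0.2, self_transition=0.95)
        model = CopyNumberHMM(make_ratios(toy_grid(6), obs), self_transition=0.95)
        ll, _ = model.forward_backward(params)
        _, _, ll_bf = brute_force_decode(obs, params)
        assert ll == pytest.approx(ll_bf, abs=1e-8)


class TestEmFit:
    def test_noiseless_converges_fast_from_truth(self, make_ratios):
        params = HmmParams(f=0.3, phi=2.0, sigma=0.05)
        rng = np.random.default_rng(3)
        states = np.repeat([2, 3, 2, 1, 2], 30)
        mu = params.means()
        model = CopyNumberHMM(make_ratios(toy_grid(len(states)), mu[states]))
        sol = model.fit_em(0.3, 2.0, max_iter=20)
        assert sol.converged and sol.n_iter <= 5
        assert sol.params.f == pytest.approx(0.3, abs=0.02)

    def test_monotone_loglik_on_random_data(self, make_ratios):
        # a decrease beyond tolerance raises inside fit_em
        rng = np.random.default_rng(4)
        for seed in range(3):
            obs = rng.normal(0, 0.25, 120)
            model = CopyNumberHMM(make_ratios(toy_grid(120), obs))
            sol = model.fit_em(0.2, 2.0, max_iter=30)
            assert np.isfinite(sol.loglik)

    def test_invalid_init_rejected(self, make_ratios):
        model = CopyNumberHMM(make_ratios(toy_grid(10), np.zeros(10)))
        with pytest.raises(ValueError):
            model.fit_em(0.0, 2.0)


class TestSolutionSelection:
    def _sol(self, f, phi, ll, frac):
        return FitSolution(
            params=HmmParams(f=f, phi=phi, sigma=0.1),
            loglik=ll,
            frac_nonneutral=frac,
            n_iter=5,
            converged=True,
        )

    def test_tied_likelihood_prefers_smaller_aberrant_fraction(self):
        # mirror whole-genome gain vs the complementary smaller loss
        gain = self._sol(0.45, 2.0, 1000.0, 0.6)
        loss = self._sol(0.30, 2.0, 1000.0, 0.4)
        assert select_solution([gain, loss], lam=2.0) is loss

    def test_clear_likelihood_difference_wins(self):
        better = self._sol(0.4, 3.0, 1010.0, 0.8)
        worse = self._sol(0.3, 2.0, 1000.0, 0.1)
        assert select_solution([better, worse], lam=2.0) is better

    def test_residual_tie_prefers_near_diploid_ploidy(self):
        diploid = self._sol(0.33, 2.05, 1000.0, 0.15)
        triploid = self._sol(0.40, 3.05, 1000.2, 0.15)
        assert select_solution([diploid, triploid], lam=2.0) is diploid


class TestFitAndZeroRule:
    def test_flat_noisy_sample_flagged_zero(self, make_ratios):
        rng = np.random.default_rng(5)
        grid = toy_grid(150, n_chroms=2)
        obs = rng.normal(0, 0.12, grid.n_bins)
        res = CopyNumberHMM(make_ratios(grid, obs)).fit(HmmConfig())
        assert res.profile.zero_ctdna
        assert res.profile.tumour_fraction == 0.0
        assert np.all(res.profile.bin_cn[res.profile.bin_cn >= 0] == 2)

    def test_summary_mentions_key_quantities(self, make_ratios):
        rng = np.random.default_rng(6)
        grid = toy_grid(100)
        res = CopyNumberHMM(make_ratios(grid, rng.normal(0, 0.1, 100))).fit(HmmConfig())
        text = res.summary()
        assert "tumour fraction" in text and "ploidy" in text


class TestUniformResegment:
    def _profile(self, grid, cn, sid):
        return SegmentProfile(
            sid, 0.3, 2.1, 2.0, segments_from_bin_cn(grid, np.asarray(cn))
        )

    def test_single_profile_identity(self):
        grid = toy_grid(6)
        p = self._profile(grid, [2, 2, 3, 3, 2, 2], "a")
        segments, cn = uniform_resegment([p])
        assert len(segments) == 3
        assert segments["start"].tolist() == [0, 1_000_000, 2_000_000]
        assert cn.loc["a"].tolist() == [2.0, 3.0, 2.0]

    def test_interleaved_breakpoints_match_boundary_union(self):
        grid = toy_grid(8)
        a = self._profile(grid, [2, 2, 3, 3, 3, 3, 2, 2], "a")
        b = self._profile(grid, [2, 4, 4, 4, 2, 2, 2, 2], "b")
        segments, cn = uniform_resegment([a, b])
        # brute-force union of all boundaries
        bounds = set()
        for p in (a, b):
            bounds.update(p.segments["start"])
            bounds.update(p.segments["end"])
        assert len(segments) == len(sorted(bounds)) - 1
        # values unchanged within original segments
        assert cn.loc["a"].tolist()[:3] == [2.0, 2.0, 3.0]

    def test_mean_copy_number_conserved(self):
        grid = toy_grid(10)
        rng = np.random.default_rng(8)
        profiles = [
            self._profile(grid, rng.choice([1, 2, 3, 4], 10), f"s{k}") for k in range(3)
        ]
        segments, cn = uniform_resegment(profiles)
        w = segments["length"].to_numpy(dtype=float)
        for p in profiles:
            orig = p.segments
            mean_orig = float(
                np.sum((orig["end"] - orig["start"]) * orig["cn"])
                / np.sum(orig["end"] - orig["start"])
            )
            vals = cn.loc[p.sample_id].to_numpy(dtype=float)
            mean_new = float(np.sum(w * vals) / np.sum(w))
            assert mean_new == pytest.approx(mean_orig, abs=1e-12)
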