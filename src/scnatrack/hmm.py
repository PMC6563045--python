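"""Joint tumour-fraction / ploidy / copy-number inference from log2 ratios.

The observed depth of a bin in cfDNA is a mixture of tumour-derived fragments
(fraction ``f``, at the tumour's local copy number ``c``) and normal-cell
fragments (fraction ``1 - f``, at copy number 2).  Relative to the sample
average, the expected log2 ratio of a bin with tumour copy number ``c`` is

    mu(c) = log2( (f*c + (1-f)*2) / (f*phi + (1-f)*2) )

where ``phi`` is the normalisation ploidy (the copy number mapping to ratio
zero; with median-centred ratios this is the sample's modal copy number).
Integer copy-number states 0..5 form a hidden Markov chain along each
chromosome with Gaussian emissions of shared scale ``sigma``; ``f``, ``phi``
and ``sigma`` are estimated by EM from a grid of initialisations, and the
best penalised solution is decoded with Viterbi into a segment profile.

The model object / results object split follows the statsmodels convention:
build :class:`CopyNumberHMM` from a :class:`~scnatrack.normalize.NormalizedRatios`,
call :meth:`~CopyNumberHMM.fit`, inspect the returned
:class:`CopyNumberHMMResults` (estimates, diagnostics, ``summary()``).
Module-level functions (:func:`emission_mean`, :func:`viterbi_states`,
:func:`em_fit`, :func:`estimate_profile`, :func:`absolute_copy_number`,
:func:`uniform_resegment`) expose the same operations functionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bins import BinGrid, CoordinateMismatchError
from .normalize import NormalizedRatios
from .profiles import SegmentProfile, segments_from_bin_cn

__all__ = [
    "HmmParams",
    "FitSolution",
    "HmmConfig",
    "CopyNumberHMM",
    "CopyNumberHMMResults",
    "emission_mean",
    "absolute_copy_number",
    "viterbi_states",
    "em_fit",
    "estimate_profile",
    "select_solution",
    "uniform_resegment",
]

NORMAL_CN = 2
EMISSION_FLOOR = -8.0


def emission_mean(
    c: np.ndarray | int,
    f: float,
    phi: float,
    floor: float = EMISSION_FLOOR,
) -> np.ndarray | float:
    """Expected log2 ratio of a bin with tumour copy number ``c``.

    Returns ``floor`` where the mixture numerator is zero (c = 0 at f = 1).
    """
    if not 0 <= f <= 1:
        raise ValueError(f"tumour fraction must be in [0, 1], got {f}")
    if phi <= 0:
        raise ValueError(f"ploidy must be positive, got {phi}")
    c_arr = np.asarray(c, dtype=float)
    num = f * c_arr + (1.0 - f) * NORMAL_CN
    den = f * phi + (1.0 - f) * NORMAL_CN
    with np.errstate(divide="ignore"):
        out = np.where(num > 0, np.log2(np.maximum(num, 1e-300) / den), floor)
    if np.isscalar(c):
        return float(out)
    return out


def absolute_copy_number(
    log2_ratio: np.ndarray | float, f: float, phi: float
) -> np.ndarray | float:
    """Continuous tumour copy number implied by a log2 ratio.

    Exact inverse of :func:`emission_mean`:
    ``((f*phi + (1-f)*2) * 2**r - (1-f)*2) / f``.  Undefined at ``f = 0``.
    """
    if f <= 0:
        raise ValueError("absolute copy number is undefined for tumour fraction 0")
    r = np.asarray(log2_ratio, dtype=float)
    den = f * phi + (1.0 - f) * NORMAL_CN
    out = (den * np.power(2.0, r) - (1.0 - f) * NORMAL_CN) / f
    if np.isscalar(log2_ratio):
        return float(out)
    return out


@dataclass(frozen=True)
class HmmParams:
    """Parameters of the copy-number HMM."""

    f: float
    phi: float
    sigma: float
    states: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    self_transition: float = 0.9999
    emission_floor: float = EMISSION_FLOOR

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise ValueError("f must be in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.self_transition < 1:
            raise ValueError("self_transition must be in (0, 1)")

    def means(self) -> np.ndarray:
        return np.asarray(
            emission_mean(np.array(self.states), self.f, self.phi, self.emission_floor)
        )


@dataclass
class FitSolution:
    """One EM fit: parameters, likelihood and the model-selection record.

    ``frac_nonneutral`` is the length fraction of decoded bins differing
    from the solution's own rounded normalisation ploidy;
    ``frac_homdel`` is the length fraction decoded as copy number 0, used
    to reject solutions that reinterpret arm-level single-copy losses as
    biologically impossible arm-wide homozygous deletions.
    """

    params: HmmParams
    loglik: float
    frac_nonneutral: float
    n_iter: int
    converged: bool
    init: tuple[float, float] = (float("nan"), float("nan"))
    frac_homdel: float = 0.0

    def penalized_loglik(self, lam: float) -> float:
        return self.loglik - lam * self.frac_nonneutral


@dataclass
class HmmConfig:
    """Configuration for profile estimation (initialisation grid, selection
    penalty, and the zero-ctDNA rule)."""

    f_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    ploidy_grid: tuple[float, ...] = (2.0, 3.0)
    states: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    self_transition: float = 0.9999
    sigma0: float = 0.2
    max_iter: int = 50
    tol: float = 1e-5
    lam: float = 5.0
    tie_tol: float = 0.5
    link_chromosomes: bool = True
    max_homdel_fraction: float = 0.02
    anchor_margin: float = 2.0
    f_min: float = 0.03
    min_nonneutral: float = 0.01
    emission_floor: float = EMISSION_FLOOR


class EstimationError(RuntimeError):
    pass


class CopyNumberHMM:
    """Copy-number HMM over the valid bins of one sample's log2 ratios.

    Masked bins are skipped, so valid bins flanking a masked gap are treated
    as adjacent.  Chromosomes are linked into a single chain by default (see
    ``link_chromosomes``); independent per-chromosome chains are available
    as an option.
    """

    def __init__(
        self,
        ratios: NormalizedRatios,
        states: Sequence[int] = (0, 1, 2, 3, 4, 5),
        self_transition: float = 0.9999,
        emission_floor: float = EMISSION_FLOOR,
        link_chromosomes: bool = True,
    ):
        if np.any(~np.isfinite(ratios.log2_ratio[ratios.valid])):
            raise ValueError("non-finite log2 ratio in a valid bin")
        if ratios.n_valid < 1:
            raise EstimationError("no valid bins")
        self.ratios = ratios
        self.grid = ratios.grid
        self.states = tuple(int(s) for s in states)
        self.self_transition = float(self_transition)
        self.emission_floor = float(emission_floor)
        self.link_chromosomes = bool(link_chromosomes)
        # observation vectors over valid bins.  By default chromosomes are
        # linked into one chain (a state change at a chromosome boundary
        # costs a transition like any other): with independent chains and a
        # uniform initial distribution, every chromosome can adopt a
        # different state for free, which lets finely spaced low-f solutions
        # harvest chromosome-level sampling noise.
        self._chrom_obs: list[np.ndarray] = []
        self._chrom_bins: list[np.ndarray] = []
        for ci in range(len(self.grid.chrom_names)):
            idx = np.flatnonzero((self.grid.chrom_index == ci) & ratios.valid)
            if idx.size:
                self._chrom_obs.append(ratios.log2_ratio[idx])
                self._chrom_bins.append(idx)
        if self.link_chromosomes:
            self._chrom_obs = [np.concatenate(self._chrom_obs)]
            self._chrom_bins = [np.concatenate(self._chrom_bins)]
        self._all_obs = np.concatenate(self._chrom_obs)
        self._all_bins = np.concatenate(self._chrom_bins)
        self._lengths = self.grid.lengths.astype(float)
        # preference order for Viterbi tie-breaks: closest to neutral first
        neutral = NORMAL_CN
        self._pref = np.array(
            sorted(range(len(self.states)), key=lambda i: (abs(self.states[i] - neutral), self.states[i]))
        )

    # ------------------------------------------------------------------ #
    # inference primitives

    def _emission_logpdf(self, obs: np.ndarray, params: HmmParams) -> np.ndarray:
        mu = params.means()
        z = (obs[:, None] - mu[None, :]) / params.sigma
        return -0.5 * z * z - np.log(params.sigma) - 0.5 * np.log(2 * np.pi)

    def forward_backward(self, params: HmmParams) -> tuple[float, np.ndarray]:
        """Scaled forward-backward over all chromosomes.

        Returns total log-likelihood and the posterior state probabilities
        for every valid bin (rows sum to 1).
        """
        K = len(self.states)
        s = params.self_transition
        o = (1.0 - s) / (K - 1)
        total_ll = 0.0
        gammas = []
        for obs in self._chrom_obs:
            logb = self._emission_logpdf(obs, params)
            # per-chromosome max stabilisation
            b = np.exp(logb - logb.max(axis=1, keepdims=True))
            T = len(obs)
            alpha = np.empty((T, K))
            c = np.empty(T)
            a = b[0] / K
            c[0] = a.sum()
            alpha[0] = a / c[0]
            for t in range(1, T):
                pred = (s - o) * alpha[t - 1] + o * alpha[t - 1].sum()
                a = b[t] * pred
                c[t] = a.sum()
                alpha[t] = a / c[t]
            beta = np.empty((T, K))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                w = b[t + 1] * beta[t + 1]
                beta[t] = ((s - o) * w + o * w.sum()) / c[t + 1]
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            gammas.append(gamma)
            total_ll += float(np.sum(np.log(c)) + np.sum(logb.max(axis=1)))
        return total_ll, np.vstack(gammas)

    def viterbi(self, params: HmmParams) -> np.ndarray:
        """MAP state path; ties broken toward the state nearest copy number 2.

        Returns the integer copy number per grid bin, -1 at masked bins.
        """
        K = len(self.states)
        s = params.self_transition
        o = (1.0 - s) / (K - 1)
        log_s, log_o = np.log(s), np.log(o)
        states_arr = np.array(self.states)
        path_cn = np.full(self.grid.n_bins, -1, dtype=np.int64)
        for obs, bins in zip(self._chrom_obs, self._chrom_bins):
            logb = self._emission_logpdf(obs, params)
            T = len(obs)
            score = logb[0] - np.log(K)
            back = np.zeros((T, K), dtype=np.int64)
            for t in range(1, T):
                stay = score + log_s
                # best jump predecessor per target state: the global maximum,
                # or the runner-up when the target IS the global maximum
                order = np.argsort(score)
                i1, i2 = int(order[-1]), int(order[-2])
                jump_src = np.where(np.arange(K) == i1, i2, i1)
                jump = score[jump_src] + log_o
                prev = np.where(stay >= jump, stay, jump)
                back[t] = np.where(stay >= jump, np.arange(K), jump_src)
                score = logb[t] + prev
            # final state: first maximum in neutral-preference order
            best = self._pref[int(np.argmax(score[self._pref]))]
            idx_path = np.empty(T, dtype=np.int64)
            idx_path[-1] = best
            for t in range(T - 1, 0, -1):
                idx_path[t - 1] = back[t, idx_path[t]]
            path_cn[bins] = states_arr[idx_path]
        return path_cn

    def path_score(self, params: HmmParams, path_cn: np.ndarray) -> float:
        """Joint log-probability of a given state path (for oracle checks)."""
        K = len(self.states)
        s = params.self_transition
        o = (1.0 - s) / (K - 1)
        state_index = {c: i for i, c in enumerate(self.states)}
        total = 0.0
        for obs, bins in zip(self._chrom_obs, self._chrom_bins):
            logb = self._emission_logpdf(obs, params)
            idx = np.array([state_index[int(path_cn[b])] for b in bins])
            total += -np.log(K) + float(logb[0, idx[0]])
            for t in range(1, len(obs)):
                total += float(logb[t, idx[t]])
                total += np.log(s) if idx[t] == idx[t - 1] else np.log(o)
        return total

    # ------------------------------------------------------------------ #
    # estimation

    def _frac_nonneutral(self, path_cn: np.ndarray, reference_cn: int = NORMAL_CN) -> float:
        valid = path_cn >= 0
        L = self._lengths[valid].sum()
        aberrant = self._lengths[valid & (path_cn != reference_cn)].sum()
        return float(aberrant / L) if L > 0 else 0.0

    def fit_em(
        self,
        f0: float,
        phi0: float,
        sigma0: float = 0.2,
        max_iter: int = 50,
        tol: float = 1e-5,
    ) -> FitSolution:
        """EM from one initialisation.

        E-step: forward-backward responsibilities.  M-step: ``(f, phi)`` by
        bounded numerical maximisation of the expected complete-data
        log-likelihood (via its sufficient statistics), ``sigma`` in closed
        form.  The log-likelihood is non-decreasing; a decrease beyond
        tolerance raises.
        """
        if not 0 < f0 <= 1:
            raise ValueError("init_f must be in (0, 1]")
        params = HmmParams(
            f=min(f0, 0.98),
            phi=phi0,
            sigma=sigma0,
            states=self.states,
            self_transition=self.self_transition,
            emission_floor=self.emission_floor,
        )
        states_arr = np.array(self.states, dtype=float)
        obs = self._all_obs
        N = obs.size
        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        for it in range(max_iter):
            ll, gamma = self.forward_backward(params)
            if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
                raise EstimationError(
                    f"EM log-likelihood decreased ({prev_ll:.6f} -> {ll:.6f})"
                )
            if ll - prev_ll < tol * max(1.0, abs(ll)) and it > 0:
                converged = True
                break
            prev_ll = ll
            # sufficient statistics per state
            n_c = gamma.sum(axis=0)
            b_c = gamma.T @ obs
            a_c = gamma.T @ (obs * obs)

            def sse(x: np.ndarray) -> float:
                mu = np.asarray(
                    emission_mean(states_arr, x[0], x[1], self.emission_floor)
                )
                return float(np.sum(a_c - 2 * mu * b_c + n_c * mu * mu))

            x0 = np.array([params.f, params.phi])
            res = minimize(
                sse,
                x0,
                method="L-BFGS-B",
                bounds=[(1e-3, 0.98), (1.2, 5.5)],
            )
            x = res.x if res.fun <= sse(x0) else x0
            sigma = max(float(np.sqrt(sse(x) / N)), 1e-3)
            params = replace(params, f=float(x[0]), phi=float(x[1]), sigma=sigma)
        if not converged:
            ll, _ = self.forward_backward(params)
        path = self.viterbi(params)
        # aberrant fraction is measured against the model's own rounded
        # normalisation ploidy, so mirror solutions that shift every state
        # label by one are scored on equal footing
        ref = int(np.floor(params.phi + 0.5))
        valid = path >= 0
        L = self._lengths[valid].sum()
        homdel = float(self._lengths[valid & (path == 0)].sum() / L) if L else 0.0
        return FitSolution(
            params=params,
            loglik=float(ll),
            frac_nonneutral=self._frac_nonneutral(path, ref),
            n_iter=it + 1,
            converged=converged,
            init=(float(f0), float(phi0)),
            frac_homdel=homdel,
        )

    def fit(self, config: HmmConfig | None = None) -> "CopyNumberHMMResults":
        """Run EM from the full initialisation grid and select the best
        penalised solution; apply the zero-ctDNA rule; decode segments."""
        config = config or HmmConfig()
        solutions: list[FitSolution] = []
        for phi0 in config.ploidy_grid:
            for f0 in config.f_grid:
                try:
                    solutions.append(
                        self.fit_em(
                            f0,
                            phi0,
                            sigma0=config.sigma0,
                            max_iter=config.max_iter,
                            tol=config.tol,
                        )
                    )
                except EstimationError:
                    continue
        if not solutions:
            raise EstimationError("all EM initialisations failed")
        best = self._select(solutions, config)
        path = self.viterbi(best.params)
        zero = (
            best.params.f < config.f_min
            or best.frac_nonneutral < config.min_nonneutral
        )
        if zero:
            path = np.where(path >= 0, NORMAL_CN, -1)
        valid = path >= 0
        mean_cn = float(
            np.sum(self._lengths[valid] * path[valid]) / np.sum(self._lengths[valid])
        )
        segments = segments_from_bin_cn(self.grid, path, self.ratios.log2_ratio)
        profile = SegmentProfile(
            sample_id=self.ratios.sample_id,
            tumour_fraction=0.0 if zero else float(best.params.f),
            ploidy=2.0 if zero else mean_cn,
            norm_ploidy=2.0 if zero else float(best.params.phi),
            segments=segments,
            loglik=best.loglik,
            zero_ctdna=bool(zero),
            bin_cn=path,
        )
        return CopyNumberHMMResults(
            model=self, config=config, solutions=solutions, best=best, profile=profile
        )


    def _select(self, solutions: list[FitSolution], config: HmmConfig) -> FitSolution:
        """Model selection with anchor-aware tie resolution.

        Solutions decoding more than ``max_homdel_fraction`` of the genome
        as homozygous deletion are inadmissible (arm-wide CN 0 is not
        biologically viable; such solutions are reinterpretations of
        single-copy losses on a compressed ladder).  Among admissible
        solutions the highest penalised log-likelihood wins; candidates
        within ``tie_tol`` are compared on the ladder-edge anchor bins
        (those decoded at the lowest or highest state by any candidate),
        which are the only bins that distinguish mirror ploidy
        interpretations; any remaining tie falls back to the deterministic
        preference order of :func:`select_solution`.
        """
        admissible = [
            s for s in solutions if s.frac_homdel <= config.max_homdel_fraction
        ]
        pool = admissible or solutions
        best_pen = max(s.penalized_loglik(config.lam) for s in pool)
        tied = [
            s for s in pool if s.penalized_loglik(config.lam) >= best_pen - config.tie_tol
        ]
        if len(tied) > 1:
            anchored = self._anchor_tiebreak(tied, margin=config.anchor_margin)
            if anchored is not None:
                return anchored
        return select_solution(pool, config.lam, config.tie_tol)

    def _anchor_tiebreak(
        self, tied: list[FitSolution], margin: float = 2.0
    ) -> FitSolution | None:
        """Compare near-tied solutions on ladder-edge anchor bins only.

        Returns a winner only when its anchor-bin fit beats every other
        candidate by at least ``margin`` log-likelihood units; exact mirror
        reparameterisations fit the anchor bins equally well up to noise and
        must fall through to the deterministic preference order.
        """
        lo, hi = min(self.states), max(self.states)
        paths = [self.viterbi(s.params) for s in tied]
        edge = np.zeros(self.grid.n_bins, dtype=bool)
        for path in paths:
            edge |= (path == lo) | (path == hi)
        if not edge.any():
            return None
        scores = []
        for s, path in zip(tied, paths):
            mu = s.params.means()
            state_index = {c: i for i, c in enumerate(self.states)}
            sel = np.flatnonzero(edge & (path >= 0))
            x = self.ratios.log2_ratio[sel]
            m = mu[[state_index[int(path[b])] for b in sel]]
            z = (x - m) / s.params.sigma
            scores.append(float(np.sum(-0.5 * z * z - np.log(s.params.sigma))))
        order = np.argsort(scores)
        if scores[order[-1]] - scores[order[-2]] < margin:
            return None
        return tied[int(order[-1])]


def select_solution(
    solutions: Sequence[FitSolution], lam: float, tie_tol: float = 0.5
) -> FitSolution:
    """Pick the solution with the highest penalised log-likelihood.

    The penalty ``lam * fraction_non_neutral`` disfavours solutions that
    relabel most of the genome as aberrant (e.g. calling a genome-wide gain
    instead of the complementary smaller loss).  Relative depth cannot
    distinguish mirror ploidy interpretations (shifting every state label by
    one) unless the genome contains an absolute anchor such as a homozygous
    deletion, so solutions within ``tie_tol`` log-likelihood units of the
    best are treated as tied and resolved deterministically: smaller
    aberrant fraction, then normalisation ploidy closest to diploid, then
    smaller tumour fraction.
    """
    best_pen = max(s.penalized_loglik(lam) for s in solutions)
    tied = [s for s in solutions if s.penalized_loglik(lam) >= best_pen - tie_tol]
    return min(
        tied,
        key=lambda s: (s.frac_nonneutral, abs(s.params.phi - 2.0), s.params.f),
    )


@dataclass
class CopyNumberHMMResults:
    """Fitted copy-number model for one sample.

    Attributes
    ----------
    profile : SegmentProfile
        Tumour fraction, ploidy and integer copy-number segments.
    best : FitSolution
        The selected EM solution (parameters, likelihood, diagnostics).
    solutions : list of FitSolution
        Every initialisation's converged fit, for model-selection inspection.
    """

    model: CopyNumberHMM
    config: HmmConfig
    solutions: list[FitSolution]
    best: FitSolution
    profile: SegmentProfile

    @property
    def params(self) -> HmmParams:
        return self.best.params

    def absolute_copy_number(self) -> np.ndarray:
        """Continuous per-bin tumour copy number (NaN at masked bins)."""
        out = np.full(self.model.grid.n_bins, np.nan)
        v = self.model.ratios.valid
        out[v] = absolute_copy_number(
            self.model.ratios.log2_ratio[v], self.params.f, self.params.phi
        )
        return out

    def summary(self) -> str:
        p = self.profile
        lines = [
            "Copy-number HMM results",
            "=" * 46,
            f"sample:                {p.sample_id}",
            f"valid bins:            {self.model.ratios.n_valid}",
            f"tumour fraction:       {p.tumour_fraction:.4f}",
            f"ploidy (mean CN):      {p.ploidy:.4f}",
            f"normalisation ploidy:  {p.norm_ploidy:.4f}",
            f"emission sigma:        {self.params.sigma:.4f}",
            f"log-likelihood:        {p.loglik:.2f}",
            f"segments:              {p.n_segments}",
            f"fraction non-neutral:  {self.best.frac_nonneutral:.4f}",
            f"zero ctDNA:            {p.zero_ctdna}",
            f"initialisations:       {len(self.solutions)}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plots import plot_profile

        return plot_profile(self.model.ratios, self.profile, ax=ax)


# ---------------------------------------------------------------------- #
# functional wrappers


def viterbi_states(
    ratios: NormalizedRatios, params: HmmParams, link_chromosomes: bool = True
) -> np.ndarray:
    return CopyNumberHMM(
        ratios,
        states=params.states,
        self_transition=params.self_transition,
        emission_floor=params.emission_floor,
        link_chromosomes=link_chromosomes,
    ).viterbi(params)


def em_fit(
    ratios: NormalizedRatios,
    init_f: float,
    init_phi: float,
    self_transition: float = 0.9999,
    max_iter: int = 50,
    tol: float = 1e-5,
    sigma0: float = 0.2,
) -> FitSolution:
    return CopyNumberHMM(ratios, self_transition=self_transition).fit_em(
        init_f, init_phi, sigma0=sigma0, max_iter=max_iter, tol=tol
    )


def estimate_profile(
    ratios: NormalizedRatios, config: HmmConfig | None = None
) -> SegmentProfile:
    config = config or HmmConfig()
    model = CopyNumberHMM(
        ratios,
        states=config.states,
        self_transition=config.self_transition,
        emission_floor=config.emission_floor,
        link_chromosomes=config.link_chromosomes,
    )
    return model.fit(config).profile


def uniform_resegment(
    profiles: Sequence[SegmentProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express all profiles on the union of their segment boundaries.

    Returns ``(segments, cn_matrix)`` where ``segments`` has columns chrom,
    start, end, length and ``cn_matrix`` is samples x common-segments with
    each sample's integer copy number (NaN where a sample has no coverage).
    Values are unchanged within each sample's original segments, so every
    sample's length-weighted mean copy number is conserved exactly over its
    covered length.
    """
    if not profiles:
        raise ValueError("no profiles")
    chroms: list[str] = []
    for p in profiles:
        for c in p.segments["chrom"]:
            if c not in chroms:
                chroms.append(c)
    seg_rows = []
    per_sample_cols: dict[str, list[float]] = {p.sample_id: [] for p in profiles}
    if len(per_sample_cols) != len(profiles):
        raise ValueError("duplicate sample ids")
    for chrom in chroms:
        bounds: set[int] = set()
        for p in profiles:
            sub = p.segments[p.segments["chrom"] == chrom]
            bounds.update(int(x) for x in sub["start"])
            bounds.update(int(x) for x in sub["end"])
        edges = sorted(bounds)
        for lo, hi in zip(edges[:-1], edges[1:]):
            covered_any = False
            vals = {}
            for p in profiles:
                sub = p.segments[p.segments["chrom"] == chrom]
                hit = sub[(sub["start"] <= lo) & (sub["end"] >= hi)]
                if len(hit):
                    vals[p.sample_id] = float(hit.iloc[0]["cn"])
                    covered_any = True
                else:
                    vals[p.sample_id] = float("nan")
            if not covered_any:
                continue
            seg_rows.append({"chrom": chrom, "start": lo, "end": hi, "length": hi - lo})
            for sid, v in vals.items():
                per_sample_cols[sid].append(v)
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "length"])
    cn_matrix = pd.DataFrame(per_sample_cols).T
    cn_matrix.index.name = "sample_id"
    return segments, cn_matrix
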