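"""Synthetic ctDNA cohort generator.

Emulates the study design the pipeline is built for: plasma lcWGS of ~30
advanced oesophagogastric adenocarcinoma patients at ~12 million 100 bp reads
per sample, reduced to binned read counts.  The generator produces

* ground-truth tumour genomes as mixtures of clones with arm-level gains and
  losses plus narrow high-level focal amplifications at driver-gene loci,
* binned read counts with multiplicative GC and mappability bias and
  negative-binomial overdispersion,
* clinical metadata (cfDNA concentration, liver metastases, primary in situ,
  tumour site, response group, overall/progression-free survival), and
* paired progression samples obtained by shifting the clone mixture weights,
  optionally with new private events.

Counts are simulated directly at bin level — the analysis consumes only bin
counts, so no read-level simulation is needed.  Defaults reproduce the study
conditions: a 23.3% zero-ctDNA rate, tumour fractions with medians of ~18%
(liver metastases) vs ~7% (no liver metastases), cfDNA concentrations with a
median of ~8.9 ng/mL, and overall survival whose hazard depends on the
ctDNA-concentration tertile (medians 19.5 / 11.3 / 12.8 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bins import (
    HG19_AUTOSOMES,
    HG19_CENTROMERES,
    BinCounts,
    BinGrid,
    build_bin_grid,
    driver_gene_catalog,
)

__all__ = [
    "TruthParams",
    "TruthProfile",
    "ProgressionShift",
    "CohortConfig",
    "annotate_grid",
    "simulate_truth_profile",
    "simulate_bin_counts",
    "simulate_progression_pair",
    "simulate_cohort",
    "truth_on_grid",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------- #
# grid annotation


def annotate_grid(
    grid: BinGrid,
    seed,
    gc_mean: float = 0.42,
    gc_sd: float = 0.05,
    low_mapp_fraction: float = 0.05,
) -> BinGrid:
    """Draw realistic GC fractions and mappability scores for a grid.

    GC is approximately normal around 0.42 (clipped to [0.30, 0.65]); most
    bins are near-perfectly mappable, with a configurable fraction of
    low-mappability bins (< 0.9) to exercise the masking rules.
    """
    rng = _rng(seed)
    gc = np.clip(rng.normal(gc_mean, gc_sd, grid.n_bins), 0.30, 0.65)
    mapp = 1.0 - rng.uniform(0.0, 0.05, grid.n_bins)
    n_low = int(round(low_mapp_fraction * grid.n_bins))
    if n_low:
        low = rng.choice(grid.n_bins, size=n_low, replace=False)
        mapp[low] = rng.uniform(0.3, 0.88, n_low)
    return grid.with_annotations(gc, mapp)


def arm_intervals(grid: BinGrid) -> list[tuple[str, int, int]]:
    """(chrom, start, end) of each chromosome arm on the grid's chromosomes.

    Uses hg19 centromere positions when the chromosome is a named hg19
    autosome, otherwise splits at 45% of the length.
    """
    arms = []
    for chrom in grid.chrom_names:
        length = grid.chrom_lengths[chrom]
        centro = HG19_CENTROMERES.get(chrom)
        if centro is None or centro >= length:
            # scaled-down or non-hg19 chromosome: split at 45% of the length
            centro = int(0.45 * length)
        if centro > 0:
            arms.append((chrom, 0, centro))
        if centro < length:
            arms.append((chrom, centro, length))
    return arms


# ---------------------------------------------------------------------- #
# truth profiles


@dataclass
class TruthParams:
    """Event counts and copy-number ranges for a simulated tumour genome."""

    n_arm_events: int = 8
    base_cn: int = 2
    n_clones: int = 1
    n_private_events: int = 2
    clone_weights: tuple[float, ...] | None = None
    focal_genes: tuple[tuple[str, int], ...] = ()
    focal_width: int | None = None
    max_focal_width: int = 3_000_000
    # focal homozygous deletions (CN 0), a recurrent feature of CIN genomes
    # (CDKN2A, SMAD4, ...) and the absolute-copy-number anchor that makes
    # tumour ploidy identifiable from relative depth alone
    n_homdel: int = 3
    homdel_width: int = 3_000_000
    min_cn: int = 0
    max_cn: int = 6


@dataclass
class TruthProfile:
    """Ground-truth tumour genome: clone mixture on a bin grid.

    ``clones`` is a list of (weight, per-bin integer copy number); weights sum
    to one.  The mixed copy number and the tumour ploidy (length-weighted mean
    of the mixed genome) are derived properties.
    """

    sample_id: str
    grid: BinGrid
    tumour_fraction: float
    clones: list[tuple[float, np.ndarray]]
    focal_amps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.tumour_fraction <= 1:
            raise ValueError("tumour fraction must be in [0, 1]")
        w = sum(w for w, _ in self.clones)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"clone weights sum to {w}, expected 1")
        for _, cn in self.clones:
            if len(cn) != self.grid.n_bins:
                raise ValueError("clone CN length must match the grid")

    @property
    def mixed_cn(self) -> np.ndarray:
        """Per-bin copy number of the mixed tumour genome (continuous)."""
        out = np.zeros(self.grid.n_bins)
        for w, cn in self.clones:
            out += w * cn
        return out

    @property
    def ploidy(self) -> float:
        """Length-weighted mean copy number of the mixed tumour genome."""
        lengths = self.grid.lengths.astype(float)
        return float(np.sum(lengths * self.mixed_cn) / lengths.sum())


def _apply_interval(cn: np.ndarray, grid: BinGrid, chrom: str, start: int, end: int, value: int) -> None:
    mid = (grid.start + grid.end) // 2
    sel = (grid.bin_chrom == chrom) & (mid >= start) & (mid < end)
    cn[sel] = value


def simulate_truth_profile(
    grid: BinGrid,
    params: TruthParams | None = None,
    seed=0,
    sample_id: str = "sim",
    tumour_fraction: float = 0.3,
) -> TruthProfile:
    """Draw a clone mixture with arm-level events and focal amplifications.

    Trunk (shared) arm events are drawn first; each clone beyond the first
    receives additional private arm events.  Focal amplifications are
    truncal, centred on the named driver-gene locus and at most
    ``params.max_focal_width`` wide.
    """
    params = params or TruthParams()
    rng = _rng(seed)
    arms = arm_intervals(grid)
    n_needed = (
        params.n_arm_events
        + (params.n_clones - 1) * params.n_private_events
        + params.n_homdel
    )
    if n_needed > len(arms):
        raise ValueError(
            f"{n_needed} arm events requested but only {len(arms)} arms available"
        )
    order = rng.permutation(len(arms))
    trunk_arms = [arms[i] for i in order[: params.n_arm_events]]
    spare = list(order[params.n_arm_events:])

    base = np.full(grid.n_bins, params.base_cn, dtype=np.int64)
    for chrom, start, end in trunk_arms:
        delta = int(rng.choice([-1, 1, 1, 2]))
        value = int(np.clip(params.base_cn + delta, params.min_cn, params.max_cn))
        if value == params.base_cn:
            value = min(params.base_cn + 1, params.max_cn)
        _apply_interval(base, grid, chrom, start, end, value)

    # truncal focal homozygous deletions, placed on arms untouched by the
    # arm-level events so the CN-0 anchor is unambiguous
    for _ in range(params.n_homdel):
        if not spare:
            break
        ai = int(spare.pop())
        chrom, a_start, a_end = arms[ai]
        if a_end - a_start <= params.homdel_width:
            continue
        pos = int(rng.uniform(a_start, a_end - params.homdel_width))
        _apply_interval(base, grid, chrom, pos, pos + params.homdel_width, 0)

    clones_cn = [base]
    for _ in range(params.n_clones - 1):
        cn = base.copy()
        for _ in range(params.n_private_events):
            ai = int(spare.pop())
            chrom, start, end = arms[ai]
            delta = int(rng.choice([-1, 1, 1, 2]))
            value = int(np.clip(params.base_cn + delta, params.min_cn, params.max_cn))
            if value == params.base_cn:
                value = min(params.base_cn + 1, params.max_cn)
            _apply_interval(cn, grid, chrom, start, end, value)
        clones_cn.append(cn)

    focal: list[tuple[str, int]] = []
    if params.focal_genes:
        catalog = driver_gene_catalog().records.set_index("gene")
        for gene, amp_cn in params.focal_genes:
            if gene not in catalog.index:
                raise ValueError(f"gene {gene} not in the driver catalog")
            rec = catalog.loc[gene]
            if rec["chrom"] not in grid.chrom_names:
                continue
            centre = (int(rec["start"]) + int(rec["end"])) // 2
            gene_w = int(rec["end"]) - int(rec["start"])
            if params.focal_width is not None:
                width = int(params.focal_width)
            else:
                lo = min(max(gene_w, 1_000_000), params.max_focal_width)
                width = int(rng.uniform(lo, params.max_focal_width))
            width = min(width, params.max_focal_width)
            start = max(0, centre - width // 2)
            end = min(grid.chrom_lengths[rec["chrom"]], start + width)
            for cn in clones_cn:
                _apply_interval(cn, grid, rec["chrom"], start, end, int(amp_cn))
            focal.append((gene, int(amp_cn)))

    if params.clone_weights is not None:
        weights = list(params.clone_weights)
        if len(weights) != params.n_clones:
            raise ValueError("clone_weights length must equal n_clones")
    elif params.n_clones == 1:
        weights = [1.0]
    else:
        weights = list(rng.dirichlet(np.full(params.n_clones, 5.0)))
    return TruthProfile(
        sample_id=sample_id,
        grid=grid,
        tumour_fraction=float(tumour_fraction),
        clones=list(zip(weights, clones_cn)),
        focal_amps=focal,
    )


def truth_on_grid(truth: TruthProfile, grid: BinGrid) -> TruthProfile:
    """Re-express a truth profile on another grid (e.g. 500 kb -> 50 kb).

    Each new bin takes the copy number of the base-grid bin containing its
    midpoint, so the piecewise-constant truth is preserved up to half-bin
    boundary shifts.
    """
    base = truth.grid
    new_clones = []
    mapping = np.full(grid.n_bins, -1, dtype=np.int64)
    for chrom in grid.chrom_names:
        sel_new = grid.bin_chrom == chrom
        sel_base = base.bin_chrom == chrom
        if not sel_base.any():
            raise ValueError(f"chromosome {chrom} absent from the base grid")
        base_idx = np.flatnonzero(sel_base)
        mids = (grid.start[sel_new] + grid.end[sel_new]) // 2
        pos = np.searchsorted(base.start[base_idx], mids, side="right") - 1
        mapping[sel_new] = base_idx[np.clip(pos, 0, base_idx.size - 1)]
    for w, cn in truth.clones:
        new_clones.append((w, cn[mapping]))
    return TruthProfile(
        sample_id=truth.sample_id,
        grid=grid,
        tumour_fraction=truth.tumour_fraction,
        clones=new_clones,
        focal_amps=list(truth.focal_amps),
    )


# ---------------------------------------------------------------------- #
# read counts


def gc_bias_curve(gc: np.ndarray, curvature: float = 8.0, peak: float = 0.45) -> np.ndarray:
    """Multiplicative quadratic GC bias, maximal at ``peak`` and floored."""
    return np.maximum(1.0 - curvature * (np.asarray(gc) - peak) ** 2, 0.1)


def simulate_bin_counts(
    truth: TruthProfile,
    grid: BinGrid | None = None,
    n_reads: int = 12_000_000,
    gc_curvature: float = 8.0,
    gc_peak: float = 0.45,
    dispersion: float = 100.0,
    seed=0,
) -> BinCounts:
    """Draw negative-binomial bin counts for a truth profile.

    Expected counts are proportional to
    ``bin_length * (f * CN_tumour + (1 - f) * 2) * gc_bias * mappability``,
    scaled so the expected total equals ``n_reads``.  ``dispersion`` is the
    negative-binomial size parameter (variance ``mu + mu^2 / size``);
    ``numpy.inf`` gives Poisson counts.
    """
    grid = grid or truth.grid
    if grid is not truth.grid and not grid.same_frame(truth.grid):
        truth = truth_on_grid(truth, grid)
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(seed)
    f = truth.tumour_fraction
    signal = f * truth.mixed_cn + (1.0 - f) * 2.0
    mass = (
        grid.lengths.astype(float)
        * signal
        * gc_bias_curve(grid.gc, gc_curvature, gc_peak)
        * grid.mappability
    )
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate input: zero total expected mass")
    mu = mass / total * n_reads
    if np.isfinite(dispersion):
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p)
    else:
        counts = rng.poisson(mu)
    return BinCounts(sample_id=truth.sample_id, grid=grid, counts=counts)


# ---------------------------------------------------------------------- #
# progression pairs


@dataclass
class ProgressionShift:
    """How the clone mixture changes between pretreatment and progression."""

    new_weights: tuple[float, ...] | None = None
    n_new_events: int = 0
    new_tumour_fraction: float | None = None


def simulate_progression_pair(
    truth_pre: TruthProfile,
    shift: ProgressionShift,
    seed=0,
) -> TruthProfile:
    """Derive the progression-timepoint truth from the pretreatment truth.

    Trunk events are preserved; the mixed profile changes only where the
    reweighted clones differ or where new private events land.
    """
    rng = _rng(seed)
    weights = (
        list(shift.new_weights)
        if shift.new_weights is not None
        else [w for w, _ in truth_pre.clones]
    )
    if len(weights) != len(truth_pre.clones):
        raise ValueError("new_weights length must match the number of clones")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"shifted weights sum to {sum(weights)}, expected 1")
    clones = [(w, cn.copy()) for w, (_, cn) in zip(weights, truth_pre.clones)]
    if shift.n_new_events:
        grid = truth_pre.grid
        arms = arm_intervals(grid)
        picks = rng.choice(len(arms), size=shift.n_new_events, replace=False)
        w_last, cn_last = clones[-1]
        for ai in picks:
            chrom, start, end = arms[int(ai)]
            delta = int(rng.choice([-1, 1, 1, 2]))
            mid = (grid.start + grid.end) // 2
            sel = (grid.bin_chrom == chrom) & (mid >= start) & (mid < end)
            cn_last[sel] = np.clip(cn_last[sel] + delta, 0, 6)
        clones[-1] = (w_last, cn_last)
    f = (
        shift.new_tumour_fraction
        if shift.new_tumour_fraction is not None
        else truth_pre.tumour_fraction
    )
    return TruthProfile(
        sample_id=truth_pre.sample_id + "-prog",
        grid=truth_pre.grid,
        tumour_fraction=float(f),
        clones=clones,
        focal_amps=list(truth_pre.focal_amps),
    )


# ---------------------------------------------------------------------- #
# whole cohort


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Rates and medians mirror the cohort the pipeline emulates: 30 patients,
    7/30 with zero ctDNA, 16/30 with liver metastases (tumour-fraction median
    ~18% vs ~7% without), cfDNA median 8.88 ng/mL, overall-survival medians
    of 19.5 / 11.3 / 12.8 months across ctDNA-concentration tertiles, 20/30
    patients with a progression sample, and responder fraction 13/23 among
    detectable cases with the progression tumour fraction falling in
    responders (x0.45 median) but not in nonresponders (x1.2).
    """

    n_patients: int = 30
    zero_ctdna_fraction: float = 7 / 30
    liver_mets_rate: float = 16 / 30
    primary_in_situ_rate: float = 23 / 30
    gastric_rate: float = 6 / 30
    f_median_liver: float = 0.1801
    f_median_no_liver: float = 0.0723
    f_log_sd: float = 0.7
    f_min: float = 0.04
    f_max: float = 0.55
    cfdna_median: float = 8.88
    cfdna_log_sd: float = 0.8
    os_median_by_tertile: tuple[float, float, float] = (19.5, 11.3, 12.8)
    os_censor_months: float = 36.0
    pfs_median: float = 7.0
    pfs_censor_months: float = 24.0
    pairing_fraction: float = 20 / 30
    responder_fraction: float = 13 / 23
    prog_f_multiplier_responder: float = 7.59 / 17.00
    prog_f_multiplier_nonresponder: float = 13.58 / 11.27
    prog_f_log_sd: float = 0.3
    prog_n_new_events: int = 1
    n_reads: int = 12_000_000
    bin_width: int = 500_000
    chrom_lengths: Mapping[str, int] | None = None
    dispersion: float = 100.0
    gc_curvature: float = 8.0
    gc_peak: float = 0.45
    low_mapp_fraction: float = 0.05
    truth: TruthParams = field(default_factory=lambda: TruthParams(n_clones=2))
    simulate_counts: bool = True

    def validate(self) -> None:
        if not 0 <= self.zero_ctdna_fraction <= 1:
            raise ValueError("zero_ctdna_fraction must be in [0, 1]")
        if not 0 <= self.pairing_fraction <= 1:
            raise ValueError("pairing_fraction must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")


def simulate_cohort(
    config: CohortConfig | None = None, seed=0
) -> tuple[list[BinCounts], pd.DataFrame, list[TruthProfile]]:
    """Simulate the full cohort: counts, metadata table, truth profiles.

    Deterministic under ``seed``.  Exactly ``round(zero_ctdna_fraction *
    n_patients)`` patients carry a zero-tumour-fraction truth (assigned
    preferentially to patients without liver metastases, matching the
    clinical pattern that undetectable cases had low metastatic burden).
    """
    config = config or CohortConfig()
    config.validate()
    rng = _rng(seed)
    chrom_lengths = config.chrom_lengths or HG19_AUTOSOMES
    grid = annotate_grid(
        build_bin_grid(chrom_lengths, config.bin_width),
        rng,
        low_mapp_fraction=config.low_mapp_fraction,
    )

    n = config.n_patients
    liver = rng.random(n) < config.liver_mets_rate
    in_situ = rng.random(n) < config.primary_in_situ_rate
    gastric = rng.random(n) < config.gastric_rate
    responder = rng.random(n) < config.responder_fraction

    n_zero = int(round(config.zero_ctdna_fraction * n))
    no_liver_idx = list(np.flatnonzero(~liver))
    liver_idx = list(np.flatnonzero(liver))
    rng.shuffle(no_liver_idx)
    rng.shuffle(liver_idx)
    zero_set = set((no_liver_idx + liver_idx)[:n_zero])

    fractions = np.zeros(n)
    for i in range(n):
        if i in zero_set:
            continue
        median = config.f_median_liver if liver[i] else config.f_median_no_liver
        f = float(np.exp(rng.normal(np.log(median), config.f_log_sd)))
        fractions[i] = float(np.clip(f, config.f_min, config.f_max))
    cfdna = np.exp(rng.normal(np.log(config.cfdna_median), config.cfdna_log_sd, n))
    ctdna_conc = cfdna * fractions

    # survival: exponential with hazard set by the ctDNA-concentration tertile
    from .metrics import tertile_assign

    tertiles = tertile_assign(ctdna_conc)
    tert_idx = {"low": 0, "medium": 1, "high": 2}
    os_months = np.empty(n)
    os_event = np.empty(n, dtype=int)
    pfs_months = np.empty(n)
    pfs_event = np.empty(n, dtype=int)
    for i in range(n):
        med = config.os_median_by_tertile[tert_idx[tertiles[i]]]
        t = rng.exponential(med / np.log(2))
        os_months[i] = min(t, config.os_censor_months)
        os_event[i] = int(t <= config.os_censor_months)
        tp = rng.exponential(config.pfs_median / np.log(2))
        pfs_months[i] = min(tp, config.pfs_censor_months)
        pfs_event[i] = int(tp <= config.pfs_censor_months)

    counts: list[BinCounts] = []
    truths: list[TruthProfile] = []
    meta_rows: list[dict] = []

    detectable = [i for i in range(n) if fractions[i] > 0]
    n_pairs = min(len(detectable), int(round(config.pairing_fraction * n)))
    paired = set(detectable[:n_pairs])

    for i in range(n):
        pid = f"P{i + 1:03d}"
        sid = f"{pid}-pre"
        truth = simulate_truth_profile(
            grid,
            config.truth,
            seed=rng,
            sample_id=sid,
            tumour_fraction=fractions[i],
        )
        truths.append(truth)
        if config.simulate_counts:
            counts.append(
                simulate_bin_counts(
                    truth,
                    grid,
                    n_reads=config.n_reads,
                    gc_curvature=config.gc_curvature,
                    gc_peak=config.gc_peak,
                    dispersion=config.dispersion,
                    seed=rng,
                )
            )
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": pid,
                "timepoint": "pretreatment",
                "response_group": "responder" if responder[i] else "nonresponder",
                "cfdna_conc": float(cfdna[i]),
                "os_months": float(os_months[i]),
                "os_event": int(os_event[i]),
                "pfs_months": float(pfs_months[i]),
                "pfs_event": int(pfs_event[i]),
                "liver_mets": "yes" if liver[i] else "no",
                "primary_in_situ": "yes" if in_situ[i] else "no",
                "site": "gastric" if gastric[i] else "nongastric",
            }
        )
        if i in paired:
            mult = (
                config.prog_f_multiplier_responder
                if responder[i]
                else config.prog_f_multiplier_nonresponder
            )
            new_f = float(
                np.clip(
                    fractions[i]
                    * np.exp(rng.normal(np.log(mult), config.prog_f_log_sd)),
                    0.0,
                    config.f_max,
                )
            )
            n_clones = len(truth.clones)
            if n_clones > 1:
                w = rng.dirichlet(np.full(n_clones, 2.0))
                new_weights = tuple(float(x) for x in w)
            else:
                new_weights = None
            truth_prog = simulate_progression_pair(
                truth,
                ProgressionShift(
                    new_weights=new_weights,
                    n_new_events=config.prog_n_new_events,
                    new_tumour_fraction=new_f,
                ),
                seed=rng,
            )
            truths.append(truth_prog)
            if config.simulate_counts:
                counts.append(
                    simulate_bin_counts(
                        truth_prog,
                        grid,
                        n_reads=config.n_reads,
                        gc_curvature=config.gc_curvature,
                        gc_peak=config.gc_peak,
                        dispersion=config.dispersion,
                        seed=rng,
                    )
                )
            cf_prog = float(
                np.exp(rng.normal(np.log(config.cfdna_median), config.cfdna_log_sd))
            )
            meta_rows.append(
                {
                    "sample_id": truth_prog.sample_id,
                    "patient_id": pid,
                    "timepoint": "progression",
                    "response_group": "responder" if responder[i] else "nonresponder",
                    "cfdna_conc": cf_prog,
                    "os_months": float(os_months[i]),
                    "os_event": int(os_event[i]),
                    "pfs_months": float(pfs_months[i]),
                    "pfs_event": int(pfs_event[i]),
                    "liver_mets": "yes" if liver[i] else "no",
                    "primary_in_situ": "yes" if in_situ[i] else "no",
                    "site": "gastric" if gastric[i] else "nongastric",
                }
            )

    meta = pd.DataFrame(meta_rows)
    return counts, meta, truths
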