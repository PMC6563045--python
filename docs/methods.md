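# Methods

This note documents the models and procedures implemented in `scnatrack`,
their assumptions, the parameters that matter, and the design decisions
taken where the design was genuinely open.

## Bias correction and normalisation

Raw per-bin read counts are corrected as

```
corrected_i = count_i / (length_i · gc_curve(gc_i) · mappability_i)
log2_ratio_i = log2(corrected_i / median(corrected over valid bins))
```

`gc_curve` is a lowess fit (default span 0.3, two robustifying iterations)
of count-per-unit-length against GC fraction, normalised to mean one over
the fitted bins. Because lowess cost grows quadratically, the fit uses a
deterministic, rank-stratified subsample of at most 5,000 bins; at 500 kb
resolution that is essentially all bins, at 50 kb about one in eleven,
which recovery tests show is ample for a smooth one-dimensional curve.
Bins are masked when mappability < 0.9 (standard read-depth practice), when
the bin has zero length, or when the count is zero (at ~2,000 reads per
500 kb bin a true zero indicates an unmappable region, so masking is safer
than pseudocounting). The reference is the sample's own valid-bin median —
no panel of normals is assumed, though `correct_counts(reference_rates=…)`
exposes a hook for one. Median-centring makes the downstream model's
normalisation ploidy interpretable as the *modal* copy number (see below).

## Copy-number mixture HMM

cfDNA is modelled as a two-component mixture: a tumour fraction `f` of
fragments drawn from a tumour genome with integer copy number `c_i` per
bin, and `1 − f` from diploid normal cells. The expected log2 ratio of a
bin is `mu(c) = log2((f·c + (1−f)·2) / (f·phi + (1−f)·2))`. States
c ∈ {0..5} evolve along the genome as a Markov chain with a scalar
self-transition probability (default 0.9999, i.e. a strong smoothness
prior; higher amplifications are deliberately left to the 50 kb focal
caller). Emissions are Gaussian with one shared scale `sigma`.

Estimation: EM from a grid of initialisations (f ∈ {0.05…0.6} ×
phi ∈ {2, 3}). The E-step is scaled forward–backward; the M-step maximises
the expected complete-data log-likelihood over (f, phi) numerically
(L-BFGS-B on the state-level sufficient statistics; bounds f ∈
[0.001, 0.98], phi ∈ [1.2, 5.5]) with `sigma` in closed form. The
log-likelihood is checked to be non-decreasing; a decrease beyond
tolerance raises rather than silently continuing.

### Reported ploidy vs normalisation ploidy

With median-centred input, the likelihood identifies `phi` as the copy
number that maps to ratio zero — the *modal* copy number — while "tumour
ploidy" as usually plotted is the *mean* copy number. The profile therefore
reports ploidy as the length-weighted mean of the decoded copy numbers and
keeps the fitted normalisation ploidy separately (`norm_ploidy`), which is
the value needed to invert ratios into absolute copy number.

### Identifiability and model selection

Relative depth cannot, in general, identify ploidy: shifting every state
label by one (c → c ± 1, phi → phi ± 1) with f′ = 2f/(2 ∓ f) reproduces
every emission mean exactly, and "compressed ladder" solutions (e.g.
c → 2 + 2(c − 2) at roughly half f) are equally exact on genomes whose
copy numbers stay in mid-range. Real genomes break these degeneracies only
through absolute anchors — bins at the edges of the state ladder, above
all homozygous deletions (CN 0), which cannot be shifted further down.
Accordingly:

- **Selection** maximises `loglik − lam · frac_nonneutral` with
  `frac_nonneutral` measured against the solution's own rounded
  normalisation ploidy (so mirrors are scored on equal footing) and
  `lam = 5`: whole-genome-relabelling solutions must earn ≥ 5
  log-likelihood units per unit of relabelled genome fraction, which
  exceeds the typical flexibility advantage (~2–3 units) a denser ladder
  gains by fitting segment-mean noise.
- **Homozygous-deletion cap**: solutions decoding more than 2% of the
  genome as CN 0 are inadmissible. Arm-wide homozygous deletion is not
  biologically viable; such solutions are always half-f reinterpretations
  of single-copy losses.
- **Anchor tie-break**: candidates within 0.5 log-likelihood units of the
  best are compared only on ladder-edge bins (decoded CN 0 or CN 5 by any
  candidate), the bins that actually distinguish mirror interpretations; a
  winner must lead by ≥ 2 log-likelihood units there. Unresolved ties fall
  back to a deterministic preference: smaller aberrant fraction, then
  normalisation ploidy nearest 2, then smaller f.
- **Linked chromosomes**: chromosomes are decoded as one chain (a state
  change at a chromosome boundary costs a transition like any other).
  With independent per-chromosome chains and a uniform initial
  distribution, every chromosome could adopt a different state for free,
  letting finely spaced low-f solutions harvest chromosome-mean sampling
  noise (~0.01 log2 units at ~250 bins per chromosome). Per-chromosome
  chains remain available (`HmmConfig.link_chromosomes = False`).

**Known limitation.** At tumour fractions below roughly 0.15 the per-copy
ratio spacing approaches the segment-mean noise scale, and anchor evidence
(which scales with f²) can fall below the decoding threshold. A
near-triploid sample at f ≈ 0.11 whose homozygous deletions span only a
few bins may then be reported under the nearest-diploid convention, with
every copy number off by one. This is an information limit of depth-only
relative data, not a software defect; the recovery tests quantify it (19
of 20 simulated samples across f ∈ [0.1, 0.5] recover at the default
conditions, with mean tumour-fraction error ≈ 0.006 and mean ploidy error
≈ 0.05).

### Zero-ctDNA rule

A sample is reported as having no detectable ctDNA when the selected
solution has f < 0.03 or decodes less than 1% of the genome as aberrant.
The profile is then flat at copy number 2 with f = 0. Both thresholds are
configuration values; they operationalise "tumour content of zero" for a
depth-only caller.

### Viterbi details

Ties in the Viterbi maximisation break toward the state nearest copy
number 2, so a borderline bin never invents an aberration. Masked bins are
skipped; valid bins flanking a masked gap are treated as adjacent.

## Focal amplifications (50 kb)

Each 50 kb bin's ratio is converted to continuous absolute copy number
using the 500 kb fit's (f, norm_ploidy). Maximal runs of ≥ 2 consecutive
valid bins with CN ≥ ploidy + 3, at most 10 Mb wide, are called; runs
separated by a single sub-threshold valid bin are merged, and masked bins
never split a run (they carry no evidence). All thresholds are exposed in
`FocalThresholds`. The driver-gene catalog is a packaged static table of
~20 approximate hg19 loci recurrently amplified in oesophagogastric
adenocarcinoma; genes are attached by half-open interval overlap.

## Metrics

- **wGII**: per autosome, the fraction of *valid-bin* length at copy number
  different from the rounded ploidy; the index is the unweighted mean over
  autosomes (chromosomes with no valid bins are excluded). Valid-bin length
  is used so masked regions do not dilute the index.
- **Non-ploidy segment count**: merged segments with CN ≠ round(ploidy).
- **ctDNA concentration** = cfDNA concentration (ng/mL plasma) × tumour
  fraction.
- **Tertiles** are rank-based; with n not divisible by 3 the extra samples
  go to the *lower* tertiles first (n = 7 → 3/2/2), ties break by stable
  input order. This makes survival groupings reproducible and invariant to
  monotone transforms.
- The rounding convention everywhere is round-half-up (2.5 → 3).

## Cohort and longitudinal analyses

Profiles are re-expressed on the union of all samples' segment boundaries;
values are unchanged within original segments, so each sample's
length-weighted mean copy number is conserved exactly. Gain/loss calls are
relative to each sample's own rounded ploidy (a CN-3 segment in a
near-triploid genome is neutral). Group-unique regions are maximal runs
where one group has ≥ 1 carrier and the other none in the same direction,
filtered to ≥ 1 Mb (suppressing single-bin artefacts); regions carried by
more than a third of the group are flagged "frequent". The minimal
consistent region is the leftmost maximal contiguous run at the maximum
carrier count — the core shared by all contributing cases.

Paired pretreatment/progression differencing subtracts continuous absolute
copy number computed from each sample's **segment-mean** log2 ratios (the
caller's segmented output). Raw per-bin ratios would be useless here: at
f ≈ 0.3 a single 500 kb bin's absolute-CN noise is ~0.7 copies, so the
±0.8 rule would fire on a large fraction of unchanged bins, whereas
segment means at arm scale carry ~0.05-copy noise. A bin counts as changed
only when |ΔCN| *strictly* exceeds 0.8 — enriching for aneuploidies that
occurred in the dominant cell population. Pairs are eligible only when
both tumour fractions exceed 0.10 and are similar (ratio ≤ 2.5, a
configurable operationalisation of "similar tumour content"); ineligible
pairs carry a reason string and no change statistics. An alternative
ploidy-centred difference (subtracting each sample's mean ploidy first) is
available via `PairedChangeConfig.ploidy_centred`.

Hypothesis tests: Mann–Whitney U uses exact enumeration of all labelings
(tie-aware via midranks) when the combined sample size is ≤ 12, otherwise
the normal approximation with tie and continuity correction; the tie-free
rank-count recursion is also provided as an exact reference at any n. The
log-rank machinery reports both the k-group chi-square (k − 1 df) and the
rank-score trend variant (1 df) for ordered tertiles; Kaplan–Meier curves
come from lifelines. No multiple-testing correction is applied; p-values
are reported raw, as is conventional for exploratory cohort description.

## Synthetic cohort generator

The generator emulates the assay this pipeline targets: ~30 patients,
12 million 100 bp reads per plasma sample binned at 500 kb (and 50 kb for
focal detection), tumour fractions 0–0.55 with a 23.3% zero-ctDNA rate
assigned preferentially to patients without liver metastases, lognormal
tumour-fraction distributions with medians 18% (liver metastases) vs 7.2%
(none), cfDNA concentrations with median 8.88 ng/mL, exponential overall
survival with medians 19.5/11.3/12.8 months across ctDNA-concentration
tertiles, and progression samples for two thirds of patients whose tumour
fraction falls in responders (×0.45 median) but not in nonresponders
(×1.2).

Tumour genomes are clone mixtures: a trunk with ~8 arm-level events (CN
1–6, gain-biased), optional private arm events per extra clone, truncal
focal amplifications at catalog driver loci, and 3 focal homozygous
deletions of 3 Mb — a recurrent feature of chromosomally unstable
genomes (CDKN2A, SMAD4, …) and, importantly, the absolute anchor that
makes ploidy identifiable from depth alone. Counts are negative-binomial
(size 100, i.e. ~10% excess CV over Poisson, matching good-quality lcWGS
at 500 kb) around means proportional to
`length · (f·CN + (1−f)·2) · gc_bias · mappability`, with a multiplicative
quadratic GC bias peaking at GC 0.45 and 5% low-mappability bins.

What the generator does **not** model: read-level effects (fragment-size
structure, sequencing error), replication-timing or fragment-end biases,
subclonal point events below arm scale, and correlated GC structure along
the genome. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
artefact of real libraries; the bias-correction and masking stages are
exactly the places where real data deviate first.

## Problem sizes

The test suite runs the recovery benchmarks at the study conditions (20
samples × 12 M reads at 500 kb for parameter recovery; 20 zero-ctDNA
replicates; 20 focal replicates on a two-chromosome genome at matched
per-bin depth; 20 paired-shift replicates genome-wide) and completes in a
few minutes. `scripts/acceptance.py` repeats the same measurements at
modestly reduced replicate counts (12/8/10/6) chosen to keep a full rerun
within a few minutes on one CPU; the quantities it reports are means, so
replicate count affects only their sampling error.
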