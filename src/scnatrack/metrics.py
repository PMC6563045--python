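"""Per-sample chromosomal-instability and circulating-DNA metrics.

Three circulating DNA metrics are computed per sample: (1) the total cfDNA
concentration extracted from plasma (ng/mL), (2) the estimated ctDNA fraction
of the cfDNA, and (3) the absolute ctDNA concentration, their product.  The
chromosomal-instability metrics are the weighted genomic instability index
(wGII: the mean over autosomes of the fraction of each chromosome's analysed
length at non-ploidy copy number), the number of non-ploidy segments, and the
tumour ploidy itself.  Samples are classified into low/medium/high tertiles
per metric for survival analysis.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .bins import BinGrid
from .profiles import SegmentProfile

__all__ = [
    "wgii",
    "nonploidy_segment_count",
    "ctdna_concentration",
    "tertile_assign",
    "sample_metrics",
]


def ploidy_reference(ploidy: float) -> int:
    """Integer copy number used as the gain/loss reference: round half up."""
    return int(np.floor(ploidy + 0.5))


def wgii(profile: SegmentProfile, grid: BinGrid) -> float:
    """Weighted genomic instability index.

    For each autosome, the fraction of its valid-bin length whose copy number
    differs from the rounded ploidy; wGII is the unweighted mean of these
    per-chromosome fractions (chromosomes with no valid bins are excluded).
    Valid-bin length (not raw chromosome length) is used so masked regions do
    not dilute the index.
    """
    bin_cn = profile.bin_copy_number(grid)
    if np.all(bin_cn < 0):
        raise ValueError("profile has no valid bins")
    ref = ploidy_reference(profile.ploidy)
    lengths = grid.lengths.astype(float)
    fracs = []
    for ci in range(len(grid.chrom_names)):
        sel = (grid.chrom_index == ci) & (bin_cn >= 0)
        total = lengths[sel].sum()
        if total == 0:
            continue
        aberrant = lengths[sel & (bin_cn != ref)].sum()
        fracs.append(aberrant / total)
    return float(np.mean(fracs))


def nonploidy_segment_count(profile: SegmentProfile) -> int:
    """Number of merged segments at non-ploidy copy number."""
    merged = profile.merged_segments()
    ref = ploidy_reference(profile.ploidy)
    return int((merged["cn"] != ref).sum())


def ctdna_concentration(cfdna_conc: float, f: float) -> float:
    """Absolute ctDNA concentration: total cfDNA (ng/mL) x tumour fraction."""
    if cfdna_conc < 0:
        raise ValueError("cfDNA concentration must be non-negative")
    if not 0 <= f <= 1:
        raise ValueError("tumour fraction must be in [0, 1]")
    return float(cfdna_conc) * float(f)


def tertile_assign(values: Sequence[float]) -> list[str]:
    """Rank-based low/medium/high tertiles.

    Group sizes differ by at most one; when the sample count is not divisible
    by three, the extra samples go to the lower tertiles first (n=7 gives
    3/2/2).  Ties are broken by stable input order, so the labelling is
    reproducible and invariant to monotone transforms of the values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("tertile assignment needs at least 3 samples")
    if np.ptp(values) == 0:
        warnings.warn("all values equal; assigning every sample to 'medium'")
        return ["medium"] * n
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=object)
    names = ["low", "medium", "high"]
    pos = 0
    for name, size in zip(names, sizes):
        labels[order[pos : pos + size]] = name
        pos += size
    return labels.tolist()


def sample_metrics(
    profiles: Sequence[SegmentProfile],
    meta: pd.DataFrame,
    grid: BinGrid,
) -> pd.DataFrame:
    """Metric table: one row per profile, joined with cfDNA concentrations.

    Adds tertile labels for the three circulating-DNA metrics and for the
    instability metrics.  ``meta`` must carry sample_id and cfdna_conc.
    """
    cf = meta.set_index("sample_id")["cfdna_conc"]
    rows = []
    for p in profiles:
        conc = float(cf.get(p.sample_id, np.nan))
        rows.append(
            {
                "sample_id": p.sample_id,
                "wgii": wgii(p, grid),
                "nonploidy_segments": nonploidy_segment_count(p),
                "ploidy": p.ploidy,
                "cfdna_conc": conc,
                "ctdna_fraction": p.tumour_fraction,
                "ctdna_conc": ctdna_concentration(conc, p.tumour_fraction)
                if np.isfinite(conc)
                else np.nan,
                "zero_ctdna": p.zero_ctdna,
            }
        )
    df = pd.DataFrame(rows)
    for col in ["cfdna_conc", "ctdna_fraction", "ctdna_conc", "wgii", "nonploidy_segments", "ploidy"]:
        if df[col].notna().all() and len(df) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df[f"{col}_tertile"] = tertile_assign(df[col].to_numpy())
    return df
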