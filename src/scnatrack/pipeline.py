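"""End-to-end pipeline: simulate -> normalize -> call -> focal -> metrics ->
cohort -> longitudinal -> survival.

Every stage is seeded through a single run seed, every output file is
recorded in a manifest with its SHA-256 checksum, and re-running with the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .bins import BinGrid, build_bin_grid, driver_gene_catalog
from .cohort import (
    PairedChangeConfig,
    aberration_matrix,
    change_recurrence,
    group_frequency,
    km_logrank,
    minimal_consistent_region,
    paired_change,
    unique_regions,
)
from .focal import FocalThresholds, annotate_amplifications, call_focal_amplifications, calls_to_frame
from .hmm import CopyNumberHMM, HmmConfig
from .metrics import sample_metrics, tertile_assign
from .normalize import correct_counts, fit_gc_bias
from .simulate import CohortConfig, annotate_grid, simulate_bin_counts, simulate_cohort, truth_on_grid

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = (
    "simulate",
    "normalize",
    "call",
    "focal",
    "metrics",
    "cohort",
    "longitudinal",
    "survival",
)


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    focal: FocalThresholds = field(default_factory=FocalThresholds)
    paired: PairedChangeConfig = field(default_factory=PairedChangeConfig)
    mappability_min: float = 0.9
    gc_span: float = 0.3
    focal_bin_width: int = 50_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "truth" in c and isinstance(c["truth"], dict):
                from .simulate import TruthParams

                t = dict(c["truth"])
                for key in ("clone_weights", "focal_genes"):
                    if t.get(key) is not None:
                        t[key] = tuple(tuple(x) if isinstance(x, list) else x for x in t[key]) if key == "focal_genes" else tuple(t[key])
                c["truth"] = TruthParams(**t)
            if c.get("os_median_by_tertile") is not None:
                c["os_median_by_tertile"] = tuple(c["os_median_by_tertile"])
            d["cohort"] = CohortConfig(**c)
        if "hmm" in d and isinstance(d["hmm"], dict):
            h = dict(d["hmm"])
            for key in ("f_grid", "ploidy_grid", "states"):
                if key in h:
                    h[key] = tuple(h[key])
            d["hmm"] = HmmConfig(**h)
        if "focal" in d and isinstance(d["focal"], dict):
            d["focal"] = FocalThresholds(**d["focal"])
        if "paired" in d and isinstance(d["paired"], dict):
            d["paired"] = PairedChangeConfig(**d["paired"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(verbose: bool, msg: str) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``<outdir>/manifest.json``):
    stage list, parameter echo, and every output file with its checksum.  A
    stage failure aborts the run; the manifest is still written with the
    failing stage named so partial outputs remain identifiable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages_run": [],
        "outputs": {},
        "failed_stage": None,
    }

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    state: dict = {}
    try:
        for stage in config.stages:
            _log(verbose, f"[scnatrack] stage: {stage}")
            _STAGES[stage](config, outdir, state, record)
            manifest["stages_run"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        _write_manifest(outdir, manifest, record)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest(outdir, manifest, record)
    return manifest


def _write_manifest(outdir: Path, manifest: dict, record) -> None:
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------- #
# stages


def _stage_simulate(config: RunConfig, outdir: Path, state: dict, record) -> None:
    counts, meta, truths = simulate_cohort(config.cohort, seed=config.seed)
    grid = counts[0].grid if counts else truths[0].grid
    state.update(counts=counts, meta=meta, truths=truths, grid=grid)
    cdir = outdir / "counts"
    cdir.mkdir(exist_ok=True)
    for c in counts:
        p = cdir / f"{c.sample_id}.counts.tsv"
        sio.write_bin_counts(c, p)
        record(p)
    mpath = outdir / "metadata.tsv"
    sio.write_metadata(meta, mpath)
    record(mpath)
    gpath = outdir / "grid.tsv"
    sio.write_grid(grid, gpath)
    record(gpath)
    tpath = outdir / "truth.json"
    tpath.write_text(
        json.dumps(
            [
                {
                    "sample_id": t.sample_id,
                    "tumour_fraction": round(t.tumour_fraction, 6),
                    "ploidy": round(t.ploidy, 6),
                    "clone_weights": [round(w, 6) for w, _ in t.clones],
                    "focal_amps": [[g, cn] for g, cn in t.focal_amps],
                }
                for t in truths
            ],
            indent=2,
        )
        + "\n"
    )
    record(tpath)
    # 50 kb counts for the focal stage, simulated from the same truths
    if "focal" in config.stages and config.cohort.simulate_counts:
        grid50 = annotate_grid(
            build_bin_grid(grid.chrom_lengths, config.focal_bin_width),
            np.random.default_rng(config.seed + 1),
            low_mapp_fraction=config.cohort.low_mapp_fraction,
        )
        rng50 = np.random.default_rng(config.seed + 2)
        state["counts50"] = [
            simulate_bin_counts(
                truth_on_grid(t, grid50),
                grid50,
                n_reads=config.cohort.n_reads,
                gc_curvature=config.cohort.gc_curvature,
                gc_peak=config.cohort.gc_peak,
                dispersion=config.cohort.dispersion,
                seed=rng50,
            )
            for t in truths
        ]
        state["grid50"] = grid50


def _normalize_many(counts, span, mappability_min):
    out = {}
    for c in counts:
        curve = fit_gc_bias(c, span=span, mappability_min=mappability_min)
        out[c.sample_id] = correct_counts(c, curve, mappability_min=mappability_min)
    return out


def _stage_normalize(config: RunConfig, outdir: Path, state: dict, record) -> None:
    ratios = _normalize_many(state["counts"], config.gc_span, config.mappability_min)
    state["ratios"] = ratios
    rdir = outdir / "ratios"
    rdir.mkdir(exist_ok=True)
    for sid, r in ratios.items():
        df = pd.DataFrame(
            {
                "chrom": r.grid.bin_chrom,
                "start": r.grid.start,
                "end": r.grid.end,
                "log2_ratio": r.log2_ratio,
                "valid": r.valid.astype(int),
            }
        )
        p = rdir / f"{sid}.ratios.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        record(p)


def _stage_call(config: RunConfig, outdir: Path, state: dict, record) -> None:
    profiles = {}
    results = {}
    for sid, r in state["ratios"].items():
        model = CopyNumberHMM(
            r,
            states=config.hmm.states,
            self_transition=config.hmm.self_transition,
            emission_floor=config.hmm.emission_floor,
            link_chromosomes=config.hmm.link_chromosomes,
        )
        res = model.fit(config.hmm)
        profiles[sid] = res.profile
        results[sid] = res
    state["profiles"] = profiles
    state["results"] = results
    spath = outdir / "profiles.seg"
    sio.write_seg(list(profiles.values()), spath)
    record(spath)
    summary = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "tumour_fraction": p.tumour_fraction,
                "ploidy": p.ploidy,
                "norm_ploidy": p.norm_ploidy,
                "zero_ctdna": int(p.zero_ctdna),
                "loglik": p.loglik,
                "n_segments": p.n_segments,
            }
            for sid, p in profiles.items()
        ]
    )
    upath = outdir / "call_summary.tsv"
    summary.to_csv(upath, sep="\t", index=False, float_format="%.6f")
    record(upath)


def _stage_focal(config: RunConfig, outdir: Path, state: dict, record) -> None:
    if "counts50" not in state:
        return
    ratios50 = _normalize_many(state["counts50"], config.gc_span, config.mappability_min)
    genes = driver_gene_catalog()
    frames = []
    for sid, r in ratios50.items():
        profile = state["profiles"].get(sid)
        if profile is None:
            continue
        calls = call_focal_amplifications(r, profile, config.focal)
        annotate_amplifications(calls, genes)
        frames.append(calls_to_frame(calls))
    state["ratios50"] = ratios50
    frames = [f for f in frames if not f.empty]
    df = pd.concat(frames, ignore_index=True) if frames else calls_to_frame([])
    p = outdir / "focal_calls.tsv"
    df.to_csv(p, sep="\t", index=False, float_format="%.6f")
    record(p)


def _stage_metrics(config: RunConfig, outdir: Path, state: dict, record) -> None:
    df = sample_metrics(list(state["profiles"].values()), state["meta"], state["grid"])
    state["metrics"] = df
    p = outdir / "metrics.tsv"
    df.to_csv(p, sep="\t", index=False, float_format="%.6f")
    record(p)


def _stage_cohort(config: RunConfig, outdir: Path, state: dict, record) -> None:
    meta = state["meta"]
    pre = meta[meta["timepoint"] == "pretreatment"]
    profiles = [
        state["profiles"][sid]
        for sid in pre["sample_id"]
        if sid in state["profiles"] and not state["profiles"][sid].zero_ctdna
    ]
    if len(profiles) < 2:
        return
    matrix = aberration_matrix(profiles)
    state["matrix"] = matrix
    groups = pre.set_index("sample_id")["response_group"]
    tracks = {}
    for name in ("responder", "nonresponder"):
        ids = [sid for sid in matrix.sample_ids if groups.get(sid) == name]
        if ids:
            tracks[name] = group_frequency(matrix, ids)
    for name, track in tracks.items():
        df = track.segments.copy()
        df["gain_count"] = track.gains
        df["loss_count"] = track.losses
        df["group_size"] = track.group_size
        p = outdir / f"frequency_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        record(p)
    if len(tracks) == 2:
        uniq = unique_regions(tracks["responder"], tracks["nonresponder"])
        mcr_rows = []
        for rec in uniq.itertuples(index=False):
            mcr = minimal_consistent_region(
                matrix, (rec.chrom, rec.start, rec.end), rec.direction
            )
            if mcr:
                mcr_rows.append(
                    {
                        "chrom": mcr[0],
                        "start": mcr[1],
                        "end": mcr[2],
                        "carrier_count": mcr[3],
                        "direction": rec.direction,
                    }
                )
        p = outdir / "unique_regions_responder.tsv"
        uniq.to_csv(p, sep="\t", index=False)
        record(p)
        p = outdir / "minimal_consistent_regions.tsv"
        pd.DataFrame(
            mcr_rows, columns=["chrom", "start", "end", "carrier_count", "direction"]
        ).to_csv(p, sep="\t", index=False)
        record(p)


def _stage_longitudinal(config: RunConfig, outdir: Path, state: dict, record) -> None:
    meta = state["meta"]
    rows = []
    changes = []
    for pid, sub in meta.groupby("patient_id"):
        if set(sub["timepoint"]) != {"pretreatment", "progression"}:
            continue
        sid_pre = sub.loc[sub["timepoint"] == "pretreatment", "sample_id"].iloc[0]
        sid_prog = sub.loc[sub["timepoint"] == "progression", "sample_id"].iloc[0]
        if sid_pre not in state["profiles"] or sid_prog not in state["profiles"]:
            continue
        pc = paired_change(
            state["profiles"][sid_pre],
            state["profiles"][sid_prog],
            state["ratios"][sid_pre],
            state["ratios"][sid_prog],
            config.paired,
            patient_id=pid,
        )
        changes.append(pc)
        rows.append(
            {
                "patient_id": pid,
                "sample_pre": sid_pre,
                "sample_prog": sid_prog,
                "eligible": int(pc.eligible),
                "reason": pc.reason,
                "percent_genome_changed": pc.percent_genome_changed
                if pc.eligible
                else np.nan,
            }
        )
    state["paired_changes"] = changes
    p = outdir / "paired_changes.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "sample_pre",
            "sample_prog",
            "eligible",
            "reason",
            "percent_genome_changed",
        ],
    ).to_csv(p, sep="\t", index=False, float_format="%.4f")
    record(p)
    if any(c.eligible for c in changes):
        track = change_recurrence(changes, state["grid"], config.paired.delta_threshold)
        df = pd.DataFrame(
            {
                "chrom": state["grid"].bin_chrom,
                "start": state["grid"].start,
                "end": state["grid"].end,
                "gain_count": track.gains,
                "loss_count": track.losses,
            }
        )
        p = outdir / "change_recurrence.tsv"
        df.to_csv(p, sep="\t", index=False)
        record(p)


def _stage_survival(config: RunConfig, outdir: Path, state: dict, record) -> None:
    meta = state["meta"]
    pre = meta[meta["timepoint"] == "pretreatment"].reset_index(drop=True)
    if len(pre) < 3:
        return
    fractions = pre["sample_id"].map(
        {sid: p.tumour_fraction for sid, p in state["profiles"].items()}
    )
    metrics = {
        "cfdna_conc": pre["cfdna_conc"].to_numpy(dtype=float),
        "ctdna_fraction": fractions.to_numpy(dtype=float),
        "ctdna_conc": (pre["cfdna_conc"] * fractions).to_numpy(dtype=float),
    }
    rows = []
    for name, values in metrics.items():
        if np.any(~np.isfinite(values)):
            continue
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            labels = tertile_assign(values)
        try:
            res = km_logrank(
                pre["os_months"], pre["os_event"], labels, ["low", "medium", "high"]
            )
        except ValueError:
            continue
        rows.append(
            {
                "metric": name,
                "logrank_chi2": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "trend_chi2": res.trend_statistic,
                "trend_p_value": res.trend_p_value,
            }
        )
    p = outdir / "survival.tsv"
    pd.DataFrame(
        rows,
        columns=["metric", "logrank_chi2", "df", "p_value", "trend_chi2", "trend_p_value"],
    ).to_csv(p, sep="\t", index=False, float_format="%.6f")
    record(p)


_STAGES = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "call": _stage_call,
    "focal": _stage_focal,
    "metrics": _stage_metrics,
    "cohort": _stage_cohort,
    "longitudinal": _stage_longitudinal,
    "survival": _stage_survival,
}
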