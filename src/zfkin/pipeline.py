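"""End-to-end runs: configuration, seeding, and the stage drivers.

A :class:`PipelineConfig` gathers every tunable constant, round-trips
losslessly through JSON, and expands its single global seed into per-stage
sub-seeds through a named-counter scheme so each stage is individually
reproducible.  The stage functions below are what both the command-line
interface and the numbered analysis scripts call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import finbody, stats
from .bouts import (ExtractionConfig, RepeatDataset, bouts_to_frame,
                    extract_bouts, qc_and_match_repeat)
from .decoding import pseudo_population_curve
from .imaging import DI_THRESHOLD, summarize_cell
from .kinematics import KinematicConfig, compute_features
from .synth import CalciumSimParams, SwimSimParams, generate_cohort, generate_tilt_trials

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "simulate_behavior",
    "analyze_posture",
    "analyze_finbody",
    "simulate_calcium",
    "analyze_tuning_and_decode",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    swim: SwimSimParams = field(default_factory=SwimSimParams)
    calcium: CalciumSimParams = field(default_factory=CalciumSimParams)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    kinematics: KinematicConfig = field(default_factory=KinematicConfig)
    condition_deltas: dict = field(default_factory=dict)
    n_repeats: int = 2
    sidak_family_size: int = 8
    n_boot_median: int = 1000
    n_boot_fit: int = 100
    di_threshold: float = DI_THRESHOLD
    decoder_sizes: tuple = (3, 5, 7, 10, 13)
    decoder_draws: int = 10
    n_shuffles: int = 100
    seed: int = 0
    outdir: str = "results"

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(o)
        return json.dumps(asdict(self), default=enc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)

        def tup(x):
            return tuple(tuple(v) if isinstance(v, list) else v for v in x)
        swim = d.pop("swim")
        for k in ("speed_bin_weights", "peak_speed_ranges", "finbody_slope_per_bin"):
            swim[k] = tup(swim[k])
        calcium = d.pop("calcium")
        extraction = d.pop("extraction")
        kin = d.pop("kinematics")
        kin["angvel_search"] = tuple(kin["angvel_search"])
        kin["speed_bin_edges"] = tuple(kin["speed_bin_edges"])
        d["decoder_sizes"] = tuple(d["decoder_sizes"])
        return cls(swim=SwimSimParams(**swim), calcium=CalciumSimParams(**calcium),
                   extraction=ExtractionConfig(**extraction),
                   kinematics=KinematicConfig(**kin), **d)

    def manifest(self) -> dict:
        text = self.to_json()
        return {"config_sha1": hashlib.sha1(text.encode()).hexdigest(),
                "seed": self.seed}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _featured_bouts(trace_result, cfg: PipelineConfig, repeat_id: str,
                    group_label: str) -> pd.DataFrame:
    kept, log = extract_bouts(trace_result.trace, cfg.extraction)
    for b in kept:
        b.repeat_id, b.group_label = repeat_id, group_label
        compute_features(b, cfg.kinematics)
    df = bouts_to_frame(kept)
    df.attrs["exclusion_log"] = log
    return df


def simulate_behavior(cfg: PipelineConfig):
    """Generate a cohort and run extraction + kinematics on every repeat.

    Returns (bout feature table over all repeats/groups, truth tables).
    """
    cohort = generate_cohort(cfg.swim, cfg.condition_deltas, cfg.n_repeats,
                             seed=stage_seed(cfg.seed, "simulate-behavior"))
    frames, truths = [], []
    for rep in cohort:
        for label in ("control", "condition"):
            df = _featured_bouts(rep[label], cfg, rep["repeat_id"], label)
            if len(df):
                frames.append(df)
            tr = rep[label].truth.copy()
            tr["repeat_id"], tr["group_label"] = rep["repeat_id"], label
            truths.append(tr)
    bouts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    truth = pd.concat(truths, ignore_index=True)
    return bouts, truth


def match_repeats(bouts: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Apply the repeat-level QC threshold and bout-count matching."""
    kept = []
    seed0 = stage_seed(cfg.seed, "match")
    for i, (rid, grp) in enumerate(bouts.groupby("repeat_id")):
        ctrl = grp[grp.group_label == "control"]
        cond = grp[grp.group_label == "condition"]
        rep = RepeatDataset(repeat_id=rid,
                            control_bouts=list(ctrl.index),
                            condition_bouts=list(cond.index))
        rep = qc_and_match_repeat(rep, cfg.extraction, seed=seed0 + i)
        if rep.qc_status == "kept":
            kept.extend(rep.control_bouts)
            kept.extend(rep.condition_bouts)
    return bouts.loc[kept]


def analyze_posture(bouts: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Climb/dive posture comparisons between control and condition."""
    crit = stats.sidak_critical(0.05, cfg.sidak_family_size)
    seed = stage_seed(cfg.seed, "analyze-posture")
    rows = []
    for direction in ("climb", "dive"):
        sub = bouts[bouts.direction == direction]
        ctrl = sub[sub.group_label == "control"].posture_deg.to_numpy()
        cond = sub[sub.group_label == "condition"].posture_deg.to_numpy()
        if ctrl.size == 0 or cond.size == 0:
            continue
        res = stats.compare_groups(ctrl, cond, f"{direction} posture [deg]",
                                   critical_p=crit, n_boot=cfg.n_boot_median,
                                   seed=seed)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def analyze_finbody(bouts: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Per-bin robust fits, bootstrap comparisons, and the speed-ratio
    correlation contrast between groups."""
    seed = stage_seed(cfg.seed, "analyze-finbody")
    report: dict = {"bins": {}}
    fast_ref = None
    ctrl_all = bouts[bouts.group_label == "control"]
    cond_all = bouts[bouts.group_label == "condition"]
    for i, name in enumerate(finbody.SPEED_BIN_NAMES):
        fc = finbody.bootstrap_fit_distribution(ctrl_all, name,
                                                n_boot=cfg.n_boot_fit,
                                                seed=seed + 2 * i)
        fx = finbody.bootstrap_fit_distribution(cond_all, name,
                                                n_boot=cfg.n_boot_fit,
                                                seed=seed + 2 * i + 1)
        entry = {"control": fc.summary(), "condition": fx.summary()}
        if fc.reliable and fx.reliable:
            entry["p_slope"] = finbody.bootstrap_difference_pvalue(
                fc.bootstrap_slopes, fx.bootstrap_slopes)
            if name == "fast":
                fast_ref = fc.slope
        report["bins"][name] = entry
    if fast_ref:
        for name, entry in report["bins"].items():
            if "p_slope" in entry:
                entry["effect_size_pct"] = stats.effect_size(
                    entry["control"]["slope"], entry["condition"]["slope"],
                    reference=fast_ref)
    try:
        r1, n1 = finbody.spearman_speed_ratio(ctrl_all)
        r2, n2 = finbody.spearman_speed_ratio(cond_all)
        z, p = finbody.compare_correlations_fisher_z(r1, n1, r2, n2)
        report["speed_ratio_correlation"] = {
            "control_rho": r1, "control_n": n1,
            "condition_rho": r2, "condition_n": n2, "z": z, "p": p}
    except ValueError:
        pass
    return report


def simulate_calcium(cfg: PipelineConfig):
    params = replace(cfg.calcium, seed=stage_seed(cfg.seed, "simulate-calcium"))
    return generate_tilt_trials(params)


def analyze_tuning_and_decode(cells, cfg: PipelineConfig) -> dict:
    """Tuning table plus pseudo-population decoding of the untuned cells."""
    table = pd.DataFrame([summarize_cell(c, cfg.di_threshold) for c in cells])
    untuned = [c for c in cells if c.tuning == "untuned"]
    report = {"tuning_table": table,
              "n_tuned": int((table.tuning != "untuned").sum()),
              "n_untuned": len(untuned)}
    sizes = [s for s in cfg.decoder_sizes if s <= len(untuned)]
    if sizes:
        results = pseudo_population_curve(
            untuned, sizes=sizes, n_draws=cfg.decoder_draws,
            n_shuffles=cfg.n_shuffles,
            seed=stage_seed(cfg.seed, "decode"))
        rows = [{"size": r.population_size, "accuracy": r.accuracy,
                 "null_median": float(np.median(r.null_accuracies))
                 if r.null_accuracies.size else np.nan}
                for r in results]
        report["decoding"] = pd.DataFrame(rows)
    return report


def run_pipeline(cfg: PipelineConfig, command: str, outdir: str | Path | None = None) -> dict:
    """Execute one named stage and write its artifacts + run manifest.

    Commands: simulate-behavior, analyze-posture, analyze-finbody,
    simulate-calcium, analyze-tuning, decode, report.
    """
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cfg.manifest()
    artifacts: dict = {"manifest": manifest}
    if command in ("simulate-behavior", "analyze-posture", "analyze-finbody", "report"):
        bouts, truth = simulate_behavior(cfg)
        bouts.to_csv(out / "bouts.csv", index=False)
        truth.to_csv(out / "bouts_truth.csv", index=False)
        artifacts["n_bouts"] = len(bouts)
        if command in ("analyze-posture", "report") and len(bouts):
            posture = analyze_posture(bouts, cfg)
            posture.to_csv(out / "posture_comparisons.csv", index=False)
            artifacts["posture"] = posture
        if command in ("analyze-finbody", "report") and len(bouts):
            rep = analyze_finbody(bouts, cfg)
            (out / "finbody_report.json").write_text(
                json.dumps(rep, default=_jsonable, indent=1))
            artifacts["finbody"] = rep
    elif command in ("simulate-calcium", "analyze-tuning", "decode"):
        cells = simulate_calcium(cfg)
        rep = analyze_tuning_and_decode(cells, cfg)
        rep["tuning_table"].to_csv(out / "tuning_table.csv", index=False)
        if "decoding" in rep:
            rep["decoding"].to_csv(out / "decoding.csv", index=False)
        artifacts["tuning"] = rep
    else:
        raise ValueError(f"unknown command {command!r}")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return artifacts


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(type(o))
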