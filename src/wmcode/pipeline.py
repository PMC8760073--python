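"""Pipeline orchestration: configuration, stages, manifest, tidy outputs.

Seven analysis stages (behavior, trajectory, tuning, decode, popcode,
waveforms, gaze) run over one or more sessions — read from disk or
generated synthetically — and write tidy CSV tables plus a manifest JSON
recording stage parameters and the seeds derived from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import gaze as gaze_mod
from . import popcode as popcode_mod
from . import tuning as tuning_mod
from . import waveforms as waveforms_mod
from ._utils import child_seed
from .decoding import decode_cv, greedy_ensemble, shuffle_null
from .session import PERIODS, SessionRecording, read_session, write_session
from .synth import GeneratorConfig, generate_session
from .tuning import epoch_rates

log = logging.getLogger("wmcode")

ALL_STAGES = ("behavior", "trajectory", "tuning", "decode", "popcode",
              "waveforms", "gaze")


class UnknownStageError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """What to run, on what, with what parameters.

    ``sessions`` is a list of paths; alternatively ``generate`` gives the
    number of synthetic sessions to create from ``generator`` parameters.
    ``params`` holds optional per-stage parameter blocks keyed by stage
    name (mirroring each stage function's keyword arguments).
    """

    stages: tuple = ALL_STAGES
    sessions: list = field(default_factory=list)
    generate: int = 0
    generator: dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import yaml
        data = yaml.safe_load(text)
    cfg = PipelineConfig.from_dict(data or {})
    cfg.stages = tuple(cfg.stages)
    return cfg


def _load_sessions(cfg: PipelineConfig) -> list[SessionRecording]:
    recs = []
    for p in cfg.sessions:
        recs.append(read_session(p))
    gen_cfg = GeneratorConfig(**cfg.generator) if cfg.generator \
        else GeneratorConfig()
    for i in range(cfg.generate):
        rec, gt = generate_session(gen_cfg, seed=child_seed(cfg.seed,
                                                            "simulate", i))
        recs.append(rec)
    return recs


# --- stage implementations -------------------------------------------------


def _stage_behavior(rec: SessionRecording, seed: int, out: Path,
                    **kw) -> dict:
    perf = behavior_mod.percent_correct(rec.trials, **kw.get("percent", {}))
    rts = behavior_mod.response_times(rec.trials)
    perf.insert(0, "session_id", rec.session_id)
    rts.insert(0, "session_id", rec.session_id)
    perf.to_csv(out / f"{rec.session_id}_performance_by_period.csv",
                index=False)
    rts.to_csv(out / f"{rec.session_id}_response_times.csv", index=False)
    return {"n_trials": int(len(rec.trials))}


def _stage_trajectory(rec: SessionRecording, seed: int, out: Path,
                      **kw) -> dict:
    frames = []
    for period in PERIODS:
        grid = behavior_mod.grid_occupancy(rec, period=period, **kw)
        g = grid.percent.copy()
        g.insert(0, "period", period)
        frames.append(g)
    occ = pd.concat(frames, ignore_index=True)
    occ.insert(0, "session_id", rec.session_id)
    occ.to_csv(out / f"{rec.session_id}_grid_occupancy.csv", index=False)

    by_period = {p: f.drop(columns="period")
                 for p, f in zip(PERIODS, frames)}
    diffs = []
    for a, b in (("early_post", "pre"), ("late_post", "pre"),
                 ("early_post", "late_post")):
        d = behavior_mod.occupancy_increase(by_period[a], by_period[b])
        d.insert(0, "contrast", f"{a}-{b}")
        diffs.append(d)
    diff = pd.concat(diffs, ignore_index=True)
    diff.insert(0, "session_id", rec.session_id)
    diff.to_csv(out / f"{rec.session_id}_grid_diff.csv", index=False)
    return {"n_condition_values": int(len(frames[0]))}


def _stage_tuning(rec: SessionRecording, seed: int, out: Path, **kw) -> dict:
    epochs = kw.pop("epochs", ("cue", "delay"))
    frames = [tuning_mod.tuning_census(rec, epoch=e, seed=seed, **kw)
              for e in epochs]
    census = pd.concat(frames, ignore_index=True)
    census.insert(0, "session_id", rec.session_id)
    census.to_csv(out / f"{rec.session_id}_tuning_results.csv", index=False)

    slopes = []
    rates = epoch_rates(rec, "delay")
    for period in PERIODS:
        rs = tuning_mod.ranked_slope(rates, period=period)
        slopes.append({"session_id": rec.session_id, "period": period,
                       "slope": rs.slope})
    pd.DataFrame(slopes).to_csv(out / f"{rec.session_id}_ranked_slopes.csv",
                                index=False)
    return {"n_units_tested": int(census["unit_id"].nunique())}


def _stage_decode(rec: SessionRecording, seed: int, out: Path, **kw) -> dict:
    epoch = kw.get("epoch", "delay")
    max_size = kw.get("max_size", 16)
    n_balance = kw.get("n_balance", 20)
    n_shuffle = kw.get("n_shuffle", 10)
    rates = epoch_rates(rec, epoch)
    X, info = tuning_mod.rate_matrix(rates)
    uids = sorted(rates["unit_id"].unique().tolist())
    y = info["target_column"].to_numpy()
    periods = info["period"].to_numpy()

    pre = periods == "pre"
    ens = greedy_ensemble(X[pre], y[pre], uids, max_size=max_size,
                          seed=child_seed(seed, "greedy"))
    cols = [uids.index(u) for u in ens.unit_ids]

    rows = []
    for period in PERIODS:
        mask = periods == period
        res = decode_cv(X[np.ix_(mask, cols)], y[mask],
                        n_balance=n_balance,
                        seed=child_seed(seed, "decode", period))
        null = shuffle_null(X[np.ix_(mask, cols)], y[mask],
                            n_shuffle=n_shuffle, n_balance=n_balance,
                            seed=child_seed(seed, "null", period))
        rows.append({
            "session_id": rec.session_id, "period": period, "epoch": epoch,
            "ensemble": ",".join(map(str, ens.unit_ids)),
            "accuracy": res.accuracy,
            "null_mean": float(null.accuracies.mean()),
            "chance": null.chance, "null_flagged": null.flagged,
        })
    pd.DataFrame(rows).to_csv(out / f"{rec.session_id}_decoding_results.csv",
                              index=False)
    return {"ensemble_size": len(cols)}


def _stage_popcode(rec: SessionRecording, seed: int, out: Path, **kw) -> dict:
    epoch = kw.get("epoch", "delay")
    sizes = tuple(kw.get("sizes", (2, 3, 5)))
    n = kw.get("n_ensembles", 1000)
    rates = epoch_rates(rec, epoch)
    X, info = tuning_mod.rate_matrix(rates)
    uids = sorted(rates["unit_id"].unique().tolist())
    frames = []
    for period in PERIODS:
        mask = ((info["period"] == period)
                & (info["target_column"] != "center")).to_numpy()
        sweep = popcode_mod.random_ensemble_sweep(
            X[mask], info.loc[mask, "target_column"].to_numpy(), uids,
            sizes=sizes, n=n, seed=child_seed(seed, "sweep", period))
        sweep.insert(0, "period", period)
        frames.append(sweep)
    stats = pd.concat(frames, ignore_index=True)
    stats.insert(0, "session_id", rec.session_id)
    stats.to_csv(out / f"{rec.session_id}_popcode_stats.csv", index=False)
    return {"n_ensembles": int(len(stats))}


def _stage_waveforms(rec: SessionRecording, seed: int, out: Path,
                     **kw) -> dict:
    table, fit = waveforms_mod.classify_session_units(rec, seed=seed, **kw)
    table.insert(0, "session_id", rec.session_id)
    table.to_csv(out / f"{rec.session_id}_waveform_class.csv", index=False)
    diag = {
        "means": fit.means.tolist(), "sds": fit.sds.tolist(),
        "weights": fit.weights.tolist(), "aic_1g": fit.aic_1g,
        "aic_2g": fit.aic_2g, "bimodal": fit.bimodal,
        "threshold": fit.threshold,
    }
    (out / f"{rec.session_id}_waveform_mixture.json").write_text(
        json.dumps(diag, indent=2))
    return {"threshold": fit.threshold}


def _stage_gaze(rec: SessionRecording, seed: int, out: Path, **kw) -> dict:
    rows = []
    for period in PERIODS:
        prop = gaze_mod.fixation_on_target_proportion(rec, period=period)
        rows.append({"session_id": rec.session_id, "period": period,
                     "metric": "fixation_on_target_proportion",
                     "value": prop})
    try:
        fix_dec = gaze_mod.decode_target_from_fixations(
            rec, period="pre", n_balance=kw.get("n_balance", 5),
            seed=child_seed(seed, "fixdec"))
        rows.append({"session_id": rec.session_id, "period": "pre",
                     "metric": "fixation_map_decoding_accuracy",
                     "value": fix_dec.accuracy})
    except ValueError as e:  # too few trials per class
        log.warning("fixation-map decoding skipped: %s", e)
    sacc = gaze_mod.saccade_frame_tuning(rec, seed=child_seed(seed, "sacc"))
    sacc.insert(0, "session_id", rec.session_id)
    sacc.to_csv(out / f"{rec.session_id}_saccade_tuning.csv", index=False)
    pd.DataFrame(rows).to_csv(out / f"{rec.session_id}_gaze_results.csv",
                              index=False)
    return {"n_saccade_tested": int(len(sacc))}


_STAGE_FN = {
    "behavior": _stage_behavior,
    "trajectory": _stage_trajectory,
    "tuning": _stage_tuning,
    "decode": _stage_decode,
    "popcode": _stage_popcode,
    "waveforms": _stage_waveforms,
    "gaze": _stage_gaze,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages over all sessions; return the manifest.

    Every stochastic stage consumes a seed derived from the master seed by
    the stated splitting rule (hash of master + stage + session), so
    identical configs yield identical outputs.
    """
    unknown = [s for s in cfg.stages if s not in _STAGE_FN]
    if unknown:
        raise UnknownStageError(f"unknown stages {unknown}; "
                                f"known: {list(ALL_STAGES)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs = _load_sessions(cfg)
    if cfg.generate:
        for rec in recs[-cfg.generate:]:
            write_session(rec, out / "sessions" / rec.session_id)

    manifest: dict = {"master_seed": cfg.seed, "stages": {},
                      "sessions": [r.session_id for r in recs]}
    for stage in cfg.stages:
        stage_info = {"params": cfg.params.get(stage, {}), "per_session": {}}
        for rec in recs:
            seed = child_seed(cfg.seed, stage, rec.session_id)
            info = _STAGE_FN[stage](rec, seed, out,
                                    **cfg.params.get(stage, {}))
            stage_info["per_session"][rec.session_id] = {
                "seed": seed, **info}
        manifest["stages"][stage] = stage_info
        log.info("stage %s done", stage)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
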