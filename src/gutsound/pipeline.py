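"""End-to-end pipeline: simulate -> detect -> extract -> train ->
evaluate -> stats.

Every run writes its artifacts under one output directory together with a
JSON run manifest recording the config hash, master seed and per-stage
counts.  Reruns with the same configuration reproduce identical CSVs.  The
pipeline can restart from a later stage if the artifacts that stage needs
are already on disk; a missing input aborts with a stage-named error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .detection import DetectorConfig, detect_recording
from .errors import PipelineError, UnusableParticipantError
from .evaluation import (bootstrap_eval, diagnostic_metrics, kfold_battery,
                         loocv)
from .features import (aggregate_participant, build_feature_matrix,
                       final_model_registry, registry_names)
from .group_stats import fit_random_intercept_lmm, long_format_observations
from .model import fit_logistic
from .simulate import PERIODS, CohortConfig, generate_cohort

log = logging.getLogger("gutsound")

STAGES = ("simulate", "detect", "extract", "train", "evaluate", "stats")


@dataclass
class PipelineConfig:
    out_dir: str = "gutsound_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    l2: float = 1.0
    eval_modes: tuple = ("loocv",)      # subset of loocv|kfold|bootstrap
    bootstrap_reps: int = 300
    eval_seed: int = 0
    write_audio: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "cohort": self.cohort.to_dict(),
            "detector": self.detector.to_dict(),
            "l2": self.l2,
            "eval_modes": list(self.eval_modes),
            "bootstrap_reps": self.bootstrap_reps,
            "eval_seed": self.eval_seed,
            "write_audio": self.write_audio,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "detector" in d:
            d["detector"] = DetectorConfig.from_dict(d["detector"])
        if "eval_modes" in d:
            d["eval_modes"] = tuple(d["eval_modes"])
        return cls(**d)


def cohort_feature_matrix(cohort, detector: DetectorConfig | None = None,
                          registry=None) -> pd.DataFrame:
    """Detect events in every recording of an in-memory cohort and return
    the participant feature matrix (detect + extract, no files)."""
    detector = detector or DetectorConfig()
    registry = registry or final_model_registry()
    durations = {p: cohort.config.duration(p) for p in PERIODS}
    vectors = []
    for part in cohort.participants:
        per_period = {period: detect_recording(rec, detector)
                      for period, rec in part.recordings.items()}
        try:
            vectors.append(aggregate_participant(
                part.participant_id, per_period, durations,
                group=part.group,
                reference_duration=cohort.config.fed_duration))
        except UnusableParticipantError as exc:
            log.warning("skipping participant: %s", exc)
    return build_feature_matrix(vectors, registry)


def _require(path: Path, stage: str, what: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing required input {what} ({path})")
    return path


def _detect_all(cohort, detector):
    events_by_participant = {}
    for part in cohort.participants:
        per_period = {}
        for period, rec in part.recordings.items():
            per_period[period] = detect_recording(rec, detector)
        events_by_participant[part.participant_id] = per_period
    return events_by_participant


def _reload_events(out, config, stage):
    """Rebuild in-memory events (with waveforms) from events.csv + audio."""
    from .detection import preprocess, segment_bursts

    manifest = pd.read_csv(_require(out / "manifest.csv", stage, "manifest"))
    events = gio.read_events(_require(out / "events.csv", stage,
                                      "event table"))
    by_key = {}
    for e in events:
        by_key.setdefault((e.participant_id, e.period), []).append(e)
    events_by_participant = {}
    for _, row in manifest.iterrows():
        pid, period = row["participant_id"], row["period"]
        audio = row["audio_path"]
        if not isinstance(audio, str) or not audio:
            raise PipelineError(stage, "manifest has no audio paths; rerun "
                                       "from 'detect' with write_audio")
        rec = gio.read_recording(audio, pid, row["group"], period)
        filtered = preprocess(rec, config.detector)
        for e in by_key.get((pid, period), []):
            ch = rec.quadrant_map.index(e.quadrant)
            i0 = int(e.onset * rec.sample_rate)
            i1 = max(int(e.offset * rec.sample_rate), i0 + 1)
            e.waveform = filtered[ch, i0:i1]
            e.sample_rate = rec.sample_rate
        events_by_participant.setdefault(pid, {})[period] = \
            by_key.get((pid, period), [])
    return events_by_participant


def run_pipeline(config: PipelineConfig, start_stage: str = "simulate"
                 ) -> dict:
    """Execute the pipeline from ``start_stage`` onward.

    Returns a mapping of artifact names to paths.  Raises
    :class:`PipelineError` naming the failing stage when an input is
    missing or a stage fails.
    """
    if start_stage not in STAGES:
        raise PipelineError(start_stage, "unknown stage")
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = final_model_registry()
    names = registry_names(registry)
    artifacts = {}
    run_log = {"config_hash": gio.config_hash(config.to_dict()),
               "seed": config.cohort.seed, "stages": {}}
    active = STAGES[STAGES.index(start_stage):]
    ctx = {}

    if "simulate" in active:
        cohort = generate_cohort(config.cohort)
        manifest = gio.write_cohort(cohort, out,
                                    write_audio=config.write_audio)
        ctx["cohort"] = cohort
        artifacts["manifest"] = out / "manifest.csv"
        run_log["stages"]["simulate"] = {"participants": len(cohort),
                                         "recordings": cohort.n_recordings}
        log.info("simulate: %d participants, %d recordings",
                 len(cohort), cohort.n_recordings)

    if "detect" in active:
        if "cohort" not in ctx:
            manifest = pd.read_csv(_require(out / "manifest.csv", "detect",
                                            "cohort manifest"))
            cohort = _cohort_from_manifest(manifest, config)
            ctx["cohort"] = cohort
        events_by_participant = _detect_all(ctx["cohort"], config.detector)
        all_events = [e for per in events_by_participant.values()
                      for evs in per.values() for e in evs]
        gio.write_events(all_events, out / "events.csv")
        ctx["events"] = events_by_participant
        artifacts["events"] = out / "events.csv"
        run_log["stages"]["detect"] = {"events": len(all_events)}
        log.info("detect: %d events", len(all_events))

    if "extract" in active:
        if "events" not in ctx:
            ctx["events"] = _reload_events(out, config, "extract")
        durations = {p: config.cohort.duration(p) for p in PERIODS}
        labels = _labels(out, ctx, config)
        vectors = []
        for pid, per_period in ctx["events"].items():
            try:
                vectors.append(aggregate_participant(
                    pid, per_period, durations, group=labels.get(pid),
                    reference_duration=config.cohort.fed_duration))
            except UnusableParticipantError as exc:
                log.warning("extract: skipping participant: %s", exc)
        df = build_feature_matrix(vectors, registry)
        df = df.sort_values("participant_id").reset_index(drop=True)
        df.to_csv(out / "features.csv", index=False)
        gio.write_registry(registry, out / "registry.csv")
        ctx["features"] = df
        artifacts["features"] = out / "features.csv"
        run_log["stages"]["extract"] = {"participants": len(df),
                                        "features": len(names)}
        log.info("extract: %d participants x %d features", len(df), len(names))

    if "train" in active:
        df = _features_frame(out, ctx, "train")
        X, y = df[names].to_numpy(float), (df["label"] == "IBS").to_numpy()
        model = fit_logistic(X, y, names, config.l2)
        gio.save_model(model, out / "model.yaml", registry)
        ctx["model"] = model
        artifacts["model"] = out / "model.yaml"
        run_log["stages"]["train"] = {"n": len(y),
                                      "features": len(names)}
        log.info("train: n=%d", len(y))

    if "evaluate" in active:
        df = _features_frame(out, ctx, "evaluate")
        X, y = df[names].to_numpy(float), (df["label"] == "IBS").to_numpy()
        rows, tables = [], []
        for mode in config.eval_modes:
            if mode == "loocv":
                table, _ = loocv(X, y, names, config.l2)
                _append_metric_rows(rows, tables, "loocv", table)
            elif mode == "kfold":
                for name, table in kfold_battery(X, y, names,
                                                 config.eval_seed,
                                                 config.l2).items():
                    _append_metric_rows(rows, tables, name, table)
            elif mode == "bootstrap":
                boot = bootstrap_eval(X, y, names, config.bootstrap_reps,
                                      config.eval_seed, config.l2)
                _append_metric_rows(rows, tables,
                                    f"bootstrap_{boot.n_reps}",
                                    boot.pooled_table)
            else:
                raise PipelineError("evaluate", f"unknown mode {mode!r}")
        pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
        pd.DataFrame(tables).to_csv(out / "contingency.csv", index=False)
        artifacts["evaluation"] = out / "evaluation.csv"
        run_log["stages"]["evaluate"] = {"modes": list(config.eval_modes)}
        log.info("evaluate: %s", ", ".join(config.eval_modes))

    if "stats" in active:
        df = _features_frame(out, ctx, "stats")
        rows = []
        for response in ("quantity_density", "summed_amplitude"):
            obs = long_format_observations(df, response)
            res = fit_random_intercept_lmm(obs)
            frame = res.summary_frame()
            frame.insert(0, "response", response)
            rows.append(frame)
        pd.concat(rows).to_csv(out / "stats.csv", index=False)
        artifacts["stats"] = out / "stats.csv"
        run_log["stages"]["stats"] = {"responses": 2}
        log.info("stats: mixed models fitted")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    artifacts["run_manifest"] = out / "run_manifest.json"
    return artifacts


def _cohort_from_manifest(manifest: pd.DataFrame, config: PipelineConfig):
    from .simulate import Cohort, ParticipantData

    participants = []
    for pid, sub in manifest.groupby("participant_id", sort=True):
        recordings = {}
        group = sub.iloc[0]["group"]
        for _, row in sub.iterrows():
            audio = row["audio_path"]
            if not isinstance(audio, str) or not audio:
                raise PipelineError("detect", "manifest has no audio paths; "
                                              "rerun simulate with write_audio")
            recordings[row["period"]] = gio.read_recording(
                audio, pid, group, row["period"])
        truth = gio.read_truth(row["truth_path"])
        participants.append(ParticipantData(pid, group, recordings, truth))
    return Cohort(config.cohort, participants)


def _labels(out, ctx, config) -> dict:
    if "cohort" in ctx:
        return {p.participant_id: p.group
                for p in ctx["cohort"].participants}
    manifest = pd.read_csv(_require(Path(config.out_dir) / "manifest.csv",
                                    "extract", "cohort manifest"))
    return dict(zip(manifest["participant_id"], manifest["group"]))


def _features_frame(out, ctx, stage) -> pd.DataFrame:
    if "features" in ctx:
        return ctx["features"]
    path = _require(out / "features.csv", stage, "feature matrix")
    return pd.read_csv(path)


def _append_metric_rows(rows, tables, mode, table):
    metrics = diagnostic_metrics(table)
    tables.append({"mode": mode, "TP": table.tp, "FN": table.fn,
                   "FP": table.fp, "TN": table.tn})
    for name, point, lo, hi in metrics.as_rows():
        rows.append({"mode": mode, "metric": name, "point": point,
                     "ci_low": lo, "ci_high": hi})
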