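"""File formats: PCM-16 WAV audio, CSV tables, YAML configs and the
human-readable model file.

Recordings can be stored either as one interleaved 4-channel WAV or as
four mono WAVs suffixed ``_RUQ``/``_LUQ``/``_RLQ``/``_LLQ``; both round
trip through :func:`read_recording` identically up to 16-bit quantization.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .detection import BowelSoundEvent, DetectorConfig
from .errors import GutSoundError, InvalidParameterError, SchemaError
from .features import ParticipantFeatureVector, RegistryEntry
from .model import ModelWeights
from .simulate import (QUADRANTS, Cohort, CohortConfig, EventTruth,
                       Recording)

_PCM16_SCALE = 32767.0


class IOValidationError(GutSoundError, IOError):
    pass


def _to_pcm16(x: np.ndarray) -> np.ndarray:
    return np.round(np.clip(x, -1.0, 1.0) * _PCM16_SCALE).astype(np.int16)


def write_recording(recording: Recording, path, layout: str = "interleaved"
                    ) -> list:
    """Write a recording as WAV; returns the list of files written.

    ``layout`` is "interleaved" (one 4-channel file) or "mono" (four files
    suffixed with the quadrant name).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sr = int(round(recording.sample_rate))
    if layout == "interleaved":
        data = _to_pcm16(recording.channels).T  # (n, 4)
        wavfile.write(path, sr, data)
        return [path]
    if layout == "mono":
        files = []
        for q in recording.quadrant_map:
            p = path.with_name(f"{path.stem}_{q}{path.suffix or '.wav'}")
            wavfile.write(p, sr, _to_pcm16(recording.channel(q)))
            files.append(p)
        return files
    raise InvalidParameterError("layout must be 'interleaved' or 'mono'")


def read_recording(paths, participant_id: str = "", group: str | None = None,
                   period: str = "", quadrant_map=QUADRANTS) -> Recording:
    """Read a 4-quadrant recording from WAV.

    ``paths`` is either one interleaved 4-channel file, or a mapping
    quadrant -> mono file, or a list of four mono files whose stems end in
    the quadrant name.  Sample rates must agree and all four quadrants must
    be covered.
    """
    if isinstance(paths, (str, Path)):
        sr, data = wavfile.read(paths)
        if data.ndim != 2 or data.shape[1] != 4:
            raise IOValidationError(
                f"{paths}: expected 4 channels, got shape {data.shape}")
        channels = data.T.astype(np.float64) / _PCM16_SCALE
        return Recording(participant_id, group, period, float(sr),
                         np.clip(channels, -1, 1), quadrant_map)
    if isinstance(paths, dict):
        by_quadrant = {q: Path(p) for q, p in paths.items()}
    else:
        by_quadrant = {}
        for p in paths:
            p = Path(p)
            for q in QUADRANTS:
                if p.stem.endswith(f"_{q}"):
                    by_quadrant[q] = p
                    break
    missing = [q for q in quadrant_map if q not in by_quadrant]
    if missing:
        raise IOValidationError(f"missing quadrant file(s): {missing}")
    rates, chans = [], []
    for q in quadrant_map:
        sr, data = wavfile.read(by_quadrant[q])
        if data.ndim != 1:
            raise IOValidationError(f"{by_quadrant[q]}: expected mono")
        rates.append(sr)
        chans.append(data.astype(np.float64) / _PCM16_SCALE)
    if len(set(rates)) != 1:
        raise IOValidationError(f"sample-rate mismatch across quadrants: {rates}")
    if len({len(c) for c in chans}) != 1:
        raise IOValidationError("channel lengths differ across quadrants")
    return Recording(participant_id, group, period, float(rates[0]),
                     np.clip(np.vstack(chans), -1, 1), quadrant_map)


# ---------------------------------------------------------------------------
# CSV tables

EVENT_COLUMNS = ["participant_id", "period", "quadrant", "onset_s",
                 "offset_s", "n_bursts", "component_intervals_s",
                 "peak_amplitude", "origin_quadrant"]

TRUTH_COLUMNS = ["participant_id", "period", "quadrant", "onset_s",
                 "offset_s", "burst_onsets_s", "peak_amplitude", "is_bowel"]


def events_to_frame(events) -> pd.DataFrame:
    rows = [{
        "participant_id": e.participant_id,
        "period": e.period,
        "quadrant": e.quadrant,
        "onset_s": e.onset,
        "offset_s": e.offset,
        "n_bursts": e.burst_number,
        "component_intervals_s": ";".join(
            f"{v:.6f}" for v in e.component_intervals),
        "peak_amplitude": e.peak_amplitude,
        "origin_quadrant": e.origin_quadrant or "",
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"event table missing columns: {sorted(missing)}")
    events = []
    for _, r in df.iterrows():
        intervals = ([float(v) for v in str(r["component_intervals_s"]).split(";")]
                     if r["component_intervals_s"] else [])
        onset = float(r["onset_s"])
        # burst offsets are not serialized; reconstruct onsets only
        burst_onsets = np.concatenate([[onset], onset + np.cumsum(intervals)])
        bursts = [(float(b), float(b)) for b in burst_onsets]
        events.append(BowelSoundEvent(
            r["participant_id"], r["period"], r["quadrant"], onset,
            float(r["offset_s"]), bursts, float(r["peak_amplitude"]),
            r["origin_quadrant"] or None))
    return events


def truth_to_frame(truths) -> pd.DataFrame:
    rows = [{
        "participant_id": t.participant_id,
        "period": t.period,
        "quadrant": t.quadrant,
        "onset_s": t.onset,
        "offset_s": t.offset,
        "burst_onsets_s": ";".join(f"{v:.6f}" for v in t.burst_onsets),
        "peak_amplitude": t.peak_amplitude,
        "is_bowel": t.is_bowel,
    } for t in truths]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth(truths, path) -> None:
    truth_to_frame(truths).to_csv(path, index=False)


def read_truth(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    truths = []
    for _, r in df.iterrows():
        onsets = [float(v) for v in str(r["burst_onsets_s"]).split(";") if v]
        truths.append(EventTruth(
            r["participant_id"], r["period"], r["quadrant"],
            float(r["onset_s"]), float(r["offset_s"]), onsets,
            float(r["peak_amplitude"]),
            str(r["is_bowel"]) in ("True", "true", "1")))
    return truths


def write_cohort(cohort: Cohort, out_dir, write_audio: bool = True,
                 layout: str = "interleaved") -> pd.DataFrame:
    """Write a cohort to disk and return (and save) its manifest.

    The manifest CSV lists one row per recording with the participant id,
    group label, period, truth file and (optionally) audio file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for part in cohort.participants:
        truth_path = out_dir / f"{part.participant_id}_truth.csv"
        write_truth(part.truth, truth_path)
        for period, rec in part.recordings.items():
            audio = ""
            if write_audio:
                files = write_recording(
                    rec, out_dir / f"{part.participant_id}_{period}.wav",
                    layout)
                audio = str(files[0])
            rows.append({
                "participant_id": part.participant_id,
                "group": part.group,
                "period": period,
                "duration_s": rec.duration,
                "sample_rate": rec.sample_rate,
                "audio_path": audio,
                "truth_path": str(truth_path),
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    save_config(cohort.config.to_dict(), out_dir / "cohort_config.yaml")
    return manifest


# ---------------------------------------------------------------------------
# configs and model files

def save_config(config_dict: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def registry_hash(registry) -> str:
    blob = ",".join(f"{e.name}:{e.domain}" for e in registry).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_model(model: ModelWeights, path, registry=None) -> None:
    d = model.to_dict()
    if registry is not None:
        d["registry_hash"] = registry_hash(registry)
    save_config(d, path)


def load_model(path) -> ModelWeights:
    return ModelWeights.from_dict(load_config(path))


def write_registry(registry, path) -> None:
    pd.DataFrame([{"name": e.name, "domain": e.domain} for e in registry]
                 ).to_csv(path, index=False)


def read_registry(path) -> list:
    df = pd.read_csv(path)
    return [RegistryEntry(r["name"], r["domain"]) for _, r in df.iterrows()]
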