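"""Bowel-sound detection: band-pass, envelope thresholding, burst
segmentation and origin-quadrant assignment.

The detector is deliberately simple and fully documented: a zero-phase
Butterworth band-pass, a short RMS envelope, and a robust (median +
scaled-MAD) noise floor so that detections are invariant to overall
signal gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError
from .simulate import QUADRANTS, Recording

_Z_MAD = 1.4826          # MAD -> sigma for Gaussian noise


@dataclass
class DetectorConfig:
    """Tunable detector parameters; defaults target bowel-sound timescales."""

    bandpass: tuple = (60.0, 1500.0)
    filter_order: int = 10
    frame: float = 0.010               # envelope frame length, s
    threshold_k: float = 4.0           # multiples of noise sigma above median
    min_event_duration: float = 0.018
    merge_gap: float = 0.150   # must exceed the largest component interval
                               # minus burst decay, or burst trains split
    merge_peak_ratio: float = 0.5
    burst_gap: float = 0.025
    burst_rel_threshold: float = 0.4   # of event peak envelope; above the
                                       # default cross-channel leakage
    dedup_peak_ratio: float = 2.0      # cross-channel ghost suppression
    tail_trim_db: float = 40.0

    def __post_init__(self):
        low, high = self.bandpass
        if not 0 < low < high:
            raise InvalidParameterError("bandpass must satisfy 0 < low < high")
        for name in ("frame", "threshold_k", "min_event_duration",
                     "merge_gap", "burst_gap"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bandpass"] = list(self.bandpass)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        if "bandpass" in d:
            d["bandpass"] = tuple(d["bandpass"])
        return cls(**d)


@dataclass
class BowelSoundEvent:
    """One detected acoustic event on a single channel."""

    participant_id: str
    period: str
    quadrant: str                       # channel the event was kept from
    onset: float
    offset: float
    bursts: list                        # [(onset, offset)] absolute seconds
    peak_amplitude: float
    origin_quadrant: str | None = None
    waveform: np.ndarray | None = field(default=None, repr=False, compare=False)
    sample_rate: float | None = field(default=None, repr=False, compare=False)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def burst_number(self) -> int:
        return len(self.bursts)

    @property
    def component_intervals(self) -> list:
        onsets = [b[0] for b in self.bursts]
        return [b - a for a, b in zip(onsets, onsets[1:])]


def preprocess(recording: Recording, config: DetectorConfig) -> np.ndarray:
    """Zero-phase band-pass of all four channels; preserves length."""
    low, high = config.bandpass
    nyq = recording.sample_rate / 2.0
    if high >= nyq:
        raise InvalidParameterError(
            f"bandpass high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(config.filter_order, [low, high], btype="bandpass",
                     fs=recording.sample_rate, output="sos")
    return sps.sosfiltfilt(sos, recording.channels, axis=-1)


def rms_envelope(x: np.ndarray, sample_rate: float, frame: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """RMS envelope in ``frame``-long windows with 50% overlap.

    Returns (frame start times, envelope values).
    """
    n_frame = max(int(round(frame * sample_rate)), 2)
    hop = max(n_frame // 2, 1)
    if len(x) < n_frame:
        return np.array([0.0]), np.array([np.sqrt(np.mean(x ** 2))] if len(x) else [0.0])
    csum = np.concatenate([[0.0], np.cumsum(x.astype(np.float64) ** 2)])
    starts = np.arange(0, len(x) - n_frame + 1, hop)
    env = np.sqrt((csum[starts + n_frame] - csum[starts]) / n_frame)
    return starts / sample_rate, env


def _threshold(env: np.ndarray, threshold_k: float) -> float:
    med = np.median(env)
    sigma = _Z_MAD * np.median(np.abs(env - med))
    return med + threshold_k * sigma


def _regions_above(times: np.ndarray, env: np.ndarray, thr: float,
                   frame: float, merge_gap: float,
                   merge_peak_ratio: float = 0.0
                   ) -> list[tuple[float, float, float]]:
    """Contiguous supra-threshold runs as (onset, offset, peak env).

    Runs separated by less than ``merge_gap`` are merged, but only when
    their envelope peaks are comparable (min/max >= ``merge_peak_ratio``);
    this keeps the bursts of one sound together without absorbing the much
    weaker leakage copies of sounds from other channels.
    """
    above = env > thr
    if not above.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    regions = []
    for i0, i1 in zip(idx[::2], idx[1::2]):
        onset = times[i0]
        offset = times[i1 - 1] + frame
        peak = float(env[i0:i1].max())
        if regions and onset - regions[-1][1] < merge_gap:
            prev = regions[-1]
            lo, hi = sorted([prev[2], peak])
            if lo >= merge_peak_ratio * hi:
                regions[-1] = (prev[0], offset, hi)
                continue
        regions.append((onset, offset, peak))
    return regions


def detect_events(filtered: np.ndarray, sample_rate: float,
                  config: DetectorConfig, *, participant_id: str = "",
                  period: str = "", quadrant: str = "") -> list[BowelSoundEvent]:
    """Detect events on one filtered channel.

    Events are supra-threshold envelope runs lasting at least
    ``min_event_duration`` after merging gaps shorter than ``merge_gap``.
    The threshold is ``median + threshold_k * 1.4826 MAD`` of the envelope,
    so detections are invariant to overall gain.
    """
    times, env = rms_envelope(filtered, sample_rate, config.frame)
    thr = _threshold(env, config.threshold_k)
    if thr <= 0:
        return []
    events = []
    for onset, offset, _ in _regions_above(times, env, thr, config.frame,
                                           config.merge_gap,
                                           config.merge_peak_ratio):
        if offset - onset < config.min_event_duration:
            continue
        i0, i1 = int(onset * sample_rate), int(offset * sample_rate)
        seg = filtered[i0:i1]
        if seg.size == 0:
            continue
        peak = float(np.max(np.abs(seg)))
        ev = BowelSoundEvent(participant_id, period, quadrant,
                             float(onset), float(offset), [], peak,
                             waveform=seg, sample_rate=sample_rate)
        ev.bursts = segment_bursts(seg, sample_rate, config, t0=onset)[0]
        events.append(ev)
    return events


def segment_bursts(event_waveform: np.ndarray, sample_rate: float,
                   config: DetectorConfig, t0: float = 0.0
                   ) -> tuple[list, list]:
    """Split one event into bursts and return (bursts, component intervals).

    Bursts are maximal envelope excursions above a fraction of the event's
    peak envelope, separated by sub-threshold gaps of at least
    ``burst_gap``.  At least one burst is always returned.
    """
    if event_waveform.size == 0 or not np.any(event_waveform):
        raise InvalidParameterError("degenerate (all-zero) event waveform")
    times, env = rms_envelope(event_waveform, sample_rate, config.frame / 2)
    thr = config.burst_rel_threshold * np.max(env)
    above = env >= thr
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    bursts = []
    for i0, i1 in zip(idx[::2], idx[1::2]):
        onset = times[i0]
        offset = times[i1 - 1] + config.frame / 2
        if bursts and onset - bursts[-1][1] < config.burst_gap:
            bursts[-1] = (bursts[-1][0], offset)
        else:
            bursts.append((onset, offset))
    if not bursts:
        bursts = [(times[0], times[-1] + config.frame / 2)]
    bursts = [(t0 + a, t0 + b) for a, b in bursts]
    onsets = [b[0] for b in bursts]
    intervals = [b - a for a, b in zip(onsets, onsets[1:])]
    return bursts, intervals


def assign_origin(event: BowelSoundEvent, filtered_channels: np.ndarray,
                  sample_rate: float, quadrant_map=QUADRANTS) -> str:
    """Quadrant whose channel peaks highest inside the event window.

    Ties break in fixed RUQ, LUQ, RLQ, LLQ order.

    Channels are compared in a narrow window around the instant of the
    event's own peak, so an unrelated louder sound elsewhere inside the
    event window cannot steal the origin.
    """
    i0 = int(event.onset * sample_rate)
    i1 = max(int(event.offset * sample_rate), i0 + 1)
    own = filtered_channels[:, i0:i1]
    ch_of_event = None
    if event.quadrant in quadrant_map:
        ch_of_event = quadrant_map.index(event.quadrant)
    if ch_of_event is not None:
        t_peak = i0 + int(np.argmax(np.abs(own[ch_of_event])))
        half = max(int(0.010 * sample_rate), 1)
        j0, j1 = max(t_peak - half, 0), t_peak + half
        peaks = np.max(np.abs(filtered_channels[:, j0:j1]), axis=1)
    else:
        peaks = np.max(np.abs(own), axis=1)
    # argmax over canonical RUQ..LUQ..RLQ..LLQ order implements the tie rule
    channels_in_order = [quadrant_map.index(q) for q in QUADRANTS]
    best = channels_in_order[int(np.argmax([peaks[c] for c in channels_in_order]))]
    return quadrant_map[best]


def _overlaps(a: BowelSoundEvent, b: BowelSoundEvent) -> bool:
    return a.onset < b.offset and b.onset < a.offset


def detect_recording(recording: Recording, config: DetectorConfig
                     ) -> list[BowelSoundEvent]:
    """Full per-recording detection: filter, detect per channel, assign
    origins, and deduplicate cross-channel leakage copies.

    A detected event is discarded as a leakage ghost when an overlapping
    event on another channel peaks at least ``dedup_peak_ratio`` times
    higher.  Remaining events are sorted by onset.
    """
    sr = recording.sample_rate
    filtered = preprocess(recording, config)

    # 1. raw supra-threshold regions per channel (bursts kept solid by a
    #    small unconditional merge at the burst-gap scale)
    raw: list[list[tuple[float, float, float]]] = []
    for ch in range(4):
        times, env = rms_envelope(filtered[ch], sr, config.frame)
        thr = _threshold(env, config.threshold_k)
        if thr <= 0:
            raw.append([])
            continue
        raw.append(_regions_above(times, env, thr, config.frame,
                                  config.burst_gap))

    # 2. cross-channel ghost pruning at region level: a region dominated by
    #    an overlapping region on another channel is a leakage copy
    pruned: list[list[tuple[float, float, float]]] = []
    for ch in range(4):
        keep = []
        for (a, b, peak) in raw[ch]:
            ghost = any(
                oa < b and a < ob
                and opeak >= config.dedup_peak_ratio * peak
                for other in range(4) if other != ch
                for (oa, ob, opeak) in raw[other])
            if not ghost:
                keep.append((a, b, peak))
        pruned.append(keep)

    # 3. merge surviving regions into events and segment bursts
    events: list[BowelSoundEvent] = []
    for ch, quadrant in enumerate(recording.quadrant_map):
        merged = []
        for (a, b, peak) in pruned[ch]:
            if merged and a - merged[-1][1] < config.merge_gap:
                merged[-1] = (merged[-1][0], b, max(merged[-1][2], peak))
            else:
                merged.append((a, b, peak))
        for (onset, offset, _) in merged:
            if offset - onset < config.min_event_duration:
                continue
            i0, i1 = int(onset * sr), int(offset * sr)
            seg = filtered[ch, i0:i1]
            if seg.size == 0:
                continue
            ev = BowelSoundEvent(recording.participant_id, recording.period,
                                 quadrant, float(onset), float(offset), [],
                                 float(np.max(np.abs(seg))),
                                 waveform=seg, sample_rate=sr)
            ev.bursts = segment_bursts(seg, sr, config, t0=onset)[0]
            ev.origin_quadrant = assign_origin(ev, filtered, sr,
                                               recording.quadrant_map)
            events.append(ev)
    events.sort(key=lambda e: (e.onset, QUADRANTS.index(e.quadrant)))
    return events


def score_detection(events, truth, tolerance: float
                    ) -> tuple[float, float, float]:
    """Greedy one-to-one onset matching; returns (precision, recall, F1).

    Predicted/truth pairs are matched greedily by increasing onset
    distance, up to ``tolerance`` seconds.  With no predictions precision
    is defined as 1; with no truth events recall is defined as 1.
    """
    if tolerance < 0:
        raise InvalidParameterError("tolerance must be >= 0")
    pred_onsets = [e.onset for e in events]
    truth_onsets = [t.onset for t in truth]
    pairs = sorted(
        (abs(p - t), i, j)
        for i, p in enumerate(pred_onsets)
        for j, t in enumerate(truth_onsets)
        if abs(p - t) <= tolerance)
    used_p, used_t = set(), set()
    matched = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matched += 1
    precision = matched / len(pred_onsets) if pred_onsets else 1.0
    recall = matched / len(truth_onsets) if truth_onsets else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1
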