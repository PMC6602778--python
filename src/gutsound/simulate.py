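"""Synthetic cohorts of 4-channel abdominal recordings with ground truth.

A bowel sound is modelled as a train of 1-5 exponentially damped sinusoid
bursts; sounds arrive on each abdominal quadrant following a (optionally
cyclically modulated) Poisson-like renewal process with a short refractory
gap so that same-quadrant sounds rarely overlap.  Each sound is written to
its origin channel at full amplitude and to the other three channels
attenuated by a leakage factor.  Broadband clicks and low-frequency rumble
are added as labelled non-bowel artifacts, plus white background noise.

All randomness flows from a master seed; per-participant streams are
derived by stable hashing of ``(seed, participant_id)`` so that cohorts
are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

QUADRANTS = ("RUQ", "LUQ", "RLQ", "LLQ")
PERIODS = ("fasted", "fed")
GROUP_IBS = "IBS"
GROUP_HEALTHY = "healthy"
GROUPS = (GROUP_IBS, GROUP_HEALTHY)


# ---------------------------------------------------------------------------
# distribution specs

def draw_dist(spec: dict, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` samples from a small declarative distribution spec.

    Supported kinds: ``constant`` (value), ``uniform`` (low, high),
    ``categorical`` (values, probs), ``lognormal`` (mean, sigma of log).
    """
    kind = spec.get("kind")
    if kind == "constant":
        return np.full(size, float(spec["value"]))
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if kind == "categorical":
        return rng.choice(np.asarray(spec["values"]), size=size, p=spec["probs"])
    if kind == "lognormal":
        return rng.lognormal(spec["mean"], spec["sigma"], size)
    raise InvalidParameterError(f"unknown distribution kind: {kind!r}")


def dist_mean(spec: dict) -> float:
    """Analytic mean of a distribution spec (used by Monte-Carlo tests)."""
    kind = spec.get("kind")
    if kind == "constant":
        return float(spec["value"])
    if kind == "uniform":
        return 0.5 * (spec["low"] + spec["high"])
    if kind == "categorical":
        return float(np.dot(spec["values"], spec["probs"]))
    if kind == "lognormal":
        return float(np.exp(spec["mean"] + 0.5 * spec["sigma"] ** 2))
    raise InvalidParameterError(f"unknown distribution kind: {kind!r}")


def _validate_dist(spec: dict, name: str) -> None:
    try:
        m = dist_mean(spec)
    except (KeyError, TypeError) as exc:
        raise InvalidParameterError(f"{name}: malformed distribution spec") from exc
    if not np.isfinite(m) or m <= 0:
        raise InvalidParameterError(f"{name}: distribution must have positive mean")
    if spec.get("kind") == "uniform" and spec["low"] <= 0:
        raise InvalidParameterError(f"{name}: support must be positive")
    if spec.get("kind") == "categorical" and min(spec["values"]) <= 0:
        raise InvalidParameterError(f"{name}: support must be positive")


# ---------------------------------------------------------------------------
# configuration

def _default_burst_counts() -> dict:
    spec = {"kind": "categorical", "values": [1, 2, 3, 4, 5],
            "probs": [0.35, 0.30, 0.20, 0.10, 0.05]}
    return {GROUP_HEALTHY: dict(spec), GROUP_IBS: dict(spec)}


def _default_intervals() -> dict:
    return {
        GROUP_HEALTHY: {"kind": "uniform", "low": 0.05, "high": 0.11},
        GROUP_IBS: {"kind": "uniform", "low": 0.07, "high": 0.13},
    }


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the development-cohort shape (31 IBS / 37 healthy) with
    higher sound quantity density in the healthy group, a fed-state rate
    increase shared by both groups, and a group difference in per-sound
    amplitude.  Durations default to the full-protocol 120 min fasted /
    40 min fed; tests scale them down via the same fields.
    """

    n_ibs: int = 31
    n_healthy: int = 37
    seed: int = 0
    fasted_duration: float = 7200.0
    fed_duration: float = 2400.0
    sample_rate: float = 44100.0
    density_healthy_fasted: float = 1.2   # sounds/s pooled over 4 quadrants
    density_ibs_fasted: float = 0.8
    fed_rate_multiplier: float = 1.6
    amplitude_scale: dict = field(
        default_factory=lambda: {GROUP_HEALTHY: 0.2, GROUP_IBS: 0.3})
    burst_count_distribution: dict = field(default_factory=_default_burst_counts)
    component_interval_distribution: dict = field(default_factory=_default_intervals)
    carrier_freq_range: tuple = (150.0, 800.0)
    damping_range: tuple = (70.0, 150.0)
    noise_rms: float = 0.01
    artifact_rate: float = 0.02
    leakage: float = 0.3
    min_event_gap: float = 0.3            # same-quadrant refractory gap, s
    mmc_enabled: bool = False
    mmc_period: float = 5400.0
    mmc_depth: float = 0.8

    def __post_init__(self):
        if self.n_ibs < 1 or self.n_healthy < 1:
            raise InvalidParameterError("n_ibs and n_healthy must be >= 1")
        for name in ("fasted_duration", "fed_duration", "sample_rate",
                     "mmc_period"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("density_healthy_fasted", "density_ibs_fasted",
                     "noise_rms", "artifact_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.fed_rate_multiplier < 1:
            raise InvalidParameterError("fed_rate_multiplier must be >= 1")
        if not 0 <= self.leakage < 1:
            raise InvalidParameterError("leakage must be in [0, 1)")
        if not 0 <= self.mmc_depth < 1:
            raise InvalidParameterError("mmc_depth must be in [0, 1)")
        for group in GROUPS:
            if self.amplitude_scale[group] <= 0:
                raise InvalidParameterError("amplitude_scale must be > 0")
            _validate_dist(self.burst_count_distribution[group],
                           f"burst_count_distribution[{group}]")
            _validate_dist(self.component_interval_distribution[group],
                           f"component_interval_distribution[{group}]")
        lo, hi = self.carrier_freq_range
        if not 0 < lo < hi:
            raise InvalidParameterError("carrier_freq_range must be 0 < low < high")
        lo, hi = self.damping_range
        if not 0 < lo <= hi:
            raise InvalidParameterError("damping_range must be 0 < low <= high")

    def density(self, group: str, period: str) -> float:
        base = (self.density_ibs_fasted if group == GROUP_IBS
                else self.density_healthy_fasted)
        return base * (self.fed_rate_multiplier if period == "fed" else 1.0)

    def duration(self, period: str) -> float:
        return self.fed_duration if period == "fed" else self.fasted_duration

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carrier_freq_range"] = list(self.carrier_freq_range)
        d["damping_range"] = list(self.damping_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("carrier_freq_range", "damping_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EventTruth:
    """Ground-truth record of one simulated acoustic event."""

    participant_id: str
    period: str
    quadrant: str
    onset: float
    offset: float
    burst_onsets: list
    peak_amplitude: float
    is_bowel: bool = True


@dataclass
class Recording:
    """One recording period: four ordered quadrant waveforms in [-1, 1]."""

    participant_id: str
    group: str
    period: str
    sample_rate: float
    channels: np.ndarray                      # shape (4, n_samples)
    quadrant_map: tuple = QUADRANTS

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise InvalidParameterError("channels must have shape (4, n)")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if self.channels.size and np.max(np.abs(self.channels)) > 1.0 + 1e-12:
            raise InvalidParameterError("samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.sample_rate

    def channel(self, quadrant: str) -> np.ndarray:
        return self.channels[self.quadrant_map.index(quadrant)]


# ---------------------------------------------------------------------------
# waveform synthesis

def synth_bowel_sound(burst_count: int,
                      component_intervals: Sequence[float],
                      carrier_freq: float,
                      damping: float,
                      amplitude: float,
                      sample_rate: float,
                      burst_amplitudes: Sequence[float] | None = None,
                      ) -> np.ndarray:
    """Synthesize one bowel sound as a train of damped sinusoid bursts.

    Each burst is ``a * exp(-damping t) * sin(2 pi f t)``; burst onsets are
    the cumulative sums of ``component_intervals``.  The segment ends when
    the last burst has decayed to 0.1% of its peak.
    """
    if burst_count < 1:
        raise InvalidParameterError("burst_count must be >= 1")
    if len(component_intervals) != burst_count - 1:
        raise InvalidParameterError(
            "need exactly burst_count - 1 component intervals")
    if carrier_freq <= 0 or damping <= 0 or amplitude <= 0 or sample_rate <= 0:
        raise InvalidParameterError("carrier_freq, damping, amplitude and "
                                    "sample_rate must be > 0")
    intervals = np.asarray(component_intervals, dtype=float)
    if intervals.size and np.any(intervals <= 0):
        raise InvalidParameterError("component intervals must be > 0")
    if burst_amplitudes is None:
        burst_amplitudes = np.full(burst_count, amplitude)
    else:
        burst_amplitudes = np.asarray(burst_amplitudes, dtype=float)
        if burst_amplitudes.shape != (burst_count,) or np.any(burst_amplitudes <= 0):
            raise InvalidParameterError("need burst_count positive burst amplitudes")

    tail = np.log(1000.0) / damping            # decay to 0.1% of peak
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    total = onsets[-1] + tail
    n = int(np.ceil(total * sample_rate))
    out = np.zeros(n)
    n_burst = int(np.ceil(tail * sample_rate))
    t = np.arange(n_burst) / sample_rate
    shape = np.exp(-damping * t) * np.sin(2.0 * np.pi * carrier_freq * t)
    for onset, a in zip(onsets, burst_amplitudes):
        i0 = int(round(onset * sample_rate))
        seg = shape[: n - i0]
        out[i0:i0 + len(seg)] += a * seg
    return out


def _renewal_onsets(rate: float, duration: float, min_gap: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Exponential-gap renewal process with a refractory gap.

    The exponential rate is inflated so the long-run event rate stays
    ``rate`` despite the enforced minimum gap.
    """
    if rate <= 0 or duration <= 0:
        return np.array([])
    if rate * min_gap >= 1.0:
        raise InvalidParameterError("min_event_gap too large for event rate")
    adj = rate / (1.0 - rate * min_gap)
    onsets = []
    t = rng.exponential(1.0 / rate)            # first arrival: plain Poisson
    while t < duration:
        onsets.append(t)
        t += min_gap + rng.exponential(1.0 / adj)
    return np.asarray(onsets)


def _mmc_thin(onsets: np.ndarray, period: float, depth: float,
              rng: np.random.Generator) -> np.ndarray:
    """Thin onsets to a sinusoidally modulated rate, preserving the mean."""
    if onsets.size == 0:
        return onsets
    accept = (1.0 + depth * np.sin(2.0 * np.pi * onsets / period)) / (1.0 + depth)
    keep = rng.uniform(size=onsets.size) < accept
    return onsets[keep]


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    # stable across platforms/runs: hash the (seed, id) pair
    digest = hashlib.sha256(f"{seed}:{participant_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _add_artifacts(channels: np.ndarray, sample_rate: float, duration: float,
                   rate: float, rng: np.random.Generator, participant_id: str,
                   period: str) -> list:
    """Broadband clicks and low-frequency rumble, labelled non-bowel."""
    truths = []
    n_total = channels.shape[1]
    n_art = rng.poisson(rate * duration)
    for _ in range(n_art):
        onset = rng.uniform(0, duration)
        ch = rng.integers(0, 4)
        if rng.uniform() < 0.5:                         # click, ~3 ms
            dur = 0.003
            n = max(int(dur * sample_rate), 4)
            seg = 0.3 * rng.normal(size=n) * np.hanning(n)
        else:                                           # rumble, 25-45 Hz
            dur = 0.5
            n = int(dur * sample_rate)
            f = rng.uniform(25, 45)
            t = np.arange(n) / sample_rate
            seg = 0.2 * np.sin(2 * np.pi * f * t) * np.hanning(n)
        i0 = int(onset * sample_rate)
        seg = seg[: n_total - i0]
        if seg.size == 0:
            continue
        channels[ch, i0:i0 + len(seg)] += seg
        truths.append(EventTruth(participant_id, period, QUADRANTS[ch],
                                 onset, onset + len(seg) / sample_rate,
                                 [onset], float(np.max(np.abs(seg))),
                                 is_bowel=False))
    return truths


def _simulate_period(participant_id: str, group: str, period: str,
                     config: CohortConfig, rng: np.random.Generator
                     ) -> tuple[Recording, list]:
    sr = config.sample_rate
    duration = config.duration(period)
    n = int(round(duration * sr))
    channels = np.zeros((4, n))
    rate_per_quadrant = config.density(group, period) / 4.0
    amp_scale = config.amplitude_scale[group]
    burst_spec = config.burst_count_distribution[group]
    interval_spec = config.component_interval_distribution[group]
    truths: list[EventTruth] = []

    for qi, quadrant in enumerate(QUADRANTS):
        if config.mmc_enabled and period == "fasted":
            onsets = _renewal_onsets(rate_per_quadrant * (1 + config.mmc_depth),
                                     duration, config.min_event_gap, rng)
            onsets = _mmc_thin(onsets, config.mmc_period, config.mmc_depth, rng)
        else:
            onsets = _renewal_onsets(rate_per_quadrant, duration,
                                     config.min_event_gap, rng)
        for onset in onsets:
            burst_count = int(draw_dist(burst_spec, rng, 1)[0])
            intervals = draw_dist(interval_spec, rng, burst_count - 1)
            carrier = rng.uniform(*config.carrier_freq_range)
            damping = rng.uniform(*config.damping_range)
            amplitude = amp_scale * rng.uniform(0.6, 1.0)
            seg = synth_bowel_sound(burst_count, intervals, carrier, damping,
                                    amplitude, sr)
            i0 = int(round(onset * sr))
            if i0 + len(seg) > n:        # skip events that overrun the period
                continue
            channels[qi, i0:i0 + len(seg)] += seg
            for other in range(4):
                if other != qi:
                    channels[other, i0:i0 + len(seg)] += config.leakage * seg
            burst_onsets = (onset + np.concatenate(
                [[0.0], np.cumsum(intervals)])).tolist()
            truths.append(EventTruth(participant_id, period, quadrant,
                                     float(onset), float(onset + len(seg) / sr),
                                     burst_onsets, float(amplitude)))

    truths += _add_artifacts(channels, sr, duration, config.artifact_rate,
                             rng, participant_id, period)
    if config.noise_rms > 0:
        channels += rng.normal(0.0, config.noise_rms, channels.shape)

    peak = np.max(np.abs(channels)) if channels.size else 0.0
    if peak > 1.0:                       # rare with default amplitudes
        channels /= peak
        for tr in truths:
            tr.peak_amplitude /= peak
    truths.sort(key=lambda tr: tr.onset)
    rec = Recording(participant_id, group, period, sr, channels)
    return rec, truths


def generate_participant(group: str, config: CohortConfig,
                         participant_id: str
                         ) -> tuple[Recording, Recording, list]:
    """Simulate both recording periods for one participant.

    Returns the fasted recording, the fed recording and the pooled truth
    table.  Deterministic given ``(config.seed, participant_id)``.
    """
    if group not in GROUPS:
        raise InvalidParameterError(f"unknown group {group!r}")
    rng = _participant_rng(config.seed, participant_id)
    fasted, truth_fasted = _simulate_period(participant_id, group, "fasted",
                                            config, rng)
    fed, truth_fed = _simulate_period(participant_id, group, "fed", config, rng)
    return fasted, fed, truth_fasted + truth_fed


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    recordings: dict                      # period -> Recording
    truth: list                           # EventTruth


@dataclass
class Cohort:
    config: CohortConfig
    participants: list                    # ParticipantData

    def __len__(self):
        return len(self.participants)

    @property
    def n_recordings(self) -> int:
        return sum(len(p.recordings) for p in self.participants)

    def truth_events(self, bowel_only: bool = True) -> list:
        out = []
        for p in self.participants:
            out.extend(t for t in p.truth if t.is_bowel or not bowel_only)
        return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort in memory (see :mod:`gutsound.io` to write it)."""
    participants = []
    for i in range(config.n_ibs):
        pid = f"IBS{i + 1:03d}"
        fasted, fed, truth = generate_participant(GROUP_IBS, config, pid)
        participants.append(ParticipantData(
            pid, GROUP_IBS, {"fasted": fasted, "fed": fed}, truth))
    for i in range(config.n_healthy):
        pid = f"H{i + 1:03d}"
        fasted, fed, truth = generate_participant(GROUP_HEALTHY, config, pid)
        participants.append(ParticipantData(
            pid, GROUP_HEALTHY, {"fasted": fasted, "fed": fed}, truth))
    return Cohort(config, participants)
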