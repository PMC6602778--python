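"""Per-sound time/frequency features and per-participant aggregation.

Spectra are averaged periodograms (Hann-windowed Welch estimate) restricted
to the detector's analysis band, so spectral shape statistics are stable
for short events and spectral flatness behaves sensibly for noise-like
signals.  The default "final model" registry exposes 26 features —
8 time-domain and 18 frequency-domain — drawn from the named
feature families; the registry is switchable by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import (DegenerateSignalError, InvalidParameterError,
                     UnusableParticipantError)
from .simulate import PERIODS, QUADRANTS

DEFAULT_BAND = (60.0, 1500.0)
DEFAULT_SUBBAND_EDGES = (60.0, 250.0, 500.0, 1000.0, 1500.0)

#: per-sound scalar features carried into aggregation, in fixed order
SOUND_FEATURE_NAMES = (
    "duration", "burst_number", "mean_component_interval", "peak_amplitude",
    "rms_energy", "zero_crossing_rate", "waveform_skewness",
    "waveform_kurtosis", "crest_factor", "spectral_centroid",
    "spectral_bandwidth", "spectral_rolloff_85", "peak_frequency",
    "spectral_flatness", "subband_ratio_1", "subband_ratio_2",
    "subband_ratio_3", "subband_ratio_4",
)

AGG_STATS = ("mean", "median", "sd", "iqr")


@dataclass
class SoundFeatureSet:
    """Time- and frequency-domain descriptors of one bowel sound."""

    duration: float
    burst_number: int
    mean_component_interval: float | None
    peak_amplitude: float
    rms_energy: float
    zero_crossing_rate: float
    waveform_skewness: float
    waveform_kurtosis: float
    crest_factor: float
    spectral_centroid: float
    spectral_bandwidth: float
    spectral_rolloff_85: float
    peak_frequency: float
    spectral_flatness: float
    subband_energy_ratios: tuple

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in SOUND_FEATURE_NAMES[:14]}
        for i, r in enumerate(self.subband_energy_ratios, start=1):
            d[f"subband_ratio_{i}"] = r
        return d


def power_spectrum(x: np.ndarray, sample_rate: float, nperseg: int = 512
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed averaged periodogram (Welch) of one event."""
    nper = min(len(x), nperseg)
    freqs, pxx = sps.welch(x, fs=sample_rate, window="hann", nperseg=nper)
    return freqs, pxx


def subband_energy_ratios(freqs: np.ndarray, power: np.ndarray,
                          band_edges=DEFAULT_SUBBAND_EDGES) -> np.ndarray:
    """Fraction of in-band spectral energy in each band; sums to 1."""
    edges = np.asarray(band_edges, dtype=float)
    if edges.size < 2:
        raise InvalidParameterError("need at least 2 band edges")
    if np.any(np.diff(edges) <= 0):
        raise InvalidParameterError("band edges must be strictly increasing")
    energies = np.empty(edges.size - 1)
    for i in range(edges.size - 1):
        mask = (freqs >= edges[i]) & (freqs < edges[i + 1])
        energies[i] = power[mask].sum()
    total = energies.sum()
    if total <= 0:
        raise DegenerateSignalError("no spectral energy inside band edges")
    return energies / total


def _spectral_flatness(power: np.ndarray) -> float:
    p = power[power > 0]
    if p.size == 0:
        return 0.0
    if p.size < power.size:
        return 0.0          # true zeros force geometric mean to 0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def sound_features(x: np.ndarray, sample_rate: float,
                   bursts: list | None = None,
                   band=DEFAULT_BAND,
                   subband_edges=DEFAULT_SUBBAND_EDGES) -> SoundFeatureSet:
    """Extract the full per-sound descriptor set from one event waveform.

    ``bursts`` is the (onset, offset) list from burst segmentation; when
    omitted the sound is treated as a single burst.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0 or not np.any(x):
        raise DegenerateSignalError("all-zero event waveform")
    duration = x.size / sample_rate
    if bursts is None or len(bursts) == 0:
        bursts = [(0.0, duration)]
    onsets = [b[0] for b in bursts]
    intervals = np.diff(onsets)
    mean_interval = float(np.mean(intervals)) if intervals.size else None

    peak = float(np.max(np.abs(x)))
    rms = float(np.sqrt(np.mean(x ** 2)))
    zcr = float(np.count_nonzero(np.diff(np.signbit(x))) / duration)
    skew = float(spstats.skew(x))
    kurt = float(spstats.kurtosis(x))
    crest = peak / rms

    freqs, pxx = power_spectrum(x, sample_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    f_in, p_in = freqs[mask], pxx[mask]
    total = p_in.sum()
    if total <= 0:
        raise DegenerateSignalError("no spectral energy inside analysis band")
    centroid = float(np.sum(f_in * p_in) / total)
    bandwidth = float(np.sqrt(np.sum((f_in - centroid) ** 2 * p_in) / total))
    cum = np.cumsum(p_in)
    rolloff = float(f_in[np.searchsorted(cum, 0.85 * total)])
    peak_freq = float(f_in[int(np.argmax(p_in))])
    flatness = _spectral_flatness(p_in)
    ratios = tuple(subband_energy_ratios(freqs, pxx, subband_edges))

    return SoundFeatureSet(
        duration=duration, burst_number=len(bursts),
        mean_component_interval=mean_interval, peak_amplitude=peak,
        rms_energy=rms, zero_crossing_rate=zcr, waveform_skewness=skew,
        waveform_kurtosis=kurt, crest_factor=crest,
        spectral_centroid=centroid, spectral_bandwidth=bandwidth,
        spectral_rolloff_85=rolloff, peak_frequency=peak_freq,
        spectral_flatness=flatness, subband_energy_ratios=ratios)


def quantity_density(events, period_duration: float) -> float:
    """Sounds per second over a recording period."""
    if period_duration <= 0:
        raise InvalidParameterError("period duration must be > 0")
    return len(events) / period_duration


def summed_amplitude(events, period_duration: float,
                     reference_duration: float) -> float:
    """Sum of per-sound peak amplitudes, scaled to a reference duration.

    Scaling compensates for unequal period lengths so fasted and fed
    periods are comparable.
    """
    if period_duration <= 0 or reference_duration <= 0:
        raise InvalidParameterError("durations must be > 0")
    total = float(sum(e.peak_amplitude for e in events))
    return total * (reference_duration / period_duration)


# ---------------------------------------------------------------------------
# per-participant aggregation

def _stat(values: np.ndarray, stat: str) -> float:
    if values.size == 0:
        return np.nan
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return float(np.median(values))
    if stat == "sd":
        return float(np.std(values))
    if stat == "iqr":
        q75, q25 = np.percentile(values, [75, 25])
        return float(q75 - q25)
    raise InvalidParameterError(f"unknown statistic {stat!r}")


def _group_keys():
    """Fixed ordering of aggregation groups: quadrant-period cells, then
    period pools, then the all-events pool."""
    keys = [f"{q}_{p}" for q in QUADRANTS for p in PERIODS]
    keys += list(PERIODS)
    keys += ["all"]
    return keys


def feature_vector_names() -> list:
    """The fixed, documented ordering of every participant-level feature."""
    names = []
    for key in _group_keys():
        for feat in SOUND_FEATURE_NAMES:
            for stat in AGG_STATS:
                names.append(f"{key}_{feat}_{stat}")
    for p in PERIODS:
        names.append(f"quantity_density_{p}")
        names.append(f"summed_amplitude_{p}")
    return names


@dataclass
class ParticipantFeatureVector:
    participant_id: str
    group: str | None
    features: dict = field(default_factory=dict)   # name -> float (NaN=missing)

    def missing_mask(self) -> dict:
        return {k: not np.isfinite(v) for k, v in self.features.items()}

    def values(self, names) -> np.ndarray:
        return np.array([self.features[n] for n in names])


def aggregate_participant(participant_id: str,
                          events_by_period: dict,
                          period_durations: dict,
                          group: str | None = None,
                          reference_duration: float | None = None,
                          band=DEFAULT_BAND,
                          subband_edges=DEFAULT_SUBBAND_EDGES
                          ) -> ParticipantFeatureVector:
    """Aggregate per-sound features into one participant-level vector.

    ``events_by_period`` maps period -> list of detected events (with
    waveforms attached); statistics (mean, median, SD, IQR) are computed per
    quadrant-period cell, per period and pooled, then per-period quantity
    density and duration-scaled summed amplitude are appended.  Empty cells
    yield NaN (imputed later from training-set medians).
    """
    all_events = [e for p in PERIODS for e in events_by_period.get(p, [])]
    if not all_events:
        raise UnusableParticipantError(
            f"participant {participant_id}: no events in either period")
    if reference_duration is None:
        reference_duration = min(period_durations[p] for p in PERIODS)

    per_event = {}
    for p in PERIODS:
        for e in events_by_period.get(p, []):
            fs = sound_features(e.waveform, e.sample_rate, e.bursts,
                                band=band, subband_edges=subband_edges)
            per_event[id(e)] = (p, e, fs.to_dict())

    def rows_for(key):
        if key == "all":
            return [r for r in per_event.values()]
        if key in PERIODS:
            return [r for r in per_event.values() if r[0] == key]
        q, p = key.rsplit("_", 1)
        return [r for r in per_event.values()
                if r[0] == p and r[1].quadrant == q]

    features = {}
    for key in _group_keys():
        rows = rows_for(key)
        for feat in SOUND_FEATURE_NAMES:
            vals = np.array([r[2][feat] for r in rows
                             if r[2][feat] is not None], dtype=float)
            for stat in AGG_STATS:
                features[f"{key}_{feat}_{stat}"] = _stat(vals, stat)
    for p in PERIODS:
        evs = events_by_period.get(p, [])
        features[f"quantity_density_{p}"] = quantity_density(
            evs, period_durations[p])
        features[f"summed_amplitude_{p}"] = summed_amplitude(
            evs, period_durations[p], reference_duration)
    return ParticipantFeatureVector(participant_id, group, features)


# ---------------------------------------------------------------------------
# feature registry

@dataclass(frozen=True)
class RegistryEntry:
    name: str
    domain: str          # "time" or "frequency"


def final_model_registry() -> list:
    """The default 26-feature classifier registry: 8 time-domain and
    18 frequency-domain participant-level features.

    Time-domain: burst number (mean, SD), component interval (mean, SD),
    mean sound duration, mean fasted peak amplitude, fasted quantity
    density and fasted summed amplitude.  Frequency-domain: mean and SD of
    centroid, bandwidth, 85% rolloff, peak frequency and flatness, plus
    mean and SD of the four subband energy ratios.
    """
    time = [
        RegistryEntry("all_burst_number_mean", "time"),
        RegistryEntry("all_burst_number_sd", "time"),
        RegistryEntry("all_mean_component_interval_mean", "time"),
        RegistryEntry("all_mean_component_interval_sd", "time"),
        RegistryEntry("all_duration_mean", "time"),
        RegistryEntry("fasted_peak_amplitude_mean", "time"),
        RegistryEntry("quantity_density_fasted", "time"),
        RegistryEntry("summed_amplitude_fasted", "time"),
    ]
    freq = []
    for feat in ("spectral_centroid", "spectral_bandwidth",
                 "spectral_rolloff_85", "peak_frequency", "spectral_flatness"):
        freq.append(RegistryEntry(f"all_{feat}_mean", "frequency"))
        freq.append(RegistryEntry(f"all_{feat}_sd", "frequency"))
    for i in range(1, 5):
        freq.append(RegistryEntry(f"all_subband_ratio_{i}_mean", "frequency"))
        freq.append(RegistryEntry(f"all_subband_ratio_{i}_sd", "frequency"))
    return time + freq


def registry_names(registry=None) -> list:
    registry = final_model_registry() if registry is None else registry
    return [e.name for e in registry]


def build_feature_matrix(vectors, registry=None):
    """Stack participant vectors into (X, y, feature_names, participant_ids).

    ``y`` is a boolean array, True for the IBS (positive) class; it is None
    when any participant lacks a group label.
    """
    import pandas as pd

    names = registry_names(registry)
    # per-period density/amplitude always travel with the matrix: the group
    # statistics need them even when the registry does not
    extras = [f"{base}_{p}" for base in ("quantity_density",
                                         "summed_amplitude")
              for p in PERIODS if f"{base}_{p}" not in names]
    rows = []
    for v in vectors:
        row = {"participant_id": v.participant_id, "label": v.group}
        row.update({n: v.features.get(n, np.nan) for n in names + extras})
        rows.append(row)
    return pd.DataFrame(rows,
                        columns=["participant_id", "label"] + names + extras)
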