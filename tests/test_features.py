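import numpy as np
import pytest

from gutsound import (aggregate_participant, build_feature_matrix,
                      final_model_registry, quantity_density, sound_features,
                      subband_energy_ratios, summed_amplitude)
from gutsound.detection import BowelSoundEvent
from gutsound.errors import (DegenerateSignalError, InvalidParameterError,
                             UnusableParticipantError)
from gutsound.features import (SOUND_FEATURE_NAMES, feature_vector_names,
                               power_spectrum, registry_names)

SR = 8000.0


def _tone(freq, duration=0.5, amp=0.5, sr=SR):
    t = np.arange(int(duration * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


def _event(waveform, quadrant="RUQ", period="fasted", peak=None, sr=SR,
           onset=0.0):
    peak = float(np.max(np.abs(waveform))) if peak is None else peak
    dur = len(waveform) / sr
    return BowelSoundEvent("p1", period, quadrant, onset, onset + dur,
                           [(onset, onset + dur)], peak,
                           waveform=waveform, sample_rate=sr)


class TestSoundFeatures:
    def test_tone_centroid_and_peak_within_one_bin(self):
        x = _tone(500.0, duration=0.1)
        fs = sound_features(x, SR)
        bin_width = SR / min(len(x), 512)
        assert abs(fs.spectral_centroid - 500.0) <= bin_width
        assert abs(fs.peak_frequency - 500.0) <= bin_width

    def test_white_noise_flatness_monte_carlo(self, rng):
        # averaged periodogram of white noise is nearly flat
        flatness = [sound_features(rng.normal(size=int(0.5 * SR)), SR
                                   ).spectral_flatness for _ in range(100)]
        assert np.mean(flatness) >= 0.8
        assert min(flatness) >= 0.7

    def test_tone_flatness_low(self):
        assert sound_features(_tone(400.0), SR).spectral_flatness < 0.1

    def test_crest_factor_brute_force(self, rng):
        x = rng.normal(size=4000)
        fs = sound_features(x, SR)
        expected = np.max(np.abs(x)) / np.sqrt(np.mean(x ** 2))
        assert fs.crest_factor == pytest.approx(expected, rel=1e-12)

    def test_zero_waveform_rejected(self):
        with pytest.raises(DegenerateSignalError):
            sound_features(np.zeros(1000), SR)

    def test_amplitude_features_scale_spectral_invariant(self, rng):
        x = rng.normal(size=4000) * np.hanning(4000)
        a, b = sound_features(x, SR), sound_features(3.0 * x, SR)
        assert b.peak_amplitude == pytest.approx(3 * a.peak_amplitude)
        assert b.rms_energy == pytest.approx(3 * a.rms_energy)
        assert b.spectral_centroid == pytest.approx(a.spectral_centroid)
        assert b.spectral_flatness == pytest.approx(a.spectral_flatness)
        assert b.crest_factor == pytest.approx(a.crest_factor)
        np.testing.assert_allclose(b.subband_energy_ratios,
                                   a.subband_energy_ratios)

    def test_burst_fields(self):
        x = _tone(300.0, duration=0.3)
        fs = sound_features(x, SR, bursts=[(0.0, 0.1), (0.12, 0.2),
                                           (0.24, 0.3)])
        assert fs.burst_number == 3
        assert fs.mean_component_interval == pytest.approx(0.12)
        single = sound_features(x, SR, bursts=[(0.0, 0.3)])
        assert single.mean_component_interval is None

    def test_centroid_within_band(self, rng):
        for _ in range(10):
            x = rng.normal(size=2000)
            fs = sound_features(x, SR)
            assert 60.0 <= fs.spectral_centroid <= 1500.0


class TestSubbandRatios:
    def test_single_band_tone(self):
        freqs, pxx = power_spectrum(_tone(200.0, duration=1.0), SR)
        ratios = subband_energy_ratios(freqs, pxx)
        assert ratios[0] >= 0.99
        assert ratios[1:].max() <= 0.01

    def test_two_tone_split(self):
        x = _tone(300.0, duration=1.0) + _tone(700.0, duration=1.0)
        ratios = subband_energy_ratios(*power_spectrum(x, SR))
        assert ratios[0] <= 0.02 and ratios[3] <= 0.02
        assert ratios[1] == pytest.approx(0.5, abs=0.05)
        assert ratios[2] == pytest.approx(0.5, abs=0.05)

    def test_normalization(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(500, 5000))
            ratios = subband_energy_ratios(*power_spectrum(x, SR))
            assert abs(ratios.sum() - 1.0) <= 1e-9
            assert np.all(ratios >= 0)

    def test_zero_energy_rejected(self):
        freqs = np.linspace(0, 4000, 100)
        with pytest.raises(DegenerateSignalError):
            subband_energy_ratios(freqs, np.zeros(100))

    def test_bad_edges_rejected(self):
        freqs = np.linspace(0, 4000, 100)
        with pytest.raises(InvalidParameterError):
            subband_energy_ratios(freqs, np.ones(100), band_edges=[100])


class TestDensityAndAmplitude:
    def test_density_definition(self):
        assert quantity_density(range(120), 60.0) == 2.0
        assert quantity_density([], 60.0) == 0.0

    def test_density_duration_validation(self):
        with pytest.raises(InvalidParameterError):
            quantity_density([], 0.0)

    def test_density_poisson_oracle(self, rng):
        lam, T = 1.5, 600.0
        n = rng.poisson(lam * T)
        est = quantity_density(range(n), T)
        assert abs(est - lam) <= 3 * np.sqrt(lam / T)

    def test_summed_amplitude_plain_sum(self):
        evs = [_event(_tone(300.0), peak=a) for a in (0.1, 0.2, 0.3)]
        assert summed_amplitude(evs, 40.0, 40.0) == pytest.approx(0.6)

    def test_summed_amplitude_scaling(self):
        evs = [_event(_tone(300.0), peak=a) for a in (0.1, 0.2, 0.3)]
        assert summed_amplitude(evs, 120.0, 40.0) == pytest.approx(0.2)

    def test_summed_amplitude_linearity(self):
        evs = [_event(_tone(300.0), peak=a) for a in (0.1, 0.2, 0.3)]
        doubled = [_event(_tone(300.0), peak=2 * a) for a in (0.1, 0.2, 0.3)]
        assert summed_amplitude(doubled, 60.0, 40.0) == pytest.approx(
            2 * summed_amplitude(evs, 60.0, 40.0))

    def test_invalid_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            summed_amplitude([], -1.0, 40.0)


class TestAggregateParticipant:
    DUR = {"fasted": 60.0, "fed": 20.0}

    def test_single_event_per_group(self):
        ev_fast = _event(_tone(300.0), quadrant="RUQ", period="fasted")
        ev_fed = _event(_tone(500.0), quadrant="LLQ", period="fed")
        v = aggregate_participant("p1", {"fasted": [ev_fast], "fed": [ev_fed]},
                                  self.DUR)
        c = sound_features(ev_fast.waveform, SR,
                           ev_fast.bursts).spectral_centroid
        assert v.features["RUQ_fasted_spectral_centroid_mean"] == pytest.approx(c)
        assert v.features["RUQ_fasted_spectral_centroid_median"] == pytest.approx(c)
        assert v.features["RUQ_fasted_spectral_centroid_sd"] == 0.0

    def test_empty_cells_are_missing(self):
        ev = _event(_tone(300.0), quadrant="RUQ", period="fasted")
        ev2 = _event(_tone(400.0), quadrant="RUQ", period="fed")
        v = aggregate_participant("p1", {"fasted": [ev], "fed": [ev2]},
                                  self.DUR)
        assert np.isnan(v.features["LLQ_fed_spectral_centroid_mean"])
        mask = v.missing_mask()
        assert mask["LLQ_fed_spectral_centroid_mean"]
        assert not mask["RUQ_fasted_spectral_centroid_mean"]

    def test_no_events_rejected(self):
        with pytest.raises(UnusableParticipantError):
            aggregate_participant("p1", {"fasted": [], "fed": []}, self.DUR)

    def test_order_invariance(self, rng):
        events = [_event(rng.normal(size=2000) * np.hanning(2000),
                         quadrant=q, period="fasted", onset=i)
                  for i, q in enumerate(["RUQ", "LUQ", "RLQ", "LLQ"] * 3)]
        fed = [_event(rng.normal(size=1500) * np.hanning(1500), period="fed")]
        a = aggregate_participant("p1", {"fasted": events, "fed": fed}, self.DUR)
        b = aggregate_participant("p1", {"fasted": events[::-1], "fed": fed},
                                  self.DUR)
        for k in a.features:
            assert a.features[k] == pytest.approx(b.features[k], nan_ok=True)

    def test_aggregates_match_brute_force(self, rng):
        # oracle: recompute the mean/SD directly from per-event features
        events = [_event(rng.normal(size=2000) * np.hanning(2000),
                         quadrant="RUQ", period="fasted", onset=i)
                  for i in range(100)]
        fed = [_event(_tone(300.0), period="fed")]
        v = aggregate_participant("p1", {"fasted": events, "fed": fed}, self.DUR)
        centroids = np.array([
            sound_features(e.waveform, SR, e.bursts).spectral_centroid
            for e in events])
        assert v.features["RUQ_fasted_spectral_centroid_mean"] == \
            pytest.approx(centroids.mean())
        assert v.features["RUQ_fasted_spectral_centroid_sd"] == \
            pytest.approx(centroids.std())
        q75, q25 = np.percentile(centroids, [75, 25])
        assert v.features["RUQ_fasted_spectral_centroid_iqr"] == \
            pytest.approx(q75 - q25)
        assert v.features["quantity_density_fasted"] == pytest.approx(100 / 60.0)


class TestRegistry:
    def test_final_model_has_26_features(self):
        registry = final_model_registry()
        assert len(registry) == 26
        assert len({e.name for e in registry}) == 26

    def test_domain_split_8_time_18_frequency(self):
        registry = final_model_registry()
        assert sum(e.domain == "time" for e in registry) == 8
        assert sum(e.domain == "frequency" for e in registry) == 18

    def test_registry_names_exist_in_feature_vector(self):
        names = set(feature_vector_names())
        for entry in final_model_registry():
            assert entry.name in names

    def test_feature_vector_ordering_fixed(self):
        assert feature_vector_names() == feature_vector_names()

    def test_build_feature_matrix_columns(self):
        ev = _event(_tone(300.0), period="fasted")
        ev2 = _event(_tone(400.0), period="fed")
        v = aggregate_participant("p1", {"fasted": [ev], "fed": [ev2]},
                                  {"fasted": 60.0, "fed": 20.0}, group="IBS")
        df = build_feature_matrix([v])
        assert list(df.columns[:2]) == ["participant_id", "label"]
        n = len(registry_names())
        assert list(df.columns[2:2 + n]) == registry_names()
        # per-period density/amplitude always travel with the matrix
        assert "quantity_density_fed" in df.columns
        assert "summed_amplitude_fed" in df.columns
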