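"""Spectral extraction: analytic identities, oracle agreement, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsespec.errors import (
    DegenerateSpectrumError,
    InsufficientBeatsError,
    UndersampledBeatError,
)
from pulsespec.segment import BeatSegment, detect_onsets, extract_beats
from pulsespec.simulate import WaveformRecord
from pulsespec.spectral import (
    FEATURE_NAMES,
    BeatSpectrum,
    aggregate_indices,
    amplitude_proportion,
    beat_spectrum,
    extract_features,
)
from pulsespec.utils import wrap_phase_deg


def make_beat(amplitudes, phases_deg, dc=0.0, n_samples=431, period=0.862):
    """Sample a finite cosine series as one BeatSegment."""
    t = np.arange(n_samples) / n_samples  # beat fractions
    x = np.full(n_samples, float(dc))
    for n, (a, p) in enumerate(zip(amplitudes, phases_deg), start=1):
        x += a * np.cos(2 * np.pi * n * t + np.radians(p))
    return BeatSegment("toy", 0, 0, period, x, n_samples / period)


def least_squares_harmonics(beat, n_harmonics=10):
    """Independent oracle: direct trigonometric least squares on the beat."""
    y = beat.samples
    t = np.arange(len(y)) / len(y)
    columns = [np.ones_like(t)]
    for n in range(1, n_harmonics + 1):
        columns.append(np.cos(2 * np.pi * n * t))
        columns.append(np.sin(2 * np.pi * n * t))
    coef, *_ = np.linalg.lstsq(np.column_stack(columns), y, rcond=None)
    a = coef[1::2]
    b = coef[2::2]
    amplitude = np.hypot(a, b)
    phase = wrap_phase_deg(np.degrees(np.arctan2(-b, a)))
    return amplitude, phase


class TestBeatSpectrum:
    def test_single_cosine_identity(self):
        beat = make_beat([1.0] + [0.0] * 9, [0.0] * 10)
        s = beat_spectrum(beat)
        assert s.amplitude[0] == pytest.approx(1.0, abs=1e-9)
        assert s.phase_deg[0] == pytest.approx(0.0, abs=1e-6)
        assert np.all(s.amplitude[1:] < 1e-9)

    def test_two_component_series(self):
        beat = make_beat([2.0, 0.5] + [0.0] * 8, [0.0, 30.0] + [0.0] * 8, dc=1.5)
        s = beat_spectrum(beat)
        assert s.amplitude[0] == pytest.approx(2.0, abs=1e-9)
        assert s.amplitude[1] == pytest.approx(0.5, abs=1e-9)
        assert s.phase_deg[1] == pytest.approx(30.0, abs=1e-6)
        assert s.dc == pytest.approx(1.5, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        amplitudes = np.exp(-0.4 * np.arange(10)) * rng.uniform(0.5, 1.5, 10)
        phases = rng.uniform(-179.0, 180.0, 10)
        beat = make_beat(amplitudes, phases, dc=2.0)
        s = beat_spectrum(beat)
        oracle_amp, oracle_phase = least_squares_harmonics(beat)
        assert np.allclose(s.amplitude, oracle_amp, rtol=1e-4, atol=1e-9)
        phase_diff = wrap_phase_deg(s.phase_deg - oracle_phase)
        assert np.all(np.abs(phase_diff) < 1e-3)
        # and both agree with the generating parameters
        assert np.allclose(s.amplitude, amplitudes, rtol=1e-4)

    def test_undersampled_beat_rejected(self):
        beat = make_beat([1.0] + [0.0] * 9, [0.0] * 10, n_samples=15)
        with pytest.raises(UndersampledBeatError):
            beat_spectrum(beat)


class TestAmplitudeProportion:
    def test_h1_mode(self):
        s = BeatSpectrum(0, np.array([2.0, 0.5] + [0.0] * 8), np.zeros(10), 0.0)
        c = amplitude_proportion(s, mode="h1")
        assert c[0] == 100.0
        assert c[1] == pytest.approx(25.0)
        assert np.all(c[2:] == 0.0)

    def test_sum_mode(self):
        s = BeatSpectrum(0, np.array([2.0, 0.5] + [0.0] * 8), np.zeros(10), 0.0)
        c = amplitude_proportion(s, mode="sum")
        assert c[0] == pytest.approx(80.0)
        assert c[1] == pytest.approx(20.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=10, max_size=10))
    def test_sum_mode_totals_100(self, amplitudes):
        s = BeatSpectrum(0, np.array(amplitudes), np.zeros(10), 0.0)
        assert np.sum(amplitude_proportion(s, mode="sum")) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        s = BeatSpectrum(0, np.zeros(10), np.zeros(10), 0.0)
        with pytest.raises(DegenerateSpectrumError):
            amplitude_proportion(s, mode="h1")
        with pytest.raises(DegenerateSpectrumError):
            amplitude_proportion(s, mode="sum")


def spectrum_with(a2=1.0, p3=0.0):
    amplitude = np.array([1.0, a2, 0.5] + [0.1] * 7)
    phase = np.zeros(10)
    phase[2] = p3
    return BeatSpectrum(0, amplitude, phase, 0.0)


class TestAggregate:
    def test_identical_spectra_have_zero_variability(self):
        spectra = [spectrum_with() for _ in range(5)]
        agg = aggregate_indices(spectra)
        assert np.allclose(agg.CV, 0.0)
        assert np.allclose(agg.P_SD, 0.0)
        assert agg.n_beats_used == 5

    def test_cv_of_alternating_proportions(self):
        # per-beat C2 = 90, 110, 90, 110 -> sample SD sqrt(400/3), mean 100
        spectra = [spectrum_with(a2=v) for v in (0.9, 1.1, 0.9, 1.1)]
        agg = aggregate_indices(spectra)
        assert agg.CV[1] == pytest.approx(100.0 * np.sqrt(400.0 / 3.0) / 100.0, rel=1e-9)
        assert agg.CV[1] == pytest.approx(11.547, abs=1e-3)

    def test_phase_wrap_handled_circularly(self):
        # phases straddling the +/-180 wrap: mean 180, mapped {179, 180, 181}
        spectra = [spectrum_with(p3=v) for v in (179.0, 180.0, -179.0)]
        agg = aggregate_indices(spectra)
        assert agg.P[2] == pytest.approx(180.0, abs=1e-9)
        assert agg.P_SD[2] == pytest.approx(1.0, abs=1e-9)

    def test_requires_three_beats(self):
        with pytest.raises(InsufficientBeatsError):
            aggregate_indices([spectrum_with(), spectrum_with()])

    def test_zero_mean_proportion_reported_missing(self):
        amplitude = np.array([1.0, 0.0] + [0.1] * 8)
        spectra = [BeatSpectrum(0, amplitude, np.zeros(10), 0.0) for _ in range(3)]
        with pytest.warns(UserWarning, match="C2"):
            agg = aggregate_indices(spectra)
        assert np.isnan(agg.CV[1])


class TestPipelineInvariances:
    def full_indices(self, record):
        beats, _ = extract_beats(record, detect_onsets(record))
        return aggregate_indices([beat_spectrum(b) for b in beats])

    def test_amplitude_scale_invariance(self, zero_jitter_record):
        record, _ = zero_jitter_record
        scaled = WaveformRecord(
            "scaled", 3.7 * record.samples, record.sampling_rate_hz, record.duration_s
        )
        base = self.full_indices(record)
        other = self.full_indices(scaled)
        assert np.allclose(base.C, other.C, atol=1e-9)
        assert np.allclose(base.CV, other.CV, atol=1e-9)
        assert np.allclose(base.P, other.P, atol=1e-6)
        assert np.allclose(base.P_SD, other.P_SD, atol=1e-6)

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(4)
        amplitudes = np.exp(-0.4 * np.arange(10))
        phases = rng.uniform(-179.0, 180.0, 10)
        beat = make_beat(amplitudes, phases, n_samples=500)
        shift = 40
        rolled = BeatSegment(
            "toy", 0, 0, beat.period_s, np.roll(beat.samples, -shift), beat.sampling_rate_hz
        )
        s0 = beat_spectrum(beat)
        s1 = beat_spectrum(rolled)
        assert np.allclose(s0.amplitude, s1.amplitude, rtol=1e-6)
        n = np.arange(1, 11)
        expected = wrap_phase_deg(s0.phase_deg + 360.0 * n * shift / 500.0)
        assert np.allclose(wrap_phase_deg(s1.phase_deg - expected), 0.0, atol=1e-3)

    def test_zero_jitter_record_has_zero_variability_indices(self, zero_jitter_record):
        record, _ = zero_jitter_record
        agg = self.full_indices(record)
        assert np.all(agg.CV < 1e-6)
        assert np.all(agg.P_SD < 1e-6)
        assert agg.C[0] == pytest.approx(100.0)


class TestExtractFeatures:
    def test_forty_named_columns_per_subject(self, small_features):
        feature_columns = [c for c in small_features.columns if c in FEATURE_NAMES]
        assert feature_columns == FEATURE_NAMES
        assert len(feature_columns) == 40
        assert small_features[feature_columns].notna().all().all()
        assert (small_features["n_beats_used"] >= 3).all()

    def test_cv1_degenerate_under_h1_normalization(self, small_features):
        assert np.allclose(small_features["CV1"], 0.0)
        assert np.allclose(small_features["C1"], 100.0)

    def test_ad_group_has_larger_variability_indices(self, small_features):
        means = small_features.groupby("group")[[f"CV{n}" for n in range(2, 11)]].mean()
        assert (means.loc["AD"] > means.loc["Control"]).all()

    def test_failures_reported_not_dropped(self, zero_jitter_record):
        record, _ = zero_jitter_record
        flat = WaveformRecord("flat", np.ones(10000), 500.0, 20.0)
        features, failures = extract_features([record, flat])
        assert list(features.index) == ["zero"]
        assert len(failures) == 1
        assert failures[0][0] == "flat"
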