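"""Peak picking, end-to-end tracking, and config validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from f0track import (
    AudioSignal,
    ConfigurationError,
    ConsistencyError,
    F0Track,
    SpectrogramGrid,
    Threshold,
    TrackerConfig,
    TrackerWarning,
    make_syllable_train,
    make_tone,
    peak_frequency_per_bin,
    track_f0,
    validate_config,
    SyllableSpec,
)


def _grid(power, freq_step=100.0, sample_rate=8000.0):
    power = np.asarray(power, dtype=float)
    n_freqs, n_times = power.shape
    window = int(round(sample_rate / freq_step))
    return SpectrogramGrid(
        times=(np.arange(n_times) * window / 2 + window / 2) / sample_rate,
        freqs=np.arange(n_freqs) * freq_step,
        power=power,
        window=window,
        hop=window // 2,
        window_function="hann",
        sample_rate=sample_rate,
    )


class TestPeakFrequencyPerBin:
    def test_single_peak_column(self):
        grid = _grid(np.array([[0.0], [0.0], [7.0], [0.0]]))
        freq, power = peak_frequency_per_bin(grid)
        assert freq[0] == 200.0 and power[0] == 7.0

    def test_all_zero_column_ties_to_lowest_frequency(self):
        grid = _grid(np.zeros((4, 3)))
        freq, power = peak_frequency_per_bin(grid)
        np.testing.assert_array_equal(freq, 0.0)
        np.testing.assert_array_equal(power, 0.0)

    def test_engineered_tie_resolves_to_lowest(self):
        col = np.array([0.0, 5.0, 1.0, 5.0, 0.0])
        grid = _grid(col[:, None])
        freq, _ = peak_frequency_per_bin(grid)
        assert freq[0] == 100.0

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_double_loop_scan(self, seed):
        rng = np.random.default_rng(seed)
        power = rng.uniform(size=(64, 40))
        grid = _grid(power)
        freq, peak = peak_frequency_per_bin(grid)
        for k in range(40):
            best_i, best_p = 0, power[0, k]
            for i in range(64):
                if power[i, k] > best_p:
                    best_i, best_p = i, power[i, k]
            assert freq[k] == grid.freqs[best_i]
            assert peak[k] == best_p


class TestTrackF0:
    def test_pure_tone_recovered_within_half_bin(self):
        sig = make_tone(2000, 2.0, 44100)
        track = track_f0(sig, TrackerConfig())
        assert track.voiced.all()
        bin_width = 44100 / 1024
        assert np.abs(track.f0_hz - 2000.0).max() <= bin_width / 2.0 + 1e-9

    def test_digital_silence_all_gated(self):
        sig = AudioSignal(samples=np.zeros(2 * 44100), sample_rate=44100.0)
        track = track_f0(sig, TrackerConfig())
        assert track.voiced_count == 0
        assert np.isnan(track.f0_hz).all()

    def test_syllable_train_per_burst_median_and_gap_silence(self):
        freqs = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
        specs = [SyllableSpec(f0=f, duration=0.1) for f in freqs]
        signal, truths = make_syllable_train(specs, gap=0.15, sample_rate=44100.0)
        config = TrackerConfig()
        track = track_f0(signal, config)
        bin_width = 44100.0 / config.window
        starts = track.times - config.window / 2.0 / 44100.0
        ends = starts + config.window / 44100.0
        for truth, f_true in zip(truths, freqs):
            inside = (starts >= truth.onset) & (ends <= truth.offset)
            assert inside.any()
            assert track.voiced[inside].all()
            assert abs(np.median(track.f0_hz[inside]) - f_true) <= bin_width
        gap_edges = [(0.0, truths[0].onset)] + [
            (truths[i].offset, truths[i + 1].onset) for i in range(len(truths) - 1)
        ]
        for lo, hi in gap_edges:
            in_gap = (starts >= lo) & (ends <= hi)
            assert in_gap.any()
            assert not track.voiced[in_gap].any()

    def test_amplitude_scaling_invariance(self):
        specs = [SyllableSpec(f0=f, duration=0.08) for f in (1500.0, 3500.0)]
        signal, _ = make_syllable_train(specs, gap=0.1, sample_rate=22050.0)
        config = TrackerConfig(window=512, overlap=256)
        base = track_f0(signal, config)
        for c in (0.25, 3.7):
            scaled = AudioSignal(samples=c * signal.samples, sample_rate=22050.0)
            other = track_f0(scaled, config)
            np.testing.assert_array_equal(other.voiced, base.voiced)
            np.testing.assert_array_equal(
                other.f0_hz[other.voiced], base.f0_hz[base.voiced]
            )

    @given(
        f_tone=st.floats(min_value=900.0, max_value=7000.0),
        band=st.tuples(
            st.floats(min_value=500.0, max_value=2000.0),
            st.floats(min_value=2500.0, max_value=9000.0),
        ),
    )
    def test_band_closure(self, f_tone, band):
        f_min, f_max = band
        sig = make_tone(f_tone, 0.25, 22050)
        config = TrackerConfig(window=512, overlap=256, f_min=f_min, f_max=f_max)
        track = track_f0(sig, config)
        voiced_f0 = track.f0_hz[track.voiced]
        assert (voiced_f0 >= f_min).all()
        assert (voiced_f0 <= min(f_max, 22050 / 2)).all()

    def test_tone_recovery_one_bin_bound_across_windows(self, rng):
        for window in (256, 512, 1024):
            config = TrackerConfig(window=window, overlap=window // 2)
            for f_true in rng.uniform(800.0, 8000.0, size=4):
                track = track_f0(make_tone(f_true, 0.5, 44100), config)
                assert track.voiced.any()
                err = np.abs(track.f0_hz[track.voiced] - f_true).max()
                assert err <= 44100.0 / window

    def test_warning_emitted_for_long_window(self):
        sig = make_tone(2000, 0.3, 44100)
        with pytest.warns(TrackerWarning, match="window duration"):
            track_f0(sig, TrackerConfig(window=2048, overlap=1024))


class TestF0TrackInvariants:
    def test_nan_voiced_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            F0Track(
                times=np.array([0.1, 0.2]),
                f0_hz=np.array([1000.0, 2000.0]),
                voiced=np.array([True, False]),
                peak_power=np.ones(2),
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            F0Track(
                times=np.array([0.1, 0.2]),
                f0_hz=np.array([1000.0]),
                voiced=np.array([True]),
                peak_power=np.ones(1),
            )


class TestValidateConfig:
    def test_defaults_clean_at_44100(self):
        assert validate_config(TrackerConfig(), 44100.0) == []

    def test_long_window_warns(self):
        msgs = validate_config(TrackerConfig(window=2048, overlap=1024), 44100.0)
        assert any("window duration" in m for m in msgs)

    def test_fmax_above_nyquist_warns(self):
        msgs = validate_config(TrackerConfig(f_max=30000.0), 44100.0)
        assert any("Nyquist" in m for m in msgs)

    def test_coarse_bins_warn(self):
        msgs = validate_config(
            TrackerConfig(window=16, overlap=8, f_min=800.0, f_max=8000.0), 44100.0
        )
        assert any("coarse" in m for m in msgs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"overlap": 1024},
            {"overlap": 2048},
            {"f_min": 5000.0, "f_max": 1000.0},
            {"f_min": -10.0},
            {"smooth_ms": -1.0},
            {"max_syllabic_rate": 0.0},
            {"window": 0},
        ],
    )
    def test_hard_invariants_raise(self, kwargs):
        with pytest.raises(ConfigurationError):
            TrackerConfig(**kwargs)

    def test_relative_threshold_out_of_range(self):
        with pytest.raises(ConfigurationError):
            TrackerConfig(threshold=Threshold.relative(1.2))
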