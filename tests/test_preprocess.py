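"""Filters, referencing, Laplacian, gaze smoothing and modality alignment."""

import numpy as np
import pytest

from neuroskill.montage import channel_names, default_montage
from neuroskill.preprocess import (align_modalities, bandpass_filter,
                                   clean_artifacts, common_average_reference,
                                   exclude_channels, moving_average_3,
                                   notch_filter, preprocess_recording,
                                   smooth_and_impute_gaze, spatial_laplacian)
from neuroskill.types import EYE_MOVEMENT_TYPE_IDX, GAZE_SIGNALS, Recording

RATE = 512.0


def tone(freq, dur=4.0, rate=RATE, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def fft_amplitude(x, freq, rate=RATE):
    spec = np.abs(np.fft.rfft(x)) * 2 / len(x)
    f = np.fft.rfftfreq(len(x), 1 / rate)
    return spec[np.argmin(np.abs(f - freq))]


def make_recording(eeg=None, gaze=None, n_eeg_s=None, n_gaze_s=None,
                   events=None):
    channels = channel_names()
    if eeg is None:
        rng = np.random.default_rng(0)
        n_eeg_s = n_eeg_s or int(10 * RATE)
        eeg = rng.standard_normal((len(channels), n_eeg_s))
    if gaze is None:
        rng = np.random.default_rng(1)
        n_gaze_s = n_gaze_s or int(10 * 50)
        gaze = rng.standard_normal((20, n_gaze_s))
        gaze[EYE_MOVEMENT_TYPE_IDX] = 1
    if events is None:
        events = [("subtask1_start", 1000.0), ("subtask1_end", 5000.0),
                  ("subtask2_start", 6000.0), ("subtask2_end", 9000.0)]
    return Recording(
        participant_id="P1", trial_id="P1_t1", eeg=eeg,
        eeg_channels=channels,
        eeg_times=np.arange(eeg.shape[1]) / RATE * 1000.0,
        gaze=gaze, gaze_signals=list(GAZE_SIGNALS),
        gaze_times=np.arange(gaze.shape[1]) / 50.0 * 1000.0,
        events=events)


class TestExcludeChannels:
    def test_default_list_leaves_116(self):
        rec = make_recording()
        assert rec.eeg.shape[0] == 124
        out = exclude_channels(rec)
        assert out.eeg.shape[0] == 116
        assert len(out.eeg_channels) == 116

    def test_empty_list_is_identity(self):
        rec = make_recording()
        out = exclude_channels(rec, [])
        assert out.eeg.shape == rec.eeg.shape

    def test_duplicate_name_single_removal_with_warning(self):
        rec = make_recording()
        with pytest.warns(UserWarning, match="duplicate"):
            out = exclude_channels(rec, ["M1", "M1"])
        assert out.eeg.shape[0] == 123

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            exclude_channels(make_recording(), ["XX9"])


class TestNotchFilter:
    def test_60hz_tone_suppressed(self):
        x = tone(60.0)
        y = notch_filter(x, RATE)
        assert np.sqrt(np.mean(y**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_dc_unchanged(self):
        x = np.full(2048, 3.0)
        y = notch_filter(x, RATE)
        assert np.abs(y - x).max() < 1e-6

    def test_10hz_tone_preserved(self):
        x = tone(10.0)
        y = notch_filter(x, RATE)
        assert fft_amplitude(y, 10.0) == pytest.approx(1.0, rel=0.01)

    def test_passband_attenuation_below_1db(self):
        for f in (55.0, 65.0):
            y = notch_filter(tone(f, dur=8.0), RATE)
            atten_db = -20 * np.log10(fft_amplitude(y, f))
            assert atten_db < 1.0

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch_filter(tone(10.0), rate=100.0, f0=60.0)


class TestBandpassFilter:
    def test_dc_offset_removed(self):
        x = np.full(int(8 * RATE), 5.0)
        y = bandpass_filter(x, RATE)
        assert abs(y.mean()) < 1e-3

    def test_50hz_preserved_within_2pct(self):
        y = bandpass_filter(tone(50.0, dur=8.0), RATE)
        assert fft_amplitude(y, 50.0) == pytest.approx(1.0, rel=0.02)

    def test_slow_drift_attenuated(self):
        y = bandpass_filter(tone(0.01, dur=200.0), RATE)
        assert fft_amplitude(y, 0.01, RATE) < 0.1

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(tone(10.0), RATE, low=250.0, high=0.2)
        with pytest.raises(ValueError):
            bandpass_filter(tone(10.0), RATE, low=0.2, high=300.0)


class TestReferencing:
    def test_car_zeroes_column_means(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 1000))
        y = common_average_reference(x)
        assert np.abs(y.mean(axis=0)).max() < 1e-10

    def test_car_preserves_channel_differences(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 500))
        y = common_average_reference(x)
        np.testing.assert_allclose(y[0] - y[1], x[0] - x[1], atol=1e-12)

    def test_car_identical_channels_zeroed(self):
        x = np.tile(np.sin(np.arange(100.0)), (4, 1))
        assert np.abs(common_average_reference(x)).max() < 1e-12


class TestLaplacian:
    def test_uniform_field_maps_to_zero(self):
        names = channel_names(include_excluded=False)
        x = np.ones((len(names), 50))
        y = spatial_laplacian(x, names)
        assert np.abs(y).max() < 1e-12

    def test_star_graph_hand_computation(self):
        # 5 channels; center C has neighbors N1..N4, each Ni has neighbor C
        names = ["C", "N1", "N2", "N3", "N4"]
        nm = {"C": ["N1", "N2", "N3", "N4"],
              "N1": ["C"], "N2": ["C"], "N3": ["C"], "N4": ["C"]}
        x = np.zeros((5, 1))
        x[0, 0] = 4.0     # only the center is active
        y = spatial_laplacian(x, names, nm)
        assert y[0, 0] == pytest.approx(4.0)      # 4 - mean(0,0,0,0)
        for i in range(1, 5):
            assert y[i, 0] == pytest.approx(-4.0)  # 0 - mean(4)

    def test_not_idempotent(self):
        rng = np.random.default_rng(4)
        names = channel_names(include_excluded=False)
        x = rng.standard_normal((len(names), 20))
        once = spatial_laplacian(x, names)
        twice = spatial_laplacian(once, names)
        assert not np.allclose(once, twice)

    def test_missing_channel_in_map_raises(self):
        with pytest.raises(KeyError):
            spatial_laplacian(np.zeros((2, 5)), ["A", "B"], {"A": ["B"]})


class TestArtifactRemoval:
    def test_noop_mode_identity(self):
        rng = np.random.default_rng(5)
        names = channel_names(include_excluded=False)
        x = rng.standard_normal((len(names), 256))
        np.testing.assert_array_equal(
            clean_artifacts(x, names, mode="none"), x)

    def test_blink_template_power_reduced(self):
        rng = np.random.default_rng(6)
        names = channel_names(include_excluded=False)
        mont = default_montage().set_index("name")
        y_coord = mont.loc[names, "y"].to_numpy()
        n = int(4 * RATE)
        x = rng.standard_normal((len(names), n))
        blink = np.zeros(n)
        width = int(0.3 * RATE)
        for start in (200, 900, 1500):
            blink[start:start + width] += np.hanning(width)
        pattern = np.clip(y_coord, 0, None) ** 2 * 60.0
        contaminated = x + pattern[:, None] * blink[None, :]
        cleaned = clean_artifacts(contaminated, names,
                                  variance_fraction=0.5, template_corr=0.8)
        frontal = pattern > 0.5 * pattern.max()
        before = np.mean(contaminated[frontal] ** 2)
        after = np.mean(cleaned[frontal] ** 2)
        assert after < 0.8 * before

    def test_rank_reduced_by_removed_components(self):
        rng = np.random.default_rng(7)
        names = channel_names(include_excluded=False)[:10]
        x = rng.standard_normal((10, 400))
        cleaned = clean_artifacts(x, names, variance_fraction=0.0,
                                  template_corr=2.0)  # drop every component
        centered = cleaned - cleaned.mean(axis=1, keepdims=True)
        assert np.linalg.matrix_rank(centered, tol=1e-8) == 0


class TestGazeSmoothing:
    def test_three_point_ma_hand_example(self):
        np.testing.assert_allclose(moving_average_3(np.array([1., 2., 3., 4.])),
                                   [1.5, 2.0, 3.0, 3.5])

    def test_constant_signal_with_gaps_stays_constant(self):
        g = np.full((20, 50), 2.0)
        g[EYE_MOVEMENT_TYPE_IDX] = 1
        g[3, 10:15] = np.nan
        out = smooth_and_impute_gaze(g)
        np.testing.assert_allclose(out[3], 2.0)

    def test_type_index_stays_categorical(self):
        rng = np.random.default_rng(8)
        g = rng.standard_normal((20, 100))
        g[EYE_MOVEMENT_TYPE_IDX] = rng.integers(1, 3, size=100)
        g[EYE_MOVEMENT_TYPE_IDX, 5] = np.nan
        out = smooth_and_impute_gaze(g)
        assert set(np.unique(out[EYE_MOVEMENT_TYPE_IDX])) <= {1.0, 2.0, 3.0}

    def test_entirely_missing_signal_raises(self):
        g = np.random.default_rng(9).standard_normal((20, 30))
        g[EYE_MOVEMENT_TYPE_IDX] = 1
        g[4] = np.nan
        with pytest.raises(ValueError, match="index 4"):
            smooth_and_impute_gaze(g)


class TestAlignment:
    def test_constant_gaze_stays_constant(self):
        gaze = np.full((20, 500), 7.0)
        gaze[EYE_MOVEMENT_TYPE_IDX] = 1
        rec = make_recording(gaze=gaze)
        seg = align_modalities(rec, 1)
        gaze_rows = seg.data[-20:]
        np.testing.assert_allclose(gaze_rows[:-1], 7.0, atol=1e-9)

    def test_linear_ramp_resampled_exactly(self):
        gaze = np.zeros((20, 500))
        gaze[0] = np.linspace(0, 10, 500)          # linear in time
        gaze[EYE_MOVEMENT_TYPE_IDX] = 1
        rec = make_recording(gaze=gaze)
        seg = align_modalities(rec, 1)
        t0, t1 = rec.segment_bounds(1)
        emask = (rec.eeg_times >= t0) & (rec.eeg_times < t1)
        expected = np.interp(rec.eeg_times[emask], rec.gaze_times, gaze[0])
        np.testing.assert_allclose(seg.data[124], expected, atol=1e-6)

    def test_fused_row_count_is_136(self):
        rec = exclude_channels(make_recording())
        seg = align_modalities(rec, 1)
        assert seg.data.shape[0] == 116 + 20 == 136

    def test_categorical_channel_held_not_interpolated(self):
        gaze = np.zeros((20, 500))
        gaze[EYE_MOVEMENT_TYPE_IDX] = np.where(
            np.arange(500) % 2 == 0, 1, 2)
        rec = make_recording(gaze=gaze)
        seg = align_modalities(rec, 1)
        assert set(np.unique(seg.data[-1])) <= {1.0, 2.0}

    def test_segment_outside_coverage_rejected(self):
        rec = make_recording(events=[("subtask1_start", 0.0),
                                     ("subtask1_end", 99000.0),
                                     ("subtask2_start", 0.0),
                                     ("subtask2_end", 1.0)])
        with pytest.raises(ValueError, match="coverage"):
            align_modalities(rec, 1)


class TestChainProperties:
    def test_linearity_of_filter_chain(self):
        rng = np.random.default_rng(10)
        names = channel_names(include_excluded=False)
        x = rng.standard_normal((len(names), 2048))
        y = rng.standard_normal((len(names), 2048))
        a, b = 1.7, -0.6

        def chain(z):
            z = notch_filter(z, RATE)
            z = bandpass_filter(z, RATE)
            z = common_average_reference(z)
            return spatial_laplacian(z, names)

        lhs = chain(a * x + b * y)
        rhs = a * chain(x) + b * chain(y)
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_full_preprocess_produces_two_labeled_shapes(self, small_cohort):
        segs = preprocess_recording(small_cohort.trials[0],
                                    artifact_mode="none")
        assert [s.subtask for s in segs] == [1, 2]
        assert all(s.data.shape[0] == 136 for s in segs)
        assert all(not np.isnan(s.data).any() for s in segs)

    def test_eeg_subset_restricts_rows(self, small_cohort):
        from neuroskill.montage import EEG32_CHANNELS

        segs = preprocess_recording(small_cohort.trials[0],
                                    artifact_mode="none",
                                    eeg_subset=EEG32_CHANNELS)
        assert segs[0].data.shape[0] == 32 + 20
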