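"""Filter contracts (FFT-measured), epoch arithmetic, channel selection and
sliding-window segmentation."""

import numpy as np
import pytest

from dcafusion.preprocess import (PreprocessError, bandpass, epoch_trial,
                                  notch_50hz, preprocess_recording,
                                  sample_index, segment_windows,
                                  select_unilateral_channels)
from dcafusion.paradigm import make_paradigm_timeline
from dcafusion.simulate import ContinuousTrialRecording, simulate_trial
from dcafusion.montage import EEG_CHANNELS, EMG_CHANNELS, EEG_LEFT, EMG_LEFT


def tone(freq, fs, seconds=4.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(x ** 2))


def tone_db(filtered, raw, freq, fs):
    """Attenuation of one frequency, measured on the FFT bin amplitudes."""
    spec_f = np.abs(np.fft.rfft(filtered))
    spec_r = np.abs(np.fft.rfft(raw))
    k = int(round(freq * len(raw) / fs))
    return 20 * np.log10(spec_f[k] / spec_r[k])


class TestNotch:
    def test_50hz_tone_removed(self):
        x = tone(50, 1500)
        y = notch_50hz(x, 1500)
        assert rms(y) <= 0.1 * rms(x)
        assert tone_db(y, x, 50, 1500) <= -20

    @pytest.mark.parametrize("freq", [30.0, 80.0])
    def test_passband_preserved(self, freq):
        x = tone(freq, 1500)
        y = notch_50hz(x, 1500)
        assert rms(y) >= 0.89 * rms(x)
        assert tone_db(y, x, freq, 1500) > -1

    def test_zero_in_zero_out(self):
        assert np.allclose(notch_50hz(np.zeros(1000), 1500), 0)

    def test_low_rate_rejected(self):
        with pytest.raises(PreprocessError):
            notch_50hz(np.zeros(500), 99.0)

    def test_shape_preserved_multichannel(self, rng):
        x = rng.normal(size=(4, 2048))
        assert notch_50hz(x, 1000).shape == x.shape


class TestBandpass:
    @pytest.mark.parametrize("freq,fs,band,passes", [
        (5.0, 1500, (10, 450), False),    # below low edge
        (80.0, 1500, (10, 450), True),    # mid-band
        (15.0, 1000, (0.3, 30), True),    # mid-band EEG
        (60.0, 1000, (0.3, 30), False),   # above high edge
        (0.15, 1000, (0.3, 30), False),   # below low edge
    ])
    def test_stop_and_pass_contracts(self, freq, fs, band, passes):
        x = tone(freq, fs, seconds=20.0)
        y = bandpass(x, fs, *band)
        # ignore filtfilt edge transients
        n = len(x) // 10
        db = tone_db(y[n:-n], x[n:-n], freq, fs)
        if passes:
            assert db > -1.0
        else:
            assert db <= -20.0

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(1000), 1000, 0.3, 30), 0)

    @pytest.mark.parametrize("low,high", [(30, 0.3), (0, 30), (10, 600)])
    def test_invalid_band_rejected(self, low, high):
        with pytest.raises(PreprocessError):
            bandpass(np.zeros(100), 1000, low, high)

    def test_filter_preserves_shape_and_finiteness(self, rng):
        x = rng.normal(size=(3, 4096))
        y = bandpass(x, 1000, 0.3, 30)
        assert y.shape == x.shape and np.isfinite(y).all()

    def test_double_filtering_stays_well_behaved(self, rng):
        """Applying a filter twice only sharpens the magnitude response:
        shapes unchanged, everything finite, passband barely touched."""
        x = tone(15.0, 1000, seconds=20.0)
        once = bandpass(x, 1000, 0.3, 30)
        twice = bandpass(once, 1000, 0.3, 30)
        assert twice.shape == x.shape and np.isfinite(twice).all()
        n = len(x) // 10
        assert tone_db(twice[n:-n], x[n:-n], 15.0, 1000) > -2.0
        y = rng.normal(size=(2, 3000))
        assert np.isfinite(notch_50hz(notch_50hz(y, 1500), 1500)).all()


def zeros_recording(fs_eeg=1000.0, fs_emg=1500.0, seconds=15.0):
    return ContinuousTrialRecording(
        eeg=np.zeros((32, int(seconds * fs_eeg))),
        emg=np.zeros((10, int(seconds * fs_emg))),
        events=[], label="standing", subject_id=1,
        fs_eeg=fs_eeg, fs_emg=fs_emg)


class TestEpoching:
    def test_default_epoch_lengths(self):
        """Full-rate paradigm: MI EEG 2000 samples, sync EEG 1000, sync
        sEMG 1500 — the canonical (T1, T2) sizes."""
        spec = make_paradigm_timeline()
        trial = epoch_trial(zeros_recording(), spec)
        assert trial.x_eeg1.shape == (32, 2000)
        assert trial.x_eeg2.shape == (32, 1000)
        assert trial.x_semg.shape == (10, 1500)

    def test_too_short_recording_names_window(self):
        spec = make_paradigm_timeline()
        with pytest.raises(PreprocessError, match="sync"):
            epoch_trial(zeros_recording(fs_emg=1500.0, seconds=8.0), spec)

    def test_boundaries_land_on_event_samples(self, profile, spec_mid):
        """Epoch cut indices equal the rounded event-time sample indices on
        a simulated trial carrying the paradigm's markers."""
        rec = simulate_trial(profile, spec_mid, "walking", seed=0)
        trial = epoch_trial(rec, spec_mid)
        fs = spec_mid.fs_eeg
        i0, i1 = sample_index(5.5, fs), sample_index(7.5, fs)
        assert np.array_equal(trial.x_eeg1, rec.eeg[:, i0:i1])
        i0, i1 = sample_index(7.5, fs), sample_index(8.5, fs)
        assert np.array_equal(trial.x_eeg2, rec.eeg[:, i0:i1])
        fse = spec_mid.fs_emg
        i0, i1 = sample_index(7.5, fse), sample_index(8.5, fse)
        assert np.array_equal(trial.x_semg, rec.emg[:, i0:i1])


class TestChannelSelection:
    def test_unilateral_counts_and_order(self):
        spec = make_paradigm_timeline()
        trial = epoch_trial(zeros_recording(), spec)
        sel = select_unilateral_channels(trial, "left")
        assert sel.x_eeg1.shape[0] == 16
        assert sel.x_semg.shape[0] == 5
        assert sel.emg_channels == EMG_LEFT
        assert sel.eeg_channels == EEG_LEFT

    def test_left_muscles_are_the_five_named(self):
        assert EMG_LEFT == ["L_RF", "L_VL", "L_TA", "L_BF", "L_LG"]

    def test_idempotent(self):
        spec = make_paradigm_timeline()
        trial = select_unilateral_channels(epoch_trial(zeros_recording(), spec),
                                           "left")
        again = select_unilateral_channels(trial, "left")
        assert again.eeg_channels == trial.eeg_channels
        assert np.array_equal(again.x_eeg1, trial.x_eeg1)

    def test_unknown_side_rejected(self):
        spec = make_paradigm_timeline()
        trial = epoch_trial(zeros_recording(), spec)
        with pytest.raises(PreprocessError, match="unknown side"):
            select_unilateral_channels(trial, "up")

    def test_values_follow_channels(self, profile, spec_mid):
        rec = simulate_trial(profile, spec_mid, "sitting", seed=1)
        trial = select_unilateral_channels(epoch_trial(rec, spec_mid), "right")
        src = [EEG_CHANNELS.index(c) for c in trial.eeg_channels]
        assert np.array_equal(trial.x_eeg1,
                              rec.eeg[src, round(5.5 * spec_mid.fs_eeg):
                                      round(7.5 * spec_mid.fs_eeg)])


class TestWindows:
    def test_window_count_1500(self):
        ws = segment_windows(np.zeros((5, 1500)), 300, 100)
        assert len(ws) == 13

    def test_single_full_window(self, rng):
        x = rng.normal(size=(2, 300))
        ws = segment_windows(x, 300, 100)
        assert len(ws) == 1
        assert np.array_equal(ws.windows[0], x)

    def test_last_window_covers_tail(self, rng):
        x = rng.normal(size=1500)
        ws = segment_windows(x, 300, 100)
        assert np.array_equal(ws.windows[-1], x[1200:1500])

    @pytest.mark.parametrize("length,wl,step", [(1000, 300, 100), (301, 300, 100),
                                                (999, 128, 64)])
    def test_count_formula_and_tiling(self, rng, length, wl, step):
        x = rng.normal(size=length)
        ws = segment_windows(x, wl, step)
        assert len(ws) == (length - wl) // step + 1
        for i, w in enumerate(ws.windows):
            assert np.array_equal(w, x[i * step:i * step + wl])
        assert (len(ws) - 1) * step + wl <= length

    def test_short_signal_rejected(self):
        with pytest.raises(PreprocessError):
            segment_windows(np.zeros(100), 300, 100)


def test_full_pipeline_shapes(small_dataset, spec_mid):
    trial = preprocess_recording(small_dataset[0], spec_mid, side="left")
    fs_e, fs_m = spec_mid.fs_eeg, spec_mid.fs_emg
    assert trial.x_eeg1.shape == (16, int(2 * fs_e))
    assert trial.x_eeg2.shape == (16, int(fs_e))
    assert trial.x_semg.shape == (5, int(fs_m))
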