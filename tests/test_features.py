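"""Handcrafted-feature oracles: exact scalar-loop agreement for MAV/WL/ZC,
statistical consistency for AR and PSD, CSP algebra, and feature-vector
layout."""

import numpy as np
import pytest

from dcafusion.csp import CSP, csp_filters
from dcafusion.features import (FeatureVector, ar_coefficients, avg_psd,
                                extract_feature_vector, mav,
                                waveform_length, zero_crossings)


# scalar-loop oracles ------------------------------------------------------

def loop_mav(w):
    s = 0.0
    for v in w:
        s += abs(v)
    return s / len(w)


def loop_wl(w):
    s = 0.0
    for i in range(len(w) - 1):
        s += abs(w[i + 1] - w[i])
    return s


def loop_zc(w, dead):
    n = 0
    for i in range(len(w) - 1):
        if w[i] * w[i + 1] < 0 and abs(w[i + 1] - w[i]) > dead:
            n += 1
    return n


class TestScalarFeatures:
    def test_mav_hand_examples(self):
        assert mav([1, -1, 1, -1]) == 1.0
        assert mav(np.zeros(10)) == 0.0

    def test_wl_hand_example(self):
        assert waveform_length([1, -1, 1, -1]) == 6.0
        assert waveform_length(np.full(50, 3.3)) == 0.0

    def test_zc_hand_examples(self):
        assert zero_crossings([1, -1, 1, -1]) == 3
        assert zero_crossings(np.abs(np.random.default_rng(0).normal(size=50))
                              + 0.1) == 0
        assert zero_crossings([1, -1, 1, -1], deadband=5.0) == 0

    def test_loop_oracle_agreement_on_random_windows(self, rng):
        for _ in range(100):
            w = rng.normal(size=int(rng.integers(2, 301)))
            # agreement to float round-off (summation order differs)
            assert mav(w) == pytest.approx(loop_mav(w), rel=1e-12)
            assert waveform_length(w) == pytest.approx(loop_wl(w), rel=1e-12)
            assert zero_crossings(w, 0.5) == loop_zc(w, 0.5)

    def test_empty_and_short_windows_rejected(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            waveform_length([1.0])


class TestAR:
    def test_ar1_coefficient_recovery(self, rng):
        """Yule-Walker consistency: an AR(1) process with phi=0.8 yields a
        first coefficient near 0.8 and near-zero higher orders."""
        n = 5000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = 0.8 * x[t - 1] + eps[t]
        phi = ar_coefficients(x, order=6)
        assert abs(phi[0] - 0.8) < 0.05
        assert np.all(np.abs(phi[1:]) < 0.1)

    def test_white_noise_near_zero_coefficients(self, rng):
        phi = ar_coefficients(rng.normal(size=5000), order=6)
        assert np.all(np.abs(phi) < 0.1)

    def test_exactly_six_values(self, rng):
        assert ar_coefficients(rng.normal(size=100)).shape == (6,)

    def test_constant_window_returns_zeros(self):
        assert np.array_equal(ar_coefficients(np.full(100, 2.0)), np.zeros(6))

    def test_matches_statsmodels_yule_walker(self, rng):
        from statsmodels.regression.linear_model import yule_walker
        x = rng.normal(size=2000)
        ours = ar_coefficients(x, order=6)
        theirs, _ = yule_walker(x - x.mean(), order=6, method="mle")
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.zeros(5), order=6)


class TestPSD:
    def test_zero_signal(self):
        assert avg_psd(np.zeros(300), 1000.0) == 0.0

    def test_amplitude_power_scaling(self):
        t = np.arange(1500) / 1500.0
        one = np.sin(2 * np.pi * 50 * t)
        two = 2.0 * one
        ratio = avg_psd(two, 1500.0) / avg_psd(one, 1500.0)
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_parseval_total_power_matches_variance(self, rng):
        from scipy.signal import welch
        x = rng.normal(size=4096)
        f, pxx = welch(x, fs=1000.0, nperseg=256)
        total = np.trapezoid(pxx, f)
        assert total == pytest.approx(x.var(), rel=0.05)


class TestCSP:
    @staticmethod
    def make_epochs(rng, scales_a, scales_b, n=30, t=400):
        xa = [rng.normal(size=(len(scales_a), t)) * np.asarray(scales_a)[:, None]
              for _ in range(n)]
        xb = [rng.normal(size=(len(scales_b), t)) * np.asarray(scales_b)[:, None]
              for _ in range(n)]
        return xa + xb, np.array([0] * n + [1] * n)

    def test_variance_contrast_concentrates_top_filter(self, rng):
        """Classes differing only in channel 2's variance: the leading
        filter puts >= 90% of its l2 weight on that channel."""
        X, y = self.make_epochs(rng, [1, 1, 3, 1], [1, 1, 1, 1])
        model = CSP(n_components=2).fit(X, y)
        w = model.filters_[0][0]
        assert w[2] ** 2 / (w @ w) >= 0.9

    def test_whitening_property(self, rng):
        X, y = self.make_epochs(rng, [1, 2, 1], [2, 1, 1])
        from dcafusion.csp import _class_cov
        cov_a = _class_cov([x for x, lab in zip(X, y) if lab == 0])
        cov_b = _class_cov([x for x, lab in zip(X, y) if lab == 1])
        w, _ = csp_filters(cov_a, cov_b, 2)
        prod = w @ (cov_a + cov_b) @ w.T
        assert np.allclose(prod, np.eye(2), atol=1e-6)

    def test_identical_covariances_give_half_eigenvalues(self, rng):
        x = [rng.normal(size=(3, 500)) for _ in range(40)]
        y = np.array([0, 1] * 20)
        model = CSP(n_components=2).fit(x, y)
        assert np.allclose(model.eigvals_, 0.5, atol=0.05)

    def test_multiclass_one_vs_rest_feature_count(self, rng):
        X, y = self.make_epochs(rng, [3, 1, 1], [1, 3, 1])
        X += [rng.normal(size=(3, 400)) * np.array([1, 1, 3])[:, None]
              for _ in range(30)]
        y = np.concatenate([y, np.full(30, 2)])
        model = CSP(n_components=2).fit(X, y)
        assert model.filters_.shape == (3, 2, 3)
        assert model.transform(X[:5]).shape == (5, 6)

    def test_matches_mne_csp_eigenvalue_structure(self, rng):
        """Cross-check against mne's CSP on a two-class problem: both find
        filters whose class-variance ratios agree (filters themselves are
        sign/scale ambiguous)."""
        mne = pytest.importorskip("mne")
        X, y = self.make_epochs(rng, [1, 1, 2.5], [1.5, 1, 1], n=40)
        ours = CSP(n_components=2).fit(X, y)
        theirs = mne.decoding.CSP(n_components=2, norm_trace=True,
                                  transform_into="csp_space")
        theirs.fit(np.asarray(X), y)

        def var_ratio(w):
            va = np.mean([np.var(w @ x) for x, lab in zip(X, y) if lab == 0])
            vb = np.mean([np.var(w @ x) for x, lab in zip(X, y) if lab == 1])
            return max(va, vb) / min(va, vb)

        ours_best = max(var_ratio(w) for w in ours.filters_[0])
        theirs_best = max(var_ratio(w) for w in theirs.filters_[:2])
        assert ours_best == pytest.approx(theirs_best, rel=0.05)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            CSP(2).fit([rng.normal(size=(3, 50))], [0])


class TestFeatureVector:
    def test_semg_block_length(self, small_trials):
        """5 channels x 13 windows x 10 features = 650 (with windows scaled
        to the fixture's sampling rate)."""
        trial = small_trials[0]
        t2 = trial.x_semg.shape[1]
        wl, step = 75, 25  # 13 windows of 375 samples at the fixture rate
        assert (t2 - wl) // step + 1 == 13
        fv = extract_feature_vector(trial, window_len=wl, step=step)
        assert fv.values.size == 5 * 13 * 10
        assert len(fv.layout) == fv.values.size

    def test_layout_names_every_entry(self, small_trials):
        fv = extract_feature_vector(small_trials[0], window_len=75, step=25)
        assert fv.layout[0] == "semg/L_RF/w0/MAV"
        assert fv.layout[9] == "semg/L_RF/w0/PSD"
        assert len(set(fv.layout)) == len(fv.layout)

    def test_deterministic(self, small_trials):
        a = extract_feature_vector(small_trials[0], window_len=75, step=25)
        b = extract_feature_vector(small_trials[0], window_len=75, step=25)
        assert np.array_equal(a.values, b.values)

    def test_csp_features_appended(self, small_trials):
        csp = CSP(n_components=2).fit(
            [t.x_eeg1 for t in small_trials],
            [t.label for t in small_trials])
        fv = extract_feature_vector(small_trials[0], csp_model=csp,
                                    window_len=75, step=25)
        assert fv.values.size == 650 + 3 * 2
        assert fv.layout[-1].startswith("eeg/csp")

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.array([np.nan]), layout=["x"])
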