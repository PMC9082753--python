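"""Handcrafted features for the classical movement-prediction baselines.

sEMG, per 300-sample sliding window (step 100): mean absolute value (MAV),
waveform length (WL), zero crossings (ZC), the six coefficients of an
order-6 autoregressive model (Yule-Walker), and the average power spectral
density (Welch).  EEG: CSP log-variance features of the MI epoch.  Feature
vectors carry an explicit layout descriptor naming every entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz
from sklearn.base import BaseEstimator, TransformerMixin

from .csp import CSP
from .preprocess import segment_windows
from .simulate import CLASSES


# ---------------------------------------------------------------------------
# scalar features
# ---------------------------------------------------------------------------

def mav(window: np.ndarray) -> float:
    """Mean absolute value."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(window)))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative absolute first difference, sum |x[t+1] - x[t]|."""
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(window))))


def zero_crossings(window: np.ndarray, deadband: float = 0.0) -> int:
    """Count of sign changes whose amplitude step exceeds ``deadband``."""
    if deadband < 0:
        raise ValueError("deadband must be >= 0")
    window = np.asarray(window, dtype=float)
    x0, x1 = window[:-1], window[1:]
    crossings = (np.sign(x0) * np.sign(x1) < 0) & (np.abs(x1 - x0) > deadband)
    return int(np.count_nonzero(crossings))


def ar_coefficients(window: np.ndarray, order: int = 6) -> np.ndarray:
    """Autoregressive coefficients by the autocorrelation (Yule-Walker)
    method: phi solving ``R phi = r`` with R the Toeplitz autocovariance
    matrix, in the convention ``x[t] = sum_k phi[k] x[t-k] + e[t]``.

    A constant (zero-variance) window returns all zeros.
    """
    window = np.asarray(window, dtype=float)
    n = window.size
    if n <= order:
        raise ValueError(f"window length {n} must exceed AR order {order}")
    x = window - window.mean()
    if np.allclose(x, 0.0):
        return np.zeros(order)
    r = np.array([x[:n - k] @ x[k:] for k in range(order + 1)]) / n
    return solve_toeplitz(r[:order], r[1:order + 1])


def avg_psd(window: np.ndarray, fs: float) -> float:
    """Mean of the Welch power-spectral-density estimate over all analysis
    frequencies."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    window = np.asarray(window, dtype=float)
    nperseg = min(256, window.size)
    _, pxx = sps.welch(window, fs=fs, nperseg=nperseg)
    return float(np.mean(pxx))


#: Per-window sEMG feature block: 10 values.
SEMG_FEATURE_NAMES = ("MAV", "WL", "ZC", "AR1", "AR2", "AR3", "AR4", "AR5",
                      "AR6", "PSD")


def semg_window_features(window: np.ndarray, fs: float,
                         zc_deadband: float = 0.0) -> np.ndarray:
    ar = ar_coefficients(window, order=6)
    return np.array([mav(window), waveform_length(window),
                     zero_crossings(window, zc_deadband), *ar,
                     avg_psd(window, fs)])


# ---------------------------------------------------------------------------
# per-trial feature vectors
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    values: np.ndarray
    layout: list   # one descriptor string per entry

    def __post_init__(self):
        if len(self.layout) != self.values.size:
            raise ValueError("layout length must equal value count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def extract_feature_vector(trial, csp_model: CSP | None = None,
                           window_len: int = 300, step: int = 100,
                           zc_deadband: float = 0.0) -> FeatureVector:
    """Handcrafted features of one preprocessed trial.

    sEMG block: for each channel, for each sliding window, the 10-feature
    block ``(MAV, WL, ZC, AR1..AR6, PSD)`` — with 5 channels and 13 windows
    that is 650 values.  If ``csp_model`` is given (fitted), its log-variance
    features of the MI EEG epoch are appended.
    """
    values, layout = [], []
    ws = segment_windows(trial.x_semg, window_len, step)
    for ci, ch in enumerate(trial.emg_channels or
                            [f"ch{i}" for i in range(trial.x_semg.shape[0])]):
        for wi, win in enumerate(ws.windows):
            block = semg_window_features(win[ci], trial.fs_emg, zc_deadband)
            values.extend(block)
            layout.extend(f"semg/{ch}/w{wi}/{n}" for n in SEMG_FEATURE_NAMES)
    if csp_model is not None:
        csp_feats = csp_model.transform([trial.x_eeg1])[0]
        values.extend(csp_feats)
        layout.extend(f"eeg/csp{k}" for k in range(csp_feats.size))
    return FeatureVector(values=np.asarray(values, dtype=float), layout=layout)


# ---------------------------------------------------------------------------
# scikit-learn transformers over lists of MultimodalTrial
# ---------------------------------------------------------------------------

class EMGFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sEMG handcrafted-feature transformer."""

    def __init__(self, window_len: int = 300, step: int = 100,
                 zc_deadband: float = 0.0):
        self.window_len = window_len
        self.step = step
        self.zc_deadband = zc_deadband

    def fit(self, X, y=None):
        self.layout_ = extract_feature_vector(
            X[0], None, self.window_len, self.step, self.zc_deadband).layout
        return self

    def transform(self, X):
        return np.vstack([
            extract_feature_vector(t, None, self.window_len, self.step,
                                   self.zc_deadband).values
            for t in X])


class CSPFeatureExtractor(BaseEstimator, TransformerMixin):
    """One-vs-rest CSP log-variance features of the MI EEG epoch."""

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        if y is None:
            y = [t.label for t in X]
        y = np.asarray([CLASSES.index(v) if isinstance(v, str) else int(v)
                        for v in y])
        self.csp_ = CSP(self.n_components).fit([t.x_eeg1 for t in X], y)
        return self

    def transform(self, X):
        return self.csp_.transform([t.x_eeg1 for t in X])


class MultimodalFeatureExtractor(BaseEstimator, TransformerMixin):
    """Concatenated sEMG handcrafted + EEG CSP features."""

    def __init__(self, window_len: int = 300, step: int = 100,
                 n_csp_components: int = 4, zc_deadband: float = 0.0):
        self.window_len = window_len
        self.step = step
        self.n_csp_components = n_csp_components
        self.zc_deadband = zc_deadband

    def fit(self, X, y=None):
        self.emg_ = EMGFeatureExtractor(self.window_len, self.step,
                                        self.zc_deadband).fit(X, y)
        self.csp_ = CSPFeatureExtractor(self.n_csp_components).fit(X, y)
        return self

    def transform(self, X):
        return np.hstack([self.emg_.transform(X), self.csp_.transform(X)])
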