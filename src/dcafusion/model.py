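"""The full movement-prediction network and its scikit-learn estimators.

Architecture: the MI EEG epoch ``x_eeg1`` and the synchronized EEG epoch
``x_eeg2`` each pass through their own :class:`~dcafusion.encoders.EEGEncoder`
(independent parameter sets — the two inputs have different lengths); the
synchronized sEMG epoch passes through an
:class:`~dcafusion.encoders.EMGEncoder`.  The two synchronized feature sets
are brought to a common representation dimension ``d`` (row-major reshape
when the feature count divides ``d``, otherwise a learned linear projection)
and fused by N stacked dense co-attention layers.  The MI EEG features bypass
fusion: the classification head sees
``flatten(F_EEG1) ++ flatten(M_N) ++ flatten(E_N)`` through a linear layer and
a softmax over the three movement classes (standing, sitting, walking).

Training: Adam on categorical cross-entropy with validation stopping — the
returned parameters are the snapshot with the lowest validation loss.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .autograd import Tensor, concat, no_grad
from .dca import DCAStack
from .encoders import (EEGEncoder, EEGEncoderConfig, EMGEncoder,
                       EMGEncoderConfig, TINY_EEG, TINY_EMG)
from .io import load_checkpoint, save_checkpoint
from .simulate import CLASSES


@dataclass
class TrainConfig:
    """Optimization settings: Adam with default moments, categorical
    cross-entropy, up to ``max_epochs`` passes, keep the snapshot with the
    lowest validation loss.  ``patience`` (epochs without validation
    improvement) bounds wall time on already-converged runs."""

    max_epochs: int = 1000
    batch_size: int = 16
    lr: float = 1e-3
    val_fraction: float = 0.1
    patience: int | None = 50
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


class _Reshaper(nn.Module):
    """Bring encoder output ``(B, f, p)`` to the DCA state ``(B, d, n)``:
    a pure reshape when ``f*p == d*n`` for integer ``n``, otherwise a learned
    linear projection to ``d * n_target``."""

    def __init__(self, n_in: int, d: int, n_target: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if d <= 0:
            raise ValueError("d must be positive")
        self.d = d
        if n_in % d == 0 and n_target is None:
            self.n = n_in // d
            self.proj = None
        else:
            self.n = n_target if n_target is not None else max(2, round(n_in / d))
            self.proj = nn.Linear(n_in, d * self.n, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        flat = x.reshape(B, -1)
        if self.proj is not None:
            flat = self.proj(flat)
        return flat.reshape(B, self.d, self.n)


class MovementFusionNet(nn.Module):
    """Encoders + stacked co-attention + linear softmax head."""

    def __init__(self, c1: int, t1: int, t2_eeg: int, c2: int, t2: int,
                 eeg_config: EEGEncoderConfig = EEGEncoderConfig(),
                 emg_config: EMGEncoderConfig = EMGEncoderConfig(),
                 d: int = 300, n_layers: int = 2, n_classes: int = 3,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0A]))
        self.input_shape = (c1, t1, t2_eeg, c2, t2)
        self.d, self.n_layers, self.n_classes = d, n_layers, n_classes
        self.eeg1_encoder = EEGEncoder(c1, t1, eeg_config, rng=rng)
        self.eeg2_encoder = EEGEncoder(c1, t2_eeg, eeg_config, rng=rng)
        self.emg_encoder = EMGEncoder(c2, t2, emg_config, rng=rng)
        self.reshape_m = _Reshaper(self.emg_encoder.n_features, d, rng=rng)
        self.reshape_e = _Reshaper(self.eeg2_encoder.n_features, d, rng=rng)
        self.dca = DCAStack(d, n_layers, rng=rng)
        head_in = (self.eeg1_encoder.n_features
                   + d * self.reshape_m.n + d * self.reshape_e.n)
        self.head = nn.Linear(head_in, n_classes, rng=rng)

    def forward(self, x_eeg1: Tensor, x_eeg2: Tensor, x_semg: Tensor) -> Tensor:
        B = x_eeg1.shape[0]
        f_eeg1 = self.eeg1_encoder(x_eeg1)
        f_eeg2 = self.eeg2_encoder(x_eeg2)
        f_semg = self.emg_encoder(x_semg)
        m0 = self.reshape_m(f_semg)
        e0 = self.reshape_e(f_eeg2)
        m_n, e_n = self.dca(m0, e0)
        feats = concat([f_eeg1.reshape(B, -1), m_n.reshape(B, -1),
                        e_n.reshape(B, -1)], axis=1)
        return self.head(feats)


class EEGOnlyNet(nn.Module):
    """Single-modality control: both EEG epochs, no sEMG, no fusion."""

    def __init__(self, c1: int, t1: int, t2_eeg: int,
                 eeg_config: EEGEncoderConfig = EEGEncoderConfig(),
                 n_classes: int = 3, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEE6]))
        self.eeg1_encoder = EEGEncoder(c1, t1, eeg_config, rng=rng)
        self.eeg2_encoder = EEGEncoder(c1, t2_eeg, eeg_config, rng=rng)
        self.head = nn.Linear(self.eeg1_encoder.n_features
                              + self.eeg2_encoder.n_features, n_classes, rng=rng)

    def forward(self, x_eeg1: Tensor, x_eeg2: Tensor, x_semg=None) -> Tensor:
        B = x_eeg1.shape[0]
        feats = concat([self.eeg1_encoder(x_eeg1).reshape(B, -1),
                        self.eeg2_encoder(x_eeg2).reshape(B, -1)], axis=1)
        return self.head(feats)


class EMGOnlyNet(nn.Module):
    """Single-modality control: sEMG encoder + head only."""

    def __init__(self, c2: int, t2: int,
                 emg_config: EMGEncoderConfig = EMGEncoderConfig(),
                 n_classes: int = 3, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x356]))
        self.emg_encoder = EMGEncoder(c2, t2, emg_config, rng=rng)
        self.head = nn.Linear(self.emg_encoder.n_features, n_classes, rng=rng)

    def forward(self, x_eeg1=None, x_eeg2=None, x_semg: Tensor = None) -> Tensor:
        B = x_semg.shape[0]
        return self.head(self.emg_encoder(x_semg).reshape(B, -1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def trials_to_arrays(trials) -> tuple:
    """Stack a list of :class:`~dcafusion.preprocess.MultimodalTrial` into
    ``(X_eeg1, X_eeg2, X_semg, y)`` with integer labels in CLASSES order."""
    x1 = np.stack([t.x_eeg1 for t in trials])
    x2 = np.stack([t.x_eeg2 for t in trials])
    xs = np.stack([t.x_semg for t in trials])
    y = np.array([CLASSES.index(t.label) for t in trials])
    return x1, x2, xs, y


def _standardize(x: np.ndarray, mean=None, std=None):
    """Per-channel standardization; statistics from the training set only."""
    if mean is None:
        mean = x.mean(axis=(0, 2), keepdims=True)
        std = x.std(axis=(0, 2), keepdims=True) + 1e-12
    return (x - mean) / std, mean, std


def _forward_batched(net, x1, x2, xs, batch_size=64):
    outs = []
    with no_grad():
        for i in range(0, len(x1), batch_size):
            sl = slice(i, i + batch_size)
            logits = net(Tensor(x1[sl]), Tensor(x2[sl]), Tensor(xs[sl]))
            outs.append(logits.data)
    return np.vstack(outs)


def _loss_acc(net, x1, x2, xs, y):
    logits = _forward_batched(net, x1, x2, xs)
    shift = logits - logits.max(axis=1, keepdims=True)
    logp = shift - np.log(np.exp(shift).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(len(y)), y].mean()
    acc = (logits.argmax(axis=1) == y).mean()
    return float(loss), float(acc)


def train_network(net: nn.Module, train_data: tuple, val_data: tuple,
                  config: TrainConfig) -> tuple:
    """Train ``net`` in place; return ``(best_state, history)``.

    ``history`` is a dict of per-epoch lists (train/validation loss and
    accuracy); ``best_state`` is the parameter snapshot at the epoch with
    minimum validation loss (validation stopping).
    """
    x1, x2, xs, y = train_data
    if len(y) == 0 or len(val_data[3]) == 0:
        raise ValueError("empty train or validation split")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A1]))
    for m in net.modules():
        if isinstance(m, nn.Dropout):
            m.rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0xD20]))
    opt = nn.Adam(net.parameters(), lr=config.lr)
    history = {"epoch": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": [], "wall_s": []}
    best = {"val_loss": np.inf, "state": net.state_dict(), "epoch": -1}
    t0 = time.perf_counter()
    n = len(y)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        net.train()
        # train metrics from the minibatches themselves (no extra full pass)
        batch_losses, batch_hits = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = net(Tensor(x1[idx]), Tensor(x2[idx]), Tensor(xs[idx]))
            loss = nn.cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data) * len(idx))
            batch_hits += int((logits.data.argmax(axis=1) == y[idx]).sum())
        net.eval()
        tr_loss, tr_acc = sum(batch_losses) / n, batch_hits / n
        va_loss, va_acc = _loss_acc(net, *val_data)
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        history["wall_s"].append(time.perf_counter() - t0)
        if va_loss < best["val_loss"]:
            best = {"val_loss": va_loss, "state": net.state_dict(),
                    "epoch": epoch}
        elif (config.patience is not None
              and epoch - best["epoch"] >= config.patience):
            break
    net.load_state_dict(best["state"])
    return best["state"], history


def _stratified_val_split(y: np.ndarray, val_fraction: float, seed: int):
    """Deterministic stratified split of indices into (train, val)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B1]))
    tr_idx, va_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        va_idx.extend(idx[:n_val])
        tr_idx.extend(idx[n_val:])
    return np.sort(tr_idx), np.sort(va_idx)


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

_SIZE_PRESETS = {
    "default": (EEGEncoderConfig(), EMGEncoderConfig(), 300),
    "tiny": (TINY_EEG, TINY_EMG, 16),
}


class _BaseNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery.  ``X`` is a sequence of
    :class:`~dcafusion.preprocess.MultimodalTrial`; ``y`` defaults to the
    trials' own labels.  Ties in the predicted probabilities break to the
    lowest class index (argmax convention)."""

    def __init__(self, size: str = "default", n_layers: int = 2,
                 max_epochs: int = 1000, batch_size: int = 16, lr: float = 1e-3,
                 val_fraction: float = 0.1, patience: int | None = 50,
                 seed: int = 0):
        self.size = size
        self.n_layers = n_layers
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    def _build(self, shapes):
        raise NotImplementedError

    def fit(self, X, y=None):
        x1, x2, xs, y_own = trials_to_arrays(X)
        y = y_own if y is None else np.asarray(
            [CLASSES.index(v) if isinstance(v, str) else int(v) for v in y])
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to fit")
        x1, self.mean1_, self.std1_ = _standardize(x1)
        x2, self.mean2_, self.std2_ = _standardize(x2)
        xs, self.means_, self.stds_ = _standardize(xs)
        shapes = (x1.shape[1], x1.shape[2], x2.shape[2], xs.shape[1], xs.shape[2])
        self.net_ = self._build(shapes)
        tr, va = _stratified_val_split(y, self.val_fraction, self.seed)
        cfg = TrainConfig(max_epochs=self.max_epochs, batch_size=self.batch_size,
                          lr=self.lr, val_fraction=self.val_fraction,
                          patience=self.patience, seed=self.seed)
        self.params_, hist = train_network(
            self.net_, (x1[tr], x2[tr], xs[tr], y[tr]),
            (x1[va], x2[va], xs[va], y[va]), cfg)
        self.history_ = hist
        self.classes_ = np.array(CLASSES, dtype=object)
        self.input_shapes_ = shapes
        return self

    def _arrays(self, X):
        x1, x2, xs, _ = trials_to_arrays(X)
        x1, _, _ = _standardize(x1, self.mean1_, self.std1_)
        x2, _, _ = _standardize(x2, self.mean2_, self.std2_)
        xs, _, _ = _standardize(xs, self.means_, self.stds_)
        return x1, x2, xs

    def predict_proba(self, X):
        x1, x2, xs = self._arrays(X)
        logits = _forward_batched(self.net_, x1, x2, xs)
        shift = np.exp(logits - logits.max(axis=1, keepdims=True))
        return shift / shift.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def save(self, path):
        config = {"class": type(self).__name__, "params": self.get_params(),
                  "input_shapes": list(self.input_shapes_)}
        arrays = dict(self.net_.state_dict())
        for name in ("mean1_", "std1_", "mean2_", "std2_", "means_", "stds_"):
            arrays[f"norm/{name}"] = getattr(self, name)
        save_checkpoint(path, arrays, config)

    @classmethod
    def load(cls, path):
        params, config = load_checkpoint(path)
        est = cls(**config["params"])
        shapes = tuple(config["input_shapes"])
        est.net_ = est._build(shapes)
        est.net_.load_state_dict(
            {k: v for k, v in params.items() if not k.startswith("norm/")})
        est.net_.eval()
        for name in ("mean1_", "std1_", "mean2_", "std2_", "means_", "stds_"):
            setattr(est, name, params[f"norm/{name}"])
        est.classes_ = np.array(CLASSES, dtype=object)
        est.input_shapes_ = shapes
        return est


class CoAttentionFusionClassifier(_BaseNetClassifier):
    """Multimodal movement classifier with stacked dense co-attention fusion."""

    def _build(self, shapes):
        eeg_cfg, emg_cfg, d = _SIZE_PRESETS[self.size]
        return MovementFusionNet(*shapes, eeg_config=eeg_cfg, emg_config=emg_cfg,
                                 d=d, n_layers=self.n_layers, seed=self.seed)


class SingleModalityClassifier(_BaseNetClassifier):
    """Encoder + linear head on one modality only (ablation control)."""

    def __init__(self, modality: str = "eeg", size: str = "default",
                 n_layers: int = 0, max_epochs: int = 1000, batch_size: int = 16,
                 lr: float = 1e-3, val_fraction: float = 0.1,
                 patience: int | None = 50, seed: int = 0):
        super().__init__(size=size, n_layers=n_layers, max_epochs=max_epochs,
                         batch_size=batch_size, lr=lr, val_fraction=val_fraction,
                         patience=patience, seed=seed)
        self.modality = modality

    def _build(self, shapes):
        eeg_cfg, emg_cfg, _ = _SIZE_PRESETS[self.size]
        c1, t1, t2_eeg, c2, t2 = shapes
        if self.modality == "eeg":
            return EEGOnlyNet(c1, t1, t2_eeg, eeg_config=eeg_cfg, seed=self.seed)
        if self.modality == "semg":
            return EMGOnlyNet(c2, t2, emg_config=emg_cfg, seed=self.seed)
        raise ValueError(f"unknown modality {self.modality!r}")
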