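"""Self-contained benchmark experiments on synthetic data.

These are the package's headline property checks, shared by the test suite
and the reproduction script.  Sizes are chosen for single-CPU runs: signals
are simulated at reduced rates (EEG 64 Hz, sEMG 96 Hz — the same 2:3 rate
ratio as the acquisition hardware) and the networks use the ``tiny``
configuration.  The methods note documents these problem sizes.
"""

from __future__ import annotations

import numpy as np

from .evaluation import accuracy
from .model import CoAttentionFusionClassifier, SingleModalityClassifier
from .paradigm import make_paradigm_timeline
from .preprocess import preprocess_dataset
from .registry import make_method
from .simulate import make_dataset


def _stratified_holdout(trials, fraction: float, seed: int):
    labels = np.array([t.label for t in trials])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x40]))
    test_i, train_i = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(fraction * len(idx)))
        test_i.extend(idx[:k])
        train_i.extend(idx[k:])
    return ([trials[i] for i in sorted(train_i)],
            [trials[i] for i in sorted(test_i)])


def make_partial_information_trials(seed: int, n_subjects: int = 5,
                                    trials_per_class: int = 40,
                                    fs_eeg: float = 64.0, fs_emg: float = 96.0):
    """Simulate and preprocess the partial-information benchmark: the
    ``partial`` class coding gives each modality discriminative power over
    only 2 of the 3 movement classes (EEG separates standing from the rest,
    sEMG separates walking from the rest), so only their fusion can resolve
    all three."""
    spec = make_paradigm_timeline(fs_eeg=fs_eeg, fs_emg=fs_emg)
    recs = make_dataset(n_subjects=n_subjects, groups=1,
                        trials_per_class_per_group=trials_per_class,
                        seed=seed, coding="partial", spec=spec)
    return preprocess_dataset(recs, spec, side="left")


def multimodal_advantage(seed: int = 11, n_subjects: int = 5,
                         trials_per_class: int = 40,
                         fusion_epochs: int = 80, single_epochs: int = 40,
                         verbose: bool = False) -> dict:
    """Train the fusion model and both single-modality controls on the
    partial-information benchmark (default 600 trials, 70/30 stratified
    holdout) and report test accuracies.

    Returns a dict with ``fusion_acc``, ``eeg_acc``, ``semg_acc``,
    ``advantage`` (fusion minus the better single modality, in accuracy
    fraction) and ``n_test``.
    """
    trials = make_partial_information_trials(seed, n_subjects, trials_per_class)
    train, test = _stratified_holdout(trials, 0.3, seed)
    y_test = [t.label for t in test]

    common = dict(size="tiny", lr=1e-3, batch_size=32, val_fraction=0.15,
                  seed=seed)
    models = {
        "fusion": CoAttentionFusionClassifier(
            n_layers=2, max_epochs=fusion_epochs, patience=None, **common),
        "eeg": SingleModalityClassifier(
            "eeg", max_epochs=single_epochs, patience=15, **common),
        "semg": SingleModalityClassifier(
            "semg", max_epochs=single_epochs, patience=15, **common),
    }
    accs = {}
    for name, est in models.items():
        est.fit(train)
        accs[name] = accuracy(est.predict(test), np.asarray(y_test))
        if verbose:
            print(f"{name}: test accuracy {accs[name]:.3f} "
                  f"({len(est.history_['epoch'])} epochs)")
    return {
        "fusion_acc": accs["fusion"],
        "eeg_acc": accs["eeg"],
        "semg_acc": accs["semg"],
        "advantage": accs["fusion"] - max(accs["eeg"], accs["semg"]),
        "n_train": len(train),
        "n_test": len(test),
    }


def modality_ordering(seed: int = 3, n_subjects: int = 2,
                      trials_per_class: int = 34) -> dict:
    """Classical-feature check mirroring the single-modality ordering: with
    the default (distinct) class coding, sEMG handcrafted features beat EEG
    CSP features under the same classifier."""
    spec = make_paradigm_timeline(fs_eeg=64.0, fs_emg=96.0)
    recs = make_dataset(n_subjects=n_subjects, groups=1,
                        trials_per_class_per_group=trials_per_class,
                        seed=seed, coding="distinct", spec=spec)
    trials = preprocess_dataset(recs, spec, side="left")
    train, test = _stratified_holdout(trials, 0.3, seed)
    y_test = np.asarray([t.label for t in test])
    out = {}
    for feats in ("semg", "eeg"):
        est = make_method(f"{feats}-lda", seed=seed)
        if feats == "semg":
            # windows scaled to the reduced sampling rate
            est.set_params(features__window_len=48, features__step=16)
        est.fit(train)
        out[f"{feats}_lda_acc"] = accuracy(est.predict(test), y_test)
    out["n_test"] = len(test)
    return out


def chance_level_control(seed: int = 5, n_subjects: int = 2,
                         trials_per_class: int = 67) -> dict:
    """Label-shuffled control: training a classical pipeline on permuted
    labels must stay at 3-class chance on held-out data."""
    spec = make_paradigm_timeline(fs_eeg=64.0, fs_emg=96.0)
    recs = make_dataset(n_subjects=n_subjects, groups=1,
                        trials_per_class_per_group=trials_per_class,
                        seed=seed, coding="distinct", spec=spec)
    trials = preprocess_dataset(recs, spec, side="left")
    train, test = _stratified_holdout(trials, 0.5, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F]))
    y_shuffled = rng.permutation([t.label for t in train])
    est = make_method("semg-lda", seed=seed)
    est.set_params(features__window_len=48, features__step=16)
    est.fit(train, y_shuffled)
    acc = accuracy(est.predict(test), np.asarray([t.label for t in test]))
    return {"shuffled_acc": acc, "n_test": len(test)}
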