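"""Evaluation protocols, metrics, and the experiment report generator.

Two protocols:

* within-subject — each subject's trials are split 70/30 (stratified by
  class) into a training portion and a held-out test set; the 70% portion is
  further partitioned into 4 stratified cross-validation folds, each serving
  once as the validation set.
* cross-subject — subjects (not trials) are partitioned: 7 random training
  subjects and 3 test subjects per fold, repeated 5 times with different
  random draws.  All trials of a subject stay on one side of the split.

The report stores raw per-fold and per-subject accuracies so that any
downstream statistics package can analyse them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CLASSES


class SplitError(ValueError):
    pass


@dataclass
class SplitPlan:
    """Fold container: each fold maps ``train``/``val``/``test`` to disjoint
    trial-index lists."""

    mode: str
    folds: list = field(default_factory=list)
    seed: int = 0

    def audit(self) -> None:
        """Raise if any fold leaks a trial between train/val/test."""
        for k, fold in enumerate(self.folds):
            sets = {name: set(fold[name]) for name in ("train", "val", "test")
                    if name in fold}
            names = list(sets)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    overlap = sets[names[i]] & sets[names[j]]
                    if overlap:
                        raise SplitError(
                            f"fold {k}: {names[i]}/{names[j]} share trials "
                            f"{sorted(overlap)[:5]}...")


def within_subject_split(trials, seed: int, test_fraction: float = 0.3,
                         n_folds: int = 4) -> SplitPlan:
    """70/30 stratified train/test split of one subject's trials, the 70%
    partitioned into ``n_folds`` stratified CV folds.

    Returns a plan with ``n_folds`` folds sharing the same test set; each
    fold's ``val`` is one CV part, ``train`` the remaining parts.  Rounding:
    per class, ``floor(0.7 * n)`` trials go to the training portion and the
    remainder to test.
    """
    labels = np.asarray([t.label for t in trials])
    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise SplitError(f"within-subject split expects one subject, got {subjects}")
    if len(trials) < 12:
        raise SplitError("need at least 12 trials")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x517]))
    train_pool, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(np.floor((1.0 - test_fraction) * len(idx)))
        train_pool.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_pool = np.asarray(sorted(train_pool))
    test_idx = sorted(int(i) for i in test_idx)

    # partition the training portion into n_folds stratified parts
    parts = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = [i for i in train_pool if labels[i] == cls]
        if len(idx) < n_folds:
            raise SplitError(
                f"class {cls!r} has {len(idx)} training trials, fewer than "
                f"{n_folds} folds")
        idx = np.asarray(idx)[rng.permutation(len(idx))]
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            parts[k].extend(int(i) for i in chunk)
    folds = []
    for k in range(n_folds):
        val = sorted(parts[k])
        train = sorted(int(i) for i in train_pool if int(i) not in set(val))
        folds.append({"train": train, "val": val, "test": list(test_idx)})
    return SplitPlan(mode="within_subject", folds=folds, seed=seed)


def cross_subject_split(trials, seed: int, n_train_subjects: int = 7,
                        n_test_subjects: int = 3, n_repeats: int = 5) -> SplitPlan:
    """Subject-level folds: ``n_repeats`` random draws of train/test subject
    sets; every trial follows its subject."""
    subject_ids = sorted({t.subject_id for t in trials})
    need = n_train_subjects + n_test_subjects
    if len(subject_ids) < need:
        raise SplitError(
            f"{len(subject_ids)} subjects but {need} required; "
            "override the subject counts for smaller datasets")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC57]))
    by_subject = {sid: [i for i, t in enumerate(trials) if t.subject_id == sid]
                  for sid in subject_ids}
    folds = []
    for _ in range(n_repeats):
        order = rng.permutation(subject_ids)
        train_s = set(order[:n_train_subjects].tolist())
        test_s = set(order[n_train_subjects:need].tolist())
        folds.append({
            "train": sorted(i for s in train_s for i in by_subject[s]),
            "test": sorted(i for s in test_s for i in by_subject[s]),
            "train_subjects": sorted(train_s),
            "test_subjects": sorted(test_s),
        })
    return SplitPlan(mode="cross_subject", folds=folds, seed=seed)


def accuracy(predictions, labels) -> float:
    """Fraction of exact label matches."""
    predictions, labels = np.asarray(predictions), np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {labels.shape}")
    return float(np.mean(predictions == labels))


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_experiment(trials, methods: dict, mode: str = "within_subject",
                   seed: int = 0, out_dir=None, split_kwargs: dict | None = None):
    """Fit and score every method under the chosen protocol.

    Parameters
    ----------
    trials : list of MultimodalTrial
    methods : dict name -> zero-argument estimator factory
    mode : "within_subject" or "cross_subject"
    seed : governs all splits (and is passed to estimators accepting it)

    Returns a tidy DataFrame with one row per (method, subject-or-fold, fold)
    plus per-method mean rows; written to CSV/JSON when ``out_dir`` given.
    """
    if not methods:
        raise ValueError("no methods configured")
    split_kwargs = split_kwargs or {}
    labels = np.asarray([t.label for t in trials])
    rows = []
    meta = {"mode": mode, "seed": seed,
            "config_hash": _config_hash({"mode": mode, "seed": seed,
                                         "methods": sorted(methods)})}
    if mode == "within_subject":
        subject_ids = sorted({t.subject_id for t in trials})
        for sid in subject_ids:
            idx = [i for i, t in enumerate(trials) if t.subject_id == sid]
            sub = [trials[i] for i in idx]
            plan = within_subject_split(sub, seed, **split_kwargs)
            plan.audit()
            for name, factory in methods.items():
                fold_accs, best = [], (np.inf, None)
                for k, fold in enumerate(plan.folds):
                    est = factory()
                    est.fit([sub[i] for i in fold["train"]])
                    val_acc = accuracy(est.predict([sub[i] for i in fold["val"]]),
                                       [sub[i].label for i in fold["val"]])
                    test_acc = accuracy(
                        est.predict([sub[i] for i in fold["test"]]),
                        [sub[i].label for i in fold["test"]])
                    fold_accs.append(test_acc)
                    if 1.0 - val_acc < best[0]:
                        best = (1.0 - val_acc, test_acc)
                    rows.append({"method": name, "subject": sid, "fold": k,
                                 "val_acc": val_acc, "test_acc": test_acc})
                rows.append({"method": name, "subject": sid, "fold": "mean",
                             "test_acc": float(np.mean(fold_accs)),
                             "best_val_test_acc": best[1]})
    elif mode == "cross_subject":
        plan = cross_subject_split(trials, seed, **split_kwargs)
        plan.audit()
        for name, factory in methods.items():
            for k, fold in enumerate(plan.folds):
                est = factory()
                est.fit([trials[i] for i in fold["train"]])
                test_acc = accuracy(est.predict([trials[i] for i in fold["test"]]),
                                    labels[fold["test"]])
                rows.append({"method": name, "fold": k, "test_acc": test_acc,
                             "test_subjects": str(fold["test_subjects"])})
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame(rows)
    means = (df[df["fold"] != "mean"].groupby("method")["test_acc"]
             .mean().rename("mean_test_acc").reset_index())
    if out_dir is not None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(json.dumps(
            {"meta": meta, "rows": rows,
             "means": means.to_dict(orient="records")}, indent=2, default=str))
    df.attrs.update(meta)
    return df, means
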