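"""Named method factories for the experiment runner and CLI.

Classical baselines are scikit-learn pipelines over the handcrafted-feature
transformers; the deep methods are the package's own estimators.  Names:
``<features>-<classifier>`` with features in {semg, eeg, multi} and
classifier in {lda, dt, nb, lsvm, rbfsvm, knn, ann}; deep methods are
``dca`` (multimodal fusion), ``deep-eeg`` and ``deep-semg`` (single
modality).
"""

from __future__ import annotations

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (CSPFeatureExtractor, EMGFeatureExtractor,
                       MultimodalFeatureExtractor)
from .model import CoAttentionFusionClassifier, SingleModalityClassifier

_FEATURES = {
    "semg": EMGFeatureExtractor,
    "eeg": CSPFeatureExtractor,
    "multi": MultimodalFeatureExtractor,
}

_CLASSIFIERS = {
    "lda": lambda seed: LinearDiscriminantAnalysis(),
    "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
    "nb": lambda seed: GaussianNB(),
    "lsvm": lambda seed: SVC(kernel="linear", random_state=seed),
    "rbfsvm": lambda seed: SVC(kernel="rbf", random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "ann": lambda seed: MLPClassifier(hidden_layer_sizes=(50,), max_iter=500,
                                      random_state=seed),
}


class _LabelledPipeline(Pipeline):
    """Pipeline whose ``fit`` defaults y to the trials' own labels."""

    def fit(self, X, y=None, **kwargs):
        if y is None:
            y = [t.label for t in X]
        return super().fit(X, y, **kwargs)


def make_method(name: str, seed: int = 0, size: str = "tiny",
                max_epochs: int = 60, **net_kwargs):
    """Instantiate a method by registry name."""
    if name == "dca":
        return CoAttentionFusionClassifier(size=size, max_epochs=max_epochs,
                                           seed=seed, **net_kwargs)
    if name in ("deep-eeg", "deep-semg"):
        modality = name.split("-")[1]
        return SingleModalityClassifier(modality=modality, size=size,
                                        max_epochs=max_epochs, seed=seed,
                                        **net_kwargs)
    try:
        feat_name, clf_name = name.split("-")
        feat, clf = _FEATURES[feat_name], _CLASSIFIERS[clf_name]
    except (ValueError, KeyError):
        raise KeyError(
            f"unknown method {name!r}; expected dca, deep-eeg, deep-semg or "
            f"<features>-<classifier> with features in {sorted(_FEATURES)} "
            f"and classifier in {sorted(_CLASSIFIERS)}") from None
    return _LabelledPipeline([
        ("features", feat()),
        ("scale", StandardScaler()),
        ("clf", clf(seed)),
    ])


def method_factory(name: str, seed: int = 0, **kwargs):
    return lambda: make_method(name, seed=seed, **kwargs)
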