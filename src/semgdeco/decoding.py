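"""Compound-motion decoders: one integrated 60-class model, or a
triple-parallel classifier chain.

The *integrated* decoder fits a single multiclass model over the 60
compound IDs.  The *chain* fits three independent classifiers — strength
(3 classes), gesture (4) and wrist angle (5) — and composes their
decisions back into a compound ID through the label algebra; the chain's
theoretical compound accuracy is the product of its three factor
accuracies.

Classifier variants follow the preset grid of a point-and-click learner:
decision trees capped at 100/20/4 leaves (Gini), linear/quadratic
discriminants, Gaussian naive Bayes, SVMs with linear / (1 + x'y)^2 /
(1 + x'y)^3 / Gaussian kernels (scale gamma in {0.56, 2.2, 8.9}, defined
on z-scored features), k-NN with k in {1, 10, 100} and euclidean / cosine
/ Minkowski-3 / squared-inverse-distance-weighted variants, and tree
ensembles.  Features are z-scored with training-set statistics before
kernel and distance based models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import MotionLabel, compound_id, decompose_id, N_CLASSES

__all__ = [
    "ModelSpec",
    "Standardizer",
    "IntegratedDecoder",
    "ChainDecoder",
    "available_variants",
    "make_estimator",
    "train_integrated",
    "train_chain",
    "predict_compound",
    "chain_theoretical_accuracy",
    "FACTOR_NAMES",
]

FACTOR_NAMES = ("strength", "gesture", "wrist")


def _inverse_square_weights(dist: np.ndarray) -> np.ndarray:
    """Squared-inverse-distance voting weights; exact hits take all votes."""
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(dist)
    exact = dist == 0.0
    rows = exact.any(axis=1)
    if rows.any():
        w[rows] = exact[rows].astype(float)
    return w


@dataclass(frozen=True)
class ModelSpec:
    """One classifier variant; ``variant`` selects a preset, ``params``
    overrides individual hyperparameters."""

    variant: str = "svm-quadratic"
    params: dict = field(default_factory=dict)
    seed: int = 0
    standardize: bool = True


def _build_registry() -> dict:
    reg: dict[str, callable] = {}

    def tree(max_leaves):
        return lambda spec: DecisionTreeClassifier(
            max_leaf_nodes=max_leaves, criterion="gini", random_state=spec.seed, **spec.params
        )

    reg["tree-fine"] = tree(100)
    reg["tree-medium"] = tree(20)
    reg["tree-coarse"] = tree(4)
    reg["lda"] = lambda spec: LinearDiscriminantAnalysis(**spec.params)
    # no regularisation by default: a singular class covariance should fail
    # loudly, mirroring the blank cells a rank-deficient fit produces
    reg["qda"] = lambda spec: QuadraticDiscriminantAnalysis(
        **{"reg_param": 0.0, **spec.params}
    )
    reg["nb-gaussian"] = lambda spec: GaussianNB(**spec.params)

    def svc(**kw):
        return lambda spec: SVC(
            decision_function_shape="ovo", C=1.0, random_state=spec.seed, **{**kw, **spec.params}
        )

    reg["svm-linear"] = svc(kernel="linear")
    reg["svm-quadratic"] = svc(kernel="poly", degree=2, coef0=1.0, gamma=1.0)
    reg["svm-cubic"] = svc(kernel="poly", degree=3, coef0=1.0, gamma=1.0)
    # preset "scale" gamma_preset is the gaussian width: K = exp(-||u-v||^2 / gamma_preset)
    reg["svm-fine-gaussian"] = svc(kernel="rbf", gamma=1.0 / 0.56)
    reg["svm-medium-gaussian"] = svc(kernel="rbf", gamma=1.0 / 2.2)
    reg["svm-coarse-gaussian"] = svc(kernel="rbf", gamma=1.0 / 8.9)

    def knn(**kw):
        return lambda spec: KNeighborsClassifier(**{**kw, **spec.params})

    reg["knn-fine"] = knn(n_neighbors=1)
    reg["knn-medium"] = knn(n_neighbors=10)
    reg["knn-coarse"] = knn(n_neighbors=100)
    reg["knn-cosine"] = knn(n_neighbors=10, metric="cosine")
    reg["knn-cubic"] = knn(n_neighbors=10, metric="minkowski", p=3)
    reg["knn-weighted"] = knn(n_neighbors=10, weights=_inverse_square_weights)

    reg["ensemble-bagged-trees"] = lambda spec: BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=spec.seed),
        n_estimators=spec.params.get("n_estimators", 30),
        random_state=spec.seed,
    )
    reg["ensemble-boosted-trees"] = lambda spec: AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=3, random_state=spec.seed),
        n_estimators=spec.params.get("n_estimators", 30),
        random_state=spec.seed,
    )
    reg["ensemble-subspace-discriminant"] = lambda spec: BaggingClassifier(
        estimator=LinearDiscriminantAnalysis(),
        n_estimators=spec.params.get("n_estimators", 30),
        max_features=0.5,
        bootstrap=False,
        random_state=spec.seed,
    )
    reg["ensemble-subspace-knn"] = lambda spec: BaggingClassifier(
        estimator=KNeighborsClassifier(n_neighbors=10),
        n_estimators=spec.params.get("n_estimators", 30),
        max_features=0.5,
        bootstrap=False,
        random_state=spec.seed,
    )
    return reg


_REGISTRY = _build_registry()

_UNSUPPORTED = {
    "nb-kernel": "kernel naive Bayes has no scikit-learn backend",
    "ensemble-rusboosted-trees": "RUSBoost has no scikit-learn backend",
}


def available_variants() -> list[str]:
    return sorted(_REGISTRY)


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a variant preset."""
    if spec.variant in _UNSUPPORTED:
        raise ValueError(f"variant {spec.variant!r} is not supported: {_UNSUPPORTED[spec.variant]}")
    if spec.variant not in _REGISTRY:
        raise ValueError(
            f"unknown variant {spec.variant!r}; available: {', '.join(available_variants())}"
        )
    return _REGISTRY[spec.variant](spec)


class Standardizer:
    """Per-dimension z-scoring with training-set statistics.

    Zero-variance dimensions pass through unscaled (with a warning): they
    carry no information but must not produce NaNs.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer needs a 2-D array with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        flat = scale == 0.0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance feature dimension(s) left unscaled",
                stacklevel=2,
            )
            scale = np.where(flat, 1.0, scale)
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer has not been fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted {self.mean_.shape[0]}"
            )
        return (X - self.mean_) / self.scale_


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {X.shape}")
    return X


class IntegratedDecoder:
    """Single multiclass model over the 60 compound IDs."""

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.standardizer = Standardizer() if spec.standardize else None
        self.clf = make_estimator(spec)
        self.n_features_: int | None = None

    def fit(self, X, y_compound, expected_classes=None) -> "IntegratedDecoder":
        X = _as_matrix(X)
        y = np.asarray(y_compound, dtype=int)
        if y.min() < 1 or y.max() > N_CLASSES:
            raise ValueError("compound ids must lie in 1..60")
        if expected_classes is not None:
            missing = sorted(set(expected_classes) - set(np.unique(y)))
            if missing:
                raise ValueError(f"training data is missing compound ids: {missing}")
        if self.standardizer is not None:
            X = self.standardizer.fit(X).transform(X)
        self.clf.fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if self.n_features_ is None:
            raise ValueError("decoder has not been fitted")
        if X.shape[1] != self.n_features_:
            raise ValueError(f"feature dimension {X.shape[1]} != fitted {self.n_features_}")
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        return self.clf.predict(X).astype(int)


class ChainDecoder:
    """Triple-parallel factor classifiers composed via the label algebra."""

    _FACTOR_INDEX = {"strength": 2, "gesture": 0, "wrist": 1}
    _FACTOR_CARDINALITY = {"strength": 3, "gesture": 4, "wrist": 5}

    def __init__(
        self,
        spec_strength: ModelSpec,
        spec_gesture: ModelSpec,
        spec_wrist: ModelSpec,
    ) -> None:
        self.specs = {"strength": spec_strength, "gesture": spec_gesture, "wrist": spec_wrist}
        self.standardizers: dict[str, Standardizer | None] = {}
        self.clfs = {name: make_estimator(spec) for name, spec in self.specs.items()}
        self.n_features_: int | None = None

    def fit(self, X, y_compound) -> "ChainDecoder":
        X = _as_matrix(X)
        y = np.asarray(y_compound, dtype=int)
        triples = np.array([decompose_id(int(c)) for c in y])  # (n, 3): g, w, s
        for name, clf in self.clfs.items():
            target = triples[:, self._FACTOR_INDEX[name]]
            levels = np.unique(target)
            if len(levels) < self._FACTOR_CARDINALITY[name]:
                missing = sorted(set(range(self._FACTOR_CARDINALITY[name])) - set(levels))
                raise ValueError(f"training data is missing {name} level(s): {missing}")
            Xf = X
            if self.specs[name].standardize:
                st = Standardizer().fit(X)
                self.standardizers[name] = st
                Xf = st.transform(X)
            else:
                self.standardizers[name] = None
            clf.fit(Xf, target)
        self.n_features_ = X.shape[1]
        return self

    def predict_factors(self, X) -> dict[str, np.ndarray]:
        X = _as_matrix(X)
        if self.n_features_ is None:
            raise ValueError("decoder has not been fitted")
        if X.shape[1] != self.n_features_:
            raise ValueError(f"feature dimension {X.shape[1]} != fitted {self.n_features_}")
        out = {}
        for name, clf in self.clfs.items():
            st = self.standardizers[name]
            out[name] = clf.predict(st.transform(X) if st is not None else X).astype(int)
        return out

    def predict(self, X) -> np.ndarray:
        f = self.predict_factors(X)
        return np.array(
            [compound_id(g, w, s) for g, w, s in zip(f["gesture"], f["wrist"], f["strength"])]
        )


def train_integrated(train_table: pd.DataFrame, spec: ModelSpec, feature_cols=None,
                     expected_classes=None) -> IntegratedDecoder:
    """Fit an integrated decoder from a feature table (as built by
    :func:`semgdeco.features.extract_dataset`)."""
    X, y = _table_xy(train_table, feature_cols)
    return IntegratedDecoder(spec).fit(X, y, expected_classes=expected_classes)


def train_chain(
    train_table: pd.DataFrame,
    spec_strength: ModelSpec,
    spec_gesture: ModelSpec,
    spec_wrist: ModelSpec,
    feature_cols=None,
) -> ChainDecoder:
    """Fit the triple-parallel chain from a feature table."""
    X, y = _table_xy(train_table, feature_cols)
    return ChainDecoder(spec_strength, spec_gesture, spec_wrist).fit(X, y)


def _table_xy(table: pd.DataFrame, feature_cols=None):
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c.startswith("ch")]
    if not feature_cols:
        raise ValueError("no feature columns (ch*) found in table")
    return table[feature_cols].to_numpy(dtype=float), table["compound_id"].to_numpy(dtype=int)


def predict_compound(decoder, X):
    """Compound-ID predictions; for a chain, also the factor decisions."""
    if isinstance(decoder, ChainDecoder):
        factors = decoder.predict_factors(X)
        ids = np.array(
            [
                compound_id(g, w, s)
                for g, w, s in zip(factors["gesture"], factors["wrist"], factors["strength"])
            ]
        )
        return ids, factors
    return decoder.predict(X)


def chain_theoretical_accuracy(acc_strength: float, acc_gesture: float, acc_wrist: float) -> float:
    """Product of the three factor accuracies, on the callers' scale.

    All three must be fractions in [0, 1] or all percentages in (1, 100];
    mixing scales is rejected.  A percentage input returns a percentage.
    """
    accs = (acc_strength, acc_gesture, acc_wrist)
    if any(a < 0 or a > 100 for a in accs):
        raise ValueError(f"accuracies out of range: {accs}")
    frac = all(a <= 1.0 for a in accs)
    pct = all(a > 1.0 or a == 0.0 for a in accs) and any(a > 1.0 for a in accs)
    if not (frac or pct):
        raise ValueError(f"mixed accuracy scales: {accs} (use all fractions or all percentages)")
    p = accs[0] * accs[1] * accs[2]
    return p / 10000.0 if pct else p
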