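"""Evaluation surfaces for compound-motion decoding.

Overall and per-mode accuracy, the 60x60 confusion matrix, factor and
joint-factor accuracies obtained by projecting compound decisions through
the label algebra, mean +/- population-std aggregation across subjects,
and the two robustness sweeps (shrinking training proportion; growing
cumulative feature set).

Aggregates use the *population* standard deviation (denominator N): this
is the convention that reproduces the study-style "mean +/- std" figures
from per-subject accuracy lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .dataset import decompose_id, N_CLASSES
from .decoding import ChainDecoder, ModelSpec, train_chain, train_integrated
from .features import FEATURE_ORDER, FeatureSpec

__all__ = [
    "EvaluationReport",
    "overall_accuracy",
    "per_mode_accuracy",
    "confusion_matrix",
    "factor_accuracy",
    "aggregate_mean_popstd",
    "evaluate_decoder",
    "split_feature_table",
    "training_proportion_sweep",
    "feature_count_sweep",
]

_FACTOR_POS = {"gesture": 0, "wrist": 1, "strength": 2}


def _check_pair(pred, truth):
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(f"pred/truth must be equal-length 1-D, got {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return pred, truth


def overall_accuracy(pred, truth) -> float:
    """Percentage of exact matches."""
    pred, truth = _check_pair(pred, truth)
    return 100.0 * float(np.mean(pred == truth))


def per_mode_accuracy(pred, truth) -> np.ndarray:
    """60-vector of per-class accuracies in %; NaN where a class has no
    test samples (undefined, never reported as 0)."""
    pred, truth = _check_pair(pred, truth)
    out = np.full(N_CLASSES, np.nan)
    for cid in range(1, N_CLASSES + 1):
        mask = truth == cid
        if mask.any():
            out[cid - 1] = 100.0 * float(np.mean(pred[mask] == cid))
    return out


def confusion_matrix(pred, truth, normalize: bool = False) -> np.ndarray:
    """60x60 count matrix, rows = true compound ID, columns = predicted.

    With ``normalize=True`` each non-empty row sums to 1; empty rows stay
    all-zero (the per-mode accuracy marks them undefined).
    """
    pred, truth = _check_pair(pred, truth)
    if truth.min() < 1 or truth.max() > N_CLASSES or pred.min() < 1 or pred.max() > N_CLASSES:
        raise ValueError("labels must lie in 1..60")
    cm = _sk_confusion(truth, pred, labels=np.arange(1, N_CLASSES + 1))
    if normalize:
        sums = cm.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = np.where(sums > 0, cm / sums, 0.0)
    return cm


def factor_accuracy(pred_compound, truth_compound, factor) -> float:
    """Accuracy in % after projecting compound IDs onto a factor (or a
    tuple of factors, e.g. ("strength", "gesture"))."""
    pred, truth = _check_pair(pred_compound, truth_compound)
    factors = (factor,) if isinstance(factor, str) else tuple(factor)
    unknown = set(factors) - set(_FACTOR_POS)
    if unknown:
        raise ValueError(f"unknown factor(s) {sorted(unknown)}; valid: {sorted(_FACTOR_POS)}")
    idx = [_FACTOR_POS[f] for f in factors]
    p = np.array([[decompose_id(int(c))[i] for i in idx] for c in pred])
    t = np.array([[decompose_id(int(c))[i] for i in idx] for c in truth])
    return 100.0 * float(np.mean(np.all(p == t, axis=1)))


def aggregate_mean_popstd(values) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (denominator N)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value to aggregate")
    return float(values.mean()), float(values.std(ddof=0))


@dataclass
class EvaluationReport:
    """Held-out evaluation of one decoder on one subject's test windows."""

    overall_accuracy: float
    per_mode_accuracy: np.ndarray
    confusion: np.ndarray
    factor_accuracy: dict[str, float]
    joint_strength_gesture: float
    n_test: int
    chain_factor_accuracy: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if int(self.confusion.sum()) != self.n_test:
            raise ValueError("confusion entries must sum to n_test")
        trace_acc = 100.0 * np.trace(self.confusion) / self.n_test
        if abs(trace_acc - self.overall_accuracy) > 1e-9:
            raise ValueError("overall accuracy inconsistent with confusion trace")

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "factor_accuracy": dict(self.factor_accuracy),
            "joint_strength_gesture": self.joint_strength_gesture,
            "n_test": self.n_test,
            "per_mode_accuracy": [None if np.isnan(v) else v for v in self.per_mode_accuracy],
            "chain_factor_accuracy": (
                dict(self.chain_factor_accuracy) if self.chain_factor_accuracy else None
            ),
        }


def evaluate_decoder(decoder, test_table: pd.DataFrame, feature_cols=None) -> EvaluationReport:
    """Score a fitted decoder on the test rows of a feature table."""
    if feature_cols is None:
        feature_cols = [c for c in test_table.columns if c.startswith("ch")]
    X = test_table[feature_cols].to_numpy(dtype=float)
    truth = test_table["compound_id"].to_numpy(dtype=int)
    chain_factors = None
    if isinstance(decoder, ChainDecoder):
        factors = decoder.predict_factors(X)
        from .dataset import compound_id as _compose

        pred = np.array(
            [
                _compose(g, w, s)
                for g, w, s in zip(factors["gesture"], factors["wrist"], factors["strength"])
            ]
        )
        t_triples = np.array([decompose_id(int(c)) for c in truth])
        chain_factors = {
            "gesture": 100.0 * float(np.mean(factors["gesture"] == t_triples[:, 0])),
            "wrist": 100.0 * float(np.mean(factors["wrist"] == t_triples[:, 1])),
            "strength": 100.0 * float(np.mean(factors["strength"] == t_triples[:, 2])),
        }
    else:
        pred = decoder.predict(X)
    return EvaluationReport(
        overall_accuracy=overall_accuracy(pred, truth),
        per_mode_accuracy=per_mode_accuracy(pred, truth),
        confusion=confusion_matrix(pred, truth),
        factor_accuracy={f: factor_accuracy(pred, truth, f) for f in ("strength", "gesture", "wrist")},
        joint_strength_gesture=factor_accuracy(pred, truth, ("strength", "gesture")),
        n_test=len(truth),
        chain_factor_accuracy=chain_factors,
    )


def split_feature_table(table: pd.DataFrame, train_fraction: float, shuffle_seed: int = 0):
    """Chronological per-(subject, class) split of an unsplit feature table.

    Same boundary rule as :func:`semgdeco.dataset.chronological_split`
    (round(fraction * n), ties toward train), applied to already-extracted
    feature rows so sweeps do not recompute features per fraction.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for _, grp in table.groupby(["subject_id", "compound_id"], sort=True):
        order = grp.sort_values("trial_position").index.to_numpy()
        n_train = int(round(train_fraction * len(order)))
        if n_train == 0 or n_train == len(order):
            raise ValueError(f"train_fraction {train_fraction} leaves an empty side")
        train_idx.append(order[:n_train])
        test_idx.append(order[n_train:])
    rng = np.random.default_rng(shuffle_seed)
    tr = np.concatenate(train_idx)
    te = np.concatenate(test_idx)
    train = table.loc[tr[rng.permutation(len(tr))]].assign(split="train")
    test = table.loc[te[rng.permutation(len(te))]].assign(split="test")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def training_proportion_sweep(
    table: pd.DataFrame,
    fractions=(0.9, 0.8, 0.7, 0.6, 0.5),
    spec: ModelSpec = ModelSpec(),
    shuffle_seed: int = 0,
) -> pd.DataFrame:
    """Test accuracy per training fraction and subject, plus the
    mean +/- popstd aggregate row values.

    Returns a tidy frame with columns (train_fraction, subject_id,
    accuracy); aggregate with :func:`aggregate_mean_popstd`.
    """
    rows = []
    for frac in fractions:
        train, test = split_feature_table(table, frac, shuffle_seed)
        for subj in sorted(table["subject_id"].unique()):
            tr = train[train["subject_id"] == subj]
            te = test[test["subject_id"] == subj]
            dec = train_integrated(tr, spec)
            rep = evaluate_decoder(dec, te)
            rows.append({"train_fraction": frac, "subject_id": subj, "accuracy": rep.overall_accuracy})
    return pd.DataFrame(rows)


def feature_count_sweep(
    windows_by_subject: dict[str, list],
    spec: ModelSpec = ModelSpec(),
    train_fraction: float = 0.9,
    shuffle_seed: int = 0,
    ssc_threshold_factor: float = 0.05,
) -> pd.DataFrame:
    """Accuracy as cumulative feature subsets grow in canonical order
    (MAV; MAV+RMS; ...; all seven), per subject.

    Features are extracted once with the full set and column-subset per
    step, which is equivalent to extracting each subset separately.
    """
    from .features import extract_windows, feature_columns

    full_spec = FeatureSpec(ssc_threshold_factor=ssc_threshold_factor)
    tables = {s: extract_windows(ws, full_spec) for s, ws in windows_by_subject.items()}
    rows = []
    for k in range(1, len(FEATURE_ORDER) + 1):
        sub = FeatureSpec(selected=FEATURE_ORDER[:k], ssc_threshold_factor=ssc_threshold_factor)
        cols = feature_columns(sub)
        for subj, table in tables.items():
            train, test = split_feature_table(table, train_fraction, shuffle_seed)
            dec = train_integrated(train, spec, feature_cols=cols)
            rep = evaluate_decoder(dec, test, feature_cols=cols)
            rows.append(
                {
                    "n_features": k,
                    "dim": sub.dim,
                    "subject_id": subj,
                    "accuracy": rep.overall_accuracy,
                }
            )
    return pd.DataFrame(rows)
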