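"""Decoder contracts: toy separability, chain composition, standardization."""

import numpy as np
import pandas as pd
import pytest

from semgdeco.dataset import compound_id, decompose_id
from semgdeco.decoding import (
    ChainDecoder,
    IntegratedDecoder,
    ModelSpec,
    Standardizer,
    available_variants,
    chain_theoretical_accuracy,
    make_estimator,
    predict_compound,
    train_chain,
    train_integrated,
)
from semgdeco.evaluation import factor_accuracy, overall_accuracy


def _toy_3class(n=30, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [sep, 0], [0, sep]])
    X = np.vstack([c + rng.standard_normal((n, 2)) for c in centers])
    y = np.repeat([1, 2, 3], n)
    return X, y


def test_linear_svm_separable_toy_training_accuracy_100():
    X, y = _toy_3class()
    dec = IntegratedDecoder(ModelSpec(variant="svm-linear")).fit(X, y)
    assert overall_accuracy(dec.predict(X), y) == 100.0


def test_quadratic_kernel_solves_xor_where_linear_cannot():
    rng = np.random.default_rng(1)
    centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
    labels = np.array([1, 1, 2, 2])
    X = np.vstack([c + 0.3 * rng.standard_normal((25, 2)) for c in centers])
    y = np.repeat(labels, 25)
    quad = IntegratedDecoder(ModelSpec(variant="svm-quadratic")).fit(X, y)
    lin = IntegratedDecoder(ModelSpec(variant="svm-linear")).fit(X, y)
    assert overall_accuracy(quad.predict(X), y) == 100.0
    assert overall_accuracy(lin.predict(X), y) < 100.0


def test_refit_same_data_gives_identical_predictions():
    X, y = _toy_3class(seed=2)
    spec = ModelSpec(variant="svm-quadratic", seed=5)
    p1 = IntegratedDecoder(spec).fit(X, y).predict(X)
    p2 = IntegratedDecoder(spec).fit(X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_one_nn_memorizes_training_labels():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((50, 4))
    y = rng.integers(1, 61, size=50)
    dec = IntegratedDecoder(ModelSpec(variant="knn-fine")).fit(X, y)
    np.testing.assert_array_equal(dec.predict(X), y)


def test_svm_decision_invariant_to_row_order():
    X, y = _toy_3class(seed=4)
    perm = np.random.default_rng(9).permutation(len(y))
    spec = ModelSpec(variant="svm-linear")
    p1 = IntegratedDecoder(spec).fit(X, y).predict(X)
    p2 = IntegratedDecoder(spec).fit(X[perm], y[perm]).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_missing_compound_class_reported():
    X, y = _toy_3class()
    with pytest.raises(ValueError, match=r"missing compound ids.*4"):
        IntegratedDecoder(ModelSpec(variant="svm-linear")).fit(
            X, y, expected_classes=range(1, 5)
        )


def test_unsupported_variants_rejected_clearly():
    with pytest.raises(ValueError, match="no scikit-learn backend"):
        make_estimator(ModelSpec(variant="nb-kernel"))
    with pytest.raises(ValueError, match="unknown variant"):
        make_estimator(ModelSpec(variant="bogus"))
    # the minimum native set is all constructible
    for v in available_variants():
        make_estimator(ModelSpec(variant=v))


def _feature_table(n_per_class=6, seed=0, classes=range(1, 61)):
    """Synthetic 12-dim feature table: one indicator block per factor."""
    rng = np.random.default_rng(seed)
    rows = []
    values = []
    for cid in classes:
        g, w, s = decompose_id(cid)
        center = 5.0 * np.concatenate([np.eye(4)[g], np.eye(5)[w], np.eye(3)[s]])
        for i in range(n_per_class):
            rows.append({"compound_id": cid, "trial_position": i * 150, "subject_id": "S1"})
            values.append(center + 0.1 * rng.standard_normal(12))
    meta = pd.DataFrame(rows)
    feats = pd.DataFrame(values, columns=[f"ch{i+1}_MAV" for i in range(12)])
    return pd.concat([meta, feats], axis=1)


def test_chain_factor_label_cardinalities_and_composition():
    table = _feature_table()
    spec = ModelSpec(variant="knn-fine")
    chain = train_chain(table, spec, spec, spec)
    assert len(chain.clfs["strength"].classes_) == 3
    assert len(chain.clfs["gesture"].classes_) == 4
    assert len(chain.clfs["wrist"].classes_) == 5
    X = table[[c for c in table.columns if c.startswith("ch")]].to_numpy()
    ids, factors = predict_compound(chain, X)
    recomposed = [
        compound_id(g, w, s)
        for g, w, s in zip(factors["gesture"], factors["wrist"], factors["strength"])
    ]
    np.testing.assert_array_equal(ids, recomposed)


def test_chain_missing_factor_level_reported():
    table = _feature_table(classes=range(1, 21))  # only strength level 0
    spec = ModelSpec(variant="knn-fine")
    with pytest.raises(ValueError, match="strength"):
        train_chain(table, spec, spec, spec)


def test_chain_and_integrated_share_prediction_interface():
    table = _feature_table()
    spec = ModelSpec(variant="knn-fine")
    X = table[[c for c in table.columns if c.startswith("ch")]].to_numpy()
    chain = train_chain(table, spec, spec, spec)
    integ = train_integrated(table, spec)
    assert chain.predict(X).shape == integ.predict(X).shape
    assert set(np.unique(chain.predict(X))) <= set(range(1, 61))


def test_chain_compound_accuracy_bounded_by_factor_accuracies():
    # noisy table: some factor errors must appear
    table = _feature_table(n_per_class=4, seed=1)
    noisy = table.copy()
    feat_cols = [c for c in table.columns if c.startswith("ch")]
    noisy[feat_cols] += 2.5 * np.random.default_rng(2).standard_normal(noisy[feat_cols].shape)
    spec = ModelSpec(variant="lda")
    chain = train_chain(table, spec, spec, spec)
    X = noisy[feat_cols].to_numpy()
    truth = noisy["compound_id"].to_numpy()
    ids, _ = predict_compound(chain, X)
    compound = overall_accuracy(ids, truth)
    factors = [factor_accuracy(ids, truth, f) for f in ("strength", "gesture", "wrist")]
    assert compound <= min(factors) + 1e-9


def test_dimension_mismatch_rejected():
    X, y = _toy_3class()
    dec = IntegratedDecoder(ModelSpec(variant="svm-linear")).fit(X, y)
    with pytest.raises(ValueError, match="dimension"):
        dec.predict(np.zeros((3, 5)))


def test_standardizer_uses_train_statistics_only():
    Xtr = np.array([[0.0, 10.0], [2.0, 30.0], [4.0, 50.0]])
    st = Standardizer().fit(Xtr)
    Z = st.transform(Xtr)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)
    Xte = np.array([[2.0, 30.0]])
    np.testing.assert_allclose(st.transform(Xte), 0.0, atol=1e-12)  # train mean, not its own
    assert not np.allclose(st.transform(Z), Z)  # double application is not identity


def test_standardizer_zero_variance_passthrough_warns():
    X = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        st = Standardizer().fit(X)
    Z = st.transform(X)
    np.testing.assert_allclose(Z[:, 1], 0.0)  # centred but unscaled


@pytest.mark.parametrize(
    "accs,expected",
    [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.5, 0.5), 0.0),
        ((0.9898, 0.9857, 0.9765), 0.9527182),
    ],
)
def test_chain_theoretical_accuracy_fractions(accs, expected):
    assert chain_theoretical_accuracy(*accs) == pytest.approx(expected, abs=1e-6)


def test_chain_theoretical_accuracy_percent_scale():
    # same three factor accuracies on the percent scale
    assert chain_theoretical_accuracy(98.98, 98.57, 97.65) == pytest.approx(95.27182, abs=1e-3)


def test_chain_theoretical_accuracy_rejects_mixed_scales():
    with pytest.raises(ValueError, match="mixed"):
        chain_theoretical_accuracy(0.99, 98.0, 0.97)
    with pytest.raises(ValueError):
        chain_theoretical_accuracy(101.0, 98.0, 97.0)
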