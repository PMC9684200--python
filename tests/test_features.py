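"""Time-domain feature extractors: worked examples, brute-force oracles,
algebraic identities, and the batch/scalar dual route."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays
from statsmodels.regression.linear_model import yule_walker

from semgdeco.dataset import MotionLabel, Window
from semgdeco.features import (
    FEATURE_ORDER,
    FeatureSpec,
    ar4_coefficient,
    extract_window,
    extract_windows,
    mav,
    rms,
    slope_sign_change,
    variance,
    waveform_length,
    zero_crossings,
)

# ---------------------------------------------------------------------------
# worked examples


@pytest.mark.parametrize(
    "fn,x,expected",
    [
        (mav, np.zeros(10), 0.0),
        (mav, np.full(5, 2.5), 2.5),
        (mav, [1, -2, 3, -4], 2.5),
        (rms, np.zeros(10), 0.0),
        (rms, np.full(6, -3.0), 3.0),
        (rms, [3, 4], np.sqrt(12.5)),
        (variance, np.full(9, 4.2), 0.0),
        (variance, [1, 2, 3], 1.0),
        (variance, [0, 2], 2.0),
        (waveform_length, np.full(7, 1.3), 0.0),
        (waveform_length, [1, -2, 3, -4], 15.0),
        (zero_crossings, [1, 2, 3, 4], 0),
        (zero_crossings, [1, -1, 2, 3, -5], 3),
    ],
)
def test_feature_examples(fn, x, expected):
    assert fn(np.asarray(x, dtype=float)) == pytest.approx(expected)


def test_waveform_length_of_ramp():
    x = np.arange(20) * 0.7
    assert waveform_length(x) == pytest.approx(19 * 0.7)


def test_zero_crossings_of_alternating_signs():
    x = np.resize([1.0, -1.0], 31)
    assert zero_crossings(x) == 30


def test_ssc_monotone_ramp_has_no_turning_points():
    assert slope_sign_change(np.linspace(0, 1, 50)) == 0


def test_ssc_counts_turning_points_above_threshold():
    # products are 1, threshold 0.05 * std([0,1,0,1,0]) ~ 0.027
    assert slope_sign_change(np.array([0.0, 1.0, 0.0, 1.0, 0.0])) == 3


def test_ssc_threshold_suppresses_tiny_oscillation():
    # products 1e-6 fall below 0.05 * std ~ 2.7e-5: the threshold bites
    assert slope_sign_change(np.array([0.0, 0.001, 0.0, 0.001, 0.0])) == 0


def test_ssc_is_not_scale_invariant_by_construction():
    # the product scales with a^2 but the threshold only with a, so a
    # borderline pattern changes count under amplitude scaling
    x = np.array([0.0, 0.001, 0.0, 0.001, 0.0])
    assert slope_sign_change(x) == 0
    assert slope_sign_change(1000.0 * x) == 3


# ---------------------------------------------------------------------------
# AR(4) coefficient


def test_ar4_white_noise_is_near_zero():
    x = np.random.default_rng(11).standard_normal(10_000)
    assert abs(ar4_coefficient(x)) < 0.05


def test_ar4_recovers_known_process():
    """Simulate x_i = sum(phi_k x_{i-k}) + e and check a4 = -phi4."""
    phi = np.array([0.5, -0.3, 0.2, -0.25])  # stable AR(4)
    rng = np.random.default_rng(17)
    n = 10_000
    x = np.zeros(n + 200)
    e = rng.standard_normal(n + 200)
    for i in range(4, n + 200):
        x[i] = phi @ x[i - 4 : i][::-1] + e[i]
    a4 = ar4_coefficient(x[200:])
    assert abs(a4 - (-phi[3])) < 0.05


def test_ar4_matches_statsmodels_yule_walker():
    x = np.random.default_rng(23).standard_normal(150)
    rho, _ = yule_walker(x, order=4, method="mle")
    assert ar4_coefficient(x) == pytest.approx(-rho[3], rel=1e-8)


def test_ar4_constant_series_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="constant"):
        assert ar4_coefficient(np.full(200, 3.3)) == 0.0


# ---------------------------------------------------------------------------
# invariants (property-based)

window_series = arrays(
    np.float64,
    150,
    elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
).filter(lambda x: np.std(x) > 1e-12)


@given(window_series)
def test_rms_var_mean_identity(x):
    """RMS^2 = ((N-1)/N) VAR + mean^2, exactly (to float tolerance)."""
    n = len(x)
    lhs = rms(x) ** 2
    rhs = (n - 1) / n * variance(x) + np.mean(x) ** 2
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


@given(window_series)
def test_mav_never_exceeds_rms(x):
    assert mav(x) <= rms(x) + 1e-12


@given(window_series, st.floats(0.1, 10.0))
def test_scaling_laws(x, a):
    assert mav(a * x) == pytest.approx(a * mav(x), rel=1e-9)
    assert rms(a * x) == pytest.approx(a * rms(x), rel=1e-9)
    assert waveform_length(a * x) == pytest.approx(a * waveform_length(x), rel=1e-9)
    assert variance(a * x) == pytest.approx(a**2 * variance(x), rel=1e-9)
    assert zero_crossings(a * x) == zero_crossings(x)
    assert ar4_coefficient(a * x) == pytest.approx(ar4_coefficient(x), abs=1e-8)


@given(window_series)
def test_count_feature_bounds(x):
    n = len(x)
    assert 0 <= zero_crossings(x) <= n - 1
    assert 0 <= slope_sign_change(x) <= n - 2
    assert waveform_length(x) >= 0 and variance(x) >= 0 and rms(x) >= 0


# ---------------------------------------------------------------------------
# brute-force loop oracle on random windows


def _loop_features(x, tf=0.05):
    n = len(x)
    mean = sum(x) / n
    mav_v = sum(abs(v) for v in x) / n
    rms_v = (sum(v * v for v in x) / n) ** 0.5
    var_v = sum((v - mean) ** 2 for v in x) / (n - 1)
    wl_v = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    zc_v = sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0)
    w = tf * var_v**0.5
    ssc_v = sum(1 for i in range(1, n - 1) if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= w)
    return mav_v, rms_v, var_v, wl_v, zc_v, ssc_v


def test_features_match_brute_force_loop_on_1000_random_windows():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((1000, 150)) * rng.uniform(0.1, 5.0, size=(1000, 1))
    for x in X:
        m, r, v, wl, zc, ssc = _loop_features(x)
        assert mav(x) == pytest.approx(m, rel=1e-12)
        assert rms(x) == pytest.approx(r, rel=1e-12)
        assert variance(x) == pytest.approx(v, rel=1e-12)
        assert waveform_length(x) == pytest.approx(wl, rel=1e-12)
        assert zero_crossings(x) == zc
        assert slope_sign_change(x) == ssc


# ---------------------------------------------------------------------------
# window/vector assembly


def _window(samples):
    return Window(samples=samples, label=MotionLabel(1, 2, 0), trial_position=0, subject_id="S1")


def test_full_feature_vector_is_56_dimensional():
    rng = np.random.default_rng(6)
    fv = extract_window(_window(rng.standard_normal((150, 8))))
    assert fv.values.shape == (56,)


def test_single_feature_vector_is_8_dimensional():
    rng = np.random.default_rng(6)
    fv = extract_window(_window(rng.standard_normal((150, 8))), FeatureSpec(selected=("MAV",)))
    assert fv.values.shape == (8,)


def test_zero_window_features():
    with pytest.warns(UserWarning):
        fv = extract_window(_window(np.zeros((150, 8))))
    np.testing.assert_array_equal(fv.values, np.zeros(56))


def test_channel_major_layout():
    rng = np.random.default_rng(8)
    w = _window(rng.standard_normal((150, 8)))
    fv = extract_window(w)
    for c in range(8):
        assert fv.values[c * 7 + 0] == pytest.approx(mav(w.samples[:, c]))
        assert fv.values[c * 7 + 6] == slope_sign_change(w.samples[:, c])


def test_batch_table_matches_per_window_scalar_path():
    rng = np.random.default_rng(9)
    windows = [_window(rng.standard_normal((150, 8))) for _ in range(20)]
    table = extract_windows(windows, FeatureSpec())
    feat_cols = [c for c in table.columns if c.startswith("ch")]
    assert len(table) == 20 and len(feat_cols) == 56
    for i, w in enumerate(windows):
        np.testing.assert_allclose(
            table.loc[i, feat_cols].to_numpy(dtype=float),
            extract_window(w).values,
            rtol=1e-10,
            atol=1e-12,
        )


def test_spec_rejects_bad_selections():
    with pytest.raises(ValueError):
        FeatureSpec(selected=())
    with pytest.raises(ValueError):
        FeatureSpec(selected=("MAV", "MAV"))
    with pytest.raises(ValueError):
        FeatureSpec(selected=("RMS", "MAV"))  # non-canonical order
    with pytest.raises(ValueError):
        FeatureSpec(selected=("MAV", "XXX"))
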