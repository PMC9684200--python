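"""Time-domain feature extraction for short sEMG windows.

Seven classic features per channel — mean absolute value (MAV), root mean
square (RMS), sample variance (VAR), the 4th coefficient of an order-4
autoregressive fit (ARC), waveform length (WL), zero crossings (ZC) and
slope sign changes (SSC).  With 8 channels and all seven features a window
maps to a 56-dimensional vector, laid out channel-major (all selected
features for channel 1, then channel 2, ...).

Definitions, for a window x_1..x_N (N = 150 at 1000 Hz / 150 ms):

    MAV = (1/N) sum |x_i|
    RMS = sqrt((1/N) sum x_i^2)
    VAR = (1/(N-1)) sum (x_i - mean)^2
    WL  = sum_{i<N} |x_{i+1} - x_i|
    ZC  = #{i : x_i * x_{i+1} < 0}
    SSC = #{i : (x_i - x_{i-1})(x_i - x_{i+1}) >= w},  w = 0.05 * std(x)
    ARC = a_4 of the AR(4) model x_i = -sum_k a_k x_{i-k} + e_i
          (Yule-Walker on the mean-removed window, biased autocovariances)

The SSC threshold uses the per-window sample standard deviation; note the
threshold is linear in amplitude while the product is quadratic, so SSC is
deliberately not scale-invariant — the definition is applied as stated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, MotionLabel, Window, N_CHANNELS

FEATURE_ORDER: tuple[str, ...] = ("MAV", "RMS", "VAR", "ARC", "WL", "ZC", "SSC")

__all__ = [
    "FEATURE_ORDER",
    "FeatureSpec",
    "FeatureVector",
    "mav",
    "rms",
    "variance",
    "waveform_length",
    "zero_crossings",
    "slope_sign_change",
    "ar4_coefficient",
    "extract_window",
    "extract_windows",
    "extract_dataset",
    "feature_columns",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("subject_id", "compound_id", "gesture", "wrist", "strength_g", "trial_position", "split")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to extract, in canonical order."""

    selected: tuple[str, ...] = FEATURE_ORDER
    ssc_threshold_factor: float = 0.05
    ar_order: int = 4

    def __post_init__(self) -> None:
        sel = tuple(self.selected)
        if not sel:
            raise ValueError("at least one feature must be selected")
        if len(set(sel)) != len(sel):
            raise ValueError(f"duplicate features in {sel}")
        unknown = set(sel) - set(FEATURE_ORDER)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; valid: {FEATURE_ORDER}")
        canonical = tuple(f for f in FEATURE_ORDER if f in sel)
        if sel != canonical:
            raise ValueError(f"features must be in canonical order {canonical}, got {sel}")
        object.__setattr__(self, "selected", sel)

    @property
    def dim(self) -> int:
        return N_CHANNELS * len(self.selected)


@dataclass
class FeatureVector:
    """Per-window feature values, channel-major, with the window's label."""

    values: np.ndarray
    label: MotionLabel
    spec: FeatureSpec
    split: str = ""


def _series(x, min_len: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} expects a 1-D series, got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} samples, got {x.size}")
    return x


def mav(x) -> float:
    """Mean absolute value."""
    x = _series(x, 1, "mav")
    return float(np.mean(np.abs(x)))


def rms(x) -> float:
    """Root mean square."""
    x = _series(x, 1, "rms")
    return float(np.sqrt(np.mean(np.square(x))))


def variance(x) -> float:
    """Sample variance (denominator N - 1)."""
    x = _series(x, 2, "variance")
    return float(np.var(x, ddof=1))


def waveform_length(x) -> float:
    """Cumulative absolute first difference."""
    x = _series(x, 2, "waveform_length")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x) -> int:
    """Count of adjacent sample pairs that straddle zero (strict sign change)."""
    x = _series(x, 2, "zero_crossings")
    return int(np.count_nonzero(x[:-1] * x[1:] < 0))


def slope_sign_change(x, threshold_factor: float = 0.05) -> int:
    """Count of interior turning points exceeding the amplitude threshold
    w = threshold_factor * sample-std of the window."""
    x = _series(x, 3, "slope_sign_change")
    w = threshold_factor * np.std(x, ddof=1)
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    # prod > 0 guards the degenerate flat signal (w = 0, prod = 0): a
    # constant has no turning points even though 0 >= 0
    return int(np.count_nonzero((prod >= w) & (prod > 0)))


def _yule_walker_last(x: np.ndarray, order: int) -> float:
    """a_order under the sign convention x_i = -sum a_k x_{i-k} + e_i."""
    x = x - x.mean()
    n = x.size
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= 0:
        raise FloatingPointError("zero-variance series")
    R = r[np.abs(np.subtract.outer(np.arange(order), np.arange(order)))]
    try:
        phi = np.linalg.solve(R, r[1 : order + 1])
    except np.linalg.LinAlgError:
        phi, *_ = np.linalg.lstsq(R, r[1 : order + 1], rcond=None)
    return float(-phi[-1])


def ar4_coefficient(x, order: int = 4) -> float:
    """The last coefficient of an order-``order`` autoregressive fit.

    A constant (zero-variance) window carries no autoregressive
    information; it yields 0 with a warning rather than an error.
    """
    x = _series(x, order + 1, "ar4_coefficient")
    if np.ptp(x) == 0:
        warnings.warn("constant series: AR coefficient undefined, returning 0", stacklevel=2)
        return 0.0
    return _yule_walker_last(x, order)


# ---------------------------------------------------------------------------
# Batch path: all windows at once, one channel at a time.  Same math as the
# scalar functions above (tests assert agreement), vectorised for the
# ~10^5 channel-windows of a full dataset.


def _batch_ar_last(X: np.ndarray, order: int) -> np.ndarray:
    """Vectorised Yule-Walker a_order over rows of X (n_windows, n_samples)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    n = Xc.shape[1]
    r = np.stack(
        [np.einsum("ij,ij->i", Xc[:, : n - k], Xc[:, k:]) / n for k in range(order + 1)],
        axis=1,
    )  # (n_windows, order+1)
    out = np.zeros(X.shape[0])
    ok = (r[:, 0] > 0) & (np.ptp(X, axis=1) != 0)
    if not ok.all():
        warnings.warn("constant series: AR coefficient undefined, returning 0", stacklevel=2)
    if ok.any():
        idx = np.abs(np.subtract.outer(np.arange(order), np.arange(order)))
        R = r[ok][:, idx]  # (m, order, order)
        b = r[ok][:, 1 : order + 1]
        try:
            phi = np.linalg.solve(R, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            phi = np.stack([np.linalg.lstsq(Ri, bi, rcond=None)[0] for Ri, bi in zip(R, b)])
        out[ok] = -phi[:, -1]
    return out


def _batch_features(X: np.ndarray, spec: FeatureSpec) -> dict[str, np.ndarray]:
    """Feature name -> (n_windows,) values for one channel's window stack."""
    vals: dict[str, np.ndarray] = {}
    n = X.shape[1]
    for name in spec.selected:
        if name == "MAV":
            vals[name] = np.mean(np.abs(X), axis=1)
        elif name == "RMS":
            vals[name] = np.sqrt(np.mean(np.square(X), axis=1))
        elif name == "VAR":
            vals[name] = np.var(X, axis=1, ddof=1)
        elif name == "WL":
            vals[name] = np.sum(np.abs(np.diff(X, axis=1)), axis=1)
        elif name == "ZC":
            vals[name] = np.count_nonzero(X[:, :-1] * X[:, 1:] < 0, axis=1).astype(float)
        elif name == "SSC":
            w = spec.ssc_threshold_factor * np.std(X, axis=1, ddof=1)
            prod = (X[:, 1:-1] - X[:, :-2]) * (X[:, 1:-1] - X[:, 2:])
            vals[name] = np.count_nonzero((prod >= w[:, None]) & (prod > 0), axis=1).astype(float)
        elif name == "ARC":
            if n <= spec.ar_order:
                raise ValueError(f"ARC needs more than {spec.ar_order} samples per window")
            vals[name] = _batch_ar_last(X, spec.ar_order)
    return vals


def feature_columns(spec: FeatureSpec) -> list[str]:
    """Channel-major column names, e.g. ch1_MAV, ch1_RMS, ..., ch8_SSC."""
    return [f"ch{c + 1}_{f}" for c in range(N_CHANNELS) for f in spec.selected]


def extract_window(window: Window, spec: FeatureSpec = FeatureSpec()) -> FeatureVector:
    """Feature vector of one window (reference per-channel scalar path)."""
    scalar = {
        "MAV": mav,
        "RMS": rms,
        "VAR": variance,
        "WL": waveform_length,
        "ZC": zero_crossings,
    }
    values = np.empty(spec.dim)
    k = len(spec.selected)
    for c in range(N_CHANNELS):
        x = window.samples[:, c]
        for j, name in enumerate(spec.selected):
            try:
                if name == "ARC":
                    v = ar4_coefficient(x, spec.ar_order)
                elif name == "SSC":
                    v = slope_sign_change(x, spec.ssc_threshold_factor)
                else:
                    v = scalar[name](x)
            except ValueError as exc:
                raise ValueError(f"feature {name} failed on channel {c + 1}: {exc}") from exc
            values[c * k + j] = float(v)
    return FeatureVector(values=values, label=window.label, spec=spec)


def extract_windows(windows: list[Window], spec: FeatureSpec = FeatureSpec(), split: str = "") -> pd.DataFrame:
    """Feature table for a window list: metadata columns + channel-major features."""
    if not windows:
        cols = list(METADATA_COLUMNS) + feature_columns(spec)
        return pd.DataFrame(columns=cols)
    stack = np.stack([w.samples for w in windows])  # (n, win, 8)
    k = len(spec.selected)
    values = np.empty((len(windows), spec.dim))
    for c in range(N_CHANNELS):
        ch_vals = _batch_features(stack[:, :, c], spec)
        for j, name in enumerate(spec.selected):
            values[:, c * k + j] = ch_vals[name]
    meta = pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "compound_id": [w.label.compound_id for w in windows],
            "gesture": [w.label.gesture_name for w in windows],
            "wrist": [w.label.wrist_name for w in windows],
            "strength_g": [w.label.strength_g for w in windows],
            "trial_position": [w.trial_position for w in windows],
            "split": split,
        }
    )
    feats = pd.DataFrame(values, columns=feature_columns(spec))
    return pd.concat([meta, feats], axis=1)


def extract_dataset(split: DatasetSplit, spec: FeatureSpec = FeatureSpec()) -> pd.DataFrame:
    """Feature table over a chronological split, tagged train/test."""
    train = extract_windows(split.train, spec, split="train")
    test = extract_windows(split.test, spec, split="test")
    return pd.concat([train, test], ignore_index=True)
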