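"""Synthetic surface-EMG generator with class-conditional amplitude structure.

Real surface EMG during an isometric hold is well approximated, at the
timescales a pattern-recognition pipeline cares about, by band-limited
stochastic noise whose envelope scales with muscle activation.  Each of
the 60 compound classes (gesture x wrist angle x strength level) is given
an 8-channel expected-amplitude profile::

    amplitude[c] = subject_gain[c] * strength_gain[s] * (baseline[c]
                   + gesture_matrix[g, c] + wrist_matrix[w, c])

and the channel signal is that amplitude times a unit-variance carrier
band-limited to roughly the EMG band, plus 50 Hz mains interference,
slow baseline drift and a white noise floor — the nuisance components the
preprocessing chain is there to remove.

Everything is a pure function of (config, model, label, subject_id, seed):
trial noise streams are split from the master seed by compound ID, while a
subject's per-channel gains derive from the subject_id string alone, so
the same "subject" keeps the same electrode/physiology signature across
datasets.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .dataset import (
    MotionLabel,
    Recording,
    all_labels,
    N_CHANNELS,
    N_GESTURES,
    N_WRISTS,
    N_STRENGTHS,
    N_CLASSES,
)

__all__ = [
    "ActivationModel",
    "SyntheticConfig",
    "default_activation_model",
    "subject_gains",
    "activation_profile",
    "simulate_trial",
    "simulate_subject_dataset",
    "save_dataset",
    "load_dataset",
]

# Each gesture and each wrist angle dominates a distinct channel subset,
# mimicking electrodes targeted at eight forearm muscles: no two of the 60
# classes share an expected-amplitude profile.
_DEFAULT_GESTURE = np.array(
    [
        # ch1   ch2   ch3   ch4   ch5   ch6   ch7   ch8
        [1.00, 0.80, 0.00, 0.00, 0.00, 0.00, 0.30, 0.00],  # fist
        [0.00, 0.20, 1.00, 0.70, 0.00, 0.00, 0.00, 0.30],  # pinch
        [0.30, 0.00, 0.00, 0.20, 1.00, 0.60, 0.00, 0.00],  # poke
        [0.00, 0.30, 0.00, 0.00, 0.20, 0.00, 1.00, 0.90],  # palm
    ]
)

_DEFAULT_WRIST = np.array(
    [
        [0.90, 0.00, 0.20, 0.00, 0.00, 0.30, 0.00, 0.00],  # flexion
        [0.00, 0.90, 0.00, 0.30, 0.00, 0.00, 0.20, 0.00],  # extension
        [0.20, 0.00, 0.80, 0.00, 0.30, 0.00, 0.00, 0.20],  # ulnar
        [0.00, 0.20, 0.00, 0.80, 0.00, 0.20, 0.40, 0.00],  # radial
        [0.10, 0.10, 0.10, 0.10, 0.20, 0.10, 0.10, 0.40],  # neutrality
    ]
)


@dataclass
class ActivationModel:
    """Class-conditional expected-amplitude model over the 8 channels."""

    gesture_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_GESTURE.copy())
    wrist_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_WRIST.copy())
    strength_gains: tuple[float, float, float] = (1.0, 1.4, 1.8)
    baseline: np.ndarray = field(default_factory=lambda: np.full(N_CHANNELS, 0.1))
    subject_gain_sigma: float = 0.15

    def __post_init__(self) -> None:
        self.gesture_matrix = np.asarray(self.gesture_matrix, dtype=float)
        self.wrist_matrix = np.asarray(self.wrist_matrix, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.gesture_matrix.shape != (N_GESTURES, N_CHANNELS):
            raise ValueError(f"gesture_matrix must be {(N_GESTURES, N_CHANNELS)}")
        if self.wrist_matrix.shape != (N_WRISTS, N_CHANNELS):
            raise ValueError(f"wrist_matrix must be {(N_WRISTS, N_CHANNELS)}")
        if self.baseline.shape != (N_CHANNELS,):
            raise ValueError(f"baseline must have {N_CHANNELS} entries")
        if (self.gesture_matrix < 0).any() or (self.wrist_matrix < 0).any() or (
            self.baseline < 0
        ).any():
            raise ValueError("activation entries must be non-negative")
        g0, g1, g2 = self.strength_gains
        if not g0 < g1 < g2:
            raise ValueError("strength_gains must be strictly increasing with load")

    def class_profiles(self) -> np.ndarray:
        """Expected-amplitude profiles for all 60 classes (unit subject gains),
        ordered by compound ID; shape (60, 8)."""
        profiles = np.empty((N_CLASSES, N_CHANNELS))
        ones = np.ones(N_CHANNELS)
        for i, label in enumerate(all_labels()):
            profiles[i] = activation_profile(self, label, ones)
        return profiles

    def check_separability(self, rtol: float = 1e-6) -> None:
        """Raise if any two compound classes share an expected profile."""
        profiles = self.class_profiles()
        diff = profiles[:, None, :] - profiles[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        scale = np.linalg.norm(profiles, axis=-1)
        pair_scale = np.maximum(scale[:, None], scale[None, :])
        rel = dist / np.maximum(pair_scale, 1e-30)
        np.fill_diagonal(rel, np.inf)
        i, j = np.unravel_index(np.argmin(rel), rel.shape)
        if rel[i, j] < rtol:
            raise ValueError(
                f"activation model is degenerate: compound ids {i + 1} and {j + 1} "
                f"have indistinguishable amplitude profiles (relative distance {rel[i, j]:.2e})"
            )


@dataclass
class SyntheticConfig:
    """Acquisition-protocol parameters for the generator."""

    sampling_rate: float = 1000.0
    trial_duration: float = 60.0
    n_channels: int = N_CHANNELS
    carrier_band: tuple[float, float] = (20.0, 450.0)
    # low band edge offset (Hz) per strength level: contraction force
    # raises the EMG median frequency (motor-unit recruitment), so shape
    # features (ZC, SSC, AR) carry strength information as they do in real
    # recordings; the shift sits inside the 20-250 Hz analysis band so it
    # survives preprocessing
    strength_band_shift_hz: tuple[float, float, float] = (0.0, 20.0, 40.0)
    mains_amplitude: float = 0.5
    mains_freq: float = 50.0
    drift_amplitude: float = 0.5
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        lo, hi = self.carrier_band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ValueError(
                f"carrier_band {self.carrier_band} must lie inside (0, Nyquist)"
            )
        f = self.strength_band_shift_hz
        if len(f) != 3 or any(v < 0 for v in f) or not f[0] <= f[1] <= f[2]:
            raise ValueError(
                "strength_band_shift_hz must be three non-decreasing non-negative offsets"
            )
        if lo + f[2] >= hi:
            raise ValueError("strongest-level band collapses: lo + shift >= hi")
        if self.n_channels != N_CHANNELS:
            raise ValueError(f"generator is fixed at {N_CHANNELS} channels")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["carrier_band"] = list(self.carrier_band)
        return d


def default_activation_model() -> ActivationModel:
    """The shipped model, separability-checked at construction."""
    model = ActivationModel()
    model.check_separability()
    return model


def _subject_entropy(subject_id: str) -> int:
    return zlib.crc32(str(subject_id).encode("utf-8"))


def subject_gains(model: ActivationModel, subject_id: str) -> np.ndarray:
    """Per-channel multiplicative gains for one subject.

    Log-normal with log-scale std ``subject_gain_sigma``, derived from the
    subject_id string alone so a subject's signature is stable across
    datasets and seeds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_subject_entropy(subject_id), 0x5EBA]))
    return np.exp(model.subject_gain_sigma * rng.standard_normal(N_CHANNELS))


def activation_profile(
    model: ActivationModel, label: MotionLabel, subject_gains: np.ndarray
) -> np.ndarray:
    """Expected channel amplitudes for one labelled motion and subject."""
    if not isinstance(label, MotionLabel):
        raise TypeError("label must be a MotionLabel")
    gains = np.asarray(subject_gains, dtype=float)
    if gains.shape != (N_CHANNELS,):
        raise ValueError(f"subject_gains must have {N_CHANNELS} entries")
    if (gains <= 0).any():
        raise ValueError("subject_gains must be strictly positive")
    return (
        gains
        * model.strength_gains[label.strength]
        * (model.baseline + model.gesture_matrix[label.gesture] + model.wrist_matrix[label.wrist])
    )


def _carrier(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (zero-phase 4th-order
    Butterworth on white noise, then renormalised)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_trial(
    config: SyntheticConfig,
    model: ActivationModel,
    label: MotionLabel,
    subject_id: str,
    seed: int | None = None,
    gains: np.ndarray | None = None,
) -> Recording:
    """Generate one labelled trial.

    Per channel c: ``amplitude_c * carrier_c(t)`` plus a 50 Hz mains tone
    with random phase, a sub-1 Hz drift (slow sinusoid + linear ramp) and a
    white noise floor.  Identical arguments give bitwise-identical output.
    """
    if seed is None:
        seed = config.seed
    if gains is None:
        gains = subject_gains(model, subject_id)
    amplitude = activation_profile(model, label, gains)

    n = int(round(config.trial_duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), _subject_entropy(subject_id), label.compound_id])
    )

    # stronger contractions recruit faster motor units: raise the lower
    # band edge (hence the median frequency) with the strength level
    lo, hi = config.carrier_band
    band = (lo + config.strength_band_shift_hz[label.strength], hi)

    samples = np.empty((n, N_CHANNELS))
    for c in range(N_CHANNELS):
        carrier = _carrier(rng, n, config.sampling_rate, band)
        phase = rng.uniform(0, 2 * np.pi)
        mains = config.mains_amplitude * np.sin(2 * np.pi * config.mains_freq * t + phase)
        drift_freq = rng.uniform(0.1, 0.8)
        drift_phase = rng.uniform(0, 2 * np.pi)
        slope = rng.uniform(-1.0, 1.0)
        drift = config.drift_amplitude * (
            np.sin(2 * np.pi * drift_freq * t + drift_phase) + slope * (2 * t / t[-1] - 1.0)
        ) if n > 1 else np.zeros(n)
        noise = config.noise_floor * rng.standard_normal(n)
        samples[:, c] = amplitude[c] * carrier + mains + drift + noise

    meta = {
        "seed": int(seed),
        "config": config.as_dict(),
        "config_crc": zlib.crc32(json.dumps(config.as_dict(), sort_keys=True).encode()),
    }
    return Recording(
        samples=samples,
        sampling_rate=config.sampling_rate,
        label=label,
        subject_id=str(subject_id),
        meta=meta,
    )


def simulate_subject_dataset(
    config: SyntheticConfig,
    model: ActivationModel,
    subject_id: str,
    seed: int | None = None,
) -> list[Recording]:
    """All 60 trials of one subject, in compound-ID order.

    Per-trial noise streams are split deterministically by (seed,
    subject_id, compound ID); the subject's channel gains are shared by all
    60 trials.
    """
    if seed is None:
        seed = config.seed
    gains = subject_gains(model, subject_id)
    return [
        simulate_trial(config, model, label, subject_id, seed=seed, gains=gains)
        for label in all_labels()
    ]


# ---------------------------------------------------------------------------
# On-disk form: per-trial CSV (columns ch1..ch8) + JSON sidecar + manifest CSV


def _trial_stem(rec: Recording) -> str:
    return f"{rec.subject_id}_mode{rec.label.compound_id:02d}"


def save_dataset(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write trials as CSV + JSON sidecars and return the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        stem = _trial_stem(rec)
        trial_path = out / f"{stem}.csv"
        sidecar_path = out / f"{stem}.json"
        header = ",".join(f"ch{i + 1}" for i in range(N_CHANNELS))
        np.savetxt(trial_path, rec.samples, delimiter=",", header=header, comments="", fmt="%.6g")
        sidecar = {
            "sampling_rate_hz": rec.sampling_rate,
            "subject_id": rec.subject_id,
            **rec.label.as_dict(),
            **{k: v for k, v in rec.meta.items()},
        }
        sidecar_path.write_text(json.dumps(sidecar, indent=1))
        rows.append((trial_path.name, sidecar_path.name, rec.label.compound_id))
    manifest = out / "manifest.csv"
    with manifest.open("w") as fh:
        fh.write("trial_file,sidecar_file,compound_id\n")
        for r in rows:
            fh.write(f"{r[0]},{r[1]},{r[2]}\n")
    return manifest


def load_dataset(manifest_path: str | Path) -> list[Recording]:
    """Read back a dataset written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    recs: list[Recording] = []
    with manifest_path.open() as fh:
        next(fh)  # header
        for line in fh:
            trial_file, sidecar_file, _ = line.strip().split(",")
            sidecar = json.loads((base / sidecar_file).read_text())
            samples = np.loadtxt(base / trial_file, delimiter=",", skiprows=1)
            label = MotionLabel.from_compound_id(int(sidecar["compound_id"]))
            meta = {
                k: v
                for k, v in sidecar.items()
                if k not in {"sampling_rate_hz", "subject_id", "compound_id", "gesture", "wrist", "strength_g"}
            }
            recs.append(
                Recording(
                    samples=samples,
                    sampling_rate=float(sidecar["sampling_rate_hz"]),
                    label=label,
                    subject_id=str(sidecar["subject_id"]),
                    meta=meta,
                )
            )
    return recs
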