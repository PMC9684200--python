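"""Compound-motion label algebra, trial containers, windowing and splitting.

A *compound motion* is the simultaneous combination of one hand gesture,
one wrist angle and one strength level.  With 4 gestures, 5 wrist angles
and 3 strength levels the label set is the full 4 x 5 x 3 = 60 product,
each cell carrying an integer compound ID in 1..60::

    compound_id = 20 * strength + 5 * gesture + wrist + 1

with factor indices in the canonical orders below.  The same triple can be
encoded either as a single 60-way indicator (one-hot) or as three
concatenated factor indicators of lengths 4 + 5 + 3 = 12 (multilabel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GESTURES: tuple[str, ...] = ("fist", "pinch", "poke", "palm")
WRISTS: tuple[str, ...] = ("flexion", "extension", "ulnar", "radial", "neutrality")
STRENGTHS_G: tuple[int, ...] = (0, 480, 960)

N_GESTURES = len(GESTURES)
N_WRISTS = len(WRISTS)
N_STRENGTHS = len(STRENGTHS_G)
N_CLASSES = N_GESTURES * N_WRISTS * N_STRENGTHS
N_CHANNELS = 8

__all__ = [
    "GESTURES",
    "WRISTS",
    "STRENGTHS_G",
    "N_GESTURES",
    "N_WRISTS",
    "N_STRENGTHS",
    "N_CLASSES",
    "N_CHANNELS",
    "MotionLabel",
    "Recording",
    "Window",
    "DatasetSplit",
    "compound_id",
    "decompose_id",
    "all_labels",
    "encode_onehot",
    "encode_multilabel",
    "decode_multilabel",
    "slice_windows",
    "chronological_split",
]


def _check_factor(name: str, index: int, n: int) -> None:
    if not isinstance(index, (int, np.integer)) or not 0 <= index < n:
        raise ValueError(f"invalid {name} index {index!r}: must be an integer in 0..{n - 1}")


def compound_id(gesture: int, wrist: int, strength: int) -> int:
    """Map factor indices to the compound ID in 1..60.

    ``gesture`` indexes :data:`GESTURES`, ``wrist`` indexes :data:`WRISTS`
    and ``strength`` indexes :data:`STRENGTHS_G`.  The map is the bijection
    ``20*strength + 5*gesture + wrist + 1``.
    """
    _check_factor("gesture", gesture, N_GESTURES)
    _check_factor("wrist", wrist, N_WRISTS)
    _check_factor("strength", strength, N_STRENGTHS)
    return 20 * strength + 5 * gesture + wrist + 1


def decompose_id(cid: int) -> tuple[int, int, int]:
    """Invert :func:`compound_id`; returns (gesture, wrist, strength) indices."""
    if not isinstance(cid, (int, np.integer)) or not 1 <= cid <= N_CLASSES:
        raise ValueError(f"compound id {cid!r} outside 1..{N_CLASSES}")
    z = int(cid) - 1
    strength, rem = divmod(z, 20)
    gesture, wrist = divmod(rem, 5)
    return gesture, wrist, strength


@dataclass(frozen=True)
class MotionLabel:
    """One compound-motion class: a (gesture, wrist angle, strength) triple."""

    gesture: int
    wrist: int
    strength: int

    def __post_init__(self) -> None:
        # compound_id validates all three indices
        compound_id(self.gesture, self.wrist, self.strength)

    @property
    def compound_id(self) -> int:
        return compound_id(self.gesture, self.wrist, self.strength)

    @classmethod
    def from_compound_id(cls, cid: int) -> "MotionLabel":
        g, w, s = decompose_id(cid)
        return cls(g, w, s)

    @property
    def gesture_name(self) -> str:
        return GESTURES[self.gesture]

    @property
    def wrist_name(self) -> str:
        return WRISTS[self.wrist]

    @property
    def strength_g(self) -> int:
        return STRENGTHS_G[self.strength]

    def as_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "gesture": self.gesture_name,
            "wrist": self.wrist_name,
            "strength_g": self.strength_g,
        }


def all_labels() -> list[MotionLabel]:
    """The 60 compound labels in compound-ID order."""
    return [MotionLabel.from_compound_id(cid) for cid in range(1, N_CLASSES + 1)]


def encode_onehot(label: MotionLabel) -> np.ndarray:
    """60-dimensional indicator with a single 1 at position compound_id - 1."""
    vec = np.zeros(N_CLASSES, dtype=float)
    vec[label.compound_id - 1] = 1.0
    return vec


def encode_multilabel(label: MotionLabel) -> np.ndarray:
    """12-dimensional factor encoding: one-hot(4) + one-hot(5) + one-hot(3)."""
    vec = np.zeros(N_GESTURES + N_WRISTS + N_STRENGTHS, dtype=float)
    vec[label.gesture] = 1.0
    vec[N_GESTURES + label.wrist] = 1.0
    vec[N_GESTURES + N_WRISTS + label.strength] = 1.0
    return vec


def decode_multilabel(vec: np.ndarray) -> MotionLabel:
    """Invert :func:`encode_multilabel` by per-block argmax."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_GESTURES + N_WRISTS + N_STRENGTHS,):
        raise ValueError(f"expected a 12-vector, got shape {vec.shape}")
    g = int(np.argmax(vec[:N_GESTURES]))
    w = int(np.argmax(vec[N_GESTURES : N_GESTURES + N_WRISTS]))
    s = int(np.argmax(vec[N_GESTURES + N_WRISTS :]))
    return MotionLabel(g, w, s)


@dataclass
class Recording:
    """One labelled multichannel trial.

    ``samples`` is (n_samples, 8) in arbitrary amplitude units at
    ``sampling_rate`` Hz.  ``meta`` carries provenance (generator seed and
    config hash) and, after conditioning, a ``preprocessing`` block.
    """

    samples: np.ndarray
    sampling_rate: float
    label: MotionLabel
    subject_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be (n_samples, {N_CHANNELS}), got {self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Window:
    """A fixed-length slice of one trial — the unit of classification."""

    samples: np.ndarray  # (window_samples, 8)
    label: MotionLabel
    trial_position: int  # start index within the trial, in samples
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(f"window must be (n, {N_CHANNELS}), got {self.samples.shape}")


def slice_windows(
    recording: Recording, window_ms: float = 150.0, overlap: float = 0.0
) -> list[Window]:
    """Cut a trial into consecutive disjoint windows, dropping the remainder.

    With the study settings (60 s at 1000 Hz, 150 ms windows, 0 overlap)
    this yields 400 windows per trial.  Only 0 overlap is supported; the
    parameter exists to make the contract explicit.
    """
    if overlap != 0.0:
        raise NotImplementedError("only 0-overlap windowing is supported")
    wlen = int(round(window_ms * recording.sampling_rate / 1000.0))
    if wlen < 1:
        raise ValueError(f"window of {window_ms} ms is below one sample")
    n = recording.n_samples // wlen
    return [
        Window(
            samples=recording.samples[i * wlen : (i + 1) * wlen],
            label=recording.label,
            trial_position=i * wlen,
            subject_id=recording.subject_id,
        )
        for i in range(n)
    ]


@dataclass
class DatasetSplit:
    """Chronological train/test partition of windows, per compound class."""

    train: list[Window]
    test: list[Window]
    train_fraction: float
    shuffle_seed: int


def chronological_split(
    windows: Iterable[Window], train_fraction: float = 0.9, shuffle_seed: int = 0
) -> DatasetSplit:
    """Per class, the chronologically first ``train_fraction`` of windows
    becomes the training set and the remainder the test set; each side is
    then shuffled (reproducibly from ``shuffle_seed``).

    The boundary uses ``round(fraction * n)``; at 400 windows and 0.9 this
    is the 360/40 split of the study protocol.  Early windows never appear
    in the test set, so there is no temporal leakage.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    # group per (subject, class): the protocol's "first 90% of each mode"
    # applies within each subject's trial
    by_class: dict[tuple[str, int], list[Window]] = {}
    for w in windows:
        by_class.setdefault((w.subject_id, w.label.compound_id), []).append(w)
    if not by_class:
        raise ValueError("no windows to split")

    train: list[Window] = []
    test: list[Window] = []
    for subj, cid in sorted(by_class):
        ws = sorted(by_class[(subj, cid)], key=lambda w: w.trial_position)
        n_train = int(round(train_fraction * len(ws)))
        if n_train == 0 or n_train == len(ws):
            raise ValueError(
                f"train_fraction {train_fraction} leaves an empty side for "
                f"compound id {cid} ({len(ws)} windows)"
            )
        train.extend(ws[:n_train])
        test.extend(ws[n_train:])

    rng = np.random.default_rng(shuffle_seed)
    train = [train[i] for i in rng.permutation(len(train))]
    test = [test[i] for i in rng.permutation(len(test))]
    return DatasetSplit(train=train, test=test, train_fraction=train_fraction, shuffle_seed=shuffle_seed)
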