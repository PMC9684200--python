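"""Trial-level signal conditioning: detrend, mains notch, EMG bandpass.

The chain is applied to the whole trial, in this order, before windowing:

1. least-squares linear detrend per channel,
2. 2nd-order IIR notch at 50 Hz (default -3 dB bandwidth 2 Hz, Q = 25),
3. 4th-order Butterworth bandpass with edges 20 and 250 Hz.

Filtering is causal single-pass by default — the decoding budget is a
sub-200 ms pipeline, so a real deployment cannot look ahead — with a
zero-phase (forward-backward) option for offline studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .dataset import Recording

__all__ = [
    "FilterSpec",
    "design_notch",
    "design_bandpass",
    "detrend_linear",
    "notch_filter",
    "bandpass_filter",
    "preprocess_trial",
]


@dataclass(frozen=True)
class FilterSpec:
    """Conditioning-chain parameters.

    ``bandpass_order`` counts pole pairs per band edge (the convention of
    "4th-order Butterworth bandpass"); the transfer function of the
    bandpass is of order ``2 * bandpass_order``.
    """

    notch_freq: float = 50.0
    notch_order: int = 2
    notch_bandwidth: float = 2.0
    bandpass_low: float = 20.0
    bandpass_high: float = 250.0
    bandpass_order: int = 4
    phase_mode: str = "causal"  # or "zero-phase"
    detrend_mode: str = "linear"  # or "constant"

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.bandpass_low < self.bandpass_high < nyq:
            raise ValueError(
                f"bandpass ({self.bandpass_low}, {self.bandpass_high}) Hz must lie "
                f"inside (0, {nyq}) Hz"
            )
        if not 0 < self.notch_freq < nyq:
            raise ValueError(f"notch frequency {self.notch_freq} Hz outside (0, {nyq}) Hz")
        if self.phase_mode not in ("causal", "zero-phase"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if self.detrend_mode not in ("linear", "constant"):
            raise ValueError(f"unknown detrend_mode {self.detrend_mode!r}")
        if self.notch_order != 2:
            raise ValueError("only the 2nd-order notch is supported")

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _check_stable(sos: np.ndarray, name: str) -> np.ndarray:
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(f"{name} filter design is unstable (pole on/outside unit circle)")
    return sos


def design_notch(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Second-order IIR notch as SOS; stability-checked."""
    spec.validate(sampling_rate)
    q = spec.notch_freq / spec.notch_bandwidth
    b, a = signal.iirnotch(spec.notch_freq, q, fs=sampling_rate)
    return _check_stable(signal.tf2sos(b, a), "notch")


def design_bandpass(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Butterworth bandpass as SOS; stability-checked."""
    spec.validate(sampling_rate)
    sos = signal.butter(
        spec.bandpass_order,
        (spec.bandpass_low, spec.bandpass_high),
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    return _check_stable(sos, "bandpass")


def _apply_sos(sos: np.ndarray, samples: np.ndarray, phase_mode: str) -> np.ndarray:
    if phase_mode == "zero-phase":
        return signal.sosfiltfilt(sos, samples, axis=0)
    return signal.sosfilt(sos, samples, axis=0)


def detrend_linear(recording: Recording, mode: str = "linear") -> Recording:
    """Subtract the per-channel least-squares line (or mean, mode='constant')."""
    if recording.n_samples < 2:
        raise ValueError("detrending needs at least 2 samples per channel")
    out = signal.detrend(recording.samples, axis=0, type=mode)
    return replace(recording, samples=out, meta=dict(recording.meta))


def notch_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Suppress the mains line with the 2nd-order IIR notch."""
    sos = design_notch(spec, recording.sampling_rate)
    out = _apply_sos(sos, recording.samples, spec.phase_mode)
    return replace(recording, samples=out, meta=dict(recording.meta))


def bandpass_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Restrict to the EMG band with the Butterworth bandpass."""
    sos = design_bandpass(spec, recording.sampling_rate)
    out = _apply_sos(sos, recording.samples, spec.phase_mode)
    return replace(recording, samples=out, meta=dict(recording.meta))


def preprocess_trial(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Full conditioning chain: detrend -> notch -> bandpass, whole trial.

    Re-running on an already-conditioned recording raises: the chain is
    not idempotent (each pass re-shapes the passband edges).
    """
    if recording.meta.get("preprocessing") is not None:
        raise ValueError("recording has already been preprocessed")
    spec.validate(recording.sampling_rate)
    rec = detrend_linear(recording, mode=spec.detrend_mode)
    rec = notch_filter(rec, spec)
    rec = bandpass_filter(rec, spec)
    meta = dict(rec.meta)
    meta["preprocessing"] = spec.as_dict()
    rec.meta = meta
    return rec
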