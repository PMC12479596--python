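"""Signal conditioning: band-pass/notch filtering, common average reference,
downsampling, and global field power (GFP) with peak extraction.

All steps are deterministic and zero-phase; the canonical order is
``bandpass_notch`` -> ``average_reference`` -> ``downsample``, after which the
data remain average-referenced (the polyphase resampler is a channel-wise
linear operation, so a zero channel-mean is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import InvalidArgumentError
from .io import Recording

__all__ = [
    "GFPSeries",
    "bandpass_notch",
    "average_reference",
    "downsample",
    "gfp",
    "gfp_peaks",
    "preprocess",
]


@dataclass
class GFPSeries:
    """Per-sample global field power (spatial SD of the average-referenced
    potentials) and the indices of its strict local maxima."""

    values: np.ndarray
    sfreq: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def bandpass_notch(
    recording: Recording,
    low_hz: float = 1.0,
    high_hz: float = 40.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Second-order Butterworth band-pass plus IIR notch, applied zero-phase.

    Zero-phase (forward-backward) filtering preserves the timing of
    topographic transitions, which is what the downstream segmentation
    measures.
    """
    nyq = recording.sfreq / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidArgumentError(f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    if not (0 < notch_hz < nyq):
        raise InvalidArgumentError(f"notch frequency {notch_hz} must be below Nyquist {nyq}")
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=recording.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=recording.sfreq)
    out = signal.filtfilt(b, a, out, axis=1)
    return recording.copy_with(data=out)


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the common average: subtract the channel mean at every
    sample. Idempotent."""
    data = recording.data
    return recording.copy_with(data=data - data.mean(axis=0, keepdims=True))


def downsample(recording: Recording, target_hz: float = 250.0) -> Recording:
    """Polyphase resampling to ``target_hz`` (anti-aliased, zero-phase)."""
    if target_hz >= recording.sfreq:
        raise InvalidArgumentError(f"target_hz {target_hz} must be below sfreq {recording.sfreq}")
    from fractions import Fraction

    frac = Fraction(target_hz / recording.sfreq).limit_denominator(1000)
    out = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    return recording.copy_with(data=out, sfreq=target_hz)


def gfp(recording: Recording) -> GFPSeries:
    """GFP(t) = sqrt(mean over channels of the squared average-referenced
    potentials) — the population (1/C) spatial standard deviation."""
    data = recording.data
    data = data - data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(data**2, axis=0))
    return GFPSeries(values=values, sfreq=recording.sfreq)


def gfp_peaks(series: GFPSeries, min_separation_samples: int = 1) -> np.ndarray:
    """Strict local maxima of the GFP trace (plateaus -> leftmost sample,
    endpoints excluded). Stores and returns the peak index array."""
    values = np.asarray(series.values, dtype=float)
    if values.size < 3:
        raise InvalidArgumentError("need at least 3 samples to find peaks")
    peaks, props = signal.find_peaks(values, plateau_size=1, distance=max(1, min_separation_samples))
    idx = props["left_edges"].astype(int)
    series.peak_indices = idx
    return idx


def preprocess(
    recording: Recording,
    low_hz: float = 1.0,
    high_hz: float = 40.0,
    notch_hz: float = 50.0,
    target_hz: float = 250.0,
) -> Recording:
    """Full conditioning chain: filter -> common average -> downsample
    (downsampling skipped when the record is already at ``target_hz``)."""
    rec = bandpass_notch(recording, low_hz=low_hz, high_hz=high_hz, notch_hz=notch_hz)
    rec = average_reference(rec)
    if rec.sfreq > target_hz:
        rec = downsample(rec, target_hz)
        rec = average_reference(rec)  # restore exact zero mean after resampling
    return rec
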