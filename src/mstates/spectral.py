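"""Band-power analysis: Hanning-tapered FFT spectra, canonical band
definitions, and a data-driven k-means split of the beta range.

The default bands are delta 0.5-4, theta 4-8, alpha 8-14, low beta 14-26
and high beta 26-40 Hz; the low/high beta boundary can be re-derived from
the data with :func:`data_driven_band_split`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig
from scipy.fft import next_fast_len, rfft, rfftfreq
from sklearn.cluster import KMeans

from .exceptions import InvalidArgumentError
from .io import Recording

__all__ = [
    "CANONICAL_BANDS",
    "PowerSpectrum",
    "power_spectrum",
    "band_power",
    "data_driven_band_split",
]

CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "low_beta": (14.0, 26.0),
    "high_beta": (26.0, 40.0),
}


@dataclass
class PowerSpectrum:
    """One-sided power spectrum per channel (microvolts squared per bin)."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs
    resolution: float

    def mean_over_channels(self) -> np.ndarray:
        return self.power.mean(axis=0)


def power_spectrum(recording: Recording, resolution: float = 0.034) -> PowerSpectrum:
    """Single Hanning-tapered FFT power over the whole record.

    The FFT is zero-padded to the next fast length whose grid spacing is at
    most ``resolution`` Hz.  Scaling preserves Parseval's identity: the
    band-summed power equals the mean square of the tapered signal exactly.
    """
    if recording.duration < 2.0:
        raise InvalidArgumentError("record must be at least 2 s long")
    data = recording.data
    n = recording.n_samples
    n_fft = next_fast_len(max(n, int(np.ceil(recording.sfreq / resolution))))
    taper = spsig.windows.hann(n, sym=False)
    xw = data * taper
    spec = rfft(xw, n=n_fft, axis=1)
    power = np.abs(spec) ** 2
    scale = np.full(power.shape[1], 2.0)
    scale[0] = 1.0
    if n_fft % 2 == 0:
        scale[-1] = 1.0
    power = power * scale / (n_fft * n)
    freqs = rfftfreq(n_fft, d=1.0 / recording.sfreq)
    return PowerSpectrum(freqs=freqs, power=power, resolution=recording.sfreq / n_fft)


def band_power(
    spectrum: PowerSpectrum, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, tuple[float, float, float]]:
    """Mean power over the bins with low <= f < high, averaged across
    channels, for each named band."""
    if bands is None:
        bands = CANONICAL_BANDS
    mean_spec = spectrum.mean_over_channels()
    out: dict[str, tuple[float, float, float]] = {}
    for name, (low, high) in bands.items():
        if not low < high:
            raise InvalidArgumentError(f"band {name}: low must be below high")
        sel = (spectrum.freqs >= low) & (spectrum.freqs < high)
        if not np.any(sel):
            raise InvalidArgumentError(f"band {name} ({low}-{high} Hz) contains no bins")
        out[name] = (low, high, float(mean_spec[sel].mean()))
    return out


def data_driven_band_split(
    freqs: np.ndarray,
    mean_power: np.ndarray,
    k_clusters: int = 2,
    freq_window: tuple[float, float] = (14.0, 40.0),
    seed: int | None = 0,
    n_init: int = 20,
) -> np.ndarray:
    """Boundary frequencies from k-means on (frequency, log-power) pairs.

    Both coordinates are standardized inside the window (log power first,
    since raw 1/f power would otherwise dominate the distance).  Clusters
    are ordered by mean frequency and each boundary is the midpoint between
    the frequency extents of adjacent clusters.
    """
    freqs = np.asarray(freqs, dtype=float)
    mean_power = np.asarray(mean_power, dtype=float)
    if k_clusters < 2:
        raise InvalidArgumentError("k_clusters must be >= 2")
    lo, hi = freq_window
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < k_clusters:
        raise InvalidArgumentError("fewer frequency bins than clusters in the window")
    f = freqs[sel]
    logp = np.log10(np.maximum(mean_power[sel], 1e-30))

    def standardize(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 1e-15 else np.zeros_like(v)

    feats = np.column_stack([standardize(f), standardize(logp)])
    km = KMeans(n_clusters=k_clusters, n_init=n_init, random_state=seed).fit(feats)
    labels = km.labels_
    order = np.argsort([f[labels == c].mean() for c in range(k_clusters)])
    boundaries = []
    for a, b in zip(order[:-1], order[1:]):
        boundaries.append((f[labels == a].max() + f[labels == b].min()) / 2.0)
    return np.asarray(boundaries)
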