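"""Welch PSD with 2-s sliding windows, six-band aggregation in dB/Hz, and
Hilbert amplitude/phase.

Band edges: delta 1-4, theta 4-8, alpha 8-13, beta 13-30, low-gamma 30-48
and high-gamma 52-80 Hz.  The gap at 48-52 Hz mirrors the mains notch; band
membership uses the half-open convention ``lo <= f < hi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .inverse_imaging import RegionTimeSeries

__all__ = ["BandScheme", "BandPSD", "AnalyticSignal", "default_bands",
           "welch_psd", "band_aggregate", "band_psd", "hilbert_analytic"]


@dataclass
class BandScheme:
    """Ordered, non-overlapping frequency bands (name, lo Hz, hi Hz)."""

    bands: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        names = set()
        for name, lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"band {name}: lo {lo} >= hi {hi}")
            if lo < prev_hi:
                raise ValueError(f"band {name} overlaps its predecessor")
            if name in names:
                raise ValueError(f"duplicate band name {name}")
            names.add(name)
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for nm, lo, hi in self.bands:
            if nm == name:
                return lo, hi
        raise KeyError(f"no band named {name!r}")


def default_bands() -> BandScheme:
    return BandScheme(bands=[
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("low_gamma", 30.0, 48.0),
        ("high_gamma", 52.0, 80.0),
    ])


@dataclass
class BandPSD:
    """One-sided power spectral density per region.

    ``psd_raw`` integrates to the signal variance (Parseval); ``psd_db``
    appears after band aggregation as 10*log10 of the mean in-band density.
    """

    freqs: np.ndarray                      # (n_freqs,)
    psd_raw: np.ndarray                    # (n_regions, n_freqs), >= 0
    psd_db: np.ndarray | None = None       # (n_regions, n_bands)
    band_names: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(self.psd_raw < 0):
            raise ValueError("raw PSD must be non-negative")


@dataclass
class AnalyticSignal:
    """Instantaneous envelope and wrapped phase from the analytic signal."""

    amplitude: np.ndarray                  # (n_regions, n_times), >= 0
    phase: np.ndarray                      # radians in (-pi, pi]
    rate: float


def _as_array(x) -> tuple[np.ndarray, float | None]:
    if isinstance(x, RegionTimeSeries):
        return x.x, x.rate
    return np.atleast_2d(np.asarray(x, float)), None


def welch_psd(x, rate: float | None = None, window_s: float = 2.0,
              overlap: float = 0.5) -> BandPSD:
    """Averaged-periodogram (Welch) density, Hann window, 1/window_s Hz grid."""
    data, own_rate = _as_array(x)
    rate = own_rate if rate is None else rate
    if rate is None:
        raise ValueError("sampling rate required for plain arrays")
    nperseg = int(round(window_s * rate))
    if nperseg < 8:
        raise ValueError("window too short: fewer than 8 samples")
    if nperseg > data.shape[1]:
        raise ValueError(
            f"window of {nperseg} samples exceeds signal length {data.shape[1]}"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, pxx = signal.welch(
        data, fs=rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend="constant",
        scaling="density", axis=1,
    )
    return BandPSD(freqs=freqs, psd_raw=pxx)


def band_aggregate(psd: BandPSD, scheme: BandScheme) -> BandPSD:
    """Mean raw density over in-band bins (``lo <= f < hi``), then dB/Hz."""
    cols = []
    for name, lo, hi in scheme.bands:
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        if not mask.any():
            raise ValueError(
                f"band {name} [{lo}, {hi}) contains no frequency bins"
            )
        cols.append(psd.psd_raw[:, mask].mean(axis=1))
    raw_band = np.column_stack(cols)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(raw_band)
    return BandPSD(freqs=psd.freqs, psd_raw=psd.psd_raw, psd_db=db,
                   band_names=scheme.names)


def band_psd(x, rate: float | None = None, scheme: BandScheme | None = None,
             window_s: float = 2.0, overlap: float = 0.5) -> BandPSD:
    """Welch PSD followed by six-band dB/Hz aggregation."""
    return band_aggregate(welch_psd(x, rate, window_s, overlap),
                          scheme or default_bands())


def hilbert_analytic(x, rate: float | None = None) -> AnalyticSignal:
    """FFT-based analytic signal: envelope and wrapped instantaneous phase."""
    data, own_rate = _as_array(x)
    rate = own_rate if rate is None else rate
    if not np.all(np.isfinite(data)):
        raise ValueError("signal contains non-finite values")
    analytic = signal.hilbert(data, axis=1)
    return AnalyticSignal(amplitude=np.abs(analytic),
                          phase=np.angle(analytic),
                          rate=float(rate) if rate else 0.0)
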