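"""Signal conditioning: band-pass, mains notch, preictal windowing, epoching.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero-phase, so preictal timing relationships are
preserved.  ICA-based artifact rejection is deliberately out of scope: the
pipeline accepts pre-cleaned recordings; ``bandpass``/``notch`` are the
documented hook where a cleaned recording re-enters the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import EEGRecording

logger = logging.getLogger(__name__)

__all__ = ["EpochSet", "bandpass", "notch", "select_preictal", "epoch",
           "common_average"]


@dataclass
class EpochSet:
    """Non-overlapping contiguous epochs cut from one recording."""

    epochs: np.ndarray                 # (n_epochs, n_channels, n_times)
    rate: float
    epoch_length: float                # seconds
    channel_names: list[str]
    parent_window: tuple[float, float] | None = None  # seconds rel. onset

    def __post_init__(self) -> None:
        n_t = self.epochs.shape[2]
        expected = int(round(self.epoch_length * self.rate))
        if n_t != expected:
            raise ValueError(
                f"epoch sample count {n_t} != epoch_length*rate {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _apply_sos(rec: EEGRecording, sos: np.ndarray) -> EEGRecording:
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EEGRecording(samples=filtered, rate=rec.rate,
                        channel_names=list(rec.channel_names),
                        onset_marker=rec.onset_marker)


def bandpass(rec: EEGRecording, lo: float = 0.5, hi: float = 80.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; removes DC along the way."""
    nyq = rec.rate / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.rate,
                        output="sos")
    return _apply_sos(rec, sos)


def notch(rec: EEGRecording, freq: float = 50.0, half_width: float = 2.0,
          order: int = 4) -> EEGRecording:
    """Zero-phase band-stop around the mains frequency (default 48--52 Hz)."""
    nyq = rec.rate / 2.0
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    band = [freq - half_width, freq + half_width]
    if band[1] >= nyq:
        raise ValueError("notch stop band extends past Nyquist")
    sos = signal.butter(order, band, btype="bandstop", fs=rec.rate,
                        output="sos")
    return _apply_sos(rec, sos)


def select_preictal(rec: EEGRecording, minutes: float = 10.0) -> EEGRecording:
    """The ``[onset - minutes, onset)`` window preceding seizure onset."""
    if rec.onset_marker is None:
        raise ValueError("recording has no seizure-onset marker")
    n_need = int(round(minutes * 60.0 * rec.rate))
    start = rec.onset_marker - n_need
    if start < 0:
        avail = rec.onset_marker / rec.rate / 60.0
        raise ValueError(
            f"recording provides only {avail:.2f} min before onset; "
            f"{minutes} min requested"
        )
    window = rec.samples[:, start:rec.onset_marker]
    return EEGRecording(samples=window, rate=rec.rate,
                        channel_names=list(rec.channel_names),
                        onset_marker=None)


def epoch(rec: EEGRecording, length: float = 2.0) -> EpochSet:
    """Cut into ``floor(duration/length)`` contiguous non-overlapping epochs."""
    if length <= 0:
        raise ValueError("epoch length must be positive")
    n_per = int(round(length * rec.rate))
    if n_per > rec.n_times:
        raise ValueError("epoch length exceeds recording duration")
    n_ep = rec.n_times // n_per
    dropped = rec.n_times - n_ep * n_per
    if dropped:
        logger.info("dropping %d trailing samples (%.3f s) during epoching",
                    dropped, dropped / rec.rate)
    cut = rec.samples[:, :n_ep * n_per]
    eps = cut.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2)
    return EpochSet(epochs=eps, rate=rec.rate, epoch_length=length,
                    channel_names=list(rec.channel_names))


def common_average(rec: EEGRecording) -> EEGRecording:
    """Optional common-average re-reference (off by default in the pipeline)."""
    return EEGRecording(samples=rec.samples - rec.samples.mean(axis=0),
                        rate=rec.rate, channel_names=list(rec.channel_names),
                        onset_marker=rec.onset_marker)
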