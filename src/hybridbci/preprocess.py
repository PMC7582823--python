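"""Montage derivation, band-pass filtering, and epoching.

The pipeline operates on a single occipital bipolar derivation (O1 − O2)
sampled at 500 Hz.  Two independently switchable zero-phase Butterworth
band-passes are provided: the 1–50 Hz acquisition filter applied to raw
streams and the 5–30 Hz analysis filter applied to single epochs before
feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RawStream",
    "Epoch",
    "Bandpass",
    "make_bipolar",
    "acquisition_bandpass",
    "analysis_bandpass",
    "extract_epoch",
]

O1 = "O1"
O2 = "O2"
BIPOLAR = "BIPOLAR"


@dataclass
class RawStream:
    """Multi-channel sample matrix at a fixed rate.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique labels, a subset of ``{"O1", "O2", "BIPOLAR"}``.
    t0 : float
        Stream start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError(f"channel labels not unique: {self.channel_labels}")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channel_labels:
            raise KeyError(
                f"channel {label!r} not in stream (has {self.channel_labels})"
            )
        return self.samples[self.channel_labels.index(label)]


@dataclass
class Epoch:
    """One single-channel window, the unit of classification.

    The default pipeline uses 2 s at 500 Hz, i.e. 1000 samples.
    """

    samples: np.ndarray
    fs: float
    label: Optional[str] = None
    onset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs


def make_bipolar(stream: RawStream) -> RawStream:
    """Derive the O-bipolar channel O1 − O2 from a two-electrode stream."""
    for needed in (O1, O2):
        if needed not in stream.channel_labels:
            raise ValueError(f"stream is missing channel {needed!r}")
    bipolar = stream.channel(O1) - stream.channel(O2)
    return RawStream(bipolar[np.newaxis, :], stream.fs, (BIPOLAR,), stream.t0)


def _design_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for fs={fs} Hz; "
            "need 0 < low < high < fs/2"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


class Bandpass(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth band-pass applied row-wise.

    A stateless transformer (``fit`` only validates the band) so the filter
    can sit in an sklearn pipeline in front of the featurizer.

    Parameters
    ----------
    low, high : float
        Band edges in Hz.
    fs : float
        Sampling rate in Hz.
    order : int
        Butterworth order of the one-way filter; forward-backward
        application squares the magnitude response.
    """

    def __init__(self, low: float = 5.0, high: float = 30.0, fs: float = 500.0,
                 order: int = 4):
        self.low = low
        self.high = high
        self.fs = fs
        self.order = order

    def fit(self, X=None, y=None) -> "Bandpass":
        self.sos_ = _design_sos(self.low, self.high, self.fs, self.order)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "sos_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return signal.sosfiltfilt(self.sos_, X, axis=-1)

    def magnitude_response(self, freqs: Sequence[float]) -> np.ndarray:
        """Two-pass (zero-phase) magnitude response at the given frequencies."""
        if not hasattr(self, "sos_"):
            self.fit()
        _, h = signal.sosfreqz(self.sos_, worN=np.asarray(freqs, float), fs=self.fs)
        return np.abs(h) ** 2  # filtfilt applies the filter twice


def acquisition_bandpass(stream: RawStream, low: float = 1.0, high: float = 50.0,
                         order: int = 4) -> RawStream:
    """The 1–50 Hz hardware-style acquisition filter, per channel."""
    bp = Bandpass(low, high, stream.fs, order).fit()
    return replace(stream, samples=bp.transform(stream.samples))


def analysis_bandpass(epoch: Epoch, low: float = 5.0, high: float = 30.0,
                      order: int = 4) -> Epoch:
    """The 5–30 Hz analysis filter applied to one epoch before the STFT."""
    bp = Bandpass(low, high, epoch.fs, order).fit()
    return replace(epoch, samples=bp.transform(epoch.samples)[0])


def extract_epoch(stream: RawStream, onset: float, window_s: float = 2.0,
                  label: Optional[str] = None) -> Epoch:
    """Cut ``[onset, onset + window_s)`` from a single-channel stream.

    The start index is ``round((onset - t0) * fs)`` and the window is
    onset-inclusive, end-exclusive, so the default 2 s at 500 Hz yields
    exactly 1000 samples.
    """
    if stream.samples.shape[0] != 1:
        raise ValueError(
            "extract_epoch needs a single-channel stream; apply make_bipolar "
            f"first (got channels {stream.channel_labels})"
        )
    n = int(round(window_s * stream.fs))
    start = int(round((onset - stream.t0) * stream.fs))
    if start < 0 or start + n > stream.n_times:
        raise ValueError(
            f"window [{onset}, {onset + window_s}) s exceeds stream bounds "
            f"[{stream.t0}, {stream.t0 + stream.duration}) s"
        )
    return Epoch(stream.samples[0, start:start + n].copy(), stream.fs,
                 label=label, onset=onset)
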