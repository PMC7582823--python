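"""Sliding-window STFT power features.

Each 2 s epoch (1000 samples at 500 Hz) is turned into a time-frequency
power map with a 1 s (500-sample) Kaiser window advanced one sample at a
time (overlap 499).  A 500-sample window at 500 Hz gives 1 Hz bin
spacing; keeping the integer bins in [5, 30) Hz yields 25 frequency rows,
and dropping the final frame of the 501 available leaves 500 time
columns — the 25 × 500 map the CNN consumes.

Power is the squared windowed-DFT magnitude (not dB); maps are min-max
normalized to [0, 1] before classification, which makes the power scale
irrelevant downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple, Union

import numpy as np
from scipy.signal.windows import kaiser
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import Epoch

__all__ = ["FeatureMap", "STFTFeaturizer", "stft_feature", "normalize_map",
           "peak_profile", "default_window_len"]


@dataclass
class FeatureMap:
    """Non-negative frequency × time power matrix with its axes."""

    power: np.ndarray
    freq_axis: np.ndarray  # Hz per row
    time_axis: np.ndarray  # s per column (frame start)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.power.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError(
                f"power shape {self.power.shape} inconsistent with axes "
                f"({self.freq_axis.size}, {self.time_axis.size})"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.power.shape


def default_window_len(n_samples: int, fs: float) -> int:
    """STFT window length for an epoch: 1 s, or half the epoch if shorter.

    The default 2 s epoch gets the full 500-sample (1 s) window; shorter
    epochs (the 1 s time-window study) fall back to half the epoch so a
    nonempty frame axis remains.
    """
    one_second = int(round(fs))
    return min(one_second, n_samples // 2)


def stft_feature(epoch: Epoch, window_len: int = 500, step: int = 1,
                 kaiser_beta: float = 0.5,
                 band: Tuple[float, float] = (5.0, 30.0)) -> FeatureMap:
    """Sliding-window STFT power map of one epoch.

    Parameters
    ----------
    epoch : Epoch
    window_len : int
        Frame length in samples (default 500 = 1 s at 500 Hz).
    step : int
        Frame advance in samples (default 1, i.e. overlap ``window_len-1``).
    kaiser_beta : float
        Kaiser window shape parameter.
    band : (low, high)
        Half-open frequency band [low, high) in Hz selecting the rows.

    Returns
    -------
    FeatureMap
        ``(epoch_len - window_len) // step`` columns (the final frame is
        dropped so the default pipeline yields exactly 500), rows are the
        DFT bins inside ``band``.
    """
    x = np.asarray(epoch.samples, dtype=float)
    n = x.size
    if n < window_len:
        raise ValueError(
            f"epoch of {n} samples is shorter than the {window_len}-sample window"
        )
    n_frames = (n - window_len) // step
    if n_frames < 1:
        raise ValueError(
            f"epoch of {n} samples leaves no frames for window {window_len} "
            f"and step {step}"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::step]
    frames = frames[:n_frames]
    win = kaiser(window_len, kaiser_beta, sym=False)
    spectrum = np.fft.rfft(frames * win, axis=1)
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(window_len, d=1.0 / epoch.fs)
    rows = (freqs >= band[0]) & (freqs < band[1])
    time_axis = np.arange(n_frames) * step / epoch.fs
    return FeatureMap(power[:, rows].T, freqs[rows], time_axis)


def normalize_map(fmap: FeatureMap) -> FeatureMap:
    """Min-max scale the whole map to [0, 1].

    Constant (e.g. all-zero) maps pass through unchanged; normalizing an
    already-normalized map is the identity.
    """
    if fmap.normalized:
        return fmap
    lo = fmap.power.min()
    hi = fmap.power.max()
    if hi > lo:
        power = (fmap.power - lo) / (hi - lo)
    else:
        power = fmap.power.copy()
    return replace(fmap, power=power, normalized=True)


def peak_profile(fmap: FeatureMap) -> List[Tuple[float, float]]:
    """Per-frame dominant frequency: ``[(time, argmax frequency), ...]``.

    Ties break to the lowest-frequency bin (argmax convention).
    """
    idx = np.argmax(fmap.power, axis=0)
    return [(float(t), float(fmap.freq_axis[i]))
            for t, i in zip(fmap.time_axis, idx)]


class STFTFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: epochs matrix → stack of normalized STFT power maps.

    Accepts an (n_trials, n_samples) array and returns an
    (n_trials, n_freq_rows, n_frames) tensor of min-max normalized maps,
    ready for :class:`hybridbci.classifier.CNNClassifier`.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    window_len : int or "auto"
        Frame length in samples; "auto" uses :func:`default_window_len`.
    step : int
        Frame advance in samples.
    kaiser_beta : float
    band : (low, high) in Hz, half-open.
    normalize : bool
        Min-max normalize each map (the classifier expects this).
    """

    def __init__(self, fs: float = 500.0,
                 window_len: Union[int, str] = "auto", step: int = 1,
                 kaiser_beta: float = 0.5,
                 band: Tuple[float, float] = (5.0, 30.0),
                 normalize: bool = True):
        self.fs = fs
        self.window_len = window_len
        self.step = step
        self.kaiser_beta = kaiser_beta
        self.band = band
        self.normalize = normalize

    def _window_len(self, n_samples: int) -> int:
        if self.window_len == "auto":
            return default_window_len(n_samples, self.fs)
        return int(self.window_len)

    def fit(self, X: np.ndarray, y=None) -> "STFTFeaturizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.window_len_ = self._window_len(X.shape[1])
        probe = self.transform_one(X[0])
        self.output_shape_ = probe.shape
        return self

    def transform_one(self, samples: np.ndarray) -> FeatureMap:
        ep = Epoch(samples, self.fs)
        fmap = stft_feature(ep, self._window_len(len(ep)), self.step,
                            self.kaiser_beta, self.band)
        return normalize_map(fmap) if self.normalize else fmap

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([self.transform_one(row).power for row in X])
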