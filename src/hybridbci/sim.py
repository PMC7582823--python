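"""Synthetic occipital EEG with the statistical structure the decoder assumes.

The generator emulates what a bipolar O1−O2 montage sees during a flicker
/ eye-blink task battery:

* steady-state visually evoked responses at one of six stimulus
  frequencies (fundamental plus geometrically decaying harmonics) embedded
  in 1/f^γ background noise at a configurable SNR,
* large smooth eye-blink transients (one or two per epoch) riding on the
  same background,
* per-subject multiplicative amplitude variability,
* a two-electrode channel model in which the evoked signal projects in
  antiphase onto O1 and O2 while common-mode noise is shared, so the
  bipolar derivation cancels shared noise and doubles the signal.

All randomness flows from one explicit seed through numpy Generator
objects; identical (config, seed) pairs produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .preprocess import BIPOLAR, O1, O2, Epoch, RawStream

__all__ = [
    "SignalModelConfig",
    "TrialSet",
    "SSVEP_FREQS",
    "LABELS",
    "BLINK_SINGLE",
    "BLINK_DOUBLE",
    "ssvep_label",
    "make_ssvep_epoch",
    "make_blink_epoch",
    "make_dataset",
    "make_session_stream",
]

SSVEP_FREQS: Tuple[float, ...] = (6.6, 7.5, 8.57, 10.0, 11.0, 12.0)
BLINK_SINGLE = "blink_single"
BLINK_DOUBLE = "blink_double"


def ssvep_label(freq: float) -> str:
    """Canonical class label for a stimulus frequency, e.g. ``"ssvep_8.57"``."""
    return f"ssvep_{freq:g}"


#: Canonical 8-class label space: six flicker frequencies then the two blinks.
LABELS: Tuple[str, ...] = tuple(ssvep_label(f) for f in SSVEP_FREQS) + (
    BLINK_SINGLE,
    BLINK_DOUBLE,
)

RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SignalModelConfig:
    """Parameters of the synthetic EEG model.

    SNR is defined on the bipolar trace: ``snr_db`` is the evoked-signal
    power over the power of the independent (non-cancelling) background.
    """

    fs: float = 500.0
    duration: float = 2.0
    ssvep_freqs: Tuple[float, ...] = SSVEP_FREQS
    n_harmonics: int = 2
    harmonic_decay: float = 0.5
    snr_db: float = 10.0
    noise_exponent: float = 1.0
    alpha_amp: float = 0.0  # optional 10 Hz idle rhythm; off by default (collides with the 10 Hz class)
    blink_amp_factor: float = 8.0
    blink_width_s: float = 0.3
    double_blink_gap_s: float = 0.5
    blink_cue_window_s: float = 2.0  # blinks land within this long after the cue
    subject_gain_sd: float = 0.2
    common_noise_ratio: float = 1.0  # shared-noise RMS over bipolar background RMS
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs*duration must be an integer sample count, got {n}"
            )
        freqs = tuple(float(f) for f in self.ssvep_freqs)
        object.__setattr__(self, "ssvep_freqs", freqs)
        if len(set(freqs)) != len(freqs):
            raise ValueError(f"ssvep_freqs must be distinct, got {freqs}")
        if any(f <= 0 or f >= self.fs / 2 for f in freqs):
            raise ValueError(
                f"all ssvep_freqs must lie in (0, fs/2)={self.fs / 2}, got {freqs}"
            )
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (0 < self.harmonic_decay <= 1):
            raise ValueError("harmonic_decay must be in (0, 1]")
        if self.blink_width_s <= 0:
            raise ValueError("blink_width_s must be positive")
        if self.blink_cue_window_s <= 0:
            raise ValueError("blink_cue_window_s must be positive")
        span = self._blink_margin_left + self._blink_margin_right
        window = min(self.duration, self.blink_cue_window_s)
        if span >= window:
            raise ValueError("single blink pulse does not fit inside the epoch")
        if span + self.double_blink_gap_s >= window:
            raise ValueError("double blink pulses do not fit inside the epoch")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    # margins keep the ~3-sigma flanks of the asymmetric pulse inside the
    # epoch: the fast rise needs little room, the slow decay more
    @property
    def _blink_margin_left(self) -> float:
        return 0.15 * self.blink_width_s

    @property
    def _blink_margin_right(self) -> float:
        return 0.8 * self.blink_width_s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ssvep_freqs"] = list(d["ssvep_freqs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SignalModelConfig":
        d = dict(d)
        if "ssvep_freqs" in d:
            d["ssvep_freqs"] = tuple(d["ssvep_freqs"])
        return cls(**d)


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^γ noise of length ``n``, normalized to unit RMS.

    Generated by shaping the spectrum of white Gaussian noise with
    f^(−γ/2); the DC bin is zeroed so the output is zero-mean.
    """
    white = rng.standard_normal(n)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        shaping = np.zeros_like(f)
        shaping[1:] = f[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _ssvep_waveform(freq: float, config: SignalModelConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS harmonic stack at ``freq`` with random phases."""
    t = np.arange(config.n_samples) / config.fs
    x = np.zeros_like(t)
    for h in range(1, config.n_harmonics + 1):
        amp = config.harmonic_decay ** (h - 1)
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * h * freq * t + phase)
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _blink_pulse(center: float, config: SignalModelConfig) -> np.ndarray:
    """Unit-peak smooth unipolar blink transient centered at ``center`` s.

    Asymmetric: a fast half-Gaussian rise (lid closure) and a slower
    half-Gaussian decay, so the transient keeps spectral energy inside
    the 5–30 Hz analysis band while remaining smooth.
    """
    t = np.arange(config.n_samples) / config.fs
    sigma_rise = 0.04 * config.blink_width_s
    sigma_fall = 0.25 * config.blink_width_s
    x = np.where(
        t < center,
        np.exp(-0.5 * ((t - center) / sigma_rise) ** 2),
        np.exp(-0.5 * ((t - center) / sigma_fall) ** 2),
    )
    return x


def _blink_waveform(kind: str, config: SignalModelConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-peak pulse train: one (single) or two (double) blink transients."""
    lo = config._blink_margin_left
    hi = (min(config.duration, config.blink_cue_window_s)
          - config._blink_margin_right)
    if kind == "single":
        center = rng.uniform(lo, hi)
        return _blink_pulse(center, config)
    if kind == "double":
        gap = config.double_blink_gap_s
        first = rng.uniform(lo, hi - gap)
        return _blink_pulse(first, config) + _blink_pulse(first + gap, config)
    raise ValueError(f"blink kind must be 'single' or 'double', got {kind!r}")


def _render_channels(signal_wave: np.ndarray, amplitude: float,
                     config: SignalModelConfig,
                     rng: np.random.Generator) -> dict:
    """Project an evoked waveform onto the O1/O2 channel model.

    O1 = +A/2·s + c + e1 and O2 = −A/2·s + c + e2, where c is shared
    (common-mode) noise and e1, e2 are independent backgrounds scaled so
    the bipolar residual e1 − e2 has unit RMS.  The bipolar trace is then
    A·s plus unit-RMS noise, which is where SNR is defined.
    """
    n = signal_wave.size
    gamma = config.noise_exponent
    common = config.common_noise_ratio * pink_noise(n, gamma, rng)
    e1 = pink_noise(n, gamma, rng) / np.sqrt(2.0)
    e2 = pink_noise(n, gamma, rng) / np.sqrt(2.0)
    if config.alpha_amp > 0:
        t = np.arange(n) / config.fs
        common = common + config.alpha_amp * np.sin(
            2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)
        )
    half = 0.5 * amplitude * signal_wave
    o1 = half + common + e1
    o2 = -half + common + e2
    return {O1: o1, O2: o2, BIPOLAR: o1 - o2}


def make_ssvep_epoch(freq: float, config: SignalModelConfig,
                     rng: RngLike = None, *, channel: str = BIPOLAR,
                     subject_gain: float = 1.0) -> Epoch:
    """One labeled SSVEP epoch at stimulus frequency ``freq``.

    ``freq`` must be one of ``config.ssvep_freqs``; the evoked amplitude
    is set so the bipolar trace has ``config.snr_db`` dB of SSVEP power
    over the independent background (scaled by ``subject_gain``).
    """
    if freq not in config.ssvep_freqs:
        raise ValueError(
            f"freq {freq} Hz is not a configured stimulus; "
            f"valid set: {config.ssvep_freqs}"
        )
    rng = _as_rng(rng)
    wave = _ssvep_waveform(freq, config, rng)
    amplitude = subject_gain * 10.0 ** (config.snr_db / 20.0)
    chans = _render_channels(wave, amplitude, config, rng)
    return Epoch(chans[channel], config.fs, label=ssvep_label(freq),
                 meta={"channel": channel, "subject_gain": subject_gain})


def make_blink_epoch(kind: str, config: SignalModelConfig,
                     rng: RngLike = None, *, channel: str = BIPOLAR,
                     subject_gain: float = 1.0) -> Epoch:
    """One labeled blink epoch, ``kind`` in {"single", "double"}.

    The pulse peak is ``blink_amp_factor`` times the bipolar background
    RMS (which is 1 by construction), scaled by ``subject_gain``.
    """
    rng = _as_rng(rng)
    wave = _blink_waveform(kind, config, rng)
    amplitude = subject_gain * config.blink_amp_factor
    chans = _render_channels(wave, amplitude, config, rng)
    label = BLINK_SINGLE if kind == "single" else BLINK_DOUBLE
    return Epoch(chans[channel], config.fs, label=label,
                 meta={"channel": channel, "subject_gain": subject_gain})


def _make_epoch_for_label(label: str, config: SignalModelConfig,
                          rng: np.random.Generator, channel: str,
                          subject_gain: float) -> Epoch:
    if label == BLINK_SINGLE:
        return make_blink_epoch("single", config, rng, channel=channel,
                                subject_gain=subject_gain)
    if label == BLINK_DOUBLE:
        return make_blink_epoch("double", config, rng, channel=channel,
                                subject_gain=subject_gain)
    freq = float(label.split("_", 1)[1])
    # match against configured values (labels round-trip through :g format)
    for f in config.ssvep_freqs:
        if ssvep_label(f) == label:
            freq = f
            break
    return make_ssvep_epoch(freq, config, rng, channel=channel,
                            subject_gain=subject_gain)


@dataclass
class TrialSet:
    """A balanced set of labeled trials plus its generation provenance."""

    epochs: List[Epoch]
    labels: List[str]
    subject_ids: List[int]
    label_space: Tuple[str, ...]
    config: SignalModelConfig
    seed: Optional[int]
    channel: str = BIPOLAR

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def X(self) -> np.ndarray:
        """Trials × samples matrix."""
        return np.stack([e.samples for e in self.epochs])

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def make_dataset(config: SignalModelConfig = SignalModelConfig(),
                 n_subjects: int = 5, n_trials_per_task: int = 20,
                 rng: RngLike = None, *, channel: str = BIPOLAR) -> TrialSet:
    """Balanced synthetic trial set: ``n_subjects × 8 tasks × n_trials_per_task``.

    The default 5 subjects × 8 tasks × 20 trials gives 800 trials with
    exactly 100 per class.  Per-subject amplitude gains are drawn
    log-normally with relative spread ``config.subject_gain_sd``.
    """
    if n_subjects < 1 or n_trials_per_task < 1:
        raise ValueError("n_subjects and n_trials_per_task must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is None and rng is None:
        seed = config.seed
    rng = _as_rng(seed if seed is not None else rng)
    labels_order = tuple(ssvep_label(f) for f in config.ssvep_freqs) + (
        BLINK_SINGLE, BLINK_DOUBLE)
    epochs: List[Epoch] = []
    labels: List[str] = []
    subject_ids: List[int] = []
    for subject in range(n_subjects):
        gain = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
        for label in labels_order:
            for _ in range(n_trials_per_task):
                ep = _make_epoch_for_label(label, config, rng, channel, gain)
                ep.meta["subject"] = subject
                epochs.append(ep)
                labels.append(label)
                subject_ids.append(subject)
    return TrialSet(epochs, labels, subject_ids, labels_order, config,
                    seed if isinstance(seed, (int, np.integer)) else None,
                    channel)


def make_session_stream(script: Sequence[Tuple[str, float, float]],
                        config: SignalModelConfig = SignalModelConfig(),
                        rng: RngLike = None) -> Tuple[RawStream, List[dict]]:
    """Continuous two-channel O1/O2 stream realizing a scripted intent sequence.

    Parameters
    ----------
    script : sequence of (intent, onset_s, duration_s)
        ``intent`` is a class label from :data:`LABELS`; intervals must
        not overlap.  Gaps between intents contain background only.
    config : SignalModelConfig
    rng : int or Generator, optional

    Returns
    -------
    stream : RawStream with channels O1, O2
    events : list of dict
        Ground-truth log ``{"label", "onset", "duration"}`` in input order.
    """
    rng = _as_rng(rng)
    items = []
    for intent, onset, duration in script:
        if intent not in LABELS:
            raise ValueError(f"unknown intent {intent!r}; valid: {LABELS}")
        if onset < 0 or duration <= 0:
            raise ValueError(f"bad interval for {intent!r}: {onset=} {duration=}")
        items.append((str(intent), float(onset), float(duration)))
    intervals = sorted((s, s + d, l) for l, s, d in items)
    for (s0, e0, l0), (s1, e1, l1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(
                f"overlapping intents: {l0!r} ends at {e0} s but {l1!r} "
                f"starts at {s1} s"
            )
    total_s = max((e for _, e, _ in intervals), default=0.0)
    total_s = max(total_s, config.duration)
    n = int(np.ceil(total_s * config.fs))
    gamma = config.noise_exponent
    common = config.common_noise_ratio * pink_noise(n, gamma, rng)
    o1 = common + pink_noise(n, gamma, rng) / np.sqrt(2.0)
    o2 = common + pink_noise(n, gamma, rng) / np.sqrt(2.0)
    events = []
    for label, onset, duration in items:
        i0 = int(round(onset * config.fs))
        i1 = min(int(round((onset + duration) * config.fs)), n)
        seg_cfg = dataclasses.replace(config, duration=(i1 - i0) / config.fs)
        if label in (BLINK_SINGLE, BLINK_DOUBLE):
            kind = "single" if label == BLINK_SINGLE else "double"
            wave = _blink_waveform(kind, seg_cfg, rng)
            amplitude = config.blink_amp_factor
        else:
            freq = next(f for f in config.ssvep_freqs if ssvep_label(f) == label)
            wave = _ssvep_waveform(freq, seg_cfg, rng)
            amplitude = 10.0 ** (config.snr_db / 20.0)
        half = 0.5 * amplitude * wave
        o1[i0:i1] += half
        o2[i0:i1] -= half
        events.append({"label": label, "onset": onset, "duration": duration})
    stream = RawStream(np.stack([o1, o2]), config.fs, (O1, O2))
    return stream, events
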