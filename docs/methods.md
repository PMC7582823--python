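# Methods

## The decoding problem

A gaze-controlled menu BCI presents six squares flickering at 6.6, 7.5,
8.57, 10, 11 and 12 Hz.  Fixating a flicker entrains occipital cortex at
that frequency and its harmonics (the steady-state visually evoked
potential, SSVEP); voluntary single and double eye blinks produce large
slow transients in the same derivation.  The decoder must assign each
2 s EEG window (1000 samples at 500 Hz, one bipolar channel O1 − O2) to
one of eight classes: six stimulus frequencies, single blink, double
blink.  Decoded classes drive a two-level 6 × 6 menu: SSVEP selects,
single blink confirms, double blink undoes — 36 leaf commands plus the
two blink events, 38 commands in total.

## Synthetic signal model

No public recordings exist for this task battery, so the package ships a
generator whose output has the statistical structure the decoder relies
on.  Per epoch, the bipolar trace is

    x(t) = A · s(t) + n(t),

where `n` is unit-RMS Gaussian 1/f^γ noise (γ = 1 by default, produced by
FFT spectral shaping of white noise) and `s` is the evoked waveform:

* **SSVEP**: a unit-RMS stack of `n_harmonics` (default 2) sinusoids at
  f, 2f, … with geometric amplitude decay (default ratio 0.5) and random
  phases.  `A = g_subj · 10^(snr_db/20)`, so `snr_db` is the evoked-power
  to background-power ratio on the bipolar trace.  The default
  `snr_db = 10` is a free parameter of the simulator — the studies this
  emulates never report their subjects' SSVEP SNR — chosen as a clean
  but not noiseless operating point at which the end-to-end pipeline is
  expected to work; it is deliberately far above the sub-0-dB SNR of
  much real-world SSVEP data (see Limitations).
* **Blink**: one (single) or two (double, centers `double_blink_gap_s`
  = 0.5 s apart) smooth unipolar transients with peak
  `blink_amp_factor = 8` times the background RMS.  The pulse is
  *asymmetric*: a fast half-Gaussian rise (σ = 0.04 × width) and a slower
  half-Gaussian decay (σ = 0.25 × width, width default 0.3 s).  The fast
  flank matters: a symmetric 0.3 s Gaussian has essentially no energy
  above 5 Hz, and the 5–30 Hz analysis filter would erase it — whereas
  real lid-closure artifacts have a sharp leading edge and remain clearly
  visible in a 5–30 Hz spectrogram.  Pulse placement is uniform within
  asymmetric margins (0.15 × width on the left, 0.8 × width on the
  right) that keep the ~3σ flanks inside the epoch; a placement that
  would clip the boundary is rejected at configuration time.  Blinks are
  confined to the first `blink_cue_window_s` (default 2 s) of the epoch:
  a cued voluntary blink follows the cue promptly, so its latency
  distribution does not widen when a longer segmentation window is
  analyzed.

**Channel model.**  The evoked signal projects in antiphase onto the two
electrodes, O1 = +A/2·s + c + e₁ and O2 = −A/2·s + c + e₂, where `c` is
shared (common-mode) noise with RMS `common_noise_ratio` (default 1) and
e₁, e₂ are independent backgrounds scaled so e₁ − e₂ has unit RMS.  The
bipolar derivation O1 − O2 therefore cancels `c` exactly and doubles the
signal, reproducing the empirical advantage of the occipital bipolar
montage; each single electrode sees half the signal amplitude against
`c + eᵢ`.  Blinks are given the same antiphase projection for simplicity
(real blink artifacts reach both occipital electrodes with unequal gain;
only the asymmetry matters for the bipolar trace).

**Subjects and datasets.**  `make_dataset` draws one log-normal gain per
subject (relative spread `subject_gain_sd = 0.2`) applied to the evoked
amplitude, and generates a balanced grid: the default 5 subjects × 8
tasks × 20 trials = 800 trials, 100 per class.  All randomness flows
from one explicit seed through `numpy` Generators; identical
(config, seed) pairs are bit-identical.

What the generator does **not** emulate: inter-trial SSVEP latency and
amplitude dynamics, alpha-band idle rhythm (a 10 Hz alpha component is
available but off by default because it collides with the 10 Hz stimulus
class), electrode impedance drift, motion/EMG artifacts, and monitor
refresh harmonics.  Passing tests on this generator demonstrates the
pipeline's correctness and internal consistency, not field performance
on recorded EEG.

## Preprocessing

Two independently switchable zero-phase 4th-order Butterworth band-passes
(`scipy.signal.sosfiltfilt`): 1–50 Hz for raw streams (mirroring
acquisition-stage filtering) and 5–30 Hz for epochs before feature
extraction.  Only the IIR family and the band edges are fixed by the
protocol; Butterworth forward-backward is the common EEG default, and
order/zero-phase are exposed.  Epochs are half-open windows `[onset, onset + window_s)` with
start index `round(onset · fs)`, making indexing exact and off-by-one
drift impossible.

## STFT features

Each epoch is framed with a 1 s (500-sample) Kaiser window advanced one
sample per frame (overlap 499) and each frame is Fourier transformed;
the feature is squared magnitude.  Three conventions pin down the
25 × 500 map:

* a 1000-sample epoch yields 501 frames; the final frame is dropped to
  give 500 columns;
* the 500-sample window at 500 Hz gives 1 Hz bins; the half-open band
  [5, 30) Hz keeps 25 integer bins (5…29 Hz).  An inclusive band would
  give 26 rows — this is the one unavoidable off-by-one interpretation,
  and the band is configurable;
* the Kaiser shape parameter is a free choice; β = 0.5 (a near-
  rectangular taper, the default in common numerical environments) is
  adopted and configurable.

Maps are min-max normalized to [0, 1] per map (all-zero maps pass
through; normalization is idempotent), which makes the power-vs-dB choice
immaterial downstream.  For epochs shorter than 1 s the window falls back
to half the epoch length so a frame axis remains (used by the 1 s
condition of the window study).

## CNN decoder

Four layers: 2×2 valid convolution (default 8 kernels) with bias and
ReLU, 2×2 max-pool stride 2 (odd trailing edges dropped: 24 × 499 →
12 × 249), one hidden fully connected layer (default 64 units, ReLU),
and a linear output layer with one score per class.  Loss is plain MSE
against one-hot targets — not cross-entropy — and optimization is
vanilla mini-batch gradient descent (α = 0.01, batch 32, 50 epochs by
default), which is the training rule this decoder is defined by.  Weights
initialize from a zero-mean uniform distribution scaled by 1/√fan-in,
seeded; biases start at zero.  Kernel count, pool geometry and fc width
are the smallest configuration that learns the 8-class synthetic task in
minutes on one CPU core.  Forward, backward and the update rule are
hand-written numpy; analytic gradients are verified against central
finite differences (≤ 1e-5 relative) in float64.

Ties in the output argmax break to the lowest class index; classes are
kept in sorted label order (`numpy.unique`).  Training aborts with a
diagnostic on non-finite loss.  `train()` performs the stratified 80/20
split internally (seeded) and returns the held-out split alongside the
model so evaluation uses exactly the data the model never saw.

## Control logic and closed loop

The menu state machine is a total function over
{MAIN_SELECT, MAIN_CONFIRM, SUB_SELECT, SUB_CONFIRM, DONE} × 8 events:
SSVEP events act in selection phases, blinks in confirmation phases, and
every other combination is an explicit logged no-op (the five-step
protocol does not define these cases; ignore-and-log is this package's
contract).  Double blink from MAIN_CONFIRM returns to MAIN_SELECT and
from SUB_CONFIRM to SUB_SELECT with the pending category preserved.
Every leaf (m, s) is reachable by exactly one minimal 4-event script.

The closed-loop runner consumes back-to-back non-overlapping 2 s epochs.
Real online systems emit asynchronous decisions (sub-epoch response
times); here latencies are exact multiples of the epoch length by
construction, so simulated response-time summaries characterize the
loop's bookkeeping, not human reaction time.  A double blink is decoded
as one two-pulse epoch class, not as two consecutive single blinks,
matching the 8-class training design.  No idle/rest class exists;
low-confidence epochs are not rejected (a documented limitation).

## Information transfer rate

ψ = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)) bits per selection, scaled
by 60/T selections per minute.  The "commands × ψ / T" phrasing sometimes
printed for this quantity is dimensionally ambiguous; multiplying ψ by
the command count does not reproduce the published 146.67 bits/min for
(P = 0.9692, N = 38, T = 2 s), whereas ψ · 60/T does, so the latter is
implemented.  N is always an explicit argument (whole command inventory
vs per-screen choices is a modelling decision left to the caller).
P ≤ 1/N clamps to 0 with a warning; P = 1 uses the log₂N limit.
Timing summaries use the arithmetic mean and the n−1 sample standard
deviation, rounded only for display.

## Study harness and problem sizes

`experiments.channel_study` renders the *same* seeded trials through O1,
O2 and bipolar montages and trains/evaluates per montage;
`experiments.window_study` builds one identically seeded segmentation
per window length, each with its epochs spanning exactly that window (a
cued task's blink pulses always lie inside its own segmentation), so
window length is the only varying factor.  The studies default
to 3 subjects × 8 tasks × 10 trials (240 trials per condition), the
package's standard desk-scale study size; the headline end-to-end run
uses the full 800-trial grid.

## Known limitations

* Synthetic accuracies are not comparable to recorded-EEG accuracies;
  the default 10 dB SNR is generous, and real SSVEP decoding at 2 s
  windows is substantially harder.
* The 6.6, 7.5 and 8.57 Hz classes are not bin-centered for the 1 Hz
  STFT grid; their energy splits across adjacent bins (and harmonics
  partially overlap neighbouring fundamentals), which is the main source
  of synthetic SSVEP confusions at low SNR.
* MSE + vanilla gradient descent converges slowly compared with modern
  optimizers; it is kept deliberately because this exact training rule
  is part of the decoder's definition.
* The closed loop is synchronous and epoch-quantized; asynchronous
  detection latencies are out of scope.
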