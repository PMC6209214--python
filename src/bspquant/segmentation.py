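"""EEG preprocessing and burst/suppression segmentation.

The chain mirrors standard ICU quantitative-EEG practice: epochs contaminated by
high-amplitude artifact (>500 µV) are masked, the record is band-pass filtered at
0.5–55 Hz and re-referenced to the common average, each channel is converted to a
binary burst(0)/suppression(1) signal by an amplitude-envelope detector with
hysteresis, and a cross-channel majority vote yields one global binary signal that
is more robust to single-electrode artifact than any individual channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: Standard 10–20 labels for a 19-electrode clinical montage.
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

CLINICAL_SAMPLE_RATES = (256.0, 512.0)


def n_epochs(n_samples: int, fs: float, epoch_len: float = 1.0) -> int:
    """Number of half-open epochs [k·L, (k+1)·L) covering ``n_samples``."""
    return int(np.ceil(n_samples / (fs * epoch_len)))


@dataclass
class EEGRecord:
    """Multichannel scalp EEG in microvolts.

    ``samples`` is (n_channels, n_samples); all channels share ``fs`` and length.
    ``start_time`` is seconds; every downstream interval is half-open and measured
    in seconds from the record start.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels and len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if float(self.fs) not in CLINICAL_SAMPLE_RATES:
            warnings.warn(
                f"sampling rate {self.fs} Hz is outside the conventional clinical "
                "rates (256/512 Hz); proceeding anyway",
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochMask:
    """Per-epoch validity; epoch k covers the half-open interval [k·L, (k+1)·L) s."""

    valid: np.ndarray
    epoch_len: float = 1.0

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.epoch_len <= 0:
            raise ValueError("epoch length must be positive")

    def __len__(self) -> int:
        return len(self.valid)

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Expand to a per-sample boolean validity array of length ``n_samples``."""
        spe = self.epoch_len * fs
        idx = np.minimum((np.arange(n_samples) / spe).astype(int), len(self.valid) - 1)
        return self.valid[idx]


@dataclass
class BinarySuppressionSignal:
    """Per-sample binary signal: 1 = suppression, 0 = burst.

    Values are only meaningful where the epoch mask is valid.
    """

    values: np.ndarray
    fs: float
    mask: EpochMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.mask is None:
            self.mask = EpochMask(np.ones(n_epochs(len(self.values), self.fs), bool))

    @property
    def n_samples(self) -> int:
        return len(self.values)


def apply_average_montage(eeg: EEGRecord) -> EEGRecord:
    """Re-reference to the common average (subtract the cross-channel mean).

    Requires at least two channels; with one, the average reference is the channel
    itself and the output would be identically zero, which is never intended.
    Idempotent: applying twice equals applying once.
    """
    if eeg.n_channels < 2:
        raise ValueError("average montage requires at least 2 channels")
    ref = eeg.samples.mean(axis=0, keepdims=True)
    return EEGRecord(eeg.samples - ref, eeg.fs, list(eeg.channel_labels), eeg.start_time)


def bandpass(eeg: EEGRecord, lo: float = 0.5, hi: float = 55.0, order: int = 4) -> EEGRecord:
    """Zero-phase Butterworth band-pass, default 0.5–55 Hz.

    Forward-backward filtering (``sosfiltfilt``) gives zero phase shift so burst
    boundaries are not displaced in time. ``hi`` must be below Nyquist.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= eeg.fs / 2:
        raise ValueError(f"high cutoff {hi} Hz must be below Nyquist ({eeg.fs / 2} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=eeg.fs, output="sos")
    out = np.empty_like(eeg.samples, dtype=np.float64)
    for c in range(eeg.n_channels):
        out[c] = sps.sosfiltfilt(sos, eeg.samples[c].astype(np.float64))
    return EEGRecord(out.astype(eeg.samples.dtype, copy=False), eeg.fs,
                     list(eeg.channel_labels), eeg.start_time)


def reject_artifacts(eeg: EEGRecord, thresh: float = 500.0, epoch_len: float = 1.0) -> EpochMask:
    """Mark an epoch invalid iff any sample on any channel exceeds ``thresh`` µV
    in absolute value within the half-open epoch interval."""
    if thresh <= 0:
        raise ValueError("threshold must be positive")
    ne = n_epochs(eeg.n_samples, eeg.fs, epoch_len)
    if ne == 0:
        return EpochMask(np.zeros(0, bool), epoch_len)
    spe = int(round(eeg.fs * epoch_len))
    bad = np.abs(eeg.samples).max(axis=0) > thresh
    padded = np.zeros(ne * spe, bool)
    padded[: eeg.n_samples] = bad
    return EpochMask(~padded.reshape(ne, spe).any(axis=1), epoch_len)


def _ema_envelope(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    # one-pole smoother of |v|: e_t = beta*e_{t-1} + (1-beta)*|v_t|
    beta = float(np.exp(-1.0 / (fs * tau)))
    a = np.abs(np.asarray(x, dtype=np.float64))
    zi = sps.lfilter_zi([1 - beta], [1, -beta]) * a[0]
    env, _ = sps.lfilter([1 - beta], [1, -beta], a, zi=zi)
    return env


def _enforce_min_duration(values: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge interior runs shorter than ``min_samples`` into the preceding state.

    Runs touching either record edge are exempt (the detector cannot know how the
    state continues beyond the record). Single left-to-right pass over the
    run-length encoding: a short interior run is absorbed into its predecessor,
    and runs that end up adjacent with equal state coalesce.
    """
    edges = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [len(values)]))
    n_runs = len(starts)
    if n_runs <= 2:
        return values.copy()
    merged: list[list[int]] = [[0, int(ends[0]), int(values[0])]]
    for i in range(1, n_runs):
        s, e, v = int(starts[i]), int(ends[i]), int(values[starts[i]])
        interior = i < n_runs - 1
        if interior and e - s < min_samples:
            merged[-1][1] = e  # absorb into the preceding state
        elif merged[-1][2] == v:
            merged[-1][1] = e
        else:
            merged.append([s, e, v])
    out = np.empty_like(values)
    for s, e, v in merged:
        out[s:e] = v
    return out


def binarize_channel(
    channel: np.ndarray,
    fs: float,
    theta: float = 5.0,
    tau: float = 0.2,
    min_dur: float = 0.5,
    hysteresis: float = 0.2,
) -> BinarySuppressionSignal:
    """Convert one preprocessed channel into a binary burst/suppression signal.

    An exponential moving average of the rectified voltage tracks the amplitude
    envelope (time constant ``tau`` seconds). Suppression is entered when the
    envelope falls below ``theta·(1 − hysteresis)`` and left when it rises above
    ``theta·(1 + hysteresis)``; the hysteresis band prevents chatter around the
    threshold. Interior runs of either state shorter than ``min_dur`` are merged
    into their predecessor, so no interior run is shorter than ``min_dur``.

    The channel is expected to be montaged and band-pass filtered already.
    """
    if theta <= 0:
        raise ValueError("suppression threshold theta must be positive")
    x = np.asarray(channel, dtype=np.float64).ravel()
    if x.size == 0:
        return BinarySuppressionSignal(np.zeros(0, np.uint8), fs)
    env = _ema_envelope(x, fs, tau)
    lo, hi = theta * (1 - hysteresis), theta * (1 + hysteresis)
    # hysteresis: -1 = hold previous state, else forced state; forward fill
    forced = np.full(env.shape, -1, dtype=np.int8)
    forced[env < lo] = 1
    forced[env > hi] = 0
    if forced[0] < 0:
        forced[0] = 1 if env[0] < theta else 0
    idx = np.arange(len(forced))
    have = forced >= 0
    last = np.maximum.accumulate(np.where(have, idx, -1))
    values = forced[last].astype(np.uint8)
    values = _enforce_min_duration(values, int(round(min_dur * fs)))
    return BinarySuppressionSignal(values, fs)


def vote(
    per_channel_signals: list[BinarySuppressionSignal],
    mask: EpochMask | None = None,
    tie_value: int = 0,
) -> BinarySuppressionSignal:
    """Combine per-channel binary signals into a global signal by strict majority.

    A sample is suppression iff strictly more than half of the *contributing*
    channels (those whose own epoch mask is valid there) call it suppression;
    an exact tie, or no contributing channel, falls to ``tie_value`` (default
    burst — conservative toward detecting cerebral activity). The global epoch
    mask is the caller-supplied ``mask`` (typically the artifact-rejection mask).
    """
    if not per_channel_signals:
        raise ValueError("vote requires at least one channel signal")
    n = per_channel_signals[0].n_samples
    fs = per_channel_signals[0].fs
    for s in per_channel_signals:
        if s.n_samples != n or s.fs != fs:
            raise ValueError("all channel signals must share length and sampling rate")
    votes = np.zeros(n, dtype=np.int32)
    contrib = np.zeros(n, dtype=np.int32)
    for s in per_channel_signals:
        ok = s.mask.sample_mask(n, fs)
        votes += np.where(ok, s.values, 0)
        contrib += ok
    out = (2 * votes > contrib).astype(np.uint8)
    out[2 * votes == contrib] = tie_value
    if mask is None:
        mask = EpochMask(np.ones(n_epochs(n, fs), bool))
    return BinarySuppressionSignal(out, fs, mask)
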