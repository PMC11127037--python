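"""Minimal EEG preprocessing: re-reference, band-pass, epoch, downsample.

The chain mirrors standard ERP practice for high-density recordings:
re-reference the continuous signal to a chosen electrode, band-pass filter
(zero-phase), cut stimulus-locked epochs, and decimate to the analysis
rate.  No artifact rejection or baseline correction is applied by default;
both are available as opt-in flags on :func:`epoch`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "rereference",
    "bandpass",
    "epoch",
    "downsample",
]


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        n = self.data.shape[1]
        for sample, _stim in self.events:
            if not 0 <= sample < n:
                raise ValueError(f"event sample {sample} outside recording of {n} samples")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trials x channels x timepoints.

    ``time_ms`` is relative to stimulus onset; ``labels`` maps each trial to
    a stimulus id; ``repeat_flag`` marks one-back repetition trials so that
    decoding can exclude them.
    """

    data: np.ndarray
    time_ms: np.ndarray
    labels: np.ndarray
    repeat_flag: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.repeat_flag = np.asarray(self.repeat_flag, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x timepoints)")
        n_trials, _, n_times = self.data.shape
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must equal the number of trials")
        if self.repeat_flag.shape != (n_trials,):
            raise ValueError("repeat_flag length must equal the number of trials")
        if self.time_ms.shape != (n_times,):
            raise ValueError("time_ms length must equal the time axis")
        if n_times > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time_ms must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Restrict the time axis to [tmin_ms, tmax_ms] (inclusive ends)."""
        keep = (self.time_ms >= tmin_ms - 1e-9) & (self.time_ms <= tmax_ms + 1e-9)
        if not keep.any():
            raise ValueError(f"no samples in [{tmin_ms}, {tmax_ms}] ms")
        return EpochSet(
            data=self.data[:, :, keep],
            time_ms=self.time_ms[keep],
            labels=self.labels,
            repeat_flag=self.repeat_flag,
            sampling_rate=self.sampling_rate,
        )


def rereference(recording: ContinuousRecording, reference_channel: str) -> ContinuousRecording:
    """Subtract one channel from every channel (the reference becomes zero).

    The operation is idempotent: once a channel is identically zero,
    subtracting it again changes nothing.
    """
    try:
        idx = recording.channel_names.index(reference_channel)
    except ValueError:
        raise KeyError(
            f"reference channel {reference_channel!r} not among {recording.channel_names}"
        ) from None
    data = recording.data - recording.data[idx : idx + 1, :]
    return replace(recording, data=data)


def bandpass(
    recording: ContinuousRecording,
    low_hz: float = 0.01,
    high_hz: float = 80.0,
    order: int = 4,
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    ``order`` is the total one-pass order, split between a high-pass and a
    low-pass section: with cutoffs four decades apart a single band-pass
    design is numerically ill-conditioned, so the two edges are cascaded.
    The high-pass uses Gustafsson initial conditions, whose edge handling
    stays exact even when the cutoff's impulse response is far longer than
    the recording.  Forward-backward application cancels phase delay and
    doubles the effective roll-off.
    """
    nyq = recording.sampling_rate / 2
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"need 0 < low < high < Nyquist ({nyq} Hz); got [{low_hz}, {high_hz}]"
        )
    half = max(order // 2, 1)
    b_hp, a_hp = signal.butter(half, low_hz, btype="highpass", fs=recording.sampling_rate)
    sos_lp = signal.butter(half, high_hz, btype="lowpass", fs=recording.sampling_rate, output="sos")
    data = signal.filtfilt(b_hp, a_hp, recording.data, axis=1, method="gust")
    data = signal.sosfiltfilt(sos_lp, data, axis=1)
    return replace(recording, data=data)


def epoch(
    recording: ContinuousRecording,
    tmin_ms: float = -200.0,
    tmax_ms: float = 1100.0,
    repeat_events=None,
    baseline: bool = False,
    reject_peak_to_peak: float | None = None,
) -> EpochSet:
    """Cut one epoch per event over the half-open window [tmin, tmax).

    The onset sample (t = 0) is included; the number of samples is
    floor((tmax - tmin) / 1000 * fs).  Events whose window would run past
    either edge of the recording are dropped and the count is logged.
    ``repeat_events`` is an optional set of event indices to flag as
    one-back repetitions.  ``baseline=True`` subtracts the pre-onset mean
    per trial and channel.  ``reject_peak_to_peak`` (same units as the
    data) drops trials where any channel's peak-to-peak amplitude exceeds
    the threshold; off by default.
    """
    fs = recording.sampling_rate
    offset0 = int(round(tmin_ms / 1000.0 * fs))
    n_samp = int(np.floor((tmax_ms - tmin_ms) / 1000.0 * fs))
    if n_samp < 1:
        raise ValueError("epoch window contains no samples")
    n_total = recording.data.shape[1]
    repeat_events = set() if repeat_events is None else set(repeat_events)

    kept, labels, flags = [], [], []
    dropped = 0
    for k, (sample, stim) in enumerate(recording.events):
        start = sample + offset0
        if start < 0 or start + n_samp > n_total:
            dropped += 1
            continue
        kept.append(recording.data[:, start : start + n_samp])
        labels.append(stim)
        flags.append(k in repeat_events)
    if dropped:
        logger.info("epoch: dropped %d event(s) too close to the recording edges", dropped)
    if not kept:
        raise ValueError("no epochs could be formed: all events fall outside the recording")
    data = np.stack(kept, axis=0)
    time_ms = (offset0 + np.arange(n_samp)) / fs * 1000.0
    labels = np.asarray(labels, dtype=int)
    flags = np.asarray(flags, dtype=bool)
    if baseline:
        pre = time_ms < 0
        if pre.any():
            data = data - data[:, :, pre].mean(axis=2, keepdims=True)
    if reject_peak_to_peak is not None:
        ptp = (data.max(axis=2) - data.min(axis=2)).max(axis=1)
        good = ptp <= reject_peak_to_peak
        if not good.all():
            logger.info("epoch: rejected %d trial(s) above %.3g peak-to-peak",
                        int((~good).sum()), reject_peak_to_peak)
        if not good.any():
            raise ValueError("artifact rejection removed every trial")
        data, labels, flags = data[good], labels[good], flags[good]
    return EpochSet(
        data=data,
        time_ms=time_ms,
        labels=labels,
        repeat_flag=flags,
        sampling_rate=fs,
    )


def downsample(epochs: EpochSet, target_rate: float = 256.0) -> EpochSet:
    """Polyphase resampling of the epoch time axis with anti-alias filtering.

    For an integer decimation factor the output samples coincide with every
    factor-th input sample, so the time axis is simply strided.
    """
    fs = epochs.sampling_rate
    if target_rate >= fs:
        raise ValueError(f"target rate {target_rate} must be below the source rate {fs}")
    from fractions import Fraction

    frac = Fraction(target_rate / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=2, padtype="line")
    n_out = data.shape[2]
    # output sample k sits at input position k * down / up
    time_ms = epochs.time_ms[0] + np.arange(n_out) * (down / up) / fs * 1000.0
    return EpochSet(
        data=data,
        time_ms=time_ms,
        labels=epochs.labels,
        repeat_flag=epochs.repeat_flag,
        sampling_rate=target_rate,
    )
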