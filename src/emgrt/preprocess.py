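"""Envelope preprocessing and muscle-activity detection.

The raw integer signal is normalized to [-1, 1] against the fixed sensor
full scale, rectified with an absolute-value function, and smoothed with a
4th-order digital Butterworth low-pass (5 Hz cutoff by default), producing
the per-channel envelope that all feature extraction operates on.  Muscle
activity is located by thresholding the short-time spectral power of the
envelope, which lets training trim the relaxed head and tail of each
repetition and lets the streaming path emit "No-Gesture" when nothing fires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .synth import Recording

__all__ = [
    "FilterSpec",
    "PreprocessedSignal",
    "DEFAULT_FULL_SCALE",
    "DEFAULT_FRAME_LEN",
    "DEFAULT_THRESHOLD_DB",
    "normalize",
    "rectify",
    "lowpass",
    "detect_activity",
    "preprocess",
]

#: Fixed sensor full scale: 8-bit signed range, so raw/128 lies in [-1, 1).
#: Fixed (rather than per-recording max) so streaming stays causal and the
#: train/test scales agree.
DEFAULT_FULL_SCALE = 128

#: Activity-detection frame length in samples (320 ms at 200 Hz).
DEFAULT_FRAME_LEN = 64

#: Activity threshold in dB relative to the unit PSD-density reference,
#: calibrated for the synthetic generator's default amplitudes (burst
#: frames reach -48..-42 dB, rest frames stay below -65 dB).  Configurable
#: because the reference level of a dB/Hz threshold is hardware-dependent.
DEFAULT_THRESHOLD_DB = -55.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification.

    ``mode='causal'`` is a single forward pass (streaming-compatible);
    ``'zero-phase'`` is forward-backward filtering for offline use.
    """

    order: int = 4
    cutoff_hz: float = 5.0
    fs: float = 200.0
    mode: str = "causal"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError(
                f"cutoff_hz must lie in (0, fs/2)=(0, {self.fs / 2}); "
                f"got {self.cutoff_hz}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.butter(self.order, self.cutoff_hz, btype="low", fs=self.fs)


@dataclass
class PreprocessedSignal:
    """Normalized, rectified, low-pass-filtered envelope plus activity interval.

    ``envelope`` values are nominally in [0, 1]; a causal Butterworth can
    overshoot slightly (ringing), so values are asserted within
    [-0.05, 1.05] but never clipped.  ``activity_start``/``activity_end``
    index into the *source* recording (half-open).  When ``trimmed`` the
    envelope rows cover exactly [activity_start, activity_end).
    """

    envelope: np.ndarray
    fs: float
    activity_start: int
    activity_end: int
    source_length: int
    trimmed: bool = False
    gesture_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.activity_start <= self.activity_end
                <= self.source_length):
            raise ValueError(
                f"invalid activity interval [{self.activity_start}, "
                f"{self.activity_end}) for source of {self.source_length}")
        if self.envelope.size and (self.envelope.min() < -0.05
                                   or self.envelope.max() > 1.05):
            raise ValueError("envelope values outside [-0.05, 1.05]; "
                             "input not on the expected normalized scale")

    @property
    def has_activity(self) -> bool:
        return self.activity_end > self.activity_start


def normalize(raw: np.ndarray, full_scale: int = DEFAULT_FULL_SCALE
              ) -> np.ndarray:
    """Scale integer samples into [-1, 1] by dividing by ``full_scale``."""
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    raw = np.asarray(raw)
    over = np.abs(raw) > full_scale
    if np.any(over):
        idx = tuple(np.argwhere(over)[0])
        raise ValueError(
            f"sample {raw[idx]} at (sample, channel)={idx} exceeds "
            f"full_scale={full_scale}")
    return raw / float(full_scale)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x))


#: Startup-calibration length for the causal filter's initial state, in
#: samples (160 ms at 200 Hz).  The state is step-matched to the mean of
#: this leading stretch; matching a single noisy sample instead leaves a
#: rest-level transient that rings for ~0.3 s at a 5 Hz cutoff.
FILTER_INIT_LEN = 32


def lowpass(x: np.ndarray, spec: FilterSpec = FilterSpec(),
            init_len: int = FILTER_INIT_LEN) -> np.ndarray:
    """Per-channel Butterworth low-pass.

    Causal mode initializes the filter state to the step response matched
    to the mean of each channel's first ``init_len`` samples (a short
    startup calibration), which suppresses the startup transient on
    rectified (nonnegative) signals.  After this initial state the pass is
    strictly causal.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 3 * spec.order:
        raise ValueError(f"need at least {3 * spec.order} samples to filter")
    b, a = spec.coefficients()
    if spec.mode == "zero-phase":
        y = sps.filtfilt(b, a, x, axis=0)
    else:
        zi = sps.lfilter_zi(b, a)
        x0 = x[:max(1, min(init_len, x.shape[0]))].mean(axis=0)
        y, _ = sps.lfilter(b, a, x, axis=0, zi=zi[:, None] * x0[None, :])
    return y[:, 0] if squeeze else y


def _frame_power_db(envelope: np.ndarray, fs: float, frame_len: int,
                    ref_power: float) -> np.ndarray:
    """Mean periodogram PSD level per non-overlapping frame, summed over
    channels and averaged over frequency bins, in dB relative to
    ``ref_power``.

    Averaging over frequency (rather than summing) makes this a true
    spectral-density level (dB/Hz), independent of the frame length.
    """
    n_frames = envelope.shape[0] // frame_len
    power = np.empty(n_frames)
    for i in range(n_frames):
        frame = envelope[i * frame_len:(i + 1) * frame_len]
        _, pxx = sps.periodogram(frame, fs=fs, axis=0)
        power[i] = pxx.sum(axis=1).mean()
    return 10.0 * np.log10(np.maximum(power, 1e-300) / ref_power)


def detect_activity(envelope: np.ndarray, fs: float,
                    frame_len: int = DEFAULT_FRAME_LEN,
                    threshold_db: float = DEFAULT_THRESHOLD_DB,
                    ref_power: float = 1.0,
                    ) -> Optional[tuple[int, int]]:
    """Locate the muscle-activity interval by short-time spectral power.

    The envelope is cut into non-overlapping frames (hop = frame length);
    per frame, the periodogram PSD summed over frequencies and channels is
    converted to dB relative to ``ref_power``.  Frames above ``threshold_db``
    are active; the interval spanned by the first through last active frame
    is returned as half-open sample indices.  Returns ``None`` when no frame
    is active, so callers can emit the No-Gesture class instead of raising.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.ndim == 1:
        envelope = envelope[:, None]
    if envelope.shape[0] < frame_len:
        raise ValueError(
            f"envelope of {envelope.shape[0]} samples is shorter than one "
            f"frame ({frame_len})")
    db = _frame_power_db(envelope, fs, frame_len, ref_power)
    active = np.flatnonzero(db > threshold_db)
    if active.size == 0:
        return None
    start = int(active[0]) * frame_len
    end = min((int(active[-1]) + 1) * frame_len, envelope.shape[0])
    return start, end


def preprocess(recording: Recording,
               spec: FilterSpec = FilterSpec(),
               full_scale: int = DEFAULT_FULL_SCALE,
               frame_len: int = DEFAULT_FRAME_LEN,
               threshold_db: float = DEFAULT_THRESHOLD_DB,
               trim: bool = False) -> PreprocessedSignal:
    """normalize -> rectify -> lowpass -> detect_activity.

    With ``trim=True`` (training use) the returned envelope is cut to the
    detected activity interval, removing the relaxed head and tail; with
    ``trim=False`` (streaming use) the full envelope is kept and the
    interval is metadata only.  A recording with no detected activity
    yields an empty activity interval (and, if trimming, an empty envelope).
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    env = lowpass(rectify(normalize(recording.samples, full_scale)), spec)
    interval = detect_activity(env, recording.fs, frame_len, threshold_db)
    if interval is None:
        start = end = 0
    else:
        start, end = interval
    if trim:
        return PreprocessedSignal(envelope=env[start:end], fs=recording.fs,
                                  activity_start=start, activity_end=end,
                                  source_length=recording.n_samples,
                                  trimmed=True,
                                  gesture_label=recording.gesture_label)
    return PreprocessedSignal(envelope=env, fs=recording.fs,
                              activity_start=start, activity_end=end,
                              source_length=recording.n_samples,
                              trimmed=False,
                              gesture_label=recording.gesture_label)
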