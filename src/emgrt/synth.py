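"""Synthetic multichannel surface-EMG generator.

Emulates an 8-channel armband recording protocol: each repetition is a
relax-gesture-relax sequence in which a short burst of muscle activity is
embedded in rest-state baseline noise.  The burst is modelled as zero-mean
white carrier noise amplitude-modulated by a raised-cosine envelope and
scaled per channel by a gesture-specific gain profile; samples are quantized
to the signed integer range of the sensor (8 bits by default).

The generator records the true envelope support (onset/offset sample
indices), which gives downstream latency measurements an unambiguous
reference that is independent of any activity detector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SynthConfig",
    "Recording",
    "default_gain_profiles",
    "generate_repetition",
    "generate_dataset",
]


def default_gain_profiles(n_gestures: int, n_channels: int,
                          dominant: float = 1.0,
                          background: float = 0.1) -> np.ndarray:
    """One-hot-dominant per-gesture channel gain profiles.

    Gesture ``g`` (1-based) activates channel ``(g-1) % n_channels`` at
    ``dominant`` gain and every other channel at ``background`` gain, giving
    ``n_gestures`` mutually distinct activation patterns.
    """
    profiles = np.full((n_gestures, n_channels), background, dtype=float)
    for g in range(n_gestures):
        profiles[g, g % n_channels] = dominant
    return profiles


@dataclass
class SynthConfig:
    """Parameters of the synthetic sEMG session generator.

    Amplitudes (`baseline_noise_std`, `burst_noise_std`) are in raw sensor
    units, i.e. on the signed integer scale implied by `quantization_bits`.
    `onset_delay_s` is the (min, max) of the uniformly drawn relax head
    before the gesture burst; the protocol being emulated has subjects start
    relaxed and perform the gesture promptly after recording begins.
    """

    n_channels: int = 8
    fs: float = 200.0
    n_gestures: int = 5
    gain_profiles: Optional[np.ndarray] = None
    burst_duration_s: float = 0.7
    burst_jitter: float = 0.2          # fractional jitter on burst duration
    envelope_rise_s: float = 0.08      # raised-cosine rise/fall time
    onset_delay_s: tuple[float, float] = (0.10, 0.35)
    baseline_noise_std: float = 2.0
    burst_noise_std: float = 35.0
    quantization_bits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_profiles is None:
            self.gain_profiles = default_gain_profiles(self.n_gestures,
                                                       self.n_channels)
        self.gain_profiles = np.asarray(self.gain_profiles, dtype=float)
        self.validate()

    def validate(self) -> None:
        gp = self.gain_profiles
        if gp.shape != (self.n_gestures, self.n_channels):
            raise ValueError(
                f"gain_profiles shape {gp.shape} != "
                f"({self.n_gestures}, {self.n_channels})")
        if np.any(gp < 0) or np.any(gp > 1):
            raise ValueError("gain_profiles entries must lie in [0, 1]")
        for a in range(self.n_gestures):
            for b in range(a + 1, self.n_gestures):
                if np.array_equal(gp[a], gp[b]):
                    raise ValueError(
                        f"gain profiles for gestures {a + 1} and {b + 1} "
                        "are identical; gestures must be separable")
        if self.quantization_bits < 2:
            raise ValueError("quantization_bits must be >= 2")
        if self.burst_duration_s <= 2 * self.envelope_rise_s:
            raise ValueError("burst_duration_s must exceed twice the "
                             "envelope rise time")

    @property
    def quant_min(self) -> int:
        return -(2 ** (self.quantization_bits - 1))

    @property
    def quant_max(self) -> int:
        return 2 ** (self.quantization_bits - 1) - 1

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Recording:
    """One repetition: integer samples (N x channels) plus ground truth.

    ``gesture_label`` is 1..n_gestures for a gesture repetition and 0 for a
    pure-rest recording.  ``true_onset``/``true_offset`` delimit the burst
    envelope support as a half-open sample interval; both are ``None`` for
    pure rest.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "synthetic"
    gesture_label: int = 0
    repetition_index: int = 0
    true_onset: Optional[int] = None
    true_offset: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (N x channels) array")
        if (self.true_onset is None) != (self.true_offset is None):
            raise ValueError("true_onset and true_offset must be set together")
        if self.true_onset is not None:
            n = self.samples.shape[0]
            if not (0 <= self.true_onset < self.true_offset <= n):
                raise ValueError(
                    f"invalid burst interval [{self.true_onset}, "
                    f"{self.true_offset}) for {n} samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _raised_cosine_envelope(burst_len: int, rise_len: int) -> np.ndarray:
    """Smooth burst envelope: cosine ramp up, plateau at 1, cosine ramp down."""
    env = np.ones(burst_len)
    if rise_len > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, rise_len + 1) / rise_len))
        env[:rise_len] = ramp
        env[burst_len - rise_len:] = ramp[::-1]
    return env


def quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Round half away from zero and clip to the signed `bits`-bit range."""
    q = np.sign(x) * np.floor(np.abs(x) + 0.5)
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    return np.clip(q, lo, hi).astype(np.int64)


def generate_repetition(config: SynthConfig, gesture: int,
                        total_duration_s: float,
                        rng: Optional[np.random.Generator] = None,
                        repetition_index: int = 0,
                        subject_id: str = "synthetic") -> Recording:
    """Generate one relax-gesture-relax repetition.

    ``gesture`` in 1..n_gestures embeds a burst; ``gesture = 0`` produces a
    pure-rest recording (baseline noise only, no burst, no onset/offset).

    Raises ``ValueError`` when the burst (plus the relax head) cannot fit in
    ``total_duration_s``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not 0 <= gesture <= config.n_gestures:
        raise ValueError(f"gesture must be in 0..{config.n_gestures}, "
                         f"got {gesture}")
    n = int(round(total_duration_s * config.fs))
    if n < 1:
        raise ValueError("total_duration_s too short")

    samples = rng.normal(0.0, config.baseline_noise_std,
                         size=(n, config.n_channels))

    onset = offset = None
    if gesture >= 1:
        jitter = config.burst_jitter * rng.uniform(-1.0, 1.0)
        burst_len = int(round(config.burst_duration_s * (1.0 + jitter)
                              * config.fs))
        rise_len = int(round(config.envelope_rise_s * config.fs))
        burst_len = max(burst_len, 2 * rise_len + 1)
        delay = rng.uniform(*config.onset_delay_s)
        onset = int(round(delay * config.fs))
        offset = onset + burst_len
        if offset > n:
            raise ValueError(
                f"burst of {burst_len} samples starting at {onset} does not "
                f"fit in a {n}-sample recording; increase total_duration_s")
        env = _raised_cosine_envelope(burst_len, rise_len)
        gains = config.gain_profiles[gesture - 1]
        carrier = rng.normal(0.0, 1.0, size=(burst_len, config.n_channels))
        samples[onset:offset] += (env[:, None] * carrier
                                  * config.burst_noise_std * gains[None, :])

    return Recording(samples=quantize(samples, config.quantization_bits),
                     fs=config.fs, subject_id=subject_id,
                     gesture_label=gesture,
                     repetition_index=repetition_index,
                     true_onset=onset, true_offset=offset)


def generate_dataset(config: SynthConfig,
                     reps_per_gesture_train: int,
                     reps_per_gesture_test: int,
                     train_duration_s: float = 2.0,
                     test_duration_s: float = 5.0,
                     rest_reps_train: int = 0,
                     rest_reps_test: int = 0,
                     subject_id: str = "synthetic",
                     ) -> tuple[list[Recording], list[Recording]]:
    """Generate labeled train/test splits over all gestures.

    Reproduces the acquisition design of a short training recording and a
    longer testing recording per repetition; gesture split sizes are
    exactly ``n_gestures * reps`` each.  ``rest_reps_*`` optionally append
    pure-rest (class 0) repetitions, which give the classifier genuine
    No-Gesture examples including the rest pattern at stream start.
    Fully deterministic given ``config.seed``.
    """
    if reps_per_gesture_train < 1 or reps_per_gesture_test < 1:
        raise ValueError("repetition counts must be >= 1")
    if rest_reps_train < 0 or rest_reps_test < 0:
        raise ValueError("rest repetition counts must be >= 0")
    rng = np.random.default_rng(config.seed)
    train: list[Recording] = []
    test: list[Recording] = []
    for split, reps, rest_reps, dur in (
            (train, reps_per_gesture_train, rest_reps_train,
             train_duration_s),
            (test, reps_per_gesture_test, rest_reps_test, test_duration_s)):
        for gesture in range(1, config.n_gestures + 1):
            for rep in range(reps):
                split.append(generate_repetition(
                    config, gesture, dur, rng=rng,
                    repetition_index=rep, subject_id=subject_id))
        for rep in range(rest_reps):
            split.append(generate_repetition(
                config, 0, dur, rng=rng,
                repetition_index=rep, subject_id=subject_id))
    return train, test
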