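"""Sliding-window segmentation and time-domain feature extraction.

Each classifier observation is a dense sliding window over the preprocessed
envelope.  Per channel, five classical time-domain descriptors are computed
— mean absolute value (MAV), root mean square (RMS), a slope-sign-change
statistic (SSC), waveform length (WL), and the three Hjorth parameters
(activity, mobility, complexity) — and stacked, together with the raw window
samples, into the feature matrix ``D`` of shape (l+7) x channels.  The
flattened, channel-major form of ``D`` is the network input.

Two formula choices follow the source method exactly rather than the more
common conventions, with the conventional variants provided alongside:

* ``ssc`` is the sum of absolute products of adjacent slopes,
  sum_k |(s(k)-s(k-1)) * (s(k)-s(k+1))|, not an indicator count
  (see ``ssc_count`` for the count form);
* Hjorth ``activity`` is sum(s^2)/(N-1) with no mean subtraction
  (see ``activity_centered`` for the centered variance form).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import PreprocessedSignal

__all__ = [
    "WindowSpec",
    "FeatureWindow",
    "FEATURE_NAMES",
    "mav",
    "rms",
    "ssc",
    "ssc_count",
    "wl",
    "hjorth",
    "activity_centered",
    "window_features",
    "sliding_windows",
    "batch_features",
    "build_training_set",
    "save_features",
    "load_features",
]

#: Order of the seven per-channel feature rows appended below the window rows.
FEATURE_NAMES = ("mav", "rms", "ssc", "wl",
                 "hjorth_activity", "hjorth_mobility", "hjorth_complexity")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 400 ms windows advanced by one sample
    (5 ms) at the default 200 Hz rate."""

    length_samples: int = 80
    stride_samples: int = 1

    def __post_init__(self) -> None:
        if self.length_samples < 3:
            raise ValueError("window length must be >= 3 samples "
                             "(slope and derivative features need 3)")
        if self.stride_samples < 1:
            raise ValueError("stride must be >= 1")

    def count(self, n_samples: int) -> int:
        """Number of full windows in a signal of ``n_samples``."""
        if n_samples < self.length_samples:
            return 0
        return (n_samples - self.length_samples) // self.stride_samples + 1


@dataclass
class FeatureWindow:
    """One observation: feature matrix D ((l+7) x channels) and its
    channel-major flattening (all rows of channel 1, then channel 2, ...)."""

    D: np.ndarray
    flat: np.ndarray
    window_start: int = 0
    label: Optional[int] = None


def _as_window(x, min_len: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} expects a 1-D window")
    if x.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} samples, "
                         f"got {x.size}")
    return x


def mav(window_channel) -> float:
    """Mean absolute value: (1/N) sum |s(k)|."""
    x = _as_window(window_channel, 1, "mav")
    return float(np.mean(np.abs(x)))


def rms(window_channel) -> float:
    """Root mean square: sqrt((1/N) sum s(k)^2)."""
    x = _as_window(window_channel, 1, "rms")
    return float(np.sqrt(np.mean(x * x)))


def ssc(window_channel) -> float:
    """Slope-sign-change statistic: sum_{k=2..N-1} |(s(k)-s(k-1)) * (s(k)-s(k+1))|."""
    x = _as_window(window_channel, 3, "ssc")
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    return float(np.sum(np.abs(d_prev * d_next)))


def ssc_count(window_channel, threshold: float = 0.0) -> int:
    """Conventional SSC: count of interior samples where the slope changes
    sign, with the product magnitude above ``threshold``."""
    x = _as_window(window_channel, 3, "ssc_count")
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    prod = d_prev * d_next
    return int(np.count_nonzero(prod > threshold))


def wl(window_channel) -> float:
    """Waveform length: sum_{k=2..N} |s(k) - s(k-1)|."""
    x = _as_window(window_channel, 2, "wl")
    return float(np.sum(np.abs(np.diff(x))))


def _uncentered_var(x: np.ndarray) -> float:
    # sum(x^2)/(len-1), denominator floored at 1 for the length-1 edge case
    return float(np.sum(x * x) / max(x.size - 1, 1))


def hjorth(window_channel) -> tuple[float, float, float]:
    """Hjorth activity, mobility, complexity with first-difference derivatives.

    activity = sum(s^2)/(N-1) (uncentered); mobility =
    sqrt(VAR(ds)/VAR(s)); complexity = mobility(ds)/mobility(s), which is 1
    for a pure sinusoid and grows with waveform irregularity.

    Raises on a constant (zero-variance) window; a window whose first
    difference has zero variance yields complexity 0 by convention.
    """
    x = _as_window(window_channel, 3, "hjorth")
    var_s = _uncentered_var(x)
    if var_s == 0.0:
        raise ValueError("degenerate (constant-zero) window: "
                         "Hjorth mobility undefined")
    d1 = np.diff(x)
    var_d1 = _uncentered_var(d1)
    mobility = float(np.sqrt(var_d1 / var_s))
    if var_d1 == 0.0:
        return var_s, mobility, 0.0
    d2 = np.diff(d1)
    var_d2 = _uncentered_var(d2)
    mobility_d = float(np.sqrt(var_d2 / var_d1))
    return var_s, mobility, mobility_d / mobility


def activity_centered(window_channel) -> float:
    """Conventional Hjorth activity: sample variance with mean subtraction."""
    x = _as_window(window_channel, 2, "activity_centered")
    return float(np.var(x, ddof=1))


def window_features(window: np.ndarray, window_start: int = 0,
                    label: Optional[int] = None) -> FeatureWindow:
    """Stack the l window rows with the 7 feature rows into D and flatten.

    D rows 1..l are the envelope samples; rows l+1..l+7 are, per channel,
    MAV, RMS, SSC, WL, Hjorth activity/mobility/complexity.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be 2-D (l x channels)")
    l, n_ch = window.shape
    if l < 3:
        raise ValueError("window must have at least 3 rows")
    feats = np.empty((7, n_ch))
    for ch in range(n_ch):
        col = window[:, ch]
        a, m, c = hjorth(col)
        feats[:, ch] = (mav(col), rms(col), ssc(col), wl(col), a, m, c)
    D = np.vstack([window, feats])
    return FeatureWindow(D=D, flat=np.ravel(D, order="F"),
                         window_start=window_start, label=label)


def sliding_windows(envelope: np.ndarray, spec: WindowSpec = WindowSpec()
                    ) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (start, window view) for starts 0, stride, 2*stride, ... while
    the window fits.  A signal shorter than one window yields nothing."""
    envelope = np.asarray(envelope)
    n = envelope.shape[0]
    l, s = spec.length_samples, spec.stride_samples
    for i in range(0, n - l + 1, s):
        yield i, envelope[i:i + l]


def batch_features(envelope: np.ndarray, spec: WindowSpec = WindowSpec(),
                   start_offset: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized feature extraction over all sliding windows.

    Returns ``(starts, X, degenerate)`` where ``X`` has one channel-major
    flat vector per window and ``degenerate`` flags windows with a
    zero-variance channel (their Hjorth rows are set to 0; callers decide
    whether to drop, reject, or treat them as rest).  ``starts`` are window
    start indices offset by ``start_offset``.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.ndim != 2:
        raise ValueError("envelope must be 2-D (samples x channels)")
    n, n_ch = envelope.shape
    l, stride = spec.length_samples, spec.stride_samples
    n_win = spec.count(n)
    if n_win == 0:
        return (np.empty(0, dtype=int),
                np.empty((0, n_ch * (l + 7))),
                np.empty(0, dtype=bool))
    # (n_win, l, n_ch) view; stride applied on the window axis
    w = sliding_window_view(envelope, l, axis=0)[::stride]
    w = np.swapaxes(w, 1, 2)
    starts = np.arange(n_win) * stride + start_offset

    absw = np.abs(w)
    f_mav = absw.mean(axis=1)
    f_rms = np.sqrt(np.mean(w * w, axis=1))
    d_prev = w[:, 1:-1] - w[:, :-2]
    d_next = w[:, 1:-1] - w[:, 2:]
    f_ssc = np.abs(d_prev * d_next).sum(axis=1)
    d1 = np.diff(w, axis=1)
    f_wl = np.abs(d1).sum(axis=1)

    var_s = (w * w).sum(axis=1) / (l - 1)
    var_d1 = (d1 * d1).sum(axis=1) / max(l - 2, 1)
    d2 = np.diff(d1, axis=1)
    var_d2 = (d2 * d2).sum(axis=1) / max(l - 3, 1)
    bad_s = var_s == 0.0
    bad_d1 = var_d1 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_mob = np.sqrt(var_d1 / var_s)
        f_comp = np.sqrt(var_d2 / var_d1) / f_mob
    f_mob[bad_s] = 0.0
    f_comp[bad_s | bad_d1] = 0.0
    degenerate = bad_s.any(axis=1)

    feats = np.stack([f_mav, f_rms, f_ssc, f_wl, var_s, f_mob, f_comp],
                     axis=1)                       # (n_win, 7, n_ch)
    D = np.concatenate([w, feats], axis=1)         # (n_win, l+7, n_ch)
    X = D.transpose(0, 2, 1).reshape(n_win, n_ch * (l + 7))
    return starts, X, degenerate


def build_training_set(preprocessed: Sequence[PreprocessedSignal],
                       spec: WindowSpec = WindowSpec(),
                       include_rest: bool = True,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the labeled window-feature matrix from preprocessed repetitions.

    Windows fully inside a repetition's activity interval receive its
    gesture label; with ``include_rest``, windows fully outside activity
    receive label 0 (No-Gesture).  Windows straddling the activity boundary
    are excluded as ambiguous.  Degenerate (zero-variance) windows are
    dropped; raises if no windows are produced at all.
    """
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for sig in preprocessed:
        label = sig.gesture_label if sig.gesture_label is not None else 0
        env = sig.envelope
        if sig.trimmed:
            act_lo, act_hi = 0, env.shape[0]
        else:
            act_lo = sig.activity_start
            act_hi = sig.activity_end
        if label != 0 and act_hi <= act_lo:
            raise ValueError(
                "gesture repetition with empty activity interval; "
                "preprocess with trimming/detection before training")
        # windows fully inside activity -> gesture label
        if act_hi > act_lo:
            _, X, degen = batch_features(env[act_lo:act_hi], spec, act_lo)
            if X.shape[0]:
                xs.append(X[~degen])
                ys.append(np.full(int((~degen).sum()), label, dtype=int))
        if include_rest and not sig.trimmed:
            for lo, hi in ((0, act_lo), (act_hi, env.shape[0])):
                if hi - lo <= 0:
                    continue
                _, X, degen = batch_features(env[lo:hi], spec, lo)
                if X.shape[0]:
                    xs.append(X[~degen])
                    ys.append(np.zeros(int((~degen).sum()), dtype=int))
    if not xs or sum(x.shape[0] for x in xs) == 0:
        raise ValueError("no training windows produced; signals shorter "
                         "than one window?")
    return np.concatenate(xs, axis=0), np.concatenate(ys)


def save_features(path, X: np.ndarray, y: np.ndarray, spec: WindowSpec,
                  fs: float) -> None:
    """Persist a labeled feature matrix as delimited text (label in the
    first column) plus a JSON sidecar describing the layout."""
    import json
    from pathlib import Path

    path = Path(path)
    data = np.column_stack([np.asarray(y, dtype=float), X])
    np.savetxt(path, data, delimiter="\t")
    sidecar = {
        "window_length_samples": spec.length_samples,
        "stride_samples": spec.stride_samples,
        "fs": fs,
        "flattening": "channel-major",
        "feature_rows": list(FEATURE_NAMES),
        "columns": "label, then 8*(l+7) flat feature values",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar,
                                                                  indent=2))


def load_features(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Inverse of :func:`save_features`: returns (X, y, sidecar)."""
    import json
    from pathlib import Path

    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return data[:, 1:], data[:, 0].astype(int), sidecar
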