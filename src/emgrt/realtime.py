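"""Streaming vote-threshold decision layer ("answering racer").

Each sliding window is classified independently; per-class vote counters
accumulate the window labels, and the first class whose counter reaches the
activation threshold tau wins and is emitted as the recognized gesture.  If
no counter reaches tau by the end of the stream, the decision is class 0
(No-Gesture).  Because the decision can fire while the gesture is still in
progress, the response latency — measured in signal time from gesture onset
to the right edge of the deciding window — is typically a fraction of the
gesture duration.

The reach-the-threshold comparison is ">= tau" (the operational rule);
a strict ">" variant is available via ``strict=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .ann import MLPModel, predict
from .features import WindowSpec, batch_features
from .preprocess import (DEFAULT_FRAME_LEN, DEFAULT_FULL_SCALE,
                         DEFAULT_THRESHOLD_DB, FilterSpec, preprocess)
from .synth import Recording

__all__ = [
    "DEFAULT_TAU",
    "VoteState",
    "GestureDecision",
    "reset",
    "update",
    "finalize",
    "classify_windows",
    "stream_recognize",
]

#: Default activation-time threshold: number of per-window votes a class
#: must collect before the stream commits to it.
DEFAULT_TAU = 40


@dataclass
class VoteState:
    """Per-class vote counters with activation threshold tau."""

    counts: np.ndarray
    tau: int
    strict: bool = False
    windows_seen: int = 0
    decided: bool = False
    decided_label: Optional[int] = None
    decision_window_index: Optional[int] = None

    @property
    def n_classes(self) -> int:
        return self.counts.size


@dataclass
class GestureDecision:
    """Emitted label plus, when available, the decision time.

    ``decision_sample`` is the right edge (exclusive) of the deciding
    window in absolute sample indices — the earliest sample at which the
    decision is causally computable.  ``response_ms`` is signal time from
    ``onset_sample`` to ``decision_sample``.
    """

    label: int
    decision_sample: Optional[int] = None
    onset_sample: Optional[int] = None
    response_ms: Optional[float] = None


def reset(c: int, tau: int = DEFAULT_TAU, strict: bool = False) -> VoteState:
    """Fresh vote state: all counters zero, undecided."""
    if c < 2:
        raise ValueError("need at least 2 classes")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return VoteState(counts=np.zeros(c, dtype=int), tau=tau, strict=strict)


def update(state: VoteState, window_label: int,
           window_index: int) -> VoteState:
    """Count one window vote; commit when the label's counter reaches tau.

    The first class to reach the threshold wins (ties are resolved by
    arrival order).  A vote for class 0 counts in N_0, and N_0 reaching tau
    decides No-Gesture.  Updating an already-decided state is an error:
    callers must reset between repetitions.
    """
    if state.decided:
        raise ValueError("vote state already decided; reset() before reuse")
    if not 0 <= window_label < state.n_classes:
        raise ValueError(f"label {window_label} out of range "
                         f"0..{state.n_classes - 1}")
    state.counts[window_label] += 1
    state.windows_seen += 1
    threshold = state.tau + 1 if state.strict else state.tau
    if state.counts[window_label] >= threshold:
        state.decided = True
        state.decided_label = int(window_label)
        state.decision_window_index = int(window_index)
    return state


def finalize(state: VoteState) -> int:
    """End-of-stream label: the decided class, else 0 (No-Gesture) when no
    counter reached tau."""
    if state.decided:
        return int(state.decided_label)
    return 0


def classify_windows(model: MLPModel, recording: Recording,
                     filter_spec: FilterSpec = FilterSpec(),
                     window_spec: WindowSpec = WindowSpec(),
                     full_scale: int = DEFAULT_FULL_SCALE,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Causally preprocess a recording and classify every sliding window.

    Returns ``(starts, labels)`` in stream order.  Degenerate
    (zero-variance) windows — possible only on an identically-flat signal —
    are labeled 0 (rest) without consulting the classifier.  Window labels
    are identical whether computed in batch or streamed, because the causal
    filter and the per-window features depend only on past samples.
    """
    sig = preprocess(recording, filter_spec, full_scale=full_scale, trim=False)
    starts, X, degenerate = batch_features(sig.envelope, window_spec)
    if X.shape[0] == 0:
        return starts, np.empty(0, dtype=int)
    labels = np.empty(X.shape[0], dtype=int)
    ok = ~degenerate
    if ok.any():
        labels[ok] = predict(model, X[ok])
    labels[degenerate] = 0
    return starts, labels


def stream_recognize(model: MLPModel, recording: Recording,
                     filter_spec: FilterSpec = FilterSpec(),
                     window_spec: WindowSpec = WindowSpec(),
                     tau: int = DEFAULT_TAU,
                     onset_sample: Optional[int] = None,
                     full_scale: int = DEFAULT_FULL_SCALE,
                     strict: bool = False) -> GestureDecision:
    """Run the full streaming pipeline on one repetition.

    Windows are consumed in stream order from the first available window of
    the recording; the decision fires at the first window whose label's
    counter reaches ``tau``.  ``onset_sample`` is the latency reference
    (defaults to the recording's ground-truth onset when present; pass the
    output of activity detection for real data).  A recording shorter than
    one window, or a stream in which no class reaches tau, yields label 0
    with no decision time.
    """
    if onset_sample is None:
        onset_sample = recording.true_onset
    starts, labels = classify_windows(model, recording, filter_spec,
                                      window_spec, full_scale)
    state = reset(model.output_dim, tau, strict=strict)
    for j, lab in enumerate(labels):
        update(state, int(lab), j)
        if state.decided:
            break
    label = finalize(state)
    if not state.decided:
        return GestureDecision(label=0, onset_sample=onset_sample)
    j = state.decision_window_index
    decision_sample = int(starts[j]) + window_spec.length_samples
    response_ms = None
    if onset_sample is not None:
        response_ms = max(0.0, (decision_sample - onset_sample)
                          * 1000.0 / recording.fs)
    return GestureDecision(label=label, decision_sample=decision_sample,
                           onset_sample=onset_sample,
                           response_ms=response_ms)
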