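"""Evaluation harness: confusion matrix, response times, parameter sweeps.

Accuracy is computed over gesture repetitions with the repetitions decided
as No-Gesture counted as errors.  Response times (signal-time latency from
gesture onset to the vote commitment) are averaged separately over
correctly and incorrectly decided repetitions, since the appropriate
averaging set is application-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ann import MLPModel, TrainConfig, init_model, train
from .features import WindowSpec, build_training_set
from .preprocess import (DEFAULT_FRAME_LEN, DEFAULT_THRESHOLD_DB, FilterSpec,
                         preprocess)
from .realtime import (DEFAULT_TAU, GestureDecision, classify_windows,
                       finalize, reset, update)
from .synth import Recording

__all__ = [
    "EvalReport",
    "SweepResult",
    "evaluate",
    "train_pipeline",
    "recognize_all",
    "sweep_window",
    "sweep_threshold",
]


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = prediction, class 0 included)
    with per-class sensitivity/precision, overall accuracy over gesture
    rows, and mean response times."""

    confusion: np.ndarray
    per_class_sensitivity: np.ndarray     # NaN where the row is empty
    per_class_precision: np.ndarray       # NaN where the column is empty
    overall_accuracy: float
    mean_response_ms: Optional[float]     # over correctly decided reps
    mean_response_ms_incorrect: Optional[float]
    per_gesture_response_ms: dict[int, Optional[float]] = field(
        default_factory=dict)
    n_no_gesture: int = 0

    def to_dict(self) -> dict:
        def _clean(v):
            if v is None:
                return None
            v = float(v)
            return None if np.isnan(v) else v

        return {
            "confusion": self.confusion.tolist(),
            "per_class_sensitivity": [
                _clean(v) for v in self.per_class_sensitivity],
            "per_class_precision": [
                _clean(v) for v in self.per_class_precision],
            "overall_accuracy": float(self.overall_accuracy),
            "mean_response_ms": _clean(self.mean_response_ms),
            "mean_response_ms_incorrect": _clean(
                self.mean_response_ms_incorrect),
            "per_gesture_response_ms": {
                str(k): _clean(v)
                for k, v in self.per_gesture_response_ms.items()},
            "n_no_gesture": int(self.n_no_gesture),
        }


@dataclass
class SweepResult:
    """Accuracy and latency curves over a strictly increasing parameter grid."""

    parameter: str
    grid: list
    accuracy: list[float]
    mean_response_ms: list[Optional[float]]

    def __post_init__(self) -> None:
        g = list(self.grid)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("sweep grid must be strictly increasing")


def evaluate(truths: Sequence[int],
             decisions: Sequence[GestureDecision],
             n_classes: int = 6) -> EvalReport:
    """Build the evaluation report from per-repetition truths and decisions.

    Overall accuracy = correct gesture repetitions / all gesture
    repetitions; a gesture repetition decided as class 0 lands in the
    No-Gesture column and counts as an error.
    """
    if len(truths) == 0:
        raise ValueError("no decisions to evaluate")
    if len(truths) != len(decisions):
        raise ValueError("truths and decisions must align")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    responses_correct: list[float] = []
    responses_incorrect: list[float] = []
    per_gesture: dict[int, list[float]] = {g: [] for g in range(1, n_classes)}
    for truth, dec in zip(truths, decisions):
        if not 0 <= truth < n_classes:
            raise ValueError(f"truth label {truth} out of range "
                             f"0..{n_classes - 1}")
        confusion[truth, dec.label] += 1
        if dec.response_ms is not None:
            if dec.label == truth:
                responses_correct.append(dec.response_ms)
                if truth >= 1:
                    per_gesture[truth].append(dec.response_ms)
            else:
                responses_incorrect.append(dec.response_ms)

    row_sums = confusion.sum(axis=1)
    col_sums = confusion.sum(axis=0)
    diag = np.diag(confusion)
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(row_sums > 0, diag / row_sums, np.nan)
        precision = np.where(col_sums > 0, diag / col_sums, np.nan)

    gesture_rows = confusion[1:]
    total_gestures = gesture_rows.sum()
    correct_gestures = np.diag(confusion)[1:].sum()
    accuracy = correct_gestures / total_gestures if total_gestures else np.nan

    def _mean(v):
        return float(np.mean(v)) if v else None

    return EvalReport(
        confusion=confusion,
        per_class_sensitivity=sensitivity,
        per_class_precision=precision,
        overall_accuracy=float(accuracy),
        mean_response_ms=_mean(responses_correct),
        mean_response_ms_incorrect=_mean(responses_incorrect),
        per_gesture_response_ms={g: _mean(v) for g, v in per_gesture.items()},
        n_no_gesture=int(gesture_rows[:, 0].sum()),
    )


def train_pipeline(train_recordings: Sequence[Recording],
                   filter_spec: FilterSpec = FilterSpec(),
                   window_spec: WindowSpec = WindowSpec(),
                   train_config: TrainConfig = TrainConfig(),
                   n_classes: int = 6,
                   include_rest: bool = True,
                   frame_len: int = DEFAULT_FRAME_LEN,
                   threshold_db: float = DEFAULT_THRESHOLD_DB) -> MLPModel:
    """Preprocess (with activity detection), window, featurize, and train
    the classifier on a set of repetitions.  Windows inside each detected
    activity interval carry the repetition's gesture label; head/tail and
    pure-rest windows carry label 0 when ``include_rest``."""
    sigs = [preprocess(rec, filter_spec, trim=False, frame_len=frame_len,
                       threshold_db=threshold_db)
            for rec in train_recordings]
    X, y = build_training_set(sigs, window_spec, include_rest=include_rest)
    model = init_model(X.shape[1], n_classes, train_config)
    return train(model, X, y, train_config)


def recognize_all(model: MLPModel, test_recordings: Sequence[Recording],
                  filter_spec: FilterSpec = FilterSpec(),
                  window_spec: WindowSpec = WindowSpec(),
                  tau: int = DEFAULT_TAU,
                  ) -> tuple[list[int], list[GestureDecision]]:
    """Stream-recognize every test repetition against its true onset."""
    from .realtime import stream_recognize

    truths, decisions = [], []
    for rec in test_recordings:
        truths.append(rec.gesture_label)
        decisions.append(stream_recognize(model, rec, filter_spec,
                                          window_spec, tau))
    return truths, decisions


def sweep_window(train_recordings: Sequence[Recording],
                 test_recordings: Sequence[Recording],
                 window_lengths: Sequence[int],
                 tau: int = DEFAULT_TAU,
                 filter_spec: FilterSpec = FilterSpec(),
                 train_config: TrainConfig = TrainConfig(),
                 stride: int = 1,
                 n_classes: int = 6) -> SweepResult:
    """Full retrain and re-evaluation per window length (fixed seeds), for
    studying the accuracy/latency trade-off of the window size."""
    accuracies: list[float] = []
    latencies: list[Optional[float]] = []
    for l in window_lengths:
        wspec = WindowSpec(length_samples=int(l), stride_samples=stride)
        model = train_pipeline(train_recordings, filter_spec, wspec,
                               train_config, n_classes)
        truths, decisions = recognize_all(model, test_recordings,
                                          filter_spec, wspec, tau)
        report = evaluate(truths, decisions, n_classes)
        accuracies.append(report.overall_accuracy)
        latencies.append(report.mean_response_ms)
    return SweepResult(parameter="window_length_samples",
                       grid=list(window_lengths),
                       accuracy=accuracies, mean_response_ms=latencies)


def _replay_votes(labels: np.ndarray, starts: np.ndarray, n_classes: int,
                  tau: int, window_len: int, fs: float,
                  onset: Optional[int]) -> GestureDecision:
    state = reset(n_classes, tau)
    for j, lab in enumerate(labels):
        update(state, int(lab), j)
        if state.decided:
            break
    if not state.decided:
        return GestureDecision(label=0, onset_sample=onset)
    decision_sample = int(starts[state.decision_window_index]) + window_len
    response = None
    if onset is not None:
        response = max(0.0, (decision_sample - onset) * 1000.0 / fs)
    return GestureDecision(label=finalize(state),
                           decision_sample=decision_sample,
                           onset_sample=onset, response_ms=response)


def sweep_threshold(model: MLPModel,
                    test_recordings: Sequence[Recording],
                    taus: Sequence[int],
                    filter_spec: FilterSpec = FilterSpec(),
                    window_spec: WindowSpec = WindowSpec(),
                    n_classes: Optional[int] = None) -> SweepResult:
    """Accuracy/latency versus activation threshold tau.

    The per-window label streams are computed once and the vote layer is
    replayed per tau, which is exactly equivalent to re-running the full
    stream (the window labels do not depend on tau).
    """
    c = n_classes or model.output_dim
    cached = []
    for rec in test_recordings:
        starts, labels = classify_windows(model, rec, filter_spec,
                                          window_spec)
        cached.append((rec, starts, labels))
    accuracies: list[float] = []
    latencies: list[Optional[float]] = []
    for tau in taus:
        truths, decisions = [], []
        for rec, starts, labels in cached:
            truths.append(rec.gesture_label)
            decisions.append(_replay_votes(
                labels, starts, c, int(tau),
                window_spec.length_samples, rec.fs, rec.true_onset))
        report = evaluate(truths, decisions, c)
        accuracies.append(report.overall_accuracy)
        latencies.append(report.mean_response_ms)
    return SweepResult(parameter="tau", grid=list(taus),
                       accuracy=accuracies, mean_response_ms=latencies)
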