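"""Single-hidden-layer feedforward classifier trained from scratch.

The network has three layers: the flattened window-feature vector feeds a
hidden layer of floor(input_dim / 2) sigmoid units, which feeds one sigmoid
output unit per class (five gestures plus No-Gesture by default).  Training
is full-batch gradient descent on a cross-entropy cost.  Because the output
units are independent sigmoids, the cost is the sum of per-unit binary
cross-entropies against one-hot targets (scores do not sum to 1); a
softmax/categorical variant is available via ``TrainConfig.loss``.

The feature columns of the window-feature vector span several orders of
magnitude (slope-product sums are tiny, Hjorth complexity can reach tens),
which conditions plain gradient descent very poorly.  ``train`` therefore
fits a per-column z-score standardization on the training set by default
and stores it in the model, so that inference applies the identical affine
map; set ``TrainConfig.standardize=False`` for raw inputs.

Everything is deterministic given the seed, and models round-trip through a
versioned JSON container.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MLPModel",
    "TrainConfig",
    "init_model",
    "forward",
    "cost_and_gradients",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    max_epochs: int = 2000
    tolerance: float = 1e-6     # stop when the epoch cost change falls below
    seed: int = 0
    init_scale: float = 0.05    # uniform weight-initialization half-width
    loss: str = "sigmoid_bce"   # or "softmax_ce"
    standardize: bool = True    # fit per-column z-scoring on the training set

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.loss not in ("sigmoid_bce", "softmax_ce"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class MLPModel:
    """Weights and biases of the 3-layer network.

    ``weights_ih`` is hidden x input, ``weights_ho`` is output x hidden;
    hidden_dim is always floor(input_dim / 2).
    """

    weights_ih: np.ndarray
    bias_h: np.ndarray
    weights_ho: np.ndarray
    bias_o: np.ndarray
    loss: str = "sigmoid_bce"
    input_offset: Optional[np.ndarray] = None   # z-score mean, fitted in train
    input_scale: Optional[np.ndarray] = None    # z-score std, fitted in train
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, i = self.weights_ih.shape
        o, h2 = self.weights_ho.shape
        if h2 != h or self.bias_h.shape != (h,) or self.bias_o.shape != (o,):
            raise ValueError("inconsistent layer dimensions")
        if (self.input_offset is None) != (self.input_scale is None):
            raise ValueError("input_offset and input_scale must be set "
                             "together")
        if self.input_offset is not None and (
                self.input_offset.shape != (i,)
                or self.input_scale.shape != (i,)):
            raise ValueError("input standardization vectors must match "
                             "input_dim")
        for arr in (self.weights_ih, self.bias_h,
                    self.weights_ho, self.bias_o):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite model parameters")

    @property
    def input_dim(self) -> int:
        return self.weights_ih.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.weights_ih.shape[0]

    @property
    def output_dim(self) -> int:
        return self.weights_ho.shape[0]

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.weights_ih.copy(), self.bias_h.copy(),
            self.weights_ho.copy(), self.bias_o.copy(),
            loss=self.loss,
            input_offset=None if self.input_offset is None
            else self.input_offset.copy(),
            input_scale=None if self.input_scale is None
            else self.input_scale.copy(),
            training_meta=dict(self.training_meta))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def init_model(input_dim: int, n_classes: int,
               config: TrainConfig = TrainConfig()) -> MLPModel:
    """Seeded initialization: hidden_dim = floor(input_dim / 2), weights
    uniform in [-init_scale, init_scale], biases zero."""
    if input_dim < 2:
        raise ValueError("input_dim must be >= 2")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    hidden_dim = input_dim // 2
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return MLPModel(
        weights_ih=rng.uniform(-s, s, size=(hidden_dim, input_dim)),
        bias_h=np.zeros(hidden_dim),
        weights_ho=rng.uniform(-s, s, size=(n_classes, hidden_dim)),
        bias_o=np.zeros(n_classes),
        loss=config.loss,
    )


def _standardized(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.input_offset is None:
        return X
    return (X - model.input_offset) / model.input_scale


def _forward_full(model: MLPModel, X: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hidden activations, output pre-activations, output activations.
    ``X`` must already be standardized."""
    a_h = _sigmoid(X @ model.weights_ih.T + model.bias_h)
    z_o = a_h @ model.weights_ho.T + model.bias_o
    if model.loss == "softmax_ce":
        a_o = _softmax(z_o)
    else:
        a_o = _sigmoid(z_o)
    return a_h, z_o, a_o


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Class-score vector (or matrix for a batch of rows).

    With the default per-unit sigmoid output each score lies in (0, 1) but
    the scores are not constrained to sum to 1.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.input_dim:
        raise ValueError(f"input of length {X.shape[1]} does not match "
                         f"model input_dim {model.input_dim}")
    _, _, a_o = _forward_full(model, _standardized(model, X))
    return a_o[0] if single else a_o


def cost_and_gradients(model: MLPModel, X: np.ndarray, T: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy cost (mean over samples, summed over output units) and
    its analytic gradients with respect to all parameters."""
    n = X.shape[0]
    X = _standardized(model, X)
    a_h, z_o, a_o = _forward_full(model, X)
    if model.loss == "softmax_ce":
        # -mean log softmax at the target, computed stably from logits
        zs = z_o - z_o.max(axis=1, keepdims=True)
        log_p = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
        cost = float(-(T * log_p).sum() / n)
    else:
        # per-unit BCE with logits: softplus(z) - t*z
        cost = float((np.logaddexp(0.0, z_o) - T * z_o).sum() / n)
    delta_o = (a_o - T) / n
    delta_h = (delta_o @ model.weights_ho) * a_h * (1.0 - a_h)
    grads = {
        "weights_ho": delta_o.T @ a_h,
        "bias_o": delta_o.sum(axis=0),
        "weights_ih": delta_h.T @ X,
        "bias_h": delta_h.sum(axis=0),
    }
    return cost, grads


def train(model: MLPModel, X: np.ndarray, y: np.ndarray,
          config: TrainConfig = TrainConfig()) -> MLPModel:
    """Full-batch gradient descent on the cross-entropy cost.

    Labels are integers in {0..c-1}, one-hot encoded internally.  Stops
    early when the cost change per epoch falls below ``config.tolerance``.
    Raises on a non-finite cost (divergence) with advice to lower the
    learning rate.  Deterministic: same model, data and config give
    bitwise-identical weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    if y.shape != (X.shape[0],):
        raise ValueError("y must have one label per row of X")
    c = model.output_dim
    if y.min() < 0 or y.max() >= c:
        raise ValueError(f"labels must lie in 0..{c - 1}")
    T = np.zeros((X.shape[0], c))
    T[np.arange(X.shape[0]), y] = 1.0

    m = model.copy()
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0  # constant columns pass through unscaled
        m.input_offset = X.mean(axis=0)
        m.input_scale = sd
    prev_cost = None
    cost = np.inf
    epochs_run = 0
    for epoch in range(config.max_epochs):
        cost, grads = cost_and_gradients(m, X, T)
        if not np.isfinite(cost):
            raise ValueError(
                "training diverged (non-finite cost); try a smaller "
                "learning rate")
        m.weights_ih -= config.learning_rate * grads["weights_ih"]
        m.bias_h -= config.learning_rate * grads["bias_h"]
        m.weights_ho -= config.learning_rate * grads["weights_ho"]
        m.bias_o -= config.learning_rate * grads["bias_o"]
        epochs_run = epoch + 1
        if prev_cost is not None and abs(prev_cost - cost) < config.tolerance:
            break
        prev_cost = cost
    final_cost, _ = cost_and_gradients(m, X, T)
    m.training_meta = {
        "learning_rate": config.learning_rate,
        "epochs_run": epochs_run,
        "max_epochs": config.max_epochs,
        "seed": config.seed,
        "loss": config.loss,
        "standardize": config.standardize,
        "final_cost": float(final_cost),
        "n_samples": int(X.shape[0]),
    }
    return m


def predict(model: MLPModel, x: np.ndarray) -> int | np.ndarray:
    """Argmax class label; ties break toward the lowest label index
    (numpy argmax convention)."""
    scores = forward(model, x)
    if scores.ndim == 1:
        return int(np.argmax(scores))
    return np.argmax(scores, axis=1)


def save_model(model: MLPModel, path) -> None:
    """Write the model to a versioned JSON container (text, portable)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
        "output_dim": model.output_dim,
        "loss": model.loss,
        "weights_ih": model.weights_ih.ravel().tolist(),
        "bias_h": model.bias_h.tolist(),
        "weights_ho": model.weights_ho.ravel().tolist(),
        "bias_o": model.bias_o.tolist(),
        "input_offset": None if model.input_offset is None
        else model.input_offset.tolist(),
        "input_scale": None if model.input_scale is None
        else model.input_scale.tolist(),
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> MLPModel:
    """Load a model saved by :func:`save_model`; validates version and shapes."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}")
    i, h, o = (payload["input_dim"], payload["hidden_dim"],
               payload["output_dim"])
    w_ih = np.asarray(payload["weights_ih"], dtype=float)
    w_ho = np.asarray(payload["weights_ho"], dtype=float)
    if w_ih.size != h * i or w_ho.size != o * h:
        raise ValueError("model file weight arrays inconsistent with "
                         "declared shapes")
    off = payload.get("input_offset")
    scale = payload.get("input_scale")
    return MLPModel(
        weights_ih=w_ih.reshape(h, i),
        bias_h=np.asarray(payload["bias_h"], dtype=float),
        weights_ho=w_ho.reshape(o, h),
        bias_o=np.asarray(payload["bias_o"], dtype=float),
        loss=payload.get("loss", "sigmoid_bce"),
        input_offset=None if off is None else np.asarray(off, dtype=float),
        input_scale=None if scale is None else np.asarray(scale, dtype=float),
        training_meta=payload.get("training_meta", {}),
    )
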