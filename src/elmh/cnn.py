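"""Minimal per-class convolutional network with exact parameter accounting.

The architecture mirrors a spreadsheet-style construction: each class
owns one 3x3 convolution filter with bias, a sigmoid activation, a 2x2
non-overlapping max pool, and a fully connected layer over the pooled
map with its own bias and sigmoid output.  At the default geometry the
44 Likert responses are rescaled to [0, 1] and placed row-major into a
10x10 grid (remaining cells zero); 10 -> 8 (conv, stride 1) -> 4
(pool), so each class carries 9 + 1 filter parameters and 16 + 1
output parameters: 4 x (10 + 17) = 108 in total.

There is no softmax: each class output is an independent sigmoid, the
loss is squared error against one-hot targets, training is full-batch
gradient descent with a fixed learning rate, and prediction takes the
largest output (ties break to the lowest class index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, EstimationError, GeometryError, InputError
from .quadrant import QUADRANTS

__all__ = ["CnnConfig", "CnnParameters", "arrange_input", "forward_pass",
           "count_parameters", "train", "predict", "MicroCNN",
           "save_parameters", "load_parameters"]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CnnConfig:
    """Geometry and training settings of the micro-CNN.

    ``input_side`` is an int for a square grid (the 10x10 default that
    carries the 44 items) or a ``(rows, cols)`` pair for rectangular
    demonstration geometries.
    """

    n_classes: int = 4
    input_side: "int | tuple" = 10
    filter_side: int = 3
    pool_side: int = 2
    learning_rate: float = 2.0
    max_epochs: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        r, c = self.input_shape
        if self.filter_side < 1 or min(r, c) < self.filter_side:
            raise ConfigurationError("input_side must be >= filter_side >= 1")
        cr, cc = self.conv_shape
        if cr % self.pool_side != 0 or cc % self.pool_side != 0:
            raise GeometryError(
                f"conv map {cr}x{cc} is not divisible by pool side "
                f"{self.pool_side}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")

    @property
    def input_shape(self) -> tuple:
        s = self.input_side
        return (s, s) if isinstance(s, int) else (int(s[0]), int(s[1]))

    @property
    def conv_shape(self) -> tuple:
        r, c = self.input_shape
        return (r - self.filter_side + 1, c - self.filter_side + 1)

    @property
    def pooled_shape(self) -> tuple:
        cr, cc = self.conv_shape
        return (cr // self.pool_side, cc // self.pool_side)

    @property
    def pooled_length(self) -> int:
        pr, pc = self.pooled_shape
        return pr * pc


def count_parameters(config: CnnConfig) -> int:
    """Total trainable parameters: C*(f^2+1) + C*(pooled+1); 108 at defaults."""
    c = config.n_classes
    return c * (config.filter_side ** 2 + 1) + c * (config.pooled_length + 1)


@dataclass
class CnnParameters:
    """Per-class filter and pooled-layer weights."""

    filters: np.ndarray       # (C, f, f)
    filter_bias: np.ndarray   # (C,)
    pool_weights: np.ndarray  # (C, pooled_length)
    pool_bias: np.ndarray     # (C,)

    @property
    def n_classes(self) -> int:
        return self.filters.shape[0]

    def count(self) -> int:
        return int(self.filters.size + self.filter_bias.size
                   + self.pool_weights.size + self.pool_bias.size)

    @classmethod
    def zeros(cls, config: CnnConfig) -> "CnnParameters":
        c, f, q = config.n_classes, config.filter_side, config.pooled_length
        return cls(np.zeros((c, f, f)), np.zeros(c),
                   np.zeros((c, q)), np.zeros(c))

    @classmethod
    def random(cls, config: CnnConfig, rng) -> "CnnParameters":
        c, f, q = config.n_classes, config.filter_side, config.pooled_length
        return cls(rng.uniform(-0.5, 0.5, (c, f, f)),
                   rng.uniform(-0.5, 0.5, c),
                   rng.uniform(-0.5, 0.5, (c, q)),
                   rng.uniform(-0.5, 0.5, c))

    def flat(self) -> np.ndarray:
        return np.concatenate([self.filters.ravel(), self.filter_bias,
                               self.pool_weights.ravel(), self.pool_bias])

    @classmethod
    def from_flat(cls, vec, config: CnnConfig) -> "CnnParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.size != count_parameters(config):
            raise InputError("flat parameter vector has wrong length")
        c, f, q = config.n_classes, config.filter_side, config.pooled_length
        i = 0
        filters = vec[i:i + c * f * f].reshape(c, f, f); i += c * f * f
        fb = vec[i:i + c]; i += c
        pw = vec[i:i + c * q].reshape(c, q); i += c * q
        pb = vec[i:i + c]
        return cls(filters, fb, pw, pb)


def arrange_input(responses, likert_min, likert_max,
                  input_side: int = 10) -> np.ndarray:
    """Rescale 44 Likert responses to [0, 1] and place them row-major
    into an ``input_side`` x ``input_side`` grid (remaining cells 0)."""
    r = np.asarray(responses, dtype=float).ravel()
    if r.size > input_side ** 2:
        raise InputError(f"{r.size} responses do not fit a "
                         f"{input_side}x{input_side} grid")
    if r.size == 0:
        raise InputError("empty response vector")
    if np.any(r < likert_min) or np.any(r > likert_max) or \
            not np.all(np.isfinite(r)):
        raise InputError("responses outside the Likert range")
    grid = np.zeros(input_side ** 2)
    grid[:r.size] = (r - likert_min) / (likert_max - likert_min)
    return grid.reshape(input_side, input_side)


def _batch_forward(grids, params: CnnParameters, config: CnnConfig):
    """Vectorized forward pass over a batch of grids.

    Returns (outputs, cache) where outputs is (n, C) and cache holds the
    intermediates needed for backprop.
    """
    n = grids.shape[0]
    f, q = config.filter_side, config.pool_side
    pr, pc = config.pooled_shape
    windows = sliding_window_view(grids, (f, f), axis=(1, 2))  # (n,cr,cc,f,f)
    z = np.einsum("nijkl,ckl->ncij", windows, params.filters) \
        + params.filter_bias[None, :, None, None]
    conv = _sigmoid(z)                                   # (n, C, cr, cc)
    blocks = conv.reshape(n, config.n_classes, pr, q, pc, q) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(n, config.n_classes, pr, pc,
                                             q * q)
    argmax = blocks.argmax(axis=-1)
    pooled = np.take_along_axis(blocks, argmax[..., None], axis=-1)[..., 0]
    pooled_flat = pooled.reshape(n, config.n_classes, -1)  # (n, C, pooled)
    z_out = np.einsum("ncq,cq->nc", pooled_flat, params.pool_weights) \
        + params.pool_bias[None, :]
    outputs = _sigmoid(z_out)
    cache = (windows, conv, blocks, argmax, pooled_flat, outputs)
    return outputs, cache


def forward_pass(grid, params: CnnParameters, config: CnnConfig = None):
    """Forward pass for one input grid.

    Returns ``(outputs, intermediates)``: per-class sigmoid outputs, plus a
    dict with the conv maps, pooled maps and the predicted class index
    (argmax, ties to the lowest index).
    """
    grid = np.asarray(grid, dtype=float)
    if config is None:
        config = CnnConfig(n_classes=params.n_classes,
                           input_side=tuple(grid.shape),
                           filter_side=params.filters.shape[1])
    if tuple(grid.shape) != config.input_shape:
        raise InputError("grid shape does not match the configured geometry")
    if params.count() != count_parameters(config):
        raise InputError("parameter count does not match the geometry")
    outputs, cache = _batch_forward(grid[None], params, config)
    _, conv, _, _, pooled_flat, _ = cache
    out = outputs[0]
    return out, {
        "conv": conv[0],
        "pooled": pooled_flat[0].reshape(config.n_classes,
                                         *config.pooled_shape),
        "predicted_class": int(np.argmax(out)),
    }


def _loss_and_grad(grids, targets, params: CnnParameters,
                   config: CnnConfig):
    """Mean (over persons) summed squared error and its gradient."""
    n = grids.shape[0]
    q = config.pool_side
    pr, pc = config.pooled_shape
    cr, cc = config.conv_shape
    outputs, cache = _batch_forward(grids, params, config)
    windows, conv, blocks, argmax, pooled_flat, _ = cache
    err = outputs - targets                               # (n, C)
    loss = float(np.sum(err ** 2) / n)

    dz_out = 2.0 * err * outputs * (1.0 - outputs) / n    # (n, C)
    g_pw = np.einsum("nc,ncq->cq", dz_out, pooled_flat)
    g_pb = dz_out.sum(axis=0)

    dpooled = dz_out[:, :, None] * params.pool_weights[None]  # (n, C, Q)
    dpooled = dpooled.reshape(n, config.n_classes, pr, pc)
    dblocks = np.zeros_like(blocks)
    np.put_along_axis(dblocks, argmax[..., None],
                      dpooled[..., None], axis=-1)
    dconv = dblocks.reshape(n, config.n_classes, pr, pc, q, q) \
        .transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, config.n_classes, cr, cc)
    dz = dconv * conv * (1.0 - conv)
    g_filters = np.einsum("ncij,nijkl->ckl", dz, windows)
    g_fb = dz.sum(axis=(0, 2, 3))

    grad = CnnParameters(g_filters, g_fb, g_pw, g_pb)
    return loss, grad, outputs


def train(grids, labels, config: CnnConfig = CnnConfig(),
          class_order=None):
    """Full-batch gradient-descent training against one-hot targets.

    ``grids`` is (n, side, side); ``labels`` is a sequence of class names
    (quadrant strings by default).  Returns ``(params, loss_trace,
    class_order)``.  Initialization is seeded uniform(-0.5, 0.5); training
    stops at ``max_epochs`` or when the loss improves by less than 1e-8.
    The final loss is guaranteed <= the initial loss (the best iterate
    seen is returned).
    """
    grids = np.asarray(grids, dtype=float)
    if grids.ndim != 3 or grids.shape[0] == 0:
        raise InputError("empty training set")
    labels = np.asarray(labels)
    if labels.shape[0] != grids.shape[0]:
        raise InputError("labels and grids length mismatch")
    if class_order is None:
        class_order = [q for q in QUADRANTS if q in set(labels)] \
            if set(labels) <= set(QUADRANTS) else sorted(set(labels))
    class_order = list(class_order)
    if len(class_order) != config.n_classes:
        config = CnnConfig(n_classes=len(class_order),
                           input_side=config.input_side,
                           filter_side=config.filter_side,
                           pool_side=config.pool_side,
                           learning_rate=config.learning_rate,
                           max_epochs=config.max_epochs, seed=config.seed)
    index = {c: i for i, c in enumerate(class_order)}
    targets = np.zeros((grids.shape[0], config.n_classes))
    for i, lab in enumerate(labels):
        targets[i, index[lab]] = 1.0

    rng = np.random.default_rng(config.seed)
    params = CnnParameters.random(config, rng)
    lr = config.learning_rate
    trace = []
    best = None
    prev = np.inf
    for _ in range(config.max_epochs):
        loss, grad, _ = _loss_and_grad(grids, targets, params, config)
        if not np.isfinite(loss):
            raise EstimationError("training diverged (non-finite loss); "
                                  "try a smaller learning_rate")
        trace.append(loss)
        if best is None or loss < best[0]:
            best = (loss, CnnParameters(params.filters.copy(),
                                        params.filter_bias.copy(),
                                        params.pool_weights.copy(),
                                        params.pool_bias.copy()))
        if prev - loss < 1e-8 and prev >= loss:
            break
        prev = loss
        params = CnnParameters(params.filters - lr * grad.filters,
                               params.filter_bias - lr * grad.filter_bias,
                               params.pool_weights - lr * grad.pool_weights,
                               params.pool_bias - lr * grad.pool_bias)
    return best[1], trace, class_order


def predict(responses, params: CnnParameters, likert_min=1, likert_max=5,
            class_order=QUADRANTS, config: CnnConfig = None):
    """Classify one respondent's raw Likert responses.

    Returns ``(label, outputs)`` — the predicted class name and the raw
    per-class sigmoid outputs (not normalized to sum to 1).
    """
    if config is None:
        config = CnnConfig(n_classes=params.n_classes)
    grid = arrange_input(responses, likert_min, likert_max,
                         input_side=config.input_side)
    out, info = forward_pass(grid, params, config)
    return class_order[info["predicted_class"]], out


class MicroCNN:
    """scikit-learn style classifier wrapping the micro-CNN.

    ``fit(X, y)`` takes raw response rows (n, 44) and class labels;
    ``predict(X)`` returns labels.  Fitted attributes: ``params_``,
    ``classes_``, ``loss_trace_``.
    """

    def __init__(self, n_classes=4, input_side=10, learning_rate=2.0,
                 max_epochs=5000, seed=0, likert_min=1, likert_max=5):
        self.n_classes = n_classes
        self.input_side = input_side
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.seed = seed
        self.likert_min = likert_min
        self.likert_max = likert_max

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("n_classes", "input_side", "learning_rate", "max_epochs",
                 "seed", "likert_min", "likert_max")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self, n_classes=None):
        return CnnConfig(n_classes=n_classes or self.n_classes,
                         input_side=self.input_side,
                         learning_rate=self.learning_rate,
                         max_epochs=self.max_epochs, seed=self.seed)

    def _grids(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.stack([arrange_input(row, self.likert_min,
                                       self.likert_max, self.input_side)
                         for row in X])

    def fit(self, X, y):
        grids = self._grids(X)
        params, trace, order = train(grids, y, self._config())
        self.params_ = params
        self.classes_ = np.asarray(order)
        self.loss_trace_ = np.asarray(trace)
        return self

    def decision_function(self, X):
        grids = self._grids(X)
        out, _ = _batch_forward(grids, self.params_,
                                self._config(len(self.classes_)))
        return out

    def predict(self, X):
        out = self.decision_function(X)
        return self.classes_[np.argmax(out, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def save_parameters(params: CnnParameters, config: CnnConfig, path,
                    likert_min=1, likert_max=5, class_order=QUADRANTS):
    """Write the parameter sets, geometry and Likert range as JSON."""
    doc = {
        "schema_version": 1,
        "geometry": {"n_classes": config.n_classes,
                     "input_side": config.input_side,
                     "filter_side": config.filter_side,
                     "pool_side": config.pool_side},
        "likert_min": likert_min, "likert_max": likert_max,
        "class_order": list(class_order),
        "filters": params.filters.tolist(),
        "filter_bias": params.filter_bias.tolist(),
        "pool_weights": params.pool_weights.tolist(),
        "pool_bias": params.pool_bias.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return Path(path)


def load_parameters(path):
    """Load a parameter JSON, rejecting files whose count disagrees
    with the stored geometry.  Returns (params, config, meta)."""
    doc = json.loads(Path(path).read_text())
    g = doc["geometry"]
    config = CnnConfig(n_classes=g["n_classes"], input_side=g["input_side"],
                       filter_side=g["filter_side"], pool_side=g["pool_side"])
    params = CnnParameters(np.asarray(doc["filters"], dtype=float),
                           np.asarray(doc["filter_bias"], dtype=float),
                           np.asarray(doc["pool_weights"], dtype=float),
                           np.asarray(doc["pool_bias"], dtype=float))
    if params.count() != count_parameters(config):
        raise InputError(
            f"parameter file holds {params.count()} parameters but the "
            f"geometry requires {count_parameters(config)}")
    meta = {"likert_min": doc.get("likert_min", 1),
            "likert_max": doc.get("likert_max", 5),
            "class_order": doc.get("class_order", list(QUADRANTS))}
    return params, config, meta
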