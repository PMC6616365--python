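"""The 4-3-2 perceptron that turns the four dexterity variables into a score.

Architecture: 4 inputs (tracing accuracy, pressure change sum, pressure
change max, duration, z-scored with stored training-set statistics), one
hidden layer of 3 tanh units, and a 2-unit softmax output read as class
probabilities (patient vs healthy).  The score is defined as 100 times the
probability assigned to the healthy unit, so it lives in [0, 100] and low
values flag impairment.

Training is plain full-batch backpropagation: gradient descent with
momentum on the softmax cross-entropy, seeded uniform weight init, stopping
on an absolute loss-decrease tolerance or an epoch cap.

:func:`load_reference_params` returns the published reference weights of
the original screening network.  The normalization constants behind those
weights were never published, so the loader leaves ``input_norm`` unset and
scoring refuses to run until norms are supplied explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureVector

__all__ = [
    "MLPParams",
    "STTScore",
    "TrainConfig",
    "load_reference_params",
    "normalize_features",
    "mlp_forward",
    "stt_score",
    "train_mlp",
    "save_params",
    "load_params",
]

_SCHEMA_KEY = "stt_mlp_v1"
CLASSES = ("patient", "healthy")


@dataclass
class MLPParams:
    """Full parameter set of the scoring network.

    ``hidden_weights`` is 3x4 (rows = hidden units, columns = inputs in the
    :data:`~sttkit.features.FEATURE_NAMES` order); ``output_weights`` is 2x3.
    ``input_norm`` holds per-variable (mean, sd) used to z-score inputs;
    ``class_of_output`` maps output-unit index to class label and must be a
    bijection onto {patient, healthy}.
    """

    hidden_weights: np.ndarray
    hidden_bias: np.ndarray
    output_weights: np.ndarray
    output_bias: np.ndarray
    input_norm: np.ndarray | None = None  # shape (4, 2): columns mean, sd
    class_of_output: tuple[str, str] = ("patient", "healthy")
    hidden_activation: str = "tanh"
    output_activation: str = "softmax"

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float).reshape(3, 4)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float).reshape(3)
        self.output_weights = np.asarray(self.output_weights, dtype=float).reshape(2, 3)
        self.output_bias = np.asarray(self.output_bias, dtype=float).reshape(2)
        for name in ("hidden_weights", "hidden_bias", "output_weights", "output_bias"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        if self.input_norm is not None:
            self.input_norm = np.asarray(self.input_norm, dtype=float).reshape(4, 2)
            if np.any(self.input_norm[:, 1] <= 0):
                raise ValueError("input_norm sds must be > 0")
        if sorted(self.class_of_output) != sorted(CLASSES):
            raise ValueError(
                f"class_of_output must be a bijection onto {CLASSES}, "
                f"got {self.class_of_output}"
            )
        if self.hidden_activation != "tanh":
            raise ValueError("only tanh hidden activation is supported")
        if self.output_activation != "softmax":
            raise ValueError("only softmax output activation is supported")

    @property
    def healthy_unit(self) -> int:
        return self.class_of_output.index("healthy")


@dataclass(frozen=True)
class STTScore:
    """A 0-100 score; 100 x probability of being healthy."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"score must lie in [0, 100], got {self.value}")


@dataclass(frozen=True)
class TrainConfig:
    """Backpropagation hyperparameters (full-batch gradient descent + momentum)."""

    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 2000
    loss_tolerance: float = 1e-8
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def load_reference_params() -> MLPParams:
    """The published reference weights of the original screening network.

    ``input_norm`` is left unset: the normalization constants used to fit
    these weights were never published, so they must be supplied (e.g. from
    a training split) before the network can score raw feature values.
    """
    # columns: I1 (tracing accuracy), I2 (pressure change sum),
    #          I3 (pressure change max), I4 (duration); rows H1..H3
    hidden_weights = np.array(
        [
            [-0.089, 0.720, 0.000, 1.378],
            [1.922, -1.611, -0.469, -2.402],
            [4.643, -3.705, -0.599, -4.015],
        ]
    )
    hidden_bias = np.array([-0.805, 0.609, 1.315])
    # rows O1 (patient), O2 (healthy); columns H1..H3
    output_weights = np.array(
        [
            [-0.641, -1.235, 1.123],
            [0.640, 1.220, -1.120],
        ]
    )
    output_bias = np.array([0.497, 0.500])
    return MLPParams(
        hidden_weights=hidden_weights,
        hidden_bias=hidden_bias,
        output_weights=output_weights,
        output_bias=output_bias,
        input_norm=None,
        class_of_output=("patient", "healthy"),
    )


def _as_feature_array(fv) -> np.ndarray:
    if isinstance(fv, FeatureVector):
        return fv.as_array()
    arr = np.asarray(fv, dtype=float).reshape(-1)
    if arr.size != 4:
        raise ValueError(f"expected 4 feature values, got {arr.size}")
    return arr


def normalize_features(fv, params: MLPParams) -> np.ndarray:
    """z-score the four variables with the stored per-variable (mean, sd)."""
    if params.input_norm is None:
        raise ValueError(
            "input_norm is unset; supply normalization constants "
            "(e.g. training-split means and sds) before scoring"
        )
    v = _as_feature_array(fv)
    return (v - params.input_norm[:, 0]) / params.input_norm[:, 1]


def _softmax(a: np.ndarray) -> np.ndarray:
    a = a - np.max(a, axis=-1, keepdims=True)
    e = np.exp(a)
    return e / np.sum(e, axis=-1, keepdims=True)


def mlp_forward(params: MLPParams, z) -> tuple[float, float]:
    """Forward pass on a normalized 4-vector; returns the (O1, O2) probability pair."""
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.size != 4 or not np.all(np.isfinite(z)):
        raise ValueError("input must be a finite 4-vector")
    h = np.tanh(params.hidden_bias + params.hidden_weights @ z)
    a = params.output_bias + params.output_weights @ h
    p = _softmax(a)
    return float(p[0]), float(p[1])


def stt_score(params: MLPParams, fv) -> STTScore:
    """Score a feature vector: 100 x P(healthy). Low scores flag impairment."""
    z = normalize_features(fv, params)
    p = mlp_forward(params, z)
    return STTScore(100.0 * p[params.healthy_unit])


def score_many(params: MLPParams, vectors: Sequence) -> np.ndarray:
    """Vector of scores for a sequence of feature vectors."""
    return np.array([stt_score(params, fv).value for fv in vectors])


def _forward_batch(params: MLPParams, Z: np.ndarray):
    H = np.tanh(params.hidden_bias + Z @ params.hidden_weights.T)  # (n, 3)
    A = params.output_bias + H @ params.output_weights.T  # (n, 2)
    P = _softmax(A)
    return H, P


def cross_entropy(params: MLPParams, Z: np.ndarray, Y: np.ndarray) -> float:
    """Mean softmax cross-entropy of one-hot targets ``Y`` on normalized inputs."""
    _, P = _forward_batch(params, Z)
    return float(-np.mean(np.sum(Y * np.log(np.clip(P, 1e-300, None)), axis=1)))


def loss_gradients(params: MLPParams, Z: np.ndarray, Y: np.ndarray):
    """Analytic backpropagation gradients of :func:`cross_entropy`.

    Returns (dW_hidden, db_hidden, dW_output, db_output) matching the
    parameter shapes.
    """
    n = Z.shape[0]
    H, P = _forward_batch(params, Z)
    dA = (P - Y) / n  # (n, 2)
    dW_out = dA.T @ H
    db_out = dA.sum(axis=0)
    dH = dA @ params.output_weights  # (n, 3)
    dPre = dH * (1.0 - H**2)  # tanh'
    dW_hid = dPre.T @ Z
    db_hid = dPre.sum(axis=0)
    return dW_hid, db_hid, dW_out, db_out


def train_mlp(
    features: Sequence,
    labels: Sequence[str],
    config: TrainConfig | None = None,
) -> MLPParams:
    """Fit the 4-3-2 network by full-batch backpropagation with momentum.

    Inputs are z-scored with training-set statistics which are stored in the
    returned params; output unit 0 is the patient class and unit 1 the
    healthy class.  Deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    X = np.vstack([_as_feature_array(fv) for fv in features])
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("features and labels length mismatch")
    bad = set(labels) - {"patient", "healthy", "control"}
    if bad:
        raise ValueError(f"labels must be patient/healthy (control = healthy), got {bad}")
    # the cohort label "control" is the healthy class
    y_idx = np.array([0 if lab == "patient" else 1 for lab in labels])
    for cls in (0, 1):
        if np.sum(y_idx == cls) < 2:
            raise ValueError("need >= 2 examples per class")
    Y = np.eye(2)[y_idx]

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant variable carries no information
    Z = (X - mean) / sd

    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    params = MLPParams(
        hidden_weights=rng.uniform(-s, s, size=(3, 4)),
        hidden_bias=rng.uniform(-s, s, size=3),
        output_weights=rng.uniform(-s, s, size=(2, 3)),
        output_bias=rng.uniform(-s, s, size=2),
        input_norm=np.column_stack([mean, sd]),
        class_of_output=("patient", "healthy"),
    )

    names = ("hidden_weights", "hidden_bias", "output_weights", "output_bias")
    velocity = {k: np.zeros_like(getattr(params, k)) for k in names}
    prev_loss = cross_entropy(params, Z, Y)
    if not np.isfinite(prev_loss):
        raise ArithmeticError("non-finite loss at initialization")
    for epoch in range(config.max_epochs):
        grads = dict(zip(names, loss_gradients(params, Z, Y)))
        for k in names:
            velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
            setattr(params, k, getattr(params, k) + velocity[k])
        loss = cross_entropy(params, Z, Y)
        if not np.isfinite(loss):
            raise ArithmeticError(f"non-finite loss at epoch {epoch}")
        if abs(prev_loss - loss) < config.loss_tolerance:
            break
        prev_loss = loss
    return params


# ---------------------------------------------------------------------------
# JSON persistence


def save_params(params: MLPParams, path) -> None:
    """Lossless JSON dump (schema key stt_mlp_v1)."""
    doc = {
        "schema": _SCHEMA_KEY,
        "hidden_weights": params.hidden_weights.tolist(),
        "hidden_bias": params.hidden_bias.tolist(),
        "output_weights": params.output_weights.tolist(),
        "output_bias": params.output_bias.tolist(),
        "input_norm": None if params.input_norm is None else params.input_norm.tolist(),
        "class_of_output": list(params.class_of_output),
        "hidden_activation": params.hidden_activation,
        "output_activation": params.output_activation,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_params(path) -> MLPParams:
    """Load params saved by :func:`save_params`; validates the schema."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _SCHEMA_KEY:
        raise ValueError(f"{path}: expected schema {_SCHEMA_KEY!r}, got {doc.get('schema')!r}")
    required = {
        "hidden_weights",
        "hidden_bias",
        "output_weights",
        "output_bias",
        "input_norm",
        "class_of_output",
    }
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"{path}: params file missing keys {sorted(missing)}")
    return MLPParams(
        hidden_weights=np.asarray(doc["hidden_weights"]),
        hidden_bias=np.asarray(doc["hidden_bias"]),
        output_weights=np.asarray(doc["output_weights"]),
        output_bias=np.asarray(doc["output_bias"]),
        input_norm=None if doc["input_norm"] is None else np.asarray(doc["input_norm"]),
        class_of_output=tuple(doc["class_of_output"]),
        hidden_activation=doc.get("hidden_activation", "tanh"),
        output_activation=doc.get("output_activation", "softmax"),
    )
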