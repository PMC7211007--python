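"""The multilayer fully connected deep network (MFDN).

A pixel-wise classifier: each pixel's feature vector passes through ten fully
connected hidden layers whose widths increase 32, 64, 128, 256, 512 and then
decrease 256, 128, 64, 32, followed by a 3-way softmax over (background, mLN,
remnant).  Every hidden layer applies an affine map with an implicit bias
node of value 1 followed by a nonlinearity (logistic sigmoid, tanh, or ReLU —
ReLU by default).

Training minimises softmax cross-entropy with mini-batch Adam (batch 64,
initial learning rate 1e-3 dropped by a factor 0.1 every 10 epochs, L2 weight
decay 1e-4, first-moment decay 0.9, epsilon 1e-8), shuffling the training set
before each epoch and the validation set before each validation pass.  All
randomness is driven by a single seed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, feature_matrix
from .priors import PriorMaps

__all__ = ["HIDDEN_WIDTHS", "MFDNModel", "TrainConfig", "SegmentationResult",
           "build_model", "forward", "lr_at_epoch", "planned_iterations",
           "train", "predict_labelmap", "save_model", "load_model"]

#: Hidden-layer widths; the full chain is [input, *HIDDEN_WIDTHS, 3].
HIDDEN_WIDTHS = (32, 64, 128, 256, 512, 256, 128, 64, 32)
N_CLASSES = 3

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (s(r), s'(r) expressed via the activation output)
    "relu": (lambda r: np.maximum(r, 0.0), lambda a: (a > 0).astype(float)),
    "sigmoid": (lambda r: 1.0 / (1.0 + np.exp(-r)), lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


@dataclass
class MFDNModel:
    """Weights of the network; each matrix has the bias row prepended."""

    widths: list[int]                 # [input_dim, 32, ..., 32, 3]
    weights: list[np.ndarray]         # weights[k] has shape (widths[k]+1, widths[k+1])
    activation: str = "relu"

    @property
    def input_dim(self) -> int:
        return self.widths[0]

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10          # epochs between drops
    l2: float = 1e-4
    beta1: float = 0.9                # gradient moving-average decay
    beta2: float = 0.999              # squared-gradient decay
    epsilon: float = 1e-8
    validation_frequency: int = 1200  # iterations between validation passes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        for name in ("batch_size", "lr_drop_period", "validation_frequency"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("learning_rate", "lr_drop_factor", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    labels: np.ndarray                # (H, W) uint8 predicted label map
    probabilities: np.ndarray         # (3, H, W), sums to 1 per pixel
    model_id: str = ""
    scan_id: str = ""


def build_model(input_dim: int, activation: str = "relu", seed: int = 0) -> MFDNModel:
    """Seeded fan-in scaled-uniform initialisation; biases start at zero."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}; "
                         f"choose from {sorted(_ACTIVATIONS)}")
    widths = [int(input_dim), *HIDDEN_WIDTHS, N_CLASSES]
    rng = np.random.default_rng(seed)
    weights = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / n_in)
        w = np.zeros((n_in + 1, n_out))
        w[1:] = rng.uniform(-limit, limit, size=(n_in, n_out))
        weights.append(w)
    return MFDNModel(widths=widths, weights=weights, activation=activation)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(model: MFDNModel, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    act, _ = _ACTIVATIONS[model.activation]
    activations = [X]
    a = X
    for w in model.weights[:-1]:
        a = act(a @ w[1:] + w[0])
        activations.append(a)
    w = model.weights[-1]
    probs = _softmax(a @ w[1:] + w[0])
    return probs, activations


def forward(model: MFDNModel, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Class probabilities, one row per feature row; rows sum to 1."""
    if isinstance(features, pd.DataFrame):
        features = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model input "
                         f"{model.input_dim}")
    probs, _ = _forward_cached(model, X)
    return probs


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Piecewise-constant schedule: drop by ``lr_drop_factor`` every
    ``lr_drop_period`` epochs (1-based epochs)."""
    if not 1 <= epoch <= max(config.epochs, 1):
        raise ValueError(f"epoch {epoch} outside 1..{config.epochs}")
    return config.learning_rate * config.lr_drop_factor ** ((epoch - 1) // config.lr_drop_period)


def planned_iterations(n_samples: int, batch: int, epochs: int) -> tuple[int, int]:
    """(iterations per epoch, total iterations); the last incomplete
    mini-batch of each epoch is dropped."""
    if n_samples < 1 or batch < 1 or epochs < 1:
        raise ValueError("n_samples, batch and epochs must be positive")
    if batch > n_samples:
        raise ValueError(f"batch {batch} exceeds n_samples {n_samples}")
    per_epoch = n_samples // batch
    return per_epoch, epochs * per_epoch


def _loss_and_grads(model: MFDNModel, X: np.ndarray, y: np.ndarray,
                    l2: float, grads: list[np.ndarray]) -> float:
    """Cross-entropy + L2 loss; gradients written into ``grads`` in place."""
    n = X.shape[0]
    probs, activations = _forward_cached(model, X)
    ce = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
    reg = 0.5 * l2 * sum(float((w[1:] ** 2).sum()) for w in model.weights)
    # Backprop: delta at the softmax output, then through each hidden layer.
    _, dact = _ACTIVATIONS[model.activation]
    delta = probs
    delta[np.arange(n), y] -= 1.0
    delta /= n
    for k in range(len(model.weights) - 1, -1, -1):
        a_in = activations[k]
        g = grads[k]
        np.sum(delta, axis=0, out=g[0])
        np.matmul(a_in.T, delta, out=g[1:])
        g[1:] += l2 * model.weights[k][1:]
        if k > 0:
            delta = (delta @ model.weights[k][1:].T) * dact(a_in)
    return ce + reg


def _evaluate(model: MFDNModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs, _ = _forward_cached(model, X)
    loss = -np.mean(np.log(probs[np.arange(X.shape[0]), y] + 1e-300))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return float(loss), acc


def train(model: MFDNModel, train_table: pd.DataFrame,
          val_table: pd.DataFrame | None,
          config: TrainConfig) -> tuple[MFDNModel, pd.DataFrame]:
    """Mini-batch Adam with L2 decay and the stepped lr schedule.

    Returns the trained model (modified in place) and the learning curve, one
    row per iteration with columns (iteration, epoch, lr, train_loss,
    val_loss, val_acc); validation columns are NaN except at validation
    iterations.  Fully deterministic given ``config.seed``.
    """
    X, y = feature_matrix(train_table)
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    if np.unique(y).size < 2:
        raise ValueError("training table contains a single class; "
                         "cross-entropy is degenerate")
    Xv = yv = None
    if val_table is not None and len(val_table) > 0:
        Xv, yv = feature_matrix(val_table)

    curve_cols = ("iteration", "epoch", "lr", "train_loss", "val_loss", "val_acc")
    if config.epochs == 0:
        return model, pd.DataFrame(columns=curve_cols)

    per_epoch, _ = planned_iterations(X.shape[0], config.batch_size, config.epochs)
    rng = np.random.default_rng(config.seed)

    # Flatten all parameters into one buffer so the Adam update is a handful
    # of whole-vector operations; per-layer weights become views into it.
    # Optimisation runs in float32 (deterministic on one machine); the final
    # weights are stored back as float64 for the inference path.
    dtype = np.float32
    X = X.astype(dtype)
    if Xv is not None:
        Xv = Xv.astype(dtype)
    sizes = [w.size for w in model.weights]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    theta = np.concatenate([w.ravel() for w in model.weights]).astype(dtype)
    views = [theta[o:o + s].reshape(w.shape)
             for o, s, w in zip(offsets, sizes, model.weights)]
    float64_weights = model.weights
    model.weights = views
    grad_flat = np.zeros_like(theta)
    grads = [grad_flat[o:o + s].reshape(v.shape)
             for o, s, v in zip(offsets, sizes, views)]
    m_state = np.zeros_like(theta)
    v_state = np.zeros_like(theta)

    t = 0
    records = []
    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(X.shape[0])
        for b in range(per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            loss = _loss_and_grads(model, X[idx], y[idx], config.l2, grads)
            t += 1
            m_state *= config.beta1
            m_state += (1 - config.beta1) * grad_flat
            v_state *= config.beta2
            v_state += (1 - config.beta2) * grad_flat * grad_flat
            step = lr / (1 - config.beta1 ** t)
            denom = np.sqrt(v_state / (1 - config.beta2 ** t))
            denom += config.epsilon
            theta -= step * m_state / denom
            if t % 64 == 0:
                # Flush subnormal float32 values: parameters with long runs of
                # zero gradient decay geometrically into the subnormal range,
                # where arithmetic is pathologically slow on x86.
                for buf in (theta, m_state, v_state):
                    np.copyto(buf, 0.0, where=np.abs(buf) < 1e-30)
            val_loss = val_acc = np.nan
            if Xv is not None and (t % config.validation_frequency == 0 or
                                   (epoch == config.epochs and b == per_epoch - 1)):
                vorder = rng.permutation(Xv.shape[0])
                val_loss, val_acc = _evaluate(model, Xv[vorder], yv[vorder])
            records.append((t, epoch, lr, loss, val_loss, val_acc))
    for w64, v in zip(float64_weights, views):
        w64[...] = v
    model.weights = float64_weights
    curve = pd.DataFrame.from_records(records, columns=curve_cols)
    return model, curve


def predict_labelmap(model: MFDNModel, scan: np.ndarray, priors: PriorMaps, *,
                     threshold: int = 160,
                     sigmas: tuple[float, ...] = (2.0, 4.0, 8.0),
                     chunk: int = 65536,
                     model_id: str = "", scan_id: str = "") -> SegmentationResult:
    """Per-pixel classification of a whole scan.

    The scan passes through the same threshold/Gaussian-stack pipeline used at
    training; pixels outside the foreground mask are forced to background
    with probability (1, 0, 0).  Argmax ties break toward the lower class
    code (conservative: background before mLN before remnant).
    """
    from .preprocess import gaussian_stack, mask_stack, threshold_mask

    scan = np.asarray(scan)
    if priors.shape != scan.shape:
        raise ValueError(f"prior shape {priors.shape} != scan shape {scan.shape}")
    stack = mask_stack(threshold_mask(scan, threshold), gaussian_stack(scan, sigmas),
                       sigmas=sigmas)
    h, w = scan.shape
    probs = np.zeros((N_CLASSES, h, w))
    probs[0] = 1.0
    labels = np.zeros((h, w), dtype=np.uint8)
    fr, fc = np.nonzero(stack.mask)
    from .features import _pixel_features
    for start in range(0, fr.size, chunk):
        rr, cc = fr[start:start + chunk], fc[start:start + chunk]
        p = forward(model, _pixel_features(stack, priors, rr, cc))
        probs[:, rr, cc] = p.T
        labels[rr, cc] = p.argmax(axis=1)   # argmax takes first max: low code wins ties
    return SegmentationResult(labels=labels, probabilities=probs,
                              model_id=model_id, scan_id=scan_id)


def save_model(model: MFDNModel, path: str | Path) -> None:
    """Portable checkpoint: JSON-style metadata plus per-layer weight blobs."""
    import json

    meta = {"widths": model.widths, "activation": model.activation,
            "format": "scintiseg-mfdn-v1"}
    arrays = {f"w{k}": w for k, w in enumerate(model.weights)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> MFDNModel:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        weights = [z[f"w{k}"] for k in range(len(meta["widths"]) - 1)]
    return MFDNModel(widths=list(meta["widths"]), weights=weights,
                     activation=meta["activation"])
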