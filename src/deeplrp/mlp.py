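"""Deep multilayer perceptron for phenotype prediction from gene expression.

The architecture is the field-standard fully connected net: an input layer
with one neuron per probe, ReLU hidden layers, and a softmax output layer
with one neuron per class, F(x) = argmax_k a_k^(L). Training minimizes
cross-entropy plus an L1 penalty lambda * sum|w| on the weights with the
Adam optimizer; dropout is applied to the outputs of the first and second
hidden layers during training only, and an early-stopping rule monitors the
loss on a held-out stratified validation split (10% of the training data by
default) and restores the best weights.

Everything is implemented directly in NumPy: gradients are the standard
backpropagation recursions, which keeps training fully deterministic under
a seed and gives LRP direct access to exact per-layer forward traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["MLPConfig", "MLPNetwork", "ForwardTrace", "train", "forward_trace", "predict"]


@dataclass
class MLPConfig:
    """Hyperparameters of the perceptron and its training procedure.

    Defaults follow the reference setup for this problem class: dropout
    probability 0.3 on hidden layers 1 and 2, L1 weight 1e-3, Adam with
    learning rate 1e-4, batch size 16, at most 500 epochs with early
    stopping on a 10% validation split.
    """

    layer_sizes: Sequence[int]
    p_drop: float = 0.3
    l1: float = 1e-3
    lr: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 500
    early_stop_patience: int | None = 20  # None: run max_epochs, keep final weights
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_sizes = [int(s) for s in self.layer_sizes]
        if len(self.layer_sizes) < 2:
            raise ValueError("layer_sizes needs at least input and output layers")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.p_drop < 1.0:
            raise ValueError("p_drop must be in [0, 1)")
        if self.l1 < 0:
            raise ValueError("l1 penalty must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class MLPNetwork:
    """A trained (or hand-built) perceptron.

    ``weights[l]`` has shape (n_l, n_{l+1}) with layer 0 the input layer, so
    ``weights[l][i, j]`` is the connection from neuron i of layer l to
    neuron j of layer l+1. Hidden layers use ReLU; the last layer is linear
    followed by softmax.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have the same number of layers")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
                raise ValueError(f"inconsistent shapes in weight layer {l + 1}")
            if l > 0 and self.weights[l - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {l} output size != layer {l + 1} input size")

    @property
    def L(self) -> int:
        """Number of weight layers."""
        return len(self.weights)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def copy(self) -> "MLPNetwork":
        return MLPNetwork(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            classes=list(self.classes) if self.classes is not None else None,
            metadata=dict(self.metadata),
        )


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and activations for a batch of examples.

    ``a[0]`` is the input, ``z[l]`` and ``a[l]`` (1-indexed) the
    pre-activation and activation of layer l; ``a[L]`` holds the softmax
    class probabilities while ``z[L]`` is the pre-softmax score that LRP
    backpropagates. All arrays have shape (n_examples, n_l).
    """

    z: dict[int, np.ndarray]
    a: dict[int, np.ndarray]

    @property
    def n_examples(self) -> int:
        return self.a[0].shape[0]

    @property
    def L(self) -> int:
        return max(self.z)

    def subset(self, rows: np.ndarray) -> "ForwardTrace":
        return ForwardTrace(
            z={l: v[rows] for l, v in self.z.items()},
            a={l: v[rows] for l, v in self.a.items()},
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward_trace(network: MLPNetwork, x: np.ndarray) -> ForwardTrace:
    """Feed-forward pass recording every z^(l) and a^(l); dropout disabled.

    Accepts a single profile (1-D) or a batch (2-D, samples as rows).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != network.n_inputs:
        raise ValueError(
            f"input has {x.shape[1]} features, network expects {network.n_inputs}"
        )
    z: dict[int, np.ndarray] = {}
    a: dict[int, np.ndarray] = {0: x}
    h = x
    L = network.L
    for l in range(1, L + 1):
        zl = h @ network.weights[l - 1] + network.biases[l - 1]
        z[l] = zl
        h = np.maximum(zl, 0.0) if l < L else _softmax(zl)
        a[l] = h
    return ForwardTrace(z=z, a=a)


def predict(network: MLPNetwork, data: ExpressionDataset | np.ndarray):
    """Predicted class index and softmax probability for each sample.

    Ties in the softmax output are broken toward the lowest class index.
    Returns ``(indices, probabilities)`` with shapes (n,) and (n, K).
    """
    X = data.X if isinstance(data, ExpressionDataset) else np.asarray(data, dtype=float)
    trace = forward_trace(network, X)
    probs = trace.a[network.L]
    return probs.argmax(axis=1), probs


def _init_network(config: MLPConfig, rng: np.random.Generator,
                  classes: list[str] | None) -> MLPNetwork:
    sizes = config.layer_sizes
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        # He initialization suits the ReLU hidden stack; the linear output
        # layer gets the same scale, which is harmless at these widths.
        scale = np.sqrt(2.0 / sizes[l])
        weights.append(rng.normal(0.0, scale, size=(sizes[l], sizes[l + 1])))
        biases.append(np.zeros(sizes[l + 1]))
    return MLPNetwork(weights=weights, biases=biases, classes=classes)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-300, None)
    return float(-np.mean(np.log(p)))


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[:n_val])
    val = np.sort(np.array(val_idx, dtype=int))
    mask = np.ones(len(y), dtype=bool)
    mask[val] = False
    return np.flatnonzero(mask), val


def train(dataset: ExpressionDataset, config: MLPConfig):
    """Train the perceptron; returns ``(network, log)``.

    ``log`` is a list of per-epoch records (epoch, train_loss, val_loss).
    The run is fully deterministic given (data, config): initialization,
    batch order and dropout masks all derive from ``config.seed``.
    """
    if dataset.n_classes < 2:
        raise ValueError("training requires at least 2 classes")
    if config.layer_sizes[0] != dataset.n_probes:
        raise ValueError(
            f"input layer has {config.layer_sizes[0]} neurons but data has "
            f"{dataset.n_probes} probes"
        )
    if config.layer_sizes[-1] != dataset.n_classes:
        raise ValueError(
            f"output layer has {config.layer_sizes[-1]} neurons but data has "
            f"{dataset.n_classes} classes"
        )
    rng = np.random.default_rng(config.seed)
    y = dataset.y
    train_idx, val_idx = _stratified_split(y, config.validation_fraction, rng)
    if len(train_idx) < 2 * config.batch_size:
        raise ValueError(
            f"need at least {2 * config.batch_size} training samples, "
            f"got {len(train_idx)}"
        )
    X_tr, y_tr = dataset.X[train_idx], y[train_idx]
    X_val, y_val = dataset.X[val_idx], y[val_idx]

    net = _init_network(config, rng, classes=list(dataset.class_set))
    L = net.L
    # dropout applies to the outputs of hidden layers 1 and 2 only
    dropout_layers = [l for l in (1, 2) if l <= L - 1 and config.p_drop > 0]

    params = net.weights + net.biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_weights = [w.copy() for w in net.weights]
    best_biases = [b.copy() for b in net.biases]
    best_epoch = 0
    log: list[dict] = []

    n_tr = len(X_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_tr, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = X_tr[batch], y_tr[batch]
            nb = len(batch)

            # forward with inverted dropout
            acts = [xb]
            pre: list[np.ndarray] = []
            masks: dict[int, np.ndarray] = {}
            h = xb
            for l in range(1, L + 1):
                zl = h @ net.weights[l - 1] + net.biases[l - 1]
                pre.append(zl)
                if l < L:
                    h = np.maximum(zl, 0.0)
                    if l in dropout_layers:
                        mask = (rng.random(h.shape) >= config.p_drop) / (1.0 - config.p_drop)
                        masks[l] = mask
                        h = h * mask
                else:
                    h = _softmax(zl)
                acts.append(h)

            loss = _cross_entropy(acts[-1], yb)
            if config.l1 > 0:
                loss += config.l1 * sum(float(np.abs(w).sum()) for w in net.weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1

            # backward
            delta = acts[-1].copy()
            delta[np.arange(nb), yb] -= 1.0
            delta /= nb
            grads_w = [np.empty(0)] * L
            grads_b = [np.empty(0)] * L
            for l in range(L, 0, -1):
                grads_w[l - 1] = acts[l - 1].T @ delta
                grads_b[l - 1] = delta.sum(axis=0)
                if config.l1 > 0:
                    grads_w[l - 1] += config.l1 * np.sign(net.weights[l - 1])
                if l > 1:
                    delta = delta @ net.weights[l - 1].T
                    if (l - 1) in masks:
                        delta = delta * masks[l - 1]
                    delta = delta * (pre[l - 2] > 0)

            step += 1
            grads = grads_w + grads_b
            lr_t = config.lr * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for p, g, m, v in zip(params, grads, m_state, v_state):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + adam_eps)

        val_probs = forward_trace(net, X_val).a[L]
        val_loss = _cross_entropy(val_probs, y_val)
        log.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
        })
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            if config.early_stop_patience is not None:
                best_weights = [w.copy() for w in net.weights]
                best_biases = [b.copy() for b in net.biases]
        elif (config.early_stop_patience is not None
              and epoch - best_epoch >= config.early_stop_patience):
            break

    if config.early_stop_patience is not None:
        net.weights = best_weights
        net.biases = best_biases
    net.metadata = {
        "seed": config.seed,
        "epochs_run": len(log),
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
        "config": {
            "layer_sizes": list(config.layer_sizes),
            "p_drop": config.p_drop,
            "l1": config.l1,
            "lr": config.lr,
            "batch_size": config.batch_size,
            "max_epochs": config.max_epochs,
            "early_stop_patience": config.early_stop_patience,
            "validation_fraction": config.validation_fraction,
        },
    }
    return net, log
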