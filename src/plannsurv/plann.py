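"""Partial logistic artificial neural network (PLANN) for discrete-time
survival.

A feed-forward network with one or two hidden layers maps person-period
rows (covariates plus k time-interval indicators) to the conditional
probability of the event in that interval, ``h_j = P(T in I_j | T >
tau_{j-1})``, through a single sigmoid output node.  Training minimises a
class-weighted binary cross-entropy over the long-format rows with
mini-batch gradient descent, momentum and (inverted) dropout.  Survival
curves follow from the hazards by the discrete product-limit identity
``S(tau_m) = prod_{j<=m} (1 - h_j)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .discretize import LongFormatData

__all__ = [
    "PlannConfig",
    "PlannModel",
    "activation_fn",
    "build_plann",
    "count_weights",
    "train",
    "predict_hazards",
    "hazards_to_survival",
]

_EPS = 1e-7  # hazard clipping inside the loss only


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda z, a: a * (1.0 - a)),
    "relu": (lambda z: np.maximum(0.0, z), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
}


def activation_fn(name: str, eta):
    """Evaluate a hidden-layer activation by name (sigmoid, relu or tanh)."""
    if name not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")
    return _ACTIVATIONS[name][0](np.asarray(eta, dtype=float))


@dataclass
class PlannConfig:
    """Hyper-parameters of the network.

    Defaults follow the tuned single-hidden-layer configuration for large
    transplant cohorts (node size 85, dropout 0.2, learning rate 0.2,
    momentum 0.9, event class weight 1); epoch count, batch size and the
    optimizer scheme are package defaults, all configurable.
    """

    n_hidden_layers: int = 1
    node_size: int = 85
    activation: str = "sigmoid"
    dropout_rate: float = 0.2
    learning_rate: float = 0.2
    momentum: float = 0.9
    event_class_weight: float = 1.0
    n_epochs: int = 50
    batch_size: int | str = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        if self.node_size < 1:
            raise ValueError("node_size must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.event_class_weight <= 0:
            raise ValueError("event_class_weight must be positive")
        if self.batch_size != "full" and int(self.batch_size) < 1:
            raise ValueError("batch_size must be a positive integer or 'full'")


@dataclass
class PlannModel:
    """Weights plus configuration; see :func:`build_plann`.

    ``weights`` is a list of ``(W, b)`` pairs per adjacent layer pair.
    ``scaler`` holds per-feature (mean, sd) used to standardize continuous
    inputs; it is fitted on the training features by :func:`train`.
    """

    config: PlannConfig
    n_covariates: int
    k: int
    weights: list[tuple[np.ndarray, np.ndarray]]
    loss_trace: list[float]
    feature_names: list[str] | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_inputs(self) -> int:
        return self.n_covariates + self.k

    def copy(self) -> "PlannModel":
        return PlannModel(
            config=self.config,
            n_covariates=self.n_covariates,
            k=self.k,
            weights=[(W.copy(), b.copy()) for W, b in self.weights],
            loss_trace=list(self.loss_trace),
            feature_names=None if self.feature_names is None else list(self.feature_names),
            scaler=None if self.scaler is None else (self.scaler[0].copy(), self.scaler[1].copy()),
        )

    def to_json(self, path) -> None:
        """Self-describing checkpoint so forward passes are reproducible."""
        payload = {
            "config": asdict(self.config),
            "n_covariates": self.n_covariates,
            "k": self.k,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
            "loss_trace": self.loss_trace,
            "feature_names": self.feature_names,
            "scaler": None if self.scaler is None else [self.scaler[0].tolist(), self.scaler[1].tolist()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PlannModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=PlannConfig(**payload["config"]),
            n_covariates=payload["n_covariates"],
            k=payload["k"],
            weights=[(np.asarray(W), np.asarray(b)) for W, b in payload["weights"]],
            loss_trace=list(payload["loss_trace"]),
            feature_names=payload["feature_names"],
            scaler=None if payload["scaler"] is None
            else (np.asarray(payload["scaler"][0]), np.asarray(payload["scaler"][1])),
        )


def build_plann(config: PlannConfig, n_covariates: int, k: int) -> PlannModel:
    """Construct a network with ``n_covariates + k`` inputs, the configured
    hidden layer(s) and one sigmoid output node.

    Weights use Glorot-uniform initialisation (seeded); biases start at 0.
    """
    if n_covariates < 1 or k < 1:
        raise ValueError("need at least one covariate and one interval")
    sizes = [n_covariates + k]
    sizes += [config.node_size] * config.n_hidden_layers
    sizes += [1]
    rng = np.random.default_rng(config.seed)
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return PlannModel(config=config, n_covariates=n_covariates, k=k,
                      weights=weights, loss_trace=[])


def count_weights(model: PlannModel) -> int:
    """Number of trainable parameters: one weight per connection plus one
    bias per non-input node."""
    return int(sum(W.size + b.size for W, b in model.weights))


def _forward(weights, X, activation, dropout_masks=None):
    """Forward pass; returns hazards plus the per-layer caches needed for
    backpropagation (``raw`` holds pre-dropout activations, ``acts`` the
    layer inputs actually fed forward)."""
    act, _ = _ACTIVATIONS[activation]
    a = X
    zs, acts, raw = [], [X], []
    n_hidden = len(weights) - 1
    for i in range(n_hidden):
        W, b = weights[i]
        z = a @ W + b
        a = act(z)
        raw.append(a)
        if dropout_masks is not None:
            a = a * dropout_masks[i]
        zs.append(z)
        acts.append(a)
    W, b = weights[-1]
    z_out = (a @ W + b).ravel()
    p = _sigmoid(z_out)
    zs.append(z_out)
    return p, zs, acts, raw


def _sample_weights(y, event_class_weight):
    return np.where(y == 1, event_class_weight, 1.0)


def _loss_and_gradients(weights, X, y, activation, event_class_weight,
                        dropout_masks=None):
    """Class-weighted binary cross-entropy and its analytic gradients.

    The mean is over rows; hazards are clipped to [1e-7, 1-1e-7] inside
    the loss only.
    """
    n = X.shape[0]
    sw = _sample_weights(y, event_class_weight)
    p, zs, acts, raw = _forward(weights, X, activation, dropout_masks)
    p_clip = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(np.mean(sw * (-(y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip)))))
    # output delta: d(loss)/d(z_out) via the BCE-sigmoid simplification
    delta = (sw * (p - y) / n)  # (n,)
    _, dact = _ACTIVATIONS[activation]
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights)
    W_out, _ = weights[-1]
    grads[-1] = (acts[-1].T @ delta[:, None], np.array([delta.sum()]))
    back = delta[:, None] @ W_out.T  # (n, h_last)
    for i in range(len(weights) - 2, -1, -1):
        if dropout_masks is not None:
            back = back * dropout_masks[i]
        back = back * dact(zs[i], raw[i])
        grads[i] = (acts[i].T @ back, back.sum(axis=0))
        if i > 0:
            back = back @ weights[i][0].T
    return loss, grads


def _fit_scaler(X, n_covariates):
    """Standardize continuous covariate columns only (training mean/sd);
    0/1 dummies and the interval indicators pass through unchanged."""
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    for j in range(n_covariates):
        col = X[:, j]
        if not np.isin(np.unique(col), (0.0, 1.0)).all():
            mean[j] = col.mean()
            s = col.std()
            sd[j] = s if s > 0 else 1.0
    return mean, sd


def train(model: PlannModel, long_train: LongFormatData) -> PlannModel:
    """Train in place by mini-batch SGD with momentum and inverted dropout;
    deterministic given the config seed.  Returns the model with its
    per-epoch mean-loss trace."""
    if long_train.role != "train":
        raise ValueError("train() requires long-format data with role='train'")
    X = long_train.features()
    y = long_train.targets()
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model inputs {model.n_inputs}"
        )
    model.feature_names = long_train.feature_names
    model.scaler = _fit_scaler(X, model.n_covariates)
    X = (X - model.scaler[0]) / model.scaler[1]
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 1])
    n = X.shape[0]
    batch = n if cfg.batch_size == "full" else min(int(cfg.batch_size), n)
    velocities = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    hidden_sizes = [W.shape[1] for W, _ in model.weights[:-1]]
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb, yb = X[idx], y[idx]
            masks = None
            if cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                masks = [
                    rng.binomial(1, keep, size=(len(idx), h)) / keep
                    for h in hidden_sizes
                ]
            loss, grads = _loss_and_gradients(
                model.weights, Xb, yb, cfg.activation, cfg.event_class_weight, masks
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training loss became non-finite; try a lower learning rate"
                )
            for i, ((W, b), (vW, vb), (gW, gb)) in enumerate(
                zip(model.weights, velocities, grads)
            ):
                vW[:] = cfg.momentum * vW - cfg.learning_rate * gW
                vb[:] = cfg.momentum * vb - cfg.learning_rate * gb
                model.weights[i] = (W + vW, b + vb)
            epoch_losses.append(loss)
        model.loss_trace.append(float(np.mean(epoch_losses)))
    return model


def predict_hazards(model: PlannModel, long_test: LongFormatData) -> np.ndarray:
    """Per-subject discrete hazards ``h_1..h_k`` from a forward pass with
    dropout disabled; shape ``(n_subjects, k)``, values in (0, 1)."""
    if long_test.role != "test":
        raise ValueError("predict_hazards() requires role='test' long data")
    counts = long_test.frame.groupby("subject_id", sort=False).size()
    if not (counts == model.k).all():
        raise ValueError("every test subject must have exactly k rows")
    X = long_test.features()
    if X.shape[1] != model.n_inputs:
        raise ValueError("feature count mismatch")
    if model.scaler is not None:
        X = (X - model.scaler[0]) / model.scaler[1]
    p, _, _, _ = _forward(model.weights, X, model.config.activation)
    return p.reshape(-1, model.k)


def hazards_to_survival(h: np.ndarray) -> np.ndarray:
    """Discrete product-limit composition ``S(tau_m) = prod_{j<=m} (1 - h_j)``
    per subject; rows are monotone non-increasing."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - h, axis=-1)
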