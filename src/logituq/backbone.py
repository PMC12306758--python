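"""Fully connected backbones shared by all model families.

Provides Kaiming-uniform initialization, spectral normalization of weight
matrices, plain multi-layer perceptrons with hand-written backpropagation,
an Adam optimizer, and a supervised training loop with early stopping on a
hold-out validation set.  Everything runs on numpy; networks here are small
tabular models, not GPU workloads.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Hyperparameters of the supervised training loop.

    Attributes
    ----------
    hidden : tuple of int
        Widths of the hidden layers.
    residual : bool
        Use residual blocks (all hidden widths must then be equal).  The
        SNGP variant relies on this for approximate distance preservation.
    learning_rate, beta1, beta2, eps : float
        Adam optimizer parameters.
    batch_size : int
        Minibatch size; shuffling is seeded and therefore reproducible.
    max_epochs : int
        Hard cap on the number of passes over the training data.
    patience : int
        Number of consecutive epochs without validation-loss improvement
        tolerated before stopping.  The parameters returned are always the
        ones with the best validation loss seen.
    seed : int
        Seed controlling shuffling (and any stochastic objective terms).
    """

    hidden: tuple[int, ...] = (128, 128, 128)
    residual: bool = False
    learning_rate: float = 5e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if any(w <= 0 for w in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.residual and len(set(self.hidden)) > 1:
            raise ValueError("residual blocks require equal hidden widths")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def init_kaiming_uniform(
    shape: tuple[int, ...], seed: int | np.random.Generator, gain: float = 1.0
) -> np.ndarray:
    """Kaiming-uniform weight tensor: entries uniform on [-bound, bound].

    ``bound = gain * sqrt(6 / fan_in)`` where ``fan_in`` is the trailing
    dimension of ``shape`` (weights are stored ``(out, in)``).  The default
    ``gain`` of 1 corresponds to the ReLU-scaled bound.
    """
    if len(shape) < 1:
        raise ValueError("shape must have at least one dimension")
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    if fan_in == 0:
        raise ValueError("zero fan-in")
    rng = _as_rng(seed)
    bound = gain * np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def spectral_norm(
    W: np.ndarray,
    n_iter: int = 200,
    tol: float = 1e-12,
    u0: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Largest singular value of ``W`` by power iteration.

    Returns ``(sigma, u, v)`` with ``u, v`` the leading singular vectors.
    ``u0`` warm-starts the iteration (used during training where one or two
    iterations per step suffice).
    """
    out_dim, in_dim = W.shape
    if not np.any(W):
        return 0.0, np.zeros(out_dim), np.zeros(in_dim)
    rng = np.random.default_rng(0)
    u = u0 if u0 is not None else rng.standard_normal(out_dim)
    u = u / (np.linalg.norm(u) + 1e-30)
    sigma = 0.0
    for _ in range(n_iter):
        v = W.T @ u
        v /= np.linalg.norm(v) + 1e-30
        u_new = W @ v
        sigma_new = np.linalg.norm(u_new)
        u = u_new / (sigma_new + 1e-30)
        if abs(sigma_new - sigma) <= tol * max(sigma_new, 1.0):
            sigma = sigma_new
            break
        sigma = sigma_new
    return float(sigma), u, v


def spectral_normalize(W: np.ndarray, c: float, n_iter: int = 200) -> np.ndarray:
    """Rescale ``W`` so its largest singular value is at most ``c``.

    Returns ``W * min(1, c / sigma_max(W))``; the direction of ``W`` is
    preserved and a zero matrix is returned unchanged.
    """
    if c <= 0:
        raise ValueError("spectral bound c must be positive")
    sigma, _, _ = spectral_norm(W, n_iter=n_iter)
    if sigma <= c:
        return W
    return W * (c / sigma)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy of labels ``y`` under ``logits``."""
    return float(np.mean(softplus(logits) - y * logits))


# ---------------------------------------------------------------------------
# Plain MLP with explicit backpropagation
# ---------------------------------------------------------------------------


def mlp_init(
    d_in: int, hidden: Sequence[int], rng: np.random.Generator
) -> list[dict[str, np.ndarray]]:
    """Layer list for an MLP with ReLU hidden units and a single linear output."""
    widths = [d_in, *hidden, 1]
    layers = []
    for w_in, w_out in zip(widths[:-1], widths[1:]):
        layers.append(
            {
                "W": init_kaiming_uniform((w_out, w_in), rng),
                "b": np.zeros(w_out),
            }
        )
    return layers


def mlp_forward(
    layers: Sequence[dict[str, np.ndarray]], X: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; returns logits ``(n,)`` and per-layer input activations."""
    acts = [X]
    a = X
    for i, layer in enumerate(layers):
        z = a @ layer["W"].T + layer["b"]
        a = z if i == len(layers) - 1 else np.maximum(z, 0.0)
        if i < len(layers) - 1:
            acts.append(a)
    return a[:, 0], acts


def mlp_backward(
    layers: Sequence[dict[str, np.ndarray]],
    acts: list[np.ndarray],
    dlogits: np.ndarray,
) -> list[dict[str, np.ndarray]]:
    """Gradients of a scalar loss with ``d loss / d logits = dlogits``."""
    grads: list[dict[str, np.ndarray]] = [{} for _ in layers]
    delta = dlogits[:, None]
    for i in range(len(layers) - 1, -1, -1):
        a_in = acts[i]
        grads[i]["W"] = delta.T @ a_in
        grads[i]["b"] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ layers[i]["W"]) * (acts[i] > 0)
    return grads


class SupervisedModel(Protocol):
    """Protocol consumed by :func:`train_supervised`."""

    def get_params(self) -> list[np.ndarray]: ...

    def set_params(self, params: list[np.ndarray]) -> None: ...

    def loss_and_grad(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, list[np.ndarray]]: ...

    def val_loss(self, X: np.ndarray, y: np.ndarray) -> float: ...


class PointMLP:
    """Deterministic MLP trained with binary cross entropy."""

    def __init__(self, d_in: int, hidden: Sequence[int], seed: int | np.random.Generator):
        self.layers = mlp_init(d_in, hidden, _as_rng(seed))

    def get_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in (layer["W"], layer["b"])]

    def set_params(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for layer in self.layers:
            layer["W"] = next(it).copy()
            layer["b"] = next(it).copy()

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _ = mlp_forward(self.layers, X)
        return logits

    def loss_and_grad(self, X, y, rng=None):
        logits, acts = mlp_forward(self.layers, X)
        loss = bce_with_logits(logits, y)
        dlogits = (sigmoid(logits) - y) / len(y)
        layer_grads = mlp_backward(self.layers, acts, dlogits)
        grads = [g for lg in layer_grads for g in (lg["W"], lg["b"])]
        return loss, grads

    def val_loss(self, X, y) -> float:
        return bce_with_logits(self.predict_logits(X), y)

    def project(self) -> None:  # no constraint for the plain MLP
        return None


class Adam:
    """Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], config: TrainConfig):
        self.params = params
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = config.beta1, config.beta2, config.eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainingTrace:
    """Per-epoch training record written by :func:`train_supervised`."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = np.inf

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        ).to_csv(path, index=False)


def train_supervised(
    model: SupervisedModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> TrainingTrace:
    """Minibatch Adam with early stopping on the validation loss.

    The model is left holding the parameter state with the best validation
    loss observed.  Seeded shuffling makes repeat runs bit-identical.
    """
    X_tr, y_tr = train
    X_val, y_val = val
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.get_params(), config)
    # Adam mutates the parameter arrays in place, so keep the same list.
    params = opt.params
    trace = TrainingTrace()
    best_params: list[np.ndarray] | None = None
    bad_epochs = 0
    n = len(y_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grad(X_tr[idx], y_tr[idx], rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss {loss!r} at epoch {epoch}"
                )
            opt.step(grads)
            project = getattr(model, "project", None)
            if project is not None:
                project()
            batch_losses.append(loss)
        vl = model.val_loss(X_val, y_val)
        if not np.isfinite(vl):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        trace.epochs.append(epoch)
        trace.train_loss.append(float(np.mean(batch_losses)))
        trace.val_loss.append(float(vl))
        if vl < trace.best_val_loss:
            trace.best_val_loss = float(vl)
            trace.best_epoch = epoch
            best_params = [p.copy() for p in params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best_params is not None:
        model.set_params(best_params)
    return trace
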