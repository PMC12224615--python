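"""Stacked autoencoder for the low-dimensional feature space.

The encoder maps HVG-standardized expression vectors into a bottleneck
feature space F of dimension d << g'.  Training follows the classic
stacked-autoencoder recipe: each encoder/decoder layer pair is pretrained
greedily to reconstruct the output of the preceding layer, then the full
stack is fine-tuned end to end on reconstruction MSE.  Hidden encoder
layers use ReLU; the bottleneck and hidden decoder layers use tanh; the
final reconstruction layer is linear so standardized data (unbounded) can
be reproduced.

Everything runs in plain numpy with seeded fan-in-scaled uniform
initialization: runs are bit-for-bit reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig

__all__ = ["EncoderModel", "FeatureMatrix", "pretrain_layerwise", "finetune", "encode"]


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    return z  # linear


def _act_grad(name: str, a: np.ndarray) -> np.ndarray:
    # gradients expressed through the activation output a
    if name == "relu":
        return (a > 0).astype(a.dtype)
    if name == "tanh":
        return 1.0 - a * a
    return np.ones_like(a)


class _Dense:
    """One fully connected layer with a fixed activation."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._vW = np.zeros_like(self.W)
        self._vb = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None
        self._a: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        a = _act(self.activation, x @ self.W + self.b)
        if cache:
            self._x, self._a = x, a
        return a

    def backward(self, grad_out: np.ndarray, lr: float, momentum: float) -> np.ndarray:
        """SGD step from d(loss)/d(output); returns d(loss)/d(input)."""
        dz = grad_out * _act_grad(self.activation, self._a)
        dW = self._x.T @ dz
        db = dz.sum(axis=0)
        grad_in = dz @ self.W.T
        self._vW = momentum * self._vW - lr * dW
        self._vb = momentum * self._vb - lr * db
        self.W += self._vW
        self.b += self._vb
        return grad_in

    def copy_weights_from(self, other: "_Dense") -> None:
        self.W = other.W.copy()
        self.b = other.b.copy()


@dataclass
class FeatureMatrix:
    """n x d bottleneck embedding of cells (one row per retained cell)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


class EncoderModel:
    """Mirrored encoder/decoder stack.

    ``layer_dims`` is [g', h1, ..., d]; the decoder mirrors it in reverse.
    Encoder hidden layers are ReLU with a tanh bottleneck; decoder hidden
    layers are tanh with a linear output layer.
    """

    def __init__(self, layer_dims: Sequence[int], rng: np.random.Generator):
        dims = list(layer_dims)
        if len(dims) < 2:
            raise ValueError("need at least input and bottleneck dims")
        if dims[-1] >= dims[0]:
            raise ValueError("bottleneck must be smaller than the input dim")
        self.layer_dims = dims
        n_enc = len(dims) - 1
        self.encoder: list[_Dense] = []
        for i in range(n_enc):
            act = "tanh" if i == n_enc - 1 else "relu"
            self.encoder.append(_Dense(dims[i], dims[i + 1], act, rng))
        rev = dims[::-1]
        self.decoder: list[_Dense] = []
        for i in range(n_enc):
            act = "linear" if i == n_enc - 1 else "tanh"
            self.decoder.append(_Dense(rev[i], rev[i + 1], act, rng))

    # -- forward passes ----------------------------------------------------
    def encode(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        h = np.asarray(x, float)
        for layer in self.encoder:
            h = layer.forward(h, cache=cache)
        return h

    def decode(self, h: np.ndarray, cache: bool = False) -> np.ndarray:
        for layer in self.decoder:
            h = layer.forward(h, cache=cache)
        return h

    def reconstruct(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        return self.decode(self.encode(x, cache=cache), cache=cache)

    # -- training ----------------------------------------------------------
    def backprop_encoder(self, grad_features: np.ndarray, lr: float, momentum: float) -> None:
        """Push d(loss)/d(bottleneck) through the cached encoder stack."""
        g = grad_features
        for layer in reversed(self.encoder):
            g = layer.backward(g, lr, momentum)

    def backprop_full(self, grad_recon: np.ndarray, lr: float, momentum: float) -> None:
        g = grad_recon
        for layer in reversed(self.decoder):
            g = layer.backward(g, lr, momentum)
        for layer in reversed(self.encoder):
            g = layer.backward(g, lr, momentum)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.encoder + self.decoder:
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.encoder + self.decoder:
            layer.W = next(it).copy()
            layer.b = next(it).copy()

    def reconstruction_mse(self, x: np.ndarray) -> float:
        r = self.reconstruct(x)
        return float(np.mean((r - x) ** 2))


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.isfinite(x).all():
        raise ValueError(f"{what} contains non-finite values")


def _minibatches(n: int, size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, size):
        yield order[start:start + size]


def _train_reconstruction(model_fwd, model_bwd, x: np.ndarray, target: np.ndarray,
                          epochs: int, cfg: RunConfig, rng: np.random.Generator) -> list[float]:
    """Generic minibatch MSE loop; returns per-epoch mean losses."""
    trace = []
    n = x.shape[0]
    size = min(cfg.minibatch_size, n)
    for _ in range(epochs):
        losses = []
        for idx in _minibatches(n, size, rng):
            out = model_fwd(x[idx])
            err = out - target[idx]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "reconstruction loss diverged (NaN/inf); try a smaller learning_rate"
                )
            losses.append(loss)
            model_bwd(2.0 * err / err.size)
        trace.append(float(np.mean(losses)))
    return trace


def pretrain_layerwise(x: np.ndarray, dims: Sequence[int], cfg: RunConfig) -> EncoderModel:
    """Greedy layer-wise pretraining of the stacked autoencoder.

    Each encoder layer and its mirrored decoder layer are trained as a
    shallow autoencoder reconstructing the previous layer's output; the
    full stack is then assembled from these weights.  Per-stage epoch
    traces are stored on the returned model as ``pretrain_traces``.
    """
    x = np.asarray(x, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells to pretrain")
    _check_finite(x, "pretraining input")
    dims = [x.shape[1]] + list(dims) if list(dims)[0] != x.shape[1] else list(dims)
    rng = np.random.default_rng(cfg.seed)
    model = EncoderModel(dims, rng)

    traces = []
    rep = x
    n_enc = len(model.encoder)
    for i, enc in enumerate(model.encoder):
        dec = model.decoder[n_enc - 1 - i]  # mirrored partner

        def fwd(batch, enc=enc, dec=dec):
            return dec.forward(enc.forward(batch, cache=True), cache=True)

        def bwd(grad, enc=enc, dec=dec):
            g = dec.backward(grad, cfg.learning_rate, cfg.momentum)
            enc.backward(g, cfg.learning_rate, cfg.momentum)

        traces.append(_train_reconstruction(fwd, bwd, rep, rep, cfg.pretrain_epochs, cfg, rng))
        rep = enc.forward(rep)
    model.pretrain_traces = traces
    return model


def finetune(model: EncoderModel, x: np.ndarray, cfg: RunConfig) -> EncoderModel:
    """End-to-end reconstruction fine-tuning.

    Keeps the best (lowest full-data MSE) weights seen, so the returned
    model's reconstruction error never exceeds the pretrained one.  Stores
    the per-epoch trace as ``finetune_trace``.
    """
    x = np.asarray(x, float)
    _check_finite(x, "finetuning input")
    if cfg.finetune_epochs == 0:
        model.finetune_trace = []
        return model
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0])
    best_mse = model.reconstruction_mse(x)
    best_weights = model.get_weights()
    trace = []
    n = x.shape[0]
    size = min(cfg.minibatch_size, n)
    for _ in range(cfg.finetune_epochs):
        for idx in _minibatches(n, size, rng):
            out = model.reconstruct(x[idx], cache=True)
            err = out - x[idx]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "fine-tuning loss diverged (NaN/inf); try a smaller learning_rate"
                )
            model.backprop_full(2.0 * err / err.size, cfg.learning_rate, cfg.momentum)
        mse = model.reconstruction_mse(x)
        trace.append(mse)
        if mse < best_mse:
            best_mse = mse
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    model.finetune_trace = trace
    return model


def encode(model: EncoderModel, x: np.ndarray) -> FeatureMatrix:
    """Deterministic forward pass through the encoder."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.layer_dims[0]:
        raise ValueError(
            f"input has {x.shape[1]} features, model expects {model.layer_dims[0]}"
        )
    return FeatureMatrix(model.encode(x))
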