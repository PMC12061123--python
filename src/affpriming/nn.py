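"""A compact NumPy implementation of the two-layer convolutional
classifier used for single-trial decoding.

Architecture (input: one EEG trial, channels × time):

1. spatial convolution — a 2-D convolution whose kernel spans all
   channels at a single timepoint, collapsing the channel axis into
   ``n_filters`` learned spatial filters; dropout 0.5;
2. temporal convolution — kernel 1 × 25 over time, valid padding,
   stride 1, ``n_filters`` output maps; dropout 0.5;
3. flatten → one dense unit with a sigmoid, thresholded at 0.5.

Activations, losses, optimizers and Glorot-uniform initialization
follow the usual Keras semantics (including the unusual option of an
elementwise-normalizing softmax as a hidden activation, applied along
the time axis). Gradients are analytic and are verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

TEMPORAL_KERNEL = 25
DROPOUT_RATE = 0.5
_EPS = 1e-7

ACTIVATIONS = ("relu", "softmax", "softplus", "tanh", "selu", "elu")
OPTIMIZERS = ("adam", "sgd", "rmsprop")
LEARNING_RATES = (1e-2, 1e-3, 1e-4)
LOSSES = ("binary_crossentropy", "poisson", "kl_divergence")
N_FILTERS_CHOICES = (4, 5, 6, 7, 8)

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


@dataclass(frozen=True)
class NetSpec:
    """One point of the random-search space."""
    activation: str = "relu"
    n_filters: int = 6
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "binary_crossentropy"
    dropout: float = DROPOUT_RATE
    epochs: int = 80
    batch_size: int = 32
    temporal_kernel: int = TEMPORAL_KERNEL

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation {self.activation!r} not in {ACTIVATIONS}")
        if self.n_filters not in N_FILTERS_CHOICES:
            raise ValueError(f"n_filters {self.n_filters} not in {N_FILTERS_CHOICES}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer {self.optimizer!r} not in {OPTIMIZERS}")
        if self.loss not in LOSSES:
            raise ValueError(f"loss {self.loss!r} not in {LOSSES}")
        if self.activation == "softmax":
            warnings.warn("softmax as an elementwise hidden activation is "
                          "unusual; applied along the time axis", stacklevel=2)


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "softplus":
        return np.logaddexp(z, 0.0)
    if name == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0)))
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(np.minimum(z, 0)))
    if name == "softmax":
        e = np.exp(z - z.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(name)


def _act_backward(name: str, z: np.ndarray, a: np.ndarray, grad: np.ndarray) -> np.ndarray:
    if name == "relu":
        return grad * (z > 0)
    if name == "tanh":
        return grad * (1.0 - a**2)
    if name == "softplus":
        return grad / (1.0 + np.exp(-z))
    if name == "elu":
        return grad * np.where(z > 0, 1.0, a + 1.0)
    if name == "selu":
        return grad * np.where(z > 0, _SELU_SCALE, a + _SELU_SCALE * _SELU_ALPHA)
    if name == "softmax":
        return a * (grad - (grad * a).sum(axis=-1, keepdims=True))
    raise ValueError(name)


def _loss_and_logit_grad(loss: str, p: np.ndarray, y: np.ndarray):
    """Mean loss over the batch and its gradient w.r.t. the pre-sigmoid
    logit. ``p`` is the sigmoid output, ``y`` the 0/1 labels."""
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    n = len(y)
    dp_dz = p * (1.0 - p)
    if loss == "binary_crossentropy":
        value = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))
        dz = (p - y) / n
    elif loss == "poisson":
        value = np.mean(pc - y * np.log(pc))
        dz = (1.0 - y / pc) * dp_dz / n
    elif loss == "kl_divergence":
        # sum y·log(y/p) with 0·log0 = 0: only the positive class contributes
        value = np.mean(np.where(y > 0, y * np.log(np.maximum(y, _EPS) / pc), 0.0))
        dz = np.where(y > 0, -y / pc, 0.0) * dp_dz / n
    else:
        raise ValueError(loss)
    return float(value), dz


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        self.kind, self.lr, self.t = kind, lr, 0
        self.state: dict = {}

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            if self.kind == "sgd":
                params[k] -= self.lr * g
            elif self.kind == "rmsprop":
                v = self.state.setdefault(k, np.zeros_like(g))
                v *= 0.9
                v += 0.1 * g * g
                params[k] -= self.lr * g / (np.sqrt(v) + _EPS)
            elif self.kind == "adam":
                m = self.state.setdefault(("m", k), np.zeros_like(g))
                v = self.state.setdefault(("v", k), np.zeros_like(g))
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                mhat = m / (1 - 0.9**self.t)
                vhat = v / (1 - 0.999**self.t)
                params[k] -= self.lr * mhat / (np.sqrt(vhat) + _EPS)
            else:
                raise ValueError(self.kind)


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ConvNet:
    """The two-convolution binary classifier.

    Shapes for input (B, C, T): spatial conv → (B, F, T); temporal conv
    (valid) → (B, F, U) with U = T − K + 1; flatten → dense sigmoid.
    """

    def __init__(self, spec: NetSpec, n_channels: int, n_times: int, seed: int = 0):
        if n_times <= spec.temporal_kernel:
            raise ValueError(
                f"need more than {spec.temporal_kernel} timepoints, got {n_times}")
        self.spec = spec
        self.n_channels, self.n_times = n_channels, n_times
        self.n_out = n_times - spec.temporal_kernel + 1
        rng = np.random.default_rng(seed)
        F, K = spec.n_filters, spec.temporal_kernel
        self.params = {
            "W1": _glorot(rng, (F, n_channels), n_channels, F),
            "b1": np.zeros(F),
            "W2": _glorot(rng, (F, F, K), F * K, F * K),
            "b2": np.zeros(F),
            "w3": _glorot(rng, (F * self.n_out,), F * self.n_out, 1),
            "b3": np.zeros(1),
        }
        self._opt = _Optimizer(spec.optimizer, spec.learning_rate)

    # -- forward / backward -------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> tuple:
        """Return (sigmoid output, cache). ``x`` is (B, C, T)."""
        P, s = self.params, self.spec
        z1 = np.einsum("fc,bct->bft", P["W1"], x) + P["b1"][None, :, None]
        a1 = _act(s.activation, z1)
        if train:
            m1 = (rng.random(a1.shape) >= s.dropout) / (1.0 - s.dropout)
            a1d = a1 * m1
        else:
            m1 = None
            a1d = a1
        win = np.lib.stride_tricks.sliding_window_view(a1d, s.temporal_kernel, axis=2)
        z2 = np.einsum("bfuk,gfk->bgu", win, P["W2"]) + P["b2"][None, :, None]
        a2 = _act(s.activation, z2)
        if train:
            m2 = (rng.random(a2.shape) >= s.dropout) / (1.0 - s.dropout)
            a2d = a2 * m2
        else:
            m2 = None
            a2d = a2
        flat = a2d.reshape(len(x), -1)
        logit = flat @ P["w3"] + P["b3"][0]
        p = 1.0 / (1.0 + np.exp(-logit))
        cache = (x, z1, a1, m1, a1d, z2, a2, m2, flat)
        return p, cache

    def backward(self, cache, dlogit: np.ndarray) -> dict:
        P, s = self.params, self.spec
        x, z1, a1, m1, a1d, z2, a2, m2, flat = cache
        B = len(x)
        K = s.temporal_kernel
        grads = {"w3": flat.T @ dlogit, "b3": np.array([dlogit.sum()])}
        dflat = np.outer(dlogit, P["w3"])
        da2d = dflat.reshape(a2.shape)
        da2 = da2d * m2 if m2 is not None else da2d
        dz2 = _act_backward(s.activation, z2, a2, da2)
        win = np.lib.stride_tricks.sliding_window_view(a1d, K, axis=2)
        grads["W2"] = np.einsum("bgu,bfuk->gfk", dz2, win)
        grads["b2"] = dz2.sum(axis=(0, 2))
        # full correlation of dz2 with W2 to propagate to a1
        pad = np.zeros((B, dz2.shape[1], a1d.shape[2] + K - 1))
        pad[:, :, K - 1:K - 1 + dz2.shape[2]] = dz2
        pwin = np.lib.stride_tricks.sliding_window_view(pad, K, axis=2)
        da1d = np.einsum("bgtk,gfk->bft", pwin, P["W2"][:, :, ::-1])
        da1 = da1d * m1 if m1 is not None else da1d
        dz1 = _act_backward(s.activation, z1, a1, da1)
        grads["W1"] = np.einsum("bft,bct->fc", dz1, x)
        grads["b1"] = dz1.sum(axis=(0, 2))
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray, seed: int = 0, verbose: bool = False):
        """Mini-batch training with per-epoch shuffling."""
        s = self.spec
        rng = np.random.default_rng(seed)
        n = len(x)
        history = []
        for _ in range(s.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, s.batch_size):
                idx = order[start:start + s.batch_size]
                p, cache = self.forward(x[idx], train=True, rng=rng)
                value, dlogit = _loss_and_logit_grad(s.loss, p, y[idx])
                grads = self.backward(cache, dlogit)
                self._opt.step(self.params, grads)
                epoch_loss += value * len(idx)
            history.append(epoch_loss / n)
        return history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p, _ = self.forward(x, train=False)
        return p

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) > threshold).astype(int)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == y))


def parameter_count(spec: NetSpec, n_channels: int, n_times: int) -> int:
    """Closed-form trainable-parameter count for the three layers."""
    F, K = spec.n_filters, spec.temporal_kernel
    u = n_times - K + 1
    return (F * n_channels + F) + (F * F * K + F) + (F * u + 1)
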