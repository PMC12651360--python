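"""ISNet-1D: a 1-D Inception + squeeze-and-excitation regression network.

Implemented directly in NumPy (explicit forward/backward passes, Adam with
step-decay, early stopping on validation loss) so the package has no deep
learning framework dependency and training is bit-reproducible for a fixed
seed on any platform.

Architecture (main path, lengths for the default 2623-point spectrum input):

    input (1 x 2623)
    -> conv(16, k3, same) -> batch norm -> ReLU -> max-pool(2,2)   (16 x 1311)
    -> Inception: [conv1x1 | conv1x1-conv3 | conv1x1-conv5 | pool3-conv1x1]
       depth-concatenated                                          (64 x 1311)
    -> squeeze-and-excitation channel gate (reduction 4)           (64 x 1311)
    -> conv(32, k5, same) -> ReLU -> max-pool(2,2)                 (32 x 655)
    -> flatten -> dense(64) -> ReLU -> dropout(0.3) -> dense(1)

The training objective is mean squared error plus an L2 penalty
``(1/n) sum (y_i - yhat_i)^2 + (lambda/2) ||w||^2`` applied to convolution
and dense weights (not biases or batch-norm parameters).

Numerical conventions: parameters are float32 for training throughput;
``predict`` evaluates in float64 so a sample's prediction is identical
alone or inside any batch to well below 1e-6.  Batch norm uses batch
statistics in training and running statistics in evaluation (momentum 0.1,
eps 1e-5); a layer can pin its running statistics (``frozen_stats``), which
the transfer-learning stage uses to keep frozen feature extractors
bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ISNetError",
    "TrainingDivergedError",
    "ISNetConfig",
    "TrainConfig",
    "TrainHistory",
    "TrainedNet",
    "Network",
    "build_isnet",
    "loss_eq1",
    "train",
    "predict",
]


class ISNetError(ValueError):
    """Domain error raised by the network stage."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ISNetConfig:
    """Architecture hyperparameters (defaults follow the published design)."""

    input_length: int = 2623
    stem_filters: int = 16
    stem_kernel: int = 3
    branch_filters: tuple[int, int, int, int] = (16, 16, 16, 16)
    se_reduction: int = 4
    post_filters: int = 32
    post_kernel: int = 5
    pool_size: int = 2
    pool_stride: int = 2
    fc_units: int = 64
    dropout: float = 0.3
    output_dim: int = 1

    def __post_init__(self) -> None:
        if min(self.stem_filters, self.post_filters, self.fc_units,
               *self.branch_filters) < 1:
            raise ISNetError("all filter/unit counts must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ISNetError("dropout must be in [0, 1)")
        if self.pool_size != self.pool_stride:
            raise ISNetError("only non-overlapping pooling is supported")
        if sum(self.branch_filters) % self.se_reduction != 0:
            raise ISNetError("SE reduction must divide concatenated channels")

    @property
    def inception_channels(self) -> int:
        return sum(self.branch_filters)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (defaults follow the published training table)."""

    batch_size: int = 16
    initial_lr: float = 1e-4
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 50
    l2_lambda: float = 1e-4
    max_epochs: int = 300
    early_stopping_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_drop_period, self.max_epochs) < 1:
            raise ISNetError("batch_size/lr_drop_period/max_epochs must be >= 1")
        if self.initial_lr <= 0 or self.lr_drop_factor <= 0 or self.l2_lambda < 0:
            raise ISNetError("invalid learning-rate or regularization setting")
        if not (0 < self.early_stopping_patience < self.max_epochs + 1):
            raise ISNetError("patience must be in [1, max_epochs]")


@dataclass
class TrainHistory:
    """Per-epoch training/validation losses and the best epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class TrainedNet:
    """A trained network together with its configs and history."""

    network: "Network"
    isnet_config: ISNetConfig
    train_config: TrainConfig
    best_epoch: int
    history: TrainHistory


# --------------------------------------------------------------------------
# parameters and layers
# --------------------------------------------------------------------------


class Param:
    """A trainable array with its gradient buffer and a kind tag.

    kind is one of 'weight' (L2-penalized), 'bias', 'bn'.
    """

    __slots__ = ("value", "grad", "kind", "name")

    def __init__(self, value: np.ndarray, kind: str, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.kind = kind
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _cast(w: np.ndarray, dtype) -> np.ndarray:
    return w if w.dtype == dtype else w.astype(dtype)


class Layer:
    name = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError

    def state(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


class Conv1d(Layer):
    """Stride-1, 'same'-padded 1-D convolution via im2col matmul."""

    def __init__(self, cin, cout, k, rng, name, dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad_l = (k - 1) // 2
        self.pad_r = k - 1 - self.pad_l
        scale = np.sqrt(2.0 / (cin * k))
        self.W = Param(rng.normal(0.0, scale, (cin * k, cout)).astype(dtype),
                       "weight", f"{name}.W")
        self.b = Param(np.zeros(cout, dtype=dtype), "bias", f"{name}.b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        B, C, L = x.shape
        if C != self.cin:
            raise ISNetError(f"{self.name}: expected {self.cin} channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        win = sliding_window_view(xp, self.k, axis=2)      # (B, C, L, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, L, C * self.k)
        self._cols = cols
        self._L = L
        y = cols @ _cast(self.W.value, x.dtype) + _cast(self.b.value, x.dtype)
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, cout, L)

    def backward(self, g):
        B, _, L = g.shape
        gB = np.ascontiguousarray(g.transpose(0, 2, 1))    # (B, L, cout)
        cols = self._cols
        self.W.grad += np.tensordot(cols, gB, axes=([0, 1], [0, 1])).astype(
            self.W.grad.dtype, copy=False)
        self.b.grad += gB.sum(axis=(0, 1)).astype(self.b.grad.dtype, copy=False)
        gcols = gB @ _cast(self.W.value, gB.dtype).T       # (B, L, cin*k)
        gcols = gcols.reshape(B, L, self.cin, self.k).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, self.cin, L + self.k - 1), dtype=gB.dtype)
        for t in range(self.k):
            gxp[:, :, t:t + L] += gcols[:, :, :, t]
        return gxp[:, :, self.pad_l:self.pad_l + L]


class BatchNorm1d(Layer):
    def __init__(self, c, name, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c, dtype=dtype), "bn", f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn", f"{name}.beta")
        self.run_mean = np.zeros(c, dtype=np.float64)
        self.run_var = np.ones(c, dtype=np.float64)
        self.frozen_stats = False
        self.name = name

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"run_mean": self.run_mean.copy(), "run_var": self.run_var.copy()}

    def load_state(self, state):
        self.run_mean = state["run_mean"].copy()
        self.run_var = state["run_var"].copy()

    def forward(self, x, train=False, rng=None):
        use_batch = train and not self.frozen_stats
        if use_batch:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean.astype(np.float64)
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var.astype(np.float64)
        else:
            mean = self.run_mean.astype(x.dtype)
            var = self.run_var.astype(x.dtype)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * ivar[:, None]
        self._xhat, self._ivar, self._batch_mode = xhat, ivar, use_batch
        return _cast(self.gamma.value, x.dtype)[:, None] * xhat + \
            _cast(self.beta.value, x.dtype)[:, None]

    def backward(self, g):
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (g * xhat).sum(axis=(0, 2)).astype(
            self.gamma.grad.dtype, copy=False)
        self.beta.grad += g.sum(axis=(0, 2)).astype(self.beta.grad.dtype,
                                                    copy=False)
        gamma = _cast(self.gamma.value, g.dtype)
        dxhat = g * gamma[:, None]
        if not self._batch_mode:
            return dxhat * ivar[:, None]
        B, C, L = g.shape
        n = B * L
        s1 = dxhat.sum(axis=(0, 2))[:, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[:, None]
        return (ivar[:, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self, name):
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling (size == stride); trailing samples dropped."""

    def __init__(self, size, name):
        self.size = size
        self.name = name

    def forward(self, x, train=False, rng=None):
        B, C, L = x.shape
        k = self.size
        Lo = L // k
        # running max over the k phases; first-wins tie-break
        y = x[:, :, 0:Lo * k:k]
        sel = np.zeros((B, C, Lo), dtype=np.int8)
        for t in range(1, k):
            xt = x[:, :, t:Lo * k:k]
            better = xt > y
            y = np.where(better, xt, y)
            sel = np.where(better, np.int8(t), sel)
        self._sel = sel
        self._inshape = x.shape
        return y

    def backward(self, g):
        B, C, L = self._inshape
        k = self.size
        Lo = L // k
        gx = np.zeros((B, C, L), dtype=g.dtype)
        for t in range(k):
            mask = self._sel == t
            gx[:, :, t:Lo * k:k] = np.where(mask, g, 0)
        return gx


class SamePool(Layer):
    """Stride-1 'same' max pooling (odd window) used inside the Inception block."""

    def __init__(self, size, name):
        if size % 2 != 1:
            raise ISNetError("SamePool window must be odd")
        self.size = size
        self.name = name

    def forward(self, x, train=False, rng=None):
        k = self.size
        p = (k - 1) // 2
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        # running max over window offsets; first-wins tie-break
        y = xp[:, :, 0:L]
        sel = np.zeros((B, C, L), dtype=np.int8)
        for t in range(1, k):
            xt = xp[:, :, t:t + L]
            better = xt > y
            y = np.where(better, xt, y)
            sel = np.where(better, np.int8(t), sel)
        self._sel = sel
        self._inshape = x.shape
        return y

    def backward(self, g):
        B, C, L = self._inshape
        k = self.size
        p = (k - 1) // 2
        gxp = np.zeros((B, C, L + 2 * p), dtype=g.dtype)
        for t in range(k):
            gxp[:, :, t:t + L] += np.where(self._sel == t, g, 0)
        return gxp[:, :, p:p + L]


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool over length.  Excitation: two kernel-1
    convolutions on the channel vector (ReLU between, sigmoid after); the
    resulting per-channel gates in (0, 1) rescale the feature maps.
    """

    def __init__(self, c, reduction, rng, name, dtype=np.float32):
        cr = c // reduction
        self.W1 = Param(rng.normal(0, np.sqrt(2.0 / c), (c, cr)).astype(dtype),
                        "weight", f"{name}.W1")
        self.b1 = Param(np.zeros(cr, dtype=dtype), "bias", f"{name}.b1")
        self.W2 = Param(rng.normal(0, np.sqrt(2.0 / cr), (cr, c)).astype(dtype),
                        "weight", f"{name}.W2")
        self.b2 = Param(np.zeros(c, dtype=dtype), "bias", f"{name}.b2")
        self.name = name

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def gates(self, x) -> np.ndarray:
        """Per-channel gate values in (0,1) for input feature maps."""
        z = x.mean(axis=2)
        h = np.maximum(z @ _cast(self.W1.value, x.dtype) + _cast(self.b1.value, x.dtype), 0.0)
        return 1.0 / (1.0 + np.exp(-(h @ _cast(self.W2.value, x.dtype) + _cast(self.b2.value, x.dtype))))

    def forward(self, x, train=False, rng=None):
        z = x.mean(axis=2)                                  # (B, C)
        h = z @ _cast(self.W1.value, x.dtype) + _cast(self.b1.value, x.dtype)
        hr = np.maximum(h, 0.0)
        s = 1.0 / (1.0 + np.exp(-(hr @ _cast(self.W2.value, x.dtype)
                                  + _cast(self.b2.value, x.dtype))))
        self._x, self._z, self._hr, self._s = x, z, hr, s
        return x * s[:, :, None]

    def backward(self, g):
        x, z, hr, s = self._x, self._z, self._hr, self._s
        L = x.shape[2]
        dx = g * s[:, :, None]
        ds = (g * x).sum(axis=2)                            # (B, C)
        dpre2 = ds * s * (1.0 - s)
        self.W2.grad += (hr.T @ dpre2).astype(self.W2.grad.dtype, copy=False)
        self.b2.grad += dpre2.sum(axis=0).astype(self.b2.grad.dtype, copy=False)
        dh = (dpre2 @ _cast(self.W2.value, g.dtype).T) * (hr > 0)
        self.W1.grad += (z.T @ dh).astype(self.W1.grad.dtype, copy=False)
        self.b1.grad += dh.sum(axis=0).astype(self.b1.grad.dtype, copy=False)
        dz = dh @ _cast(self.W1.value, g.dtype).T           # (B, C)
        dx += dz[:, :, None] / L
        return dx


class Inception(Layer):
    """Four parallel branches, depth-concatenated.

    (1) conv1x1; (2) conv1x1 -> conv3; (3) conv1x1 -> conv5;
    (4) max-pool(3, stride 1, same) -> conv1x1.  Each convolution is
    followed by ReLU.
    """

    def __init__(self, cin, widths, rng, name, dtype=np.float32):
        b1, b2, b3, b4 = widths
        mk = lambda ci, co, k, nm: Conv1d(ci, co, k, rng, f"{name}.{nm}", dtype)
        self.branches: list[list[Layer]] = [
            [mk(cin, b1, 1, "b1"), ReLU(f"{name}.b1.relu")],
            [mk(cin, b2, 1, "b2a"), ReLU(f"{name}.b2a.relu"),
             mk(b2, b2, 3, "b2b"), ReLU(f"{name}.b2b.relu")],
            [mk(cin, b3, 1, "b3a"), ReLU(f"{name}.b3a.relu"),
             mk(b3, b3, 5, "b3b"), ReLU(f"{name}.b3b.relu")],
            [SamePool(3, f"{name}.pool"),
             mk(cin, b4, 1, "b4"), ReLU(f"{name}.b4.relu")],
        ]
        self.widths = tuple(widths)
        self.name = name

    def params(self):
        out = []
        for branch in self.branches:
            for layer in branch:
                out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train=train, rng=rng)
            outs.append(h)
        return np.concatenate(outs, axis=1)

    def backward(self, g):
        gx = None
        start = 0
        for branch, w in zip(self.branches, self.widths):
            gb = g[:, start:start + w, :]
            start += w
            for layer in reversed(branch):
                gb = layer.backward(gb)
            gx = gb if gx is None else gx + gb
        return gx


class Flatten(Layer):
    def __init__(self, name):
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin, nout, rng, name, dtype=np.float32):
        scale = np.sqrt(2.0 / nin)
        self.W = Param(rng.normal(0, scale, (nin, nout)).astype(dtype),
                       "weight", f"{name}.W")
        self.b = Param(np.zeros(nout, dtype=dtype), "bias", f"{name}.b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        if x.shape[1] != self.W.value.shape[0]:
            raise ISNetError(f"{self.name}: input width {x.shape[1]} != "
                             f"{self.W.value.shape[0]}")
        self._x = x
        return x @ _cast(self.W.value, x.dtype) + _cast(self.b.value, x.dtype)

    def backward(self, g):
        self.W.grad += (self._x.T @ g).astype(self.W.grad.dtype, copy=False)
        self.b.grad += g.sum(axis=0).astype(self.b.grad.dtype, copy=False)
        return g @ _cast(self.W.value, g.dtype).T


class Dropout(Layer):
    def __init__(self, p, name):
        self.p = p
        self.name = name

    def forward(self, x, train=False, rng=None):
        if train and self.p > 0:
            if rng is None:
                raise ISNetError("dropout requires an rng in training mode")
            self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask.astype(x.dtype)
        self._mask = None
        return x

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask.astype(g.dtype)


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


class Network:
    """An ordered stack of named layers with explicit backprop."""

    def __init__(self, layers: list[tuple[str, Layer]], input_length: int):
        self.layers = layers
        self.input_length = input_length
        self._by_name = dict(layers)
        if len(self._by_name) != len(layers):
            raise ISNetError("duplicate layer names")

    # -- basic plumbing ----------------------------------------------------

    def layer(self, name: str) -> Layer:
        if name not in self._by_name:
            raise ISNetError(f"no layer named {name!r}")
        return self._by_name[name]

    def params(self) -> list[Param]:
        out = []
        for _, layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grads(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> dict:
        state = {p.name: p.value.copy() for p in self.params()}
        for name, layer in self.layers:
            for k, v in layer.state().items():
                state[f"{name}::{k}"] = v
        return state

    def set_state(self, state: dict) -> None:
        for p in self.params():
            p.value = state[p.name].copy()
        for name, layer in self.layers:
            own = {k.split("::", 1)[1]: v for k, v in state.items()
                   if k.startswith(f"{name}::")}
            if own:
                layer.load_state(own)

    # -- passes ------------------------------------------------------------

    def _prep(self, x: np.ndarray, dtype) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != self.input_length:
            raise ISNetError(
                f"expected input of length {self.input_length}, got {x.shape}"
            )
        return x.astype(dtype)[:, None, :]                 # (B, 1, L)

    def forward(self, x, train=False, rng=None, dtype=np.float32,
                capture: dict | None = None):
        h = self._prep(x, dtype)
        for name, layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
            if capture is not None:
                capture[name] = h
        return h                                            # (B, output_dim)

    def backward(self, g, to_layer: str | None = None):
        """Backpropagate; if ``to_layer`` is given, stop there and return the
        gradient with respect to that layer's output."""
        for name, layer in reversed(self.layers):
            if name == to_layer:
                return g
            g = layer.backward(g)
        if to_layer is not None:
            raise ISNetError(f"no layer named {to_layer!r}")
        return g


def build_isnet(config: ISNetConfig, seed: int = 0,
                dtype=np.float32) -> Network:
    """Construct an ISNet-1D with seeded (He) initialization."""
    rng = np.random.default_rng(seed)
    c = config
    L_after_pool1 = c.input_length // c.pool_size
    L_after_pool2 = L_after_pool1 // c.pool_size
    flat = c.post_filters * L_after_pool2
    layers: list[tuple[str, Layer]] = [
        ("stem_conv", Conv1d(1, c.stem_filters, c.stem_kernel, rng,
                             "stem_conv", dtype)),
        ("stem_bn", BatchNorm1d(c.stem_filters, "stem_bn", dtype=dtype)),
        ("stem_relu", ReLU("stem_relu")),
        ("pool1", MaxPool(c.pool_size, "pool1")),
        ("inception", Inception(c.stem_filters, c.branch_filters, rng,
                                "inception", dtype)),
        ("se", SEBlock(c.inception_channels, c.se_reduction, rng, "se", dtype)),
        ("final_conv", Conv1d(c.inception_channels, c.post_filters,
                              c.post_kernel, rng, "final_conv", dtype)),
        ("final_relu", ReLU("final_relu")),
        ("pool2", MaxPool(c.pool_size, "pool2")),
        ("flatten", Flatten("flatten")),
        ("fc1", Dense(flat, c.fc_units, rng, "fc1", dtype)),
        ("fc1_relu", ReLU("fc1_relu")),
        ("dropout", Dropout(c.dropout, "dropout")),
        ("out", Dense(c.fc_units, c.output_dim, rng, "out", dtype)),
    ]
    return Network(layers, input_length=c.input_length)


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------


def _collect_weights(weights) -> list[np.ndarray]:
    if isinstance(weights, TrainedNet):
        weights = weights.network
    if isinstance(weights, Network):
        return [p.value for p in weights.params() if p.kind == "weight"]
    return [np.asarray(w) for w in weights]


def loss_eq1(y, yhat, weights=(), lam: float = 0.0) -> float:
    """Mean squared error plus (lambda/2) * sum of squared weights.

    With ``lam == 0`` this is exactly the MSE.  ``weights`` may be a list of
    arrays, a Network, or a TrainedNet (only 'weight'-kind parameters are
    penalized).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ISNetError("y and yhat must be equal-length, non-empty")
    if lam < 0:
        raise ISNetError("lambda must be >= 0")
    mse = float(np.mean((y - yhat) ** 2))
    if lam == 0.0:
        return mse
    reg = sum(float(np.sum(np.asarray(w, dtype=float) ** 2))
              for w in _collect_weights(weights))
    return mse + 0.5 * lam * reg


# --------------------------------------------------------------------------
# optimizer and training
# --------------------------------------------------------------------------


class Adam:
    def __init__(self, params: Sequence[Param], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {p.name: np.zeros_like(p.value, dtype=np.float64) for p in params}
        self.v = {p.name: np.zeros_like(p.value, dtype=np.float64) for p in params}
        self.t = 0

    def step(self, params: Sequence[Param], lr: float,
             lr_multipliers: dict[str, float] | None = None) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p in params:
            mult = 1.0 if lr_multipliers is None else lr_multipliers.get(p.name, 1.0)
            if mult == 0.0:
                continue
            g = p.grad.astype(np.float64, copy=False)
            m = self.m[p.name]
            v = self.v[p.name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            step = (lr * mult) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value = (p.value.astype(np.float64) - step).astype(
                p.value.dtype)


def predict(net, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Predict firmness for standardized spectra (float64 evaluation)."""
    network = net.network if isinstance(net, TrainedNet) else net
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    out = []
    for i in range(0, X.shape[0], batch_size):
        y = network.forward(X[i:i + batch_size], train=False, dtype=np.float64)
        out.append(np.ravel(y))
    return np.concatenate(out)


def train(
    network: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    isnet_config: ISNetConfig | None = None,
    lr_multipliers: dict[str, float] | None = None,
    init_output_bias: bool = True,
) -> tuple[TrainedNet, TrainHistory]:
    """Train with Adam, step-decayed learning rate and early stopping.

    The learning rate is ``initial_lr * drop_factor ** ((epoch-1) // period)``.
    Validation loss (MSE + L2 term) is recorded every epoch; the returned
    network carries the weights of the minimum-validation-loss epoch.
    ``lr_multipliers`` maps parameter names to per-parameter learning-rate
    factors; a factor of 0 freezes the parameter exactly (its gradient is
    zeroed and the optimizer never touches it).  Deterministic given
    ``config.seed``.
    """
    X_train = np.asarray(X_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    X_val = np.asarray(X_val, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64).ravel()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ISNetError("train and validation partitions must be non-empty")

    rng = np.random.default_rng(config.seed)
    params = network.params()
    if init_output_bias:
        out_layer = network.layer("out")
        out_layer.b.value[...] = np.mean(y_train)
    adam = Adam(params)
    lam = config.l2_lambda
    n = len(X_train)

    history = TrainHistory()
    best_val = np.inf
    best_state = network.get_state()
    best_epoch = 0
    wait = 0

    for epoch in range(1, config.max_epochs + 1):
        lr = config.initial_lr * config.lr_drop_factor ** (
            (epoch - 1) // config.lr_drop_period)
        perm = rng.permutation(n)
        epoch_mse = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            yhat = network.forward(xb, train=True, rng=rng, dtype=np.float32)
            resid = np.ravel(yhat).astype(np.float64) - yb
            epoch_mse += float(resid @ resid)
            network.zero_grads()
            g = (2.0 / len(idx)) * resid[:, None].astype(np.float32)
            network.backward(g)
            for p in params:
                if lam > 0 and p.kind == "weight":
                    p.grad += (lam * p.value).astype(p.grad.dtype, copy=False)
                if lr_multipliers is not None and \
                        lr_multipliers.get(p.name, 1.0) == 0.0:
                    p.zero_grad()
            adam.step(params, lr, lr_multipliers)
        train_loss = epoch_mse / n + (0.0 if lam == 0 else 0.5 * lam * sum(
            float(np.sum(p.value.astype(np.float64) ** 2))
            for p in params if p.kind == "weight"))
        val_pred = predict(network, X_val)
        val_loss = loss_eq1(y_val, val_pred, network, lam)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = network.get_state()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stopping_patience:
                break

    network.set_state(best_state)
    history.best_epoch = best_epoch
    trained = TrainedNet(
        network=network,
        isnet_config=isnet_config or ISNetConfig(),
        train_config=config,
        best_epoch=best_epoch,
        history=history,
    )
    return trained, history
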