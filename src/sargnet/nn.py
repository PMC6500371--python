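"""Numpy neural-network engine for the pixel classifiers.

A deliberately small reverse-mode engine: just the layers the three
architectures need — dense, 1D convolution with same-length padding,
batch normalization, dropout, LSTM, global average pooling — plus a
softmax/cross-entropy loss with optional L2 weight penalties and an
Adam optimizer.  Everything is float64 numpy; construction and every
stochastic element (initialization, dropout masks) are pure functions
of the build seed, so training is bit-reproducible on one platform.

Sequences are batches of shape (N, L, C): N pixels, L positions along
the spectral axis, C channels.  Dense activations are (N, F).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from sargnet.specs import ArchitectureSpec, ConfigurationError


class Param:
    """A trainable array with its gradient and an L2 penalty coefficient."""

    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: float = 0.0) -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.l2 = float(l2)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int) -> None:
        self.w = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only while training, identity in eval."""

    def __init__(self, rng: np.random.Generator, rate: float) -> None:
        self.rate = float(rate)
        self._rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Per-feature standardization over the batch (and sequence) axes.

    Training uses batch statistics; eval uses bias-corrected exponential
    running averages (momentum 0.9, epsilon 1e-3).  The bias correction
    (dividing the zero-initialized averages by 1 − momentum^t) keeps the
    eval statistics meaningful after only a few updates, which matters
    for small datasets with a handful of batches per epoch.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.zeros(n_features)
        self.n_updates = np.zeros(1)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var, self.n_updates]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
            self.n_updates += 1
        elif self.n_updates[0] > 0:
            correction = 1.0 - self.momentum ** self.n_updates[0]
            mean = self.running_mean / correction
            var = self.running_var / correction
        else:
            mean, var = self.running_mean, np.ones_like(self.running_var)
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes])) if training else None
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        axes, xhat, istd = self._axes, self._xhat, self._istd
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if self._m is None:  # eval-mode statistics are constants
            return dxhat * istd
        m = self._m
        return (istd / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class Conv1D(Layer):
    """1D convolution with same-length (zero) padding.

    For kernel k the input is padded (k-1)//2 on the left and k//2 on
    the right, so the sequence axis survives arbitrarily deep stacks.
    """

    def __init__(self, rng, n_in: int, n_out: int, kernel_size: int, l2: float = 0.0) -> None:
        k = int(kernel_size)
        self.k = k
        self.n_in = n_in
        self.w = Param(_glorot(rng, (k * n_in, n_out), k * n_in, n_out), l2=l2)
        self.b = Param(np.zeros(n_out))
        self.pad_left = (k - 1) // 2
        self.pad_right = k // 2

    def params(self):
        return [self.w, self.b]

    def _columns(self, x_pad: np.ndarray, length: int) -> np.ndarray:
        n = x_pad.shape[0]
        cols = np.stack([x_pad[:, j:j + length, :] for j in range(self.k)], axis=2)
        return cols.reshape(n, length, self.k * self.n_in)

    def forward(self, x, training):
        n, length, _ = x.shape
        x_pad = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._cols = self._columns(x_pad, length)
        self._shape = (n, length, x.shape[2])
        return self._cols @ self.w.value + self.b.value

    def backward(self, dout):
        n, length, c_in = self._shape
        flat = dout.reshape(-1, dout.shape[-1])
        self.w.grad += self._cols.reshape(-1, self.k * c_in).T @ flat
        self.b.grad += flat.sum(axis=0)
        dcols = (dout @ self.w.value.T).reshape(n, length, self.k, c_in)
        dx_pad = np.zeros((n, length + self.k - 1, c_in))
        for j in range(self.k):
            dx_pad[:, j:j + length, :] += dcols[:, :, j, :]
        return dx_pad[:, self.pad_left:self.pad_left + length, :]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single-layer LSTM over (N, L, C) sequences.

    Gate order i, f, g, o; forget-gate bias initialized to 1.  Emits
    either the full hidden sequence (N, L, H) or the final state (N, H).
    """

    def __init__(self, rng, n_in: int, n_units: int, return_sequences: bool) -> None:
        h = int(n_units)
        self.h = h
        self.return_sequences = bool(return_sequences)
        self.wx = Param(_glorot(rng, (n_in, 4 * h), n_in, 4 * h))
        self.wh = Param(_glorot(rng, (h, 4 * h), h, 4 * h))
        bias = np.zeros(4 * h)
        bias[h:2 * h] = 1.0
        self.b = Param(bias)

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x, training):
        n, length, _ = x.shape
        h_dim = self.h
        h = np.zeros((n, h_dim))
        c = np.zeros((n, h_dim))
        self._x = x
        self._cache = []
        outputs = np.empty((n, length, h_dim))
        for t in range(length):
            a = x[:, t, :] @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim:2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            outputs[:, t, :] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, c))
        return outputs if self.return_sequences else h

    def backward(self, dout):
        x = self._x
        n, length, _ = x.shape
        h_dim = self.h
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h_dim))
        dc_next = np.zeros((n, h_dim))
        for t in reversed(range(length)):
            h_prev, c_prev, i, f, g, o, c = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t, :] + dh_next
            else:
                dh = (dout if t == length - 1 else 0.0) + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += x[:, t, :].T @ da
            self.wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t, :] = da @ self.wx.value.T
            dh_next = da @ self.wh.value.T
            dc_next = dc * f
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._length, axis=1) / self._length


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A built classifier: an ordered layer stack plus its input layout.

    The forward pass maps a (N, n_features) batch of pixel feature
    vectors to (N, 2) class probabilities; ``training=True`` activates
    dropout and batch statistics, eval mode is deterministic.
    """

    def __init__(self, spec: ArchitectureSpec, layers: Sequence[Layer], seed: int) -> None:
        self.spec = spec
        self.layers = list(layers)
        self.seed = seed
        # optional per-feature input standardization, fitted on training data
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _reshape(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.spec.n_features:
            raise ValueError(
                f"expected a (n, {self.spec.n_features}) feature batch, got shape {x.shape}"
            )
        length, channels = self.spec.input_layout
        if not self.spec.conv_blocks and not self.spec.recurrent_blocks:
            return x  # dense-only networks consume the flat vector
        if channels == 1:
            return x[:, :, None]
        # [rhos(7), rhot(7)] feature order -> channels-last (N, 7, 2)
        return x.reshape(x.shape[0], channels, length).transpose(0, 2, 1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_std
        out = self._reshape(x)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard class calls; a probability of exactly 0.5 goes to class 0."""
        return (self.predict_proba(x)[:, 1] > 0.5).astype(int)

    # -- training -----------------------------------------------------------

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Cross-entropy (+ L2 penalties) and parameter gradients.

        Gradients are freshly written (not accumulated across calls).
        """
        y = np.asarray(y, dtype=int)
        for p in self.params():
            p.grad[...] = 0.0
        logits = self.forward(x, training=True)
        p = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for param in self.params():
            if param.l2:
                loss += param.l2 * float(np.sum(param.value**2))
                param.grad += 2.0 * param.l2 * param.value
        return loss

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self.layers:
            arrays.extend(layer.buffers())
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, arrays: Sequence[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(arrays) != len(current):
            raise ValueError("state does not match this architecture")
        for target, source in zip(current, arrays):
            if target.shape != np.asarray(source).shape:
                raise ValueError("state does not match this architecture")
            target[...] = source


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: Sequence[Param], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * correction * m / (np.sqrt(v) + self.eps)


def build(spec: ArchitectureSpec, seed: int) -> Network:
    """Construct a trainable :class:`Network` from an architecture spec.

    Initialization (Glorot-uniform weights, zero biases, LSTM forget
    bias 1) and per-dropout-layer random streams all derive from
    ``seed``; building twice with the same seed yields identical
    networks.
    """
    root = np.random.SeedSequence(int(seed))
    init_rng = np.random.default_rng(root.spawn(1)[0])
    dropout_seq = root.spawn(1)[0]

    layers: list[Layer] = []
    length, channels = spec.input_layout

    def dropout_layer(rate: float) -> Dropout:
        nonlocal dropout_seq
        dropout_seq, child = dropout_seq.spawn(2)
        return Dropout(np.random.default_rng(child), rate)

    for block in spec.conv_blocks:
        conv = Conv1D(init_rng, channels, block.n_filters, block.kernel_size,
                      l2=block.l2_coefficient)
        if block.order == "conv_bn_relu":
            layers.append(conv)
            if block.batch_norm:
                layers.append(BatchNorm(block.n_filters))
            if block.activation == "relu":
                layers.append(ReLU())
        else:  # conv -> relu -> bn -> dropout
            layers.append(conv)
            if block.activation == "relu":
                layers.append(ReLU())
            if block.batch_norm:
                layers.append(BatchNorm(block.n_filters))
        if block.dropout_rate > 0:
            layers.append(dropout_layer(block.dropout_rate))
        channels = block.n_filters

    for block in spec.recurrent_blocks:
        layers.append(LSTM(init_rng, channels, block.n_units,
                           return_sequences=block.emits_sequence))
        if block.batch_norm:
            layers.append(BatchNorm(block.n_units))
        channels = block.n_units

    sequence_collapsed = bool(spec.recurrent_blocks) and not spec.recurrent_blocks[-1].emits_sequence
    if spec.global_average_pool:
        layers.append(GlobalAvgPool())
        fan_in = channels
    elif sequence_collapsed:
        fan_in = channels
    elif spec.conv_blocks or spec.recurrent_blocks:
        layers.append(Flatten())
        fan_in = channels * length
    else:
        fan_in = spec.n_features

    for block in spec.dense_blocks:
        layers.append(Dense(init_rng, fan_in, block.n_units))
        if block.activation == "relu":
            layers.append(ReLU())
        if block.dropout_rate > 0:
            layers.append(dropout_layer(block.dropout_rate))
        fan_in = block.n_units
    # the softmax of the final block lives in the loss / predict_proba

    network = Network(spec, layers, seed=int(seed))
    from sargnet.specs import parameter_count

    if network.n_parameters != parameter_count(spec):
        raise ConfigurationError(
            f"built network has {network.n_parameters} parameters, "
            f"spec expects {parameter_count(spec)}"
        )
    return network


def predict_proba(model: Network, inputs: np.ndarray) -> np.ndarray:
    """Per-class probabilities for a batch of pixel feature vectors.

    Evaluation mode: dropout inactive, batch norm on running statistics,
    so repeated calls on fixed weights are identical.
    """
    return model.predict_proba(inputs)
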