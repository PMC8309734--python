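"""Minimal numpy neural-network layer stack with explicit backpropagation.

Implements exactly the layer vocabulary needed by the feature-learning
architectures in :mod:`painfeat.deep`: dense, 1-D convolution (same padding,
arbitrary stride), max pooling with ceil semantics, nearest-neighbour
upsampling, dropout, batch normalisation, flatten, and a convolutional LSTM
operating on a (batch, segments, time, channels) tensor.  Training uses Adam
with categorical cross-entropy or mean squared error.

Conventions
-----------
* Feed-forward tensors are ``(B, L, C)`` — batch, time, channels.  The
  ConvLSTM consumes ``(B, N, L, C)`` where ``N`` is the number of time
  segments processed recurrently.
* All layers build lazily on first forward pass; weight initialisation is
  Glorot-uniform drawn from the :class:`Sequential` rng, so a fixed seed
  yields a bit-identical model.
* ``DEFAULT_DTYPE`` is float32 for speed; gradient-check tests switch a model
  to float64 via the ``dtype`` argument.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


# ---------------------------------------------------------------------------
# activations

def relu(x):
    return np.maximum(x, 0.0)


def hard_sigmoid(x):
    # Keras piecewise-linear approximation: clip(0.2 x + 0.5, 0, 1)
    return np.clip(0.2 * x + 0.5, 0.0, 1.0)


def hard_sigmoid_grad(x):
    return np.where((x > -2.5) & (x < 2.5), 0.2, 0.0)


def softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# shared 1-D convolution kernels ("same" padding, stride >= 1)

def conv1d_out_len(length: int, stride: int) -> int:
    return -(-length // stride)  # ceil


def _conv1d_forward(x, w, stride):
    """x (B, L, C), w (k, C, F) -> y (B, out, F) with same padding.

    Returns (y, cache) where cache carries what backward needs.
    """
    b, length, c = x.shape
    k = w.shape[0]
    out = conv1d_out_len(length, stride)
    pad_total = max((out - 1) * stride + k - length, 0)
    left = pad_total // 2
    xp = np.pad(x, ((0, 0), (left, pad_total - left), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L', C, k)
    win = win[:, ::stride][:, :out]  # (B, out, C, k)
    y = np.tensordot(win, w, axes=([3, 2], [0, 1]))  # (B, out, F)
    cache = (win, w, stride, length, left, pad_total)
    return y, cache


def _conv1d_backward(dy, cache):
    """dy (B, out, F) -> (dx (B, L, C), dw (k, C, F))."""
    win, w, stride, length, left, pad_total = cache
    k, c, f = w.shape
    b, out, _ = dy.shape
    # weight gradient: correlate stored input windows with dy
    dw = np.tensordot(win, dy, axes=([0, 1], [0, 1]))  # (C, k, F)
    dw = dw.transpose(1, 0, 2)  # (k, C, F)
    # input gradient: full correlation of (zero-upsampled) dy with flipped w
    if stride > 1:
        up_len = (out - 1) * stride + 1
        dyu = np.zeros((b, up_len, f), dtype=dy.dtype)
        dyu[:, ::stride] = dy
    else:
        dyu = dy
        up_len = out
    dyp = np.pad(dyu, ((0, 0), (k - 1, k - 1), (0, 0)))
    wflip = w[::-1].transpose(0, 2, 1)  # (k, F, C)
    dwin = np.lib.stride_tricks.sliding_window_view(dyp, k, axis=1)  # (B, up+k-1, F, k)
    dxp_part = np.tensordot(dwin, wflip, axes=([3, 2], [0, 1]))  # (B, up+k-1, C)
    buf_len = max(length + pad_total, up_len + k - 1)
    dxp = np.zeros((b, buf_len, c), dtype=dy.dtype)
    dxp[:, : up_len + k - 1] = dxp_part
    return dxp[:, left: left + length], dw


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base class: lazy build + forward/backward with per-layer caches."""

    trainable = True

    def build(self, input_shape, rng, dtype):  # pragma: no cover - overridden
        return input_shape

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params_and_grads(self):
        return []


class Dense(Layer):
    def __init__(self, units, activation=None):
        self.units = units
        self.activation = activation
        self.w = None

    def build(self, input_shape, rng, dtype):
        (d,) = input_shape
        self.w = _glorot(rng, (d, self.units), d, self.units, dtype)
        self.b = np.zeros(self.units, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._pre = x @ self.w + self.b
        if self.activation == "relu":
            return relu(self._pre)
        if self.activation == "softmax":
            return softmax(self._pre)
        return self._pre

    def backward(self, grad, skip_activation=False):
        if not skip_activation:
            if self.activation == "relu":
                grad = grad * (self._pre > 0)
            elif self.activation == "softmax":
                p = softmax(self._pre)
                grad = p * (grad - (grad * p).sum(axis=-1, keepdims=True))
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Conv1D(Layer):
    """Same-padded 1-D convolution over the time axis of (B, L, C)."""

    def __init__(self, filters, kernel_size, stride=1, activation=None):
        self.filters = filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.activation = activation
        self.w = None

    def build(self, input_shape, rng, dtype):
        length, c = input_shape
        k, f = self.kernel_size, self.filters
        self.w = _glorot(rng, (k, c, f), k * c, k * f, dtype)
        self.b = np.zeros(f, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        return (conv1d_out_len(length, self.stride), f)

    def forward(self, x, training=False, rng=None):
        y, self._cache = _conv1d_forward(x, self.w, self.stride)
        self._pre = y + self.b
        if self.activation == "relu":
            return relu(self._pre)
        return self._pre

    def backward(self, grad, skip_activation=False):
        if self.activation == "relu" and not skip_activation:
            grad = grad * (self._pre > 0)
        self.db[...] = grad.sum(axis=(0, 1))
        dx, dw = _conv1d_backward(grad, self._cache)
        self.dw[...] = dw
        return dx

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPool1D(Layer):
    """Non-overlapping max pooling with ceil (same-padding) semantics."""

    trainable = False

    def __init__(self, pool_size=4):
        self.pool_size = pool_size

    def build(self, input_shape, rng, dtype):
        length, c = input_shape
        return (conv1d_out_len(length, self.pool_size), c)

    def forward(self, x, training=False, rng=None):
        b, length, c = x.shape
        p = self.pool_size
        out = conv1d_out_len(length, p)
        pad = out * p - length
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        win = xp.reshape(b, out, p, c)
        self._arg = win.argmax(axis=2)
        self._shape = x.shape
        return win.max(axis=2)

    def backward(self, grad):
        b, length, c = self._shape
        p = self.pool_size
        out = grad.shape[1]
        buf = np.zeros((b, out, p, c), dtype=grad.dtype)
        np.put_along_axis(buf, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        return buf.reshape(b, out * p, c)[:, :length]


class UpSampling1D(Layer):
    trainable = False

    def __init__(self, size=4):
        self.size = size

    def build(self, input_shape, rng, dtype):
        length, c = input_shape
        return (length * self.size, c)

    def forward(self, x, training=False, rng=None):
        return np.repeat(x, self.size, axis=1)

    def backward(self, grad):
        b, length, c = grad.shape
        return grad.reshape(b, length // self.size, self.size, c).sum(axis=2)


class Dropout(Layer):
    trainable = False

    def __init__(self, rate):
        self.rate = rate

    def build(self, input_shape, rng, dtype):
        return input_shape

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    trainable = False

    def build(self, input_shape, rng, dtype):
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class BatchNorm(Layer):
    """Per-channel batch normalisation over all non-channel axes."""

    def __init__(self, momentum=0.99, eps=1e-3):
        self.momentum = momentum
        self.eps = eps
        self.gamma = None

    def build(self, input_shape, rng, dtype):
        c = input_shape[-1]
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        return input_shape

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, x - mu, axes, training)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, ivar, xc, axes, training = self._cache
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        if not training:
            return dxhat * ivar
        m = np.prod([xhat.shape[a] for a in axes])
        dvar = (dxhat * xc).sum(axis=axes) * (-0.5) * ivar ** 3
        dmu = -(dxhat * ivar).sum(axis=axes) + dvar * (-2.0 / m) * xc.sum(axis=axes)
        return dxhat * ivar + dvar * 2.0 * xc / m + dmu / m

    def params_and_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class TemporalMaxPool(Layer):
    """Max pooling over the within-segment time axis of (B, N, L, C)."""

    trainable = False

    def __init__(self, pool_size=4):
        self.pool_size = pool_size

    def build(self, input_shape, rng, dtype):
        n, length, c = input_shape
        return (n, conv1d_out_len(length, self.pool_size), c)

    def forward(self, x, training=False, rng=None):
        b, n, length, c = x.shape
        p = self.pool_size
        out = conv1d_out_len(length, p)
        pad = out * p - length
        xp = np.pad(x, ((0, 0), (0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        win = xp.reshape(b, n, out, p, c)
        self._arg = win.argmax(axis=3)
        self._shape = x.shape
        return win.max(axis=3)

    def backward(self, grad):
        b, n, length, c = self._shape
        p = self.pool_size
        out = grad.shape[2]
        buf = np.zeros((b, n, out, p, c), dtype=grad.dtype)
        np.put_along_axis(buf, self._arg[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        return buf.reshape(b, n, out * p, c)[:, :, :length]


class ConvLSTM1D(Layer):
    """Convolutional LSTM over (B, N, L, C): the N segments are the recurrent
    time steps; gates use 1-D convolutions along L (stride applies to the
    input convolution only, the recurrent convolution is stride 1).

    Gate order follows the usual (input, forget, candidate, output)
    convention with tanh cell activation and hard-sigmoid recurrent
    activation; all hidden states are returned (return_sequences)."""

    def __init__(self, filters, kernel_size, stride=1,
                 activation="tanh", recurrent_activation="hard_sigmoid"):
        self.filters = filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.activation = activation
        self.recurrent_activation = recurrent_activation
        self.wx = None

    def build(self, input_shape, rng, dtype):
        n, length, c = input_shape
        k, f = self.kernel_size, self.filters
        self.wx = _glorot(rng, (k, c, 4 * f), k * c, k * 4 * f, dtype)
        self.wh = _glorot(rng, (k, f, 4 * f), k * f, k * 4 * f, dtype)
        self.b = np.zeros(4 * f, dtype=dtype)
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        self._out_len = conv1d_out_len(length, self.stride)
        return (n, self._out_len, f)

    def forward(self, x, training=False, rng=None):
        b, n, length, c = x.shape
        f = self.filters
        lo = self._out_len
        h = np.zeros((b, lo, f), dtype=x.dtype)
        cell = np.zeros((b, lo, f), dtype=x.dtype)
        self._steps = []
        hs = np.empty((b, n, lo, f), dtype=x.dtype)
        for t in range(n):
            zx, cx = _conv1d_forward(x[:, t], self.wx, self.stride)
            zh, ch = _conv1d_forward(h, self.wh, 1)
            z = zx + zh + self.b
            zi, zf, zc, zo = np.split(z, 4, axis=-1)
            i = hard_sigmoid(zi)
            fg = hard_sigmoid(zf)
            g = np.tanh(zc)
            o = hard_sigmoid(zo)
            c_prev = cell
            cell = fg * c_prev + i * g
            tc = np.tanh(cell)
            h = o * tc
            hs[:, t] = h
            self._steps.append((cx, ch, zi, zf, zc, zo, i, fg, g, o, c_prev, tc))
        self._in_shape = x.shape
        return hs

    def backward(self, grad):
        b, n, lo, f = grad.shape
        dx = np.empty(self._in_shape, dtype=grad.dtype)
        self.dwx[...] = 0.0
        self.dwh[...] = 0.0
        self.db[...] = 0.0
        dh_next = np.zeros((b, lo, f), dtype=grad.dtype)
        dc_next = np.zeros((b, lo, f), dtype=grad.dtype)
        for t in range(n - 1, -1, -1):
            cx, ch, zi, zf, zc, zo, i, fg, g, o, c_prev, tc = self._steps[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * hard_sigmoid_grad(zi),
                 df * hard_sigmoid_grad(zf),
                 dg * (1.0 - g ** 2),
                 do * hard_sigmoid_grad(zo)], axis=-1)
            self.db += dz.sum(axis=(0, 1))
            dxt, dwx = _conv1d_backward(dz, cx)
            dh_prev, dwh = _conv1d_backward(dz, ch)
            self.dwx += dwx
            self.dwh += dwh
            dx[:, t] = dxt
            dh_next = dh_prev
            dc_next = dc * fg
        return dx

    def params_and_grads(self):
        return [(self.wx, self.dwx), (self.wh, self.dwh), (self.b, self.db)]


# ---------------------------------------------------------------------------
# container, optimiser, losses

class Sequential:
    """Ordered layer container with lazy build and shared init rng."""

    def __init__(self, layers, input_shape, rng_seed=0, dtype=None):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.dtype = dtype or DEFAULT_DTYPE
        rng = np.random.default_rng(rng_seed)
        shape = self.input_shape
        self.layer_output_shapes = []
        for layer in self.layers:
            shape = layer.build(shape, rng, self.dtype)
            self.layer_output_shapes.append(shape)
        self.output_shape = shape

    def forward(self, x, training=False, rng=None, upto=None):
        x = np.asarray(x, dtype=self.dtype)
        stop = len(self.layers) if upto is None else upto + 1
        for layer in self.layers[:stop]:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad, skip_last_activation=False):
        last = self.layers[-1]
        if isinstance(last, (Dense, Conv1D)):
            grad = last.backward(grad, skip_activation=skip_last_activation)
        else:
            grad = last.backward(grad)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        return grad

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out


class Adam:
    def __init__(self, params_and_grads, learning_rate=1e-4,
                 beta1=0.9, beta2=0.999, eps=1e-7):
        self.pg = params_and_grads
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def softmax_cross_entropy(probs, onehot):
    """Mean categorical cross-entropy and its gradient w.r.t. the softmax
    *pre-activation* (use with ``backward(..., skip_last_activation=True)``)."""
    eps = 1e-12
    loss = -np.mean(np.sum(onehot * np.log(probs + eps), axis=-1))
    dpre = (probs - onehot) / probs.shape[0]
    return float(loss), dpre


def mse_loss(output, target):
    diff = output - target
    loss = float(np.mean(diff ** 2))
    dout = 2.0 * diff / diff.size
    return loss, dout
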