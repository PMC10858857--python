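"""Minimal NumPy neural-network layers with hand-written backprop.

Provides exactly what the sleep-stage classifier needs: stride-1 'same'
2-D convolution (im2col matmul forward, kernel-offset scatter backward),
leaky ReLU, non-overlapping 2x2 max pooling, a single-layer peephole
LSTM with full backprop-through-time, a dense layer, softmax
cross-entropy, and Adam.  Everything is deterministic given the RNG
passed at construction; dtype follows the ``dtype`` argument (float32
for training speed, float64 in gradient-check tests).

The peephole LSTM cell computes, per step (``@`` = matmul, ``*`` =
elementwise, sigma = logistic)::

    i_t = sigma(x_t @ Wxi + h_{t-1} @ Whi + p_i * C_{t-1} + b_i)
    f_t = sigma(x_t @ Wxf + h_{t-1} @ Whf + p_f * C_{t-1} + b_f)
    g_t = tanh (x_t @ Wxc + h_{t-1} @ Whc + b_c)          # candidate
    C_t = f_t * C_{t-1} + i_t * g_t                        # cell state
    o_t = sigma(x_t @ Wxo + h_{t-1} @ Who + p_o * C_t + b_o)
    h_t = o_t * tanh(C_t)

The peephole weights act diagonally (one scalar per unit) on the cell
state; the output gate peeks at the *current* cell state.  The hidden
output gates the cell state, not the candidate: gating the candidate
would leave the accumulated state unread, so the conventional
peephole formulation is used.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' convolution over NCHW tensors."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32, name: str = "conv"):
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))
        self.W = Param(w.astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), f"{name}.b")
        self.kernel = kernel
        self.name = name
        # asymmetric padding for even kernels
        self.pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2, (kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        # the first layer of a network can skip the input gradient
        self.compute_input_grad = True

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        _, h, w = in_shape
        return (self.W.value.shape[0], h, w)

    def forward(self, x):
        kh, kw = self.kernel
        pt, pb, pl, pr = self.pad
        n, c, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError(f"layer {self.name}: empty input map {x.shape}")
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        # win: (n, c, h, w, kh, kw) -> cols (n*h*w, c*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        kh, kw = self.kernel
        pt, pb, pl, pr = self.pad
        f = dout.shape[1]
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.W.grad += (d2.T @ cols).reshape(self.W.value.shape)
        self.b.grad += d2.sum(axis=0)
        self._cache = None
        if not self.compute_input_grad:
            return None
        # input gradient = transposed conv: correlate the padded output
        # gradient with the channel-swapped, spatially flipped kernel
        wflip = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, f * kh * kw)
        dp = np.pad(dout, ((0, 0), (0, 0), (kh - 1 - pt, kh - 1 - pb), (kw - 1 - pl, kw - 1 - pr)))
        win = np.lib.stride_tricks.sliding_window_view(dp, (kh, kw), axis=(2, 3))
        cols2 = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, f * kh * kw)
        dx = cols2 @ wflip.T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class LeakyReLU(Layer):
    """max(x, slope*x); negative pre-activations scaled by exactly ``slope``."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x):
        self._scale = np.where(x < 0, np.asarray(self.slope, dtype=x.dtype), np.asarray(1.0, dtype=x.dtype))
        return x * self._scale

    def backward(self, dout):
        out = dout * self._scale
        self._scale = None
        return out


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling; odd trailing rows/cols are cropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.size or w < self.size:
            raise ValueError(
                f"max-pool {self.size}x{self.size} needs a map of at least that size, got {h}x{w}"
            )
        return (c, h // self.size, w // self.size)

    def forward(self, x):
        s = self.size
        n, c, h, w = x.shape
        h2, w2 = h // s, w // s
        xr = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.size
        n, c, h, w = self._in_shape
        h2, w2 = h // s, w // s
        dflat = np.zeros((n, c, h2, w2, s * s), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : h2 * s, : w2 * s] = (
            dflat.reshape(n, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * s, w2 * s)
        )
        return dx


class ConvToSequence(Layer):
    """Bridge CNN maps to the LSTM: (N,C,H,W) -> (N, W, C*H).

    The conv output's time (width) axis becomes the sequence axis; the
    channel and height axes flatten into the per-step feature vector.
    """

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (w, c * h)

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.transpose(0, 3, 1, 2).reshape(n, w, c * h)

    def backward(self, dout):
        n, c, h, w = self._shape
        return dout.reshape(n, w, c, h).transpose(0, 2, 3, 1)


def lstm_cell_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
    p_i: np.ndarray,
    p_f: np.ndarray,
    p_o: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One peephole-LSTM step for a single input vector (or batch).

    ``Wx`` is (D, 4H), ``Wh`` is (H, 4H) and ``b`` is (4H,), gate order
    [input, forget, candidate, output]; ``p_*`` are the per-unit
    peephole weights.  Returns ``(h, C)``.
    """
    H = h_prev.shape[-1]
    z = x @ Wx + h_prev @ Wh + b
    zi, zf, zg, zo = z[..., :H], z[..., H : 2 * H], z[..., 2 * H : 3 * H], z[..., 3 * H :]
    i = sigmoid(zi + p_i * C_prev)
    f = sigmoid(zf + p_f * C_prev)
    g = np.tanh(zg)
    C = f * C_prev + i * g
    o = sigmoid(zo + p_o * C)
    h = o * np.tanh(C)
    return h, C


class PeepholeLSTM(Layer):
    """Single peephole-LSTM layer; consumes (N,T,D), emits the last h (N,H)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "lstm"):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = Param(rng.uniform(-k, k, size=(input_size, 4 * hidden)).astype(dtype), f"{name}.Wx")
        self.Wh = Param(rng.uniform(-k, k, size=(hidden, 4 * hidden)).astype(dtype), f"{name}.Wh")
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.b = Param(b, f"{name}.b")
        self.p_i = Param(np.zeros(hidden, dtype=dtype), f"{name}.p_i")
        self.p_f = Param(np.zeros(hidden, dtype=dtype), f"{name}.p_f")
        self.p_o = Param(np.zeros(hidden, dtype=dtype), f"{name}.p_o")
        self.hidden = hidden

    def params(self):
        return [self.Wx, self.Wh, self.b, self.p_i, self.p_f, self.p_o]

    def out_shape(self, in_shape):
        t, d = in_shape
        if d != self.Wx.value.shape[0]:
            raise ValueError(f"LSTM expects {self.Wx.value.shape[0]}-dim steps, got {d}")
        return (self.hidden,)

    def forward(self, x):
        n, T, d = x.shape
        H = self.hidden
        dt = x.dtype
        h = np.zeros((n, H), dtype=dt)
        C = np.zeros((n, H), dtype=dt)
        cache = []
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        pi, pf, po = self.p_i.value, self.p_f.value, self.p_o.value
        z_all = x.reshape(n * T, d) @ Wx
        z_all = z_all.reshape(n, T, 4 * H)
        for t in range(T):
            z = z_all[:, t] + h @ Wh + b
            C_prev, h_prev = C, h
            i = sigmoid(z[:, :H] + pi * C_prev)
            f = sigmoid(z[:, H : 2 * H] + pf * C_prev)
            g = np.tanh(z[:, 2 * H : 3 * H])
            C = f * C_prev + i * g
            o = sigmoid(z[:, 3 * H :] + po * C)
            tC = np.tanh(C)
            h = o * tC
            cache.append((h_prev, C_prev, i, f, g, o, C, tC))
        self._cache = (x, cache)
        return h

    def backward(self, dout):
        x, cache = self._cache
        n, T, d = x.shape
        H = self.hidden
        Wx, Wh = self.Wx.value, self.Wh.value
        pi, pf, po = self.p_i.value, self.p_f.value, self.p_o.value
        dx = np.zeros_like(x)
        dh = dout.astype(x.dtype)
        dC = np.zeros((n, H), dtype=x.dtype)
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.b.value)
        dpi = np.zeros_like(pi)
        dpf = np.zeros_like(pf)
        dpo = np.zeros_like(po)
        for t in range(T - 1, -1, -1):
            h_prev, C_prev, i, f, g, o, C, tC = cache[t]
            do = dh * tC
            da_o = do * o * (1.0 - o)
            dC = dC + dh * o * (1.0 - tC * tC) + da_o * po
            dpo += (da_o * C).sum(axis=0)
            di = dC * g
            df = dC * C_prev
            dg = dC * i
            da_i = di * i * (1.0 - i)
            da_f = df * f * (1.0 - f)
            da_g = dg * (1.0 - g * g)
            dpi += (da_i * C_prev).sum(axis=0)
            dpf += (da_f * C_prev).sum(axis=0)
            dz = np.concatenate([da_i, da_f, da_g, da_o], axis=1)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dC = dC * f + da_i * pi + da_f * pf
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        self.p_i.grad += dpi
        self.p_f.grad += dpf
        self.p_o.grad += dpo
        self._cache = None
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "fc"):
        k = 1.0 / np.sqrt(in_dim)
        self.W = Param(rng.uniform(-k, k, size=(in_dim, out_dim)).astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(out_dim, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        return (self.W.value.shape[1],)

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with bias correction; lr=0 leaves parameters untouched."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
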