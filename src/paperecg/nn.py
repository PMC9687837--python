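"""Minimal CPU neural-network core used by the InRes architecture.

Dense/convolutional layers, pooling, rectifier-family activations (including
the learnable-slope PReLU), residual combination with a trainable scaling
factor, softmax losses, and the usual first-order optimizers, all in numpy
with explicit backward passes. Convolutions are stride-1 with
size-preserving zero padding and run as im2col matrix products; their
gradients reuse the same machinery (input gradients are a correlation with
the flipped kernels). Layout is channels-first: ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


# ---------------------------------------------------------------------------
# im2col helpers

def _im2col(x: np.ndarray, kh: int, kw: int, pads: tuple[int, int, int, int]):
    """Extract kh x kw patches (zero padding ``(pt, pb, pl, pr)``).

    Returns ``(N*H*W, C*kh*kw)`` with output size equal to input size.
    """
    pt, pb, pl, pr = pads
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """Stride-1 'same' convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, name: str = "conv"):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self._cache = None

    def forward(self, x):
        k = self.k
        pt, pb = (k - 1) // 2, k // 2
        cols = _im2col(x, k, k, (pt, pb, pt, pb))
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        n, _, h, w = x.shape
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k = self.k
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.w.grad += (dmat.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=0)
        # dx = correlation of dout with the flipped kernels
        pt, pb = (k - 1) // 2, k // 2
        dcols = _im2col(dout, k, k, (pb, pt, pb, pt))
        wflip = self.w.value[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(-1, c)
        dx = dcols @ wflip
        self._cache = None
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def params(self):
        return [self.w, self.b]


class Pool2D(Layer):
    """2x2 pooling, max or average.

    ``stride=2`` halves the spatial size (odd inputs are edge-padded);
    ``stride=1`` is size-preserving with an edge-replicated window anchored
    top-left, which lets pooling layers live inside residual units without
    breaking the shape match required by the skip connection.
    """

    def __init__(self, kind: str = "max", stride: int = 2):
        if kind not in ("max", "average"):
            raise ConfigurationError(f"unknown pooling kind {kind!r}")
        self.kind, self.stride = kind, stride
        self._cache = None

    def forward(self, x):
        if self.stride == 2:
            return self._forward_s2(x)
        return self._forward_s1(x)

    def backward(self, dout):
        if self.stride == 2:
            return self._backward_s2(dout)
        return self._backward_s1(dout)

    # -- stride 2 ------------------------------------------------------------
    def _forward_s2(self, x):
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        hh, ww = x.shape[2] // 2, x.shape[3] // 2
        win = x.reshape(n, c, hh, 2, ww, 2)
        if self.kind == "max":
            out = win.max(axis=(3, 5))
            eq = win == out[:, :, :, None, :, None]
            flat = eq.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
            first = np.cumsum(flat, axis=-1) == 1
            mask = (flat & first).reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._cache = ((h, w), (ph, pw), mask)
        else:
            out = win.mean(axis=(3, 5))
            self._cache = ((h, w), (ph, pw), None)
        return out

    def _backward_s2(self, dout):
        (h, w), (ph, pw), mask = self._cache
        n, c, hh, ww = dout.shape
        if self.kind == "max":
            dx = (mask * dout[:, :, :, None, :, None]).reshape(n, c, hh * 2, ww * 2)
        else:
            dx = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        if ph:
            dx[:, :, h - 1, :] += dx[:, :, h, :]
            dx = dx[:, :, :h, :]
        if pw:
            dx[:, :, :, w - 1] += dx[:, :, :, w]
            dx = dx[:, :, :, :w]
        self._cache = None
        return dx

    # -- stride 1 ------------------------------------------------------------
    def _forward_s1(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)), mode="edge")
        slices = [xp[:, :, di:di + h, dj:dj + w] for di in (0, 1) for dj in (0, 1)]
        if self.kind == "max":
            out = np.maximum.reduce(slices)
            taken = np.zeros_like(out, dtype=bool)
            masks = []
            for s in slices:
                m = (s == out) & ~taken
                taken |= m
                masks.append(m)
            self._cache = (x.shape, masks)
        else:
            out = sum(slices) / 4.0
            self._cache = (x.shape, None)
        return out

    def _backward_s1(self, dout):
        xshape, masks = self._cache
        n, c, h, w = xshape
        dxp = np.zeros((n, c, h + 1, w + 1))
        for idx, (di, dj) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            contrib = dout * masks[idx] if self.kind == "max" else dout / 4.0
            dxp[:, :, di:di + h, dj:dj + w] += contrib
        dx = dxp[:, :, :h, :w]
        dx[:, :, h - 1, :] += dxp[:, :, h, :w]
        dx[:, :, :, w - 1] += dxp[:, :, :h, w]
        dx[:, :, h - 1, w - 1] += dxp[:, :, h, w]
        self._cache = None
        return dx


def prelu(b, k):
    """Parametric ReLU: ``b`` if ``b >= 0`` else ``k * b`` (elementwise)."""
    b = np.asarray(b, dtype=np.float64)
    return np.where(b >= 0, b, k * b)


class Activation(Layer):
    """Stateless rectifier-family activations."""

    def __init__(self, kind: str):
        kind = kind.lower()
        if kind not in ("relu", "leakyrelu", "elu", "tanh"):
            raise ConfigurationError(f"unknown activation {kind!r}")
        self.kind = kind
        self._cache = None

    def forward(self, x):
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
            self._cache = x >= 0
        elif self.kind == "leakyrelu":
            out = np.where(x >= 0, x, 0.01 * x)
            self._cache = x >= 0
        elif self.kind == "elu":
            out = np.where(x >= 0, x, np.expm1(x))
            self._cache = (x, out)
        else:
            out = np.tanh(x)
            self._cache = out
        return out

    def backward(self, dout):
        if self.kind == "relu":
            dx = dout * self._cache
        elif self.kind == "leakyrelu":
            dx = dout * np.where(self._cache, 1.0, 0.01)
        elif self.kind == "elu":
            x, out = self._cache
            dx = dout * np.where(x >= 0, 1.0, out + 1.0)
        else:
            dx = dout * (1.0 - self._cache**2)
        self._cache = None
        return dx


class PReLU(Layer):
    """Per-channel learnable negative slope, initialized at 0.1."""

    def __init__(self, channels: int, init: float = 0.1, name: str = "prelu"):
        self.k = Param(np.full(channels, init), f"{name}.k")
        self._cache = None

    def forward(self, x):
        k = self.k.value.reshape(1, -1, *([1] * (x.ndim - 2)))
        self._cache = x
        return np.where(x >= 0, x, k * x)

    def backward(self, dout):
        x = self._cache
        k = self.k.value.reshape(1, -1, *([1] * (x.ndim - 2)))
        neg = x < 0
        axes = (0,) + tuple(range(2, x.ndim))
        self.k.grad += np.sum(dout * x * neg, axis=axes)
        self._cache = None
        return dout * np.where(neg, k, 1.0)

    def params(self):
        return [self.k]


def make_activation(kind: str, channels: int, prelu_init: float = 0.1) -> Layer:
    if kind.lower() == "prelu":
        return PReLU(channels, init=prelu_init)
    return Activation(kind)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
                       f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._cache = None

    def forward(self, x):
        self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        x = self._cache
        self.w.grad += x.T @ dout
        self.b.grad += dout.sum(axis=0)
        self._cache = None
        return dout @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalPool(Layer):
    def __init__(self, kind: str):
        if kind not in ("average", "max"):
            raise ConfigurationError(f"unknown global pool {kind!r}")
        self.kind = kind

    def forward(self, x):
        self._cache = x
        if self.kind == "average":
            return x.mean(axis=(2, 3))
        return x.max(axis=(2, 3))

    def backward(self, dout):
        x = self._cache
        n, c, h, w = x.shape
        if self.kind == "average":
            return np.broadcast_to(
                dout[:, :, None, None], x.shape
            ) / (h * w)
        mx = x.max(axis=(2, 3), keepdims=True)
        eq = (x == mx).reshape(n, c, -1)
        first = np.cumsum(eq, axis=-1) == 1
        mask = (eq & first).reshape(x.shape)
        return mask * dout[:, :, None, None]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class ResidualUnit(Layer):
    """``y = act(resnet(x) + alpha * inception(x))``.

    ``alpha`` is the residual scaling factor: a learnable scalar
    (initialized small, typically 0.1) that damps the inception branch
    before the residual addition, stabilizing training of the wide combined
    block. With scaling disabled, ``alpha`` is fixed at 1.
    """

    def __init__(self, inception: Sequential, resnet: Sequential,
                 activation: Layer, rsf_init: float | None = 0.1,
                 name: str = "unit"):
        self.inception = inception
        self.resnet = resnet
        self.activation = activation
        self.rsf = Param(np.array(rsf_init), f"{name}.rsf") if rsf_init is not None else None
        self._cache = None

    @property
    def alpha(self) -> float:
        return float(self.rsf.value) if self.rsf is not None else 1.0

    def forward(self, x):
        i = self.inception.forward(x)
        r = self.resnet.forward(x)
        if i.shape != r.shape:
            raise ConfigurationError(
                f"branch shapes differ: {i.shape} vs {r.shape}"
            )
        self._cache = i
        return self.activation.forward(r + self.alpha * i)

    def backward(self, dout):
        i = self._cache
        da = self.activation.backward(dout)
        if self.rsf is not None:
            self.rsf.grad += np.sum(da * i)
        dx = self.resnet.backward(da)
        dx = dx + self.inception.backward(self.alpha * da)
        self._cache = None
        return dx

    def params(self):
        out = self.inception.params() + self.resnet.params()
        if self.rsf is not None:
            out.append(self.rsf)
        out.extend(self.activation.params())
        return out


# ---------------------------------------------------------------------------
# losses

_EPS = 1e-12

LOSSES = (
    "categorical_crossentropy",
    "binary_crossentropy",
    "kullback_leibler_divergence",
    "mean_squared_error",
    "mean_absolute_error",
    "mean_squared_logarithmic_error",
)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grad(logits: np.ndarray, y_onehot: np.ndarray,
                  kind: str = "categorical_crossentropy"):
    """Loss value and gradient w.r.t. the logits, through a softmax head."""
    if kind not in LOSSES:
        raise ConfigurationError(f"unknown loss {kind!r}")
    n, k = logits.shape
    p = softmax(logits)
    y = y_onehot
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    if kind == "categorical_crossentropy":
        loss = -np.mean(np.sum(y * np.log(pc), axis=1))
        dz = (p - y) / n
        return float(loss), dz
    if kind == "binary_crossentropy":
        loss = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))
        g = (-y / pc + (1 - y) / (1 - pc)) / (n * k)
    elif kind == "kullback_leibler_divergence":
        yc = np.clip(y, _EPS, 1.0)
        loss = np.sum(y * (np.log(yc) - np.log(pc))) / n
        g = -y / pc / n
    elif kind == "mean_squared_error":
        loss = np.mean((p - y) ** 2)
        g = 2.0 * (p - y) / (n * k)
    elif kind == "mean_absolute_error":
        loss = np.mean(np.abs(p - y))
        g = np.sign(p - y) / (n * k)
    else:  # mean_squared_logarithmic_error
        d = np.log1p(pc) - np.log1p(y)
        loss = np.mean(d**2)
        g = 2.0 * d / (1.0 + pc) / (n * k)
    # backprop dL/dp through the softmax Jacobian
    dz = p * (g - np.sum(p * g, axis=1, keepdims=True))
    return float(loss), dz


# ---------------------------------------------------------------------------
# optimizers

class Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self._state: dict[int, dict] = {}

    def state(self, p: Param) -> dict:
        return self._state.setdefault(id(p), {})

    def step(self, params: list[Param]) -> None:
        self.t += 1
        for p in params:
            self._update(p)
            p.grad[...] = 0.0

    def _update(self, p: Param) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float, momentum: float = 0.0):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, p):
        if self.momentum:
            st = self.state(p)
            v = st.get("v", np.zeros_like(p.value))
            v = self.momentum * v - self.lr * p.grad
            st["v"] = v
            p.value += v
        else:
            p.value -= self.lr * p.grad


class RMSprop(Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, p):
        st = self.state(p)
        s = st.get("s", np.zeros_like(p.value))
        s = self.rho * s + (1 - self.rho) * p.grad**2
        st["s"] = s
        p.value -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _update(self, p):
        st = self.state(p)
        m = st.get("m", np.zeros_like(p.value))
        v = st.get("v", np.zeros_like(p.value))
        m = self.b1 * m + (1 - self.b1) * p.grad
        v = self.b2 * v + (1 - self.b2) * p.grad**2
        st["m"], st["v"] = m, v
        mhat = m / (1 - self.b1**self.t)
        vhat = v / (1 - self.b2**self.t)
        p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    def _update(self, p):
        st = self.state(p)
        m = st.get("m", np.zeros_like(p.value))
        u = st.get("u", np.zeros_like(p.value))
        m = self.b1 * m + (1 - self.b1) * p.grad
        u = np.maximum(self.b2 * u, np.abs(p.grad))
        st["m"], st["u"] = m, u
        p.value -= self.lr / (1 - self.b1**self.t) * m / (u + self.eps)


class Nadam(Adam):
    def _update(self, p):
        st = self.state(p)
        m = st.get("m", np.zeros_like(p.value))
        v = st.get("v", np.zeros_like(p.value))
        m = self.b1 * m + (1 - self.b1) * p.grad
        v = self.b2 * v + (1 - self.b2) * p.grad**2
        st["m"], st["v"] = m, v
        mhat = m / (1 - self.b1 ** (self.t + 1))
        vhat = v / (1 - self.b2**self.t)
        nudge = (1 - self.b1) * p.grad / (1 - self.b1**self.t)
        p.value -= self.lr * (self.b1 * mhat + nudge) / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {
    "adam": Adam,
    "nadam": Nadam,
    "adamax": Adamax,
    "sgd": SGD,
    "rmsprop": RMSprop,
}


def make_optimizer(kind: str, lr: float) -> Optimizer:
    try:
        return OPTIMIZERS[kind.lower()](lr)
    except KeyError:
        raise ConfigurationError(f"unknown optimizer {kind!r}") from None
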