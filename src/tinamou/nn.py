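"""Minimal convolutional neural network on numpy.

Implements exactly the layer vocabulary the tinamou classifier needs —
strided 2-D convolution (bias-free, L2 kernel + activity regularization),
batch normalization, ReLU, 2x2 max pooling, flatten, dense, dropout and a
softmax cross-entropy head — with reverse-mode gradients and an Adam
optimizer.  Data layout is NCHW; all randomness flows through an explicit
``numpy.random.Generator`` so training is reproducible from a seed.

The implementation is deliberately compact rather than fast: it targets
the band-limited spectrogram images of this pipeline at study scale, and
its gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- im2col

def _pad_amounts(size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _im2col_indices(c: int, h: int, w: int, kh: int, kw: int, stride: int):
    out_h = (h - kh) // stride + 1
    out_w = (w - kw) // stride + 1
    i0 = np.repeat(np.arange(kh), kw)
    i0 = np.tile(i0, c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j0 = np.tile(np.arange(kw), kh * c)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(c), kh * kw).reshape(-1, 1)
    return k, i, j, out_h, out_w


class Layer:
    """Base layer: forward/backward plus (param, grad) pairs."""

    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


class Conv2D(Layer):
    """Bias-free strided convolution with L2 kernel + activity penalties."""

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int = 1,
                 padding: str = "same", l2: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, in_channels, kernel, kernel))
        self.params = {"w": w}
        self.grads = {"w": np.zeros_like(w)}
        self.kernel, self.stride, self.padding, self.l2 = kernel, stride, padding, l2
        self.in_channels, self.filters = in_channels, filters

    def forward(self, x, training, rng=None):
        n, c, h, w = x.shape
        pt, pb = _pad_amounts(h, self.kernel, self.stride, self.padding)
        pl, pr = _pad_amounts(w, self.kernel, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        k, i, j, oh, ow = _im2col_indices(c, xp.shape[2], xp.shape[3], self.kernel, self.kernel, self.stride)
        cols = xp[:, k, i, j]                       # (n, c*kh*kw, oh*ow)
        w_mat = self.params["w"].reshape(self.filters, -1)
        out = np.einsum("fk,nkp->nfp", w_mat, cols).reshape(n, self.filters, oh, ow)
        self._cache = (xp.shape, (pt, pb, pl, pr), cols, (k, i, j), out)
        return out

    def backward(self, dout):
        xp_shape, (pt, pb, pl, pr), cols, (k, i, j), out = self._cache
        n = dout.shape[0]
        # activity regularization: d/dout of l2*sum(out^2)
        if self.l2:
            dout = dout + 2.0 * self.l2 * out
        dout_mat = dout.reshape(n, self.filters, -1)
        w_mat = self.params["w"].reshape(self.filters, -1)
        dw = np.einsum("nfp,nkp->fk", dout_mat, cols).reshape(self.params["w"].shape)
        if self.l2:
            dw = dw + 2.0 * self.l2 * self.params["w"]
        self.grads["w"] = dw
        dcols = np.einsum("fk,nfp->nkp", w_mat, dout_mat)
        dxp = np.zeros(xp_shape)
        np.add.at(dxp, (slice(None), k, i, j), dcols)
        h, w = xp_shape[2] - pt - pb, xp_shape[3] - pl - pr
        return dxp[:, :, pt : pt + h, pl : pl + w]

    def reg_loss(self):
        if not self.l2:
            return 0.0
        return self.l2 * float(np.sum(self.params["w"] ** 2)) + self.l2 * float(np.sum(self._cache[4] ** 2))


class BatchNorm(Layer):
    """Batch normalization over batch (+ spatial axes for conv maps).

    ``momentum`` follows the moving-average-decay convention:
    ``moving = momentum * moving + (1 - momentum) * batch_stat``.
    """

    def __init__(self, channels: int, momentum: float = 0.01, eps: float = 1e-5, spatial: bool = True):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {"gamma": np.zeros(channels), "beta": np.zeros(channels)}
        self.momentum, self.eps, self.spatial = momentum, eps, spatial
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)

    def _axes(self, x):
        return (0, 2, 3) if (self.spatial and x.ndim == 4) else (0,)

    def _shape(self, x):
        return (1, -1, 1, 1) if (self.spatial and x.ndim == 4) else (1, -1)

    def forward(self, x, training, rng=None):
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
        self._cache = (xhat, var, axes, shp, x.shape)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dout):
        xhat, var, axes, shp, xshape = self._cache
        m = np.prod([xshape[a] for a in axes])
        self.grads["gamma"] = np.sum(dout * xhat, axis=axes)
        self.grads["beta"] = np.sum(dout, axis=axes)
        g = self.params["gamma"].reshape(shp)
        istd = 1.0 / np.sqrt(var.reshape(shp) + self.eps)
        dxhat = dout * g
        return istd / m * (m * dxhat - np.sum(dxhat, axis=axes, keepdims=True)
                           - xhat * np.sum(dxhat * xhat, axis=axes, keepdims=True))


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (odd trailing row/column dropped)."""

    def forward(self, x, training, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xv.max(axis=(3, 5))
        self._cache = (x.shape, xv, out)
        return out

    def backward(self, dout):
        xshape, xv, out = self._cache
        mask = xv == out[:, :, :, None, :, None]
        # guard double-counting ties: normalize within each pooling cell
        mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        dx = np.zeros(xshape)
        n, c, h2, _, w2, _ = xv.shape
        dx[:, :, : h2 * 2, : w2 * 2] = (mask * dout[:, :, :, None, :, None]).reshape(n, c, h2 * 2, w2 * 2)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, units))
        self.params = {"w": w, "b": np.zeros(units)}
        self.grads = {"w": np.zeros_like(w), "b": np.zeros(units)}

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Sequential network with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch_size], training=False))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray,
                       rng: np.random.Generator | None = None) -> float:
        """Cross-entropy + regularization loss; fills layer gradients."""
        logits = self.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        n = len(x)
        ce = -float(np.sum(y_onehot * np.log(probs + 1e-12))) / n
        reg = sum(layer.reg_loss() for layer in self.layers)
        dlogits = (probs - y_onehot) / n
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return ce + reg

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield (li, name), layer.params[name], layer.grads[name]

    @property
    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())


class Adam:
    """Adam optimizer over a Network's parameters."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.m = {key: np.zeros_like(p) for key, p, _ in net.parameters()}
        self.v = {key: np.zeros_like(p) for key, p, _ in net.parameters()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for key, p, g in self.net.parameters():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def recalibrate_batchnorm(net: Network, x: np.ndarray, batch_size: int = 512) -> None:
    """Reset every BatchNorm layer's moving statistics to the statistics of
    ``x`` (accumulated batch-wise).

    With a small moving-average decay the running statistics track the
    last training batch, which is a noisy basis for inference; a single
    pass over clean (unaugmented) training data gives stable estimates.
    """
    bns = [l for l in net.layers if isinstance(l, BatchNorm)]
    sums = {id(l): [0.0, 0.0, 0] for l in bns}
    for i in range(0, len(x), batch_size):
        h = x[i : i + batch_size]
        for layer in net.layers:
            if isinstance(layer, BatchNorm):
                axes = layer._axes(h)
                m = np.prod([h.shape[a] for a in axes])
                acc = sums[id(layer)]
                acc[0] += h.mean(axis=axes) * m
                acc[1] += (h ** 2).mean(axis=axes) * m
                acc[2] += m
            # batch statistics inside BN, inference behaviour elsewhere
            # (dropout off) so downstream moments are noise-free
            h = layer.forward(h, training=isinstance(layer, BatchNorm))
    for layer in bns:
        s1, s2, m = sums[id(layer)]
        mean = s1 / m
        layer.moving_mean = mean
        layer.moving_var = s2 / m - mean ** 2


def numerical_gradient(f, param: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``param``
    (mutated in place); used to verify analytic gradients in tests."""
    grad = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = param[idx]
        param[idx] = orig + eps
        fp = f()
        param[idx] = orig - eps
        fm = f()
        param[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
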