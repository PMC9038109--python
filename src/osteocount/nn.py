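"""Minimal NumPy neural-network engine for the crop classifier.

Implements exactly the pieces the residual classifier needs — convolution
(im2col), batch normalization, ReLU, max/global-average pooling, a linear
head, residual blocks, softmax cross-entropy and Adam — with explicit
backpropagation. Everything is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


# ---------------------------------------------------------------------------
# im2col helpers

def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, oh, ow) patch view copy."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride,
                                  j : j + stride * ow : stride]
    return cols


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int) -> np.ndarray:
    """Accumulate (N, C, k, k, oh, ow) gradients back onto the padded input."""
    n, c, hp, wp = shape
    oh, ow = dcols.shape[-2:]
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                dcols[:, :, i, j]
            )
    return dxp


# ---------------------------------------------------------------------------
# Layers

class Layer:
    """Base layer: parameter/buffer dicts plus cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def sublayers(self) -> list[tuple[str, "Layer"]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.params["W"] = rng.normal(0.0, scale, (cout, cin * k * k)).astype(dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, oh, ow).reshape(n, c * k * k, oh * ow)
        y = (self.params["W"] @ cols).reshape(n, self.cout, oh, ow)
        if train:
            self._cache = (cols, xp.shape, (oh, ow))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (oh, ow) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, oh * ow)
        self.grads["W"] = np.matmul(dyf, cols.swapaxes(1, 2)).sum(axis=0)
        dcols = (self.params["W"].T @ dyf).reshape(
            n, self.cin, self.k, self.k, oh, ow
        )
        dxp = _col2im(dcols, xp_shape, self.k, self.stride)
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p, p : dxp.shape[3] - p] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.buffers["running_mean"] = np.zeros(c, dtype=dtype)
        self.buffers["running_var"] = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mean
            ).astype(x.dtype)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * var
            ).astype(x.dtype)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar)
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.params["gamma"][None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int, pad: int = 0) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        cols = _im2col(xp, k, s, oh, ow).reshape(n, c, k * k, oh, ow)
        idx = cols.argmax(axis=2)
        y = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (idx, xp.shape, (oh, ow))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xp_shape, (oh, ow) = self._cache
        n, c = dy.shape[:2]
        k = self.k
        dcols = np.zeros((n, c, k * k, oh, ow), dtype=dy.dtype)
        np.put_along_axis(dcols, idx[:, :, None], dy[:, :, None], axis=2)
        dxp = _col2im(
            dcols.reshape(n, c, k, k, oh, ow), xp_shape, k, self.stride
        )
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p, p : dxp.shape[3] - p] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        else:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.params["W"] = rng.normal(0.0, scale, (cout, cin)).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        super().__init__()
        self.layers = layers

    def sublayers(self) -> list[tuple[str, Layer]]:
        return self.layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """conv3x3-BN-ReLU-conv3x3-BN plus (projected) identity, then ReLU."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        self.branch = Sequential([
            ("conv1", Conv2d(cin, cout, 3, stride, 1, rng, dtype)),
            ("bn1", BatchNorm2d(cout, dtype=dtype)),
            ("relu1", ReLU()),
            ("conv2", Conv2d(cout, cout, 3, 1, 1, rng, dtype)),
            ("bn2", BatchNorm2d(cout, dtype=dtype)),
        ])
        if stride != 1 or cin != cout:
            self.shortcut: Layer | None = Sequential([
                ("conv", Conv2d(cin, cout, 1, stride, 0, rng, dtype)),
                ("bn", BatchNorm2d(cout, dtype=dtype)),
            ])
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def sublayers(self) -> list[tuple[str, Layer]]:
        subs = [("branch", self.branch)]
        if self.shortcut is not None:
            subs.append(("shortcut", self.shortcut))
        subs.append(("relu_out", self.relu_out))
        return subs

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        branch = self.branch.forward(x, train)
        identity = self.shortcut.forward(x, train) if self.shortcut is not None else x
        return self.relu_out.forward(branch + identity, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dx = self.branch.backward(dsum)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dsum)
        else:
            dx = dx + dsum
        return dx


# ---------------------------------------------------------------------------
# Model

def _walk(layer: Layer, prefix: str = ""):
    yield prefix, layer
    for name, sub in layer.sublayers():
        yield from _walk(sub, f"{prefix}.{name}" if prefix else name)


class Model:
    """A named layer stack with flat parameter/buffer access."""

    def __init__(self, root: Sequential, arch: str) -> None:
        self.root = root
        self.arch = arch

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.root.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.root.backward(dy)

    def _flat(self, attr: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in _walk(self.root):
            for key, val in getattr(layer, attr).items():
                out[f"{name}.{key}" if name else key] = val
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        return self._flat("params")

    def gradients(self) -> dict[str, np.ndarray]:
        return self._flat("grads")

    def buffers(self) -> dict[str, np.ndarray]:
        return self._flat("buffers")

    def load_state(self, params: dict[str, np.ndarray],
                   buffers: dict[str, np.ndarray] | None = None) -> None:
        own_params = self.parameters()
        for key, val in params.items():
            if key not in own_params:
                raise ValidationError(f"unknown parameter {key!r} for arch {self.arch}")
            if own_params[key].shape != val.shape:
                raise ValidationError(f"shape mismatch for {key!r}")
            own_params[key][...] = val
        if buffers:
            own_buffers = self.buffers()
            for key, val in buffers.items():
                own_buffers[key][...] = val

    def state_copy(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        return (
            {k: v.copy() for k, v in self.parameters().items()},
            {k: v.copy() for k, v in self.buffers().items()},
        )


def build_model(arch: str = "small", seed: int = 0, n_classes: int = 2,
                dtype=np.float32) -> Model:
    """Build the classifier network.

    ``resnet18``: the full published architecture — 7x7/stride-2 stem into 64
    maps, 3x3 max-pool, four two-block residual stages of width 64/128/256/512,
    global average pooling and a fully connected softmax head.
    ``small``: a reduced-width two-stage residual net (16/32) for CPU-scale
    training with the same structure.
    """
    rng = np.random.default_rng(seed)
    if arch == "small":
        # stem downsamples before the residual stages, like the full network
        root = Sequential([
            ("stem_conv", Conv2d(3, 16, 3, 1, 1, rng, dtype)),
            ("stem_bn", BatchNorm2d(16, dtype=dtype)),
            ("stem_relu", ReLU()),
            ("stem_pool", MaxPool2d(2, 2)),
            ("stage1", ResidualBlock(16, 16, 1, rng, dtype)),
            ("stage2", ResidualBlock(16, 32, 2, rng, dtype)),
            ("gap", GlobalAvgPool()),
            ("fc", Linear(32, n_classes, rng, dtype)),
        ])
    elif arch == "resnet18":
        layers: list[tuple[str, Layer]] = [
            ("stem_conv", Conv2d(3, 64, 7, 2, 3, rng, dtype)),
            ("stem_bn", BatchNorm2d(64, dtype=dtype)),
            ("stem_relu", ReLU()),
            ("stem_pool", MaxPool2d(3, 2, 1)),
        ]
        widths = [64, 128, 256, 512]
        cin = 64
        for stage, cout in enumerate(widths, start=1):
            stride = 1 if stage == 1 else 2
            layers.append((f"stage{stage}a", ResidualBlock(cin, cout, stride, rng, dtype)))
            layers.append((f"stage{stage}b", ResidualBlock(cout, cout, 1, rng, dtype)))
            cin = cout
        layers += [("gap", GlobalAvgPool()), ("fc", Linear(512, n_classes, rng, dtype))]
        root = Sequential(layers)
    else:
        raise ValidationError(f"unknown architecture {arch!r}")
    return Model(root, arch)


# ---------------------------------------------------------------------------
# Loss and optimizer

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam with L2 regularization added to the gradient (lambda * theta)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.002,
                 weight_decay: float = 1e-5, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for key, theta in self.params.items():
            g = grads[key].astype(theta.dtype) + self.weight_decay * theta
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
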