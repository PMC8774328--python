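"""Minimal NumPy layer engine with explicit backpropagation.

Implements exactly the layer vocabulary the backbone registry needs:
convolution (arbitrary stride/padding/groups), batch normalization,
ReLU/ReLU6/sigmoid, max/average pooling, global average pooling, linear
maps, squeeze-excitation, and the residual block families. Every layer is
stateless across calls: ``forward`` returns ``(output, cache)`` and
``backward(grad, cache)`` returns the input gradient while accumulating
parameter gradients, so several forward passes (the raw / crop / erase
streams) can be in flight before any backward runs.

All computation is float32; convolution uses im2col + GEMM.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                yield value
        for child in self.modules():
            yield from child.parameters()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self, trainable_only: bool = True) -> int:
        # all parameters in this engine are trainable
        del trainable_only
        return sum(p.size for p in self.parameters())

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x, kh, kw, sh, sw, ph, pw):
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (x.shape[2] - kh) // sh + 1
    wo = (x.shape[3] - kw) // sw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::sh, ::sw]  # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += dcols[:, :, i, j]
    if ph or pw:
        return dxp[:, :, ph : ph + h, pw : pw + w]
    return dxp


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, bias=True, rng=None):
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.padding, self.groups = stride, padding, groups
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin // groups, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x, train=False):
        n = x.shape[0]
        g, k = self.groups, self.k
        cols, ho, wo = _im2col(x, k, k, self.stride, self.stride, self.padding, self.padding)
        w = self.weight.data.reshape(g, self.cout // g, -1)
        if g == 1:
            y = np.einsum("of,nfl->nol", w[0], cols, optimize=True)
        else:
            cols_g = cols.reshape(n, g, -1, cols.shape[-1])
            y = np.einsum("gof,ngfl->ngol", w, cols_g, optimize=True)
            y = y.reshape(n, self.cout, -1)
        if self.bias is not None:
            y = y + self.bias.data[None, :, None]
        y = y.reshape(n, self.cout, ho, wo).astype(DTYPE, copy=False)
        return y, (x.shape, cols, ho, wo)

    def backward(self, dy, cache):
        xshape, cols, ho, wo = cache
        n = dy.shape[0]
        g, k = self.groups, self.k
        dyf = dy.reshape(n, self.cout, -1)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        w = self.weight.data.reshape(g, self.cout // g, -1)
        if g == 1:
            self.weight.grad += np.einsum("nol,nfl->of", dyf, cols, optimize=True).reshape(
                self.weight.data.shape
            )
            dcols = np.einsum("of,nol->nfl", w[0], dyf, optimize=True)
        else:
            dyg = dyf.reshape(n, g, self.cout // g, -1)
            cols_g = cols.reshape(n, g, -1, cols.shape[-1])
            self.weight.grad += np.einsum("ngol,ngfl->gof", dyg, cols_g, optimize=True).reshape(
                self.weight.data.shape
            )
            dcols = np.einsum("gof,ngol->ngfl", w, dyg, optimize=True).reshape(
                n, -1, cols.shape[-1]
            )
        return _col2im(
            dcols.astype(DTYPE, copy=False), xshape, k, k, self.stride, self.stride,
            self.padding, self.padding, ho, wo,
        )


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        y = self.weight.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]
        return y.astype(DTYPE, copy=False), (xhat, invstd, train)

    def backward(self, dy, cache):
        xhat, invstd, train = cache
        self.weight.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        gamma = self.weight.data[None, :, None, None]
        if not train:
            return dy * gamma * invstd[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dy.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = gamma * invstd[None, :, None, None] / m * (m * dy - s1 - xhat * s2)
        return dx.astype(DTYPE, copy=False)


class ReLU(Module):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        return y, (x > 0)

    def backward(self, dy, cache):
        return dy * cache


class ReLU6(Module):
    def forward(self, x, train=False):
        y = np.clip(x, 0, 6)
        return y, ((x > 0) & (x < 6))

    def backward(self, dy, cache):
        return dy * cache


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(y, dtype=DTYPE), (x.shape, idx, ho, wo)

    def backward(self, dy, cache):
        xshape, idx, ho, wo = cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.padding
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oi[None, None] * s + idx // k
        cols = oj[None, None] * s + idx % k
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols), dy)
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class GlobalAvgPool(Module):
    """Adaptive average pool to 1x1, returned as (n, c)."""

    def forward(self, x, train=False):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        return np.broadcast_to(dy[:, :, None, None] / (h * w), cache).astype(DTYPE)


class Linear(Module):
    def __init__(self, fin, fout, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fin), size=(fout, fin)))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x, train=False):
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data
        return y.astype(DTYPE, copy=False), x

    def backward(self, dy, cache):
        self.weight.grad += dy.T @ cache
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.data).astype(DTYPE, copy=False)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy


class SEModule(Module):
    """Squeeze-excitation: global pool -> fc -> ReLU -> fc -> sigmoid -> scale."""

    def __init__(self, c, reduction=16, rng=None):
        self.fc1 = Linear(c, c // reduction, rng=rng)
        self.fc2 = Linear(c // reduction, c, rng=rng)

    def forward(self, x, train=False):
        pool = GlobalAvgPool()
        z, pc = pool.forward(x)
        h1, c1 = self.fc1.forward(z)
        a1 = np.maximum(h1, 0)
        h2, c2 = self.fc2.forward(a1)
        s = 1.0 / (1.0 + np.exp(-h2))
        y = x * s[:, :, None, None]
        return y.astype(DTYPE, copy=False), (x, s, h1, c1, c2, pc)

    def backward(self, dy, cache):
        x, s, h1, c1, c2, pc = cache
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        dh2 = ds * s * (1 - s)
        da1 = self.fc2.backward(dh2.astype(DTYPE), c2)
        dh1 = da1 * (h1 > 0)
        dz = self.fc1.backward(dh1.astype(DTYPE), c1)
        dx = dx + GlobalAvgPool().backward(dz, pc)
        return dx.astype(DTYPE, copy=False)


class BasicBlock(Module):
    """Two 3x3 convolutions with identity shortcut (18/34-layer residual nets)."""

    expansion = 1

    def __init__(self, cin, planes, stride=1, rng=None):
        self.conv1 = Conv2d(cin, planes, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.downsample = None
        if stride != 1 or cin != planes:
            self.downsample = Sequential(
                Conv2d(cin, planes, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(planes)
            )

    def forward(self, x, train=False):
        h, c1 = self.conv1.forward(x, train)
        h, b1 = self.bn1.forward(h, train)
        m1 = h > 0
        h = np.maximum(h, 0)
        h, c2 = self.conv2.forward(h, train)
        h, b2 = self.bn2.forward(h, train)
        if self.downsample is not None:
            idn, dc = self.downsample.forward(x, train)
        else:
            idn, dc = x, None
        y = h + idn
        m2 = y > 0
        return np.maximum(y, 0), (c1, b1, m1, c2, b2, dc, m2)

    def backward(self, dy, cache):
        c1, b1, m1, c2, b2, dc, m2 = cache
        dy = dy * m2
        dh = self.bn2.backward(dy, b2)
        dh = self.conv2.backward(dh, c2)
        dh = dh * m1
        dh = self.bn1.backward(dh, b1)
        dx = self.conv1.backward(dh, c1)
        if self.downsample is not None:
            dx = dx + self.downsample.backward(dy, dc)
        else:
            dx = dx + dy
        return dx


class Bottleneck(Module):
    """1x1 -> 3x3 (optionally grouped) -> 1x1 residual block, optional SE."""

    expansion = 4

    def __init__(self, cin, planes, stride=1, groups=1, base_width=64, se=False, rng=None):
        width = int(planes * (base_width / 64.0)) * groups
        out = planes * self.expansion
        self.conv1 = Conv2d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, padding=1, groups=groups,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, out, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out)
        self.se = SEModule(out, rng=rng) if se else None
        self.downsample = None
        if stride != 1 or cin != out:
            self.downsample = Sequential(
                Conv2d(cin, out, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(out)
            )

    def forward(self, x, train=False):
        h, c1 = self.conv1.forward(x, train)
        h, b1 = self.bn1.forward(h, train)
        m1 = h > 0
        h = np.maximum(h, 0)
        h, c2 = self.conv2.forward(h, train)
        h, b2 = self.bn2.forward(h, train)
        m2 = h > 0
        h = np.maximum(h, 0)
        h, c3 = self.conv3.forward(h, train)
        h, b3 = self.bn3.forward(h, train)
        sc = None
        if self.se is not None:
            h, sc = self.se.forward(h, train)
        if self.downsample is not None:
            idn, dc = self.downsample.forward(x, train)
        else:
            idn, dc = x, None
        y = h + idn
        m3 = y > 0
        return np.maximum(y, 0), (c1, b1, m1, c2, b2, m2, c3, b3, sc, dc, m3)

    def backward(self, dy, cache):
        c1, b1, m1, c2, b2, m2, c3, b3, sc, dc, m3 = cache
        dy = dy * m3
        dh = dy
        if self.se is not None:
            dh = self.se.backward(dh, sc)
        dh = self.bn3.backward(dh, b3)
        dh = self.conv3.backward(dh, c3)
        dh = dh * m2
        dh = self.bn2.backward(dh, b2)
        dh = self.conv2.backward(dh, c2)
        dh = dh * m1
        dh = self.bn1.backward(dh, b1)
        dx = self.conv1.backward(dh, c1)
        if self.downsample is not None:
            dx = dx + self.downsample.backward(dy, dc)
        else:
            dx = dx + dy
        return dx


class InvertedResidual(Module):
    """MobileNetV2 block: expand 1x1 -> depthwise 3x3 -> project 1x1."""

    def __init__(self, cin, cout, stride=1, expand=6, rng=None):
        hidden = cin * expand
        self.use_res = stride == 1 and cin == cout
        layers = []
        if expand != 1:
            layers += [Conv2d(cin, hidden, 1, bias=False, rng=rng), BatchNorm2d(hidden), ReLU6()]
        layers += [
            Conv2d(hidden, hidden, 3, stride=stride, padding=1, groups=hidden, bias=False, rng=rng),
            BatchNorm2d(hidden),
            ReLU6(),
            Conv2d(hidden, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout),
        ]
        self.body = Sequential(*layers)

    def forward(self, x, train=False):
        y, cache = self.body.forward(x, train)
        if self.use_res:
            y = y + x
        return y, cache

    def backward(self, dy, cache):
        dx = self.body.backward(dy, cache)
        if self.use_res:
            dx = dx + dy
        return dx


# ---------------------------------------------------------------------------
# Optimizers


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= DTYPE(self.lr) * v


class Adam:
    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= DTYPE(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


OPTIMIZERS = {"adam": Adam, "sgd": SGD}


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax of an (n, c) score matrix."""
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
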