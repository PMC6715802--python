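"""Minimal CNN engine on numpy.

Layers keep explicit parameter objects and hand-written backward passes so
that the rest of the package can inspect and manipulate network internals:
receptive-field walks, copying a classification head into a 1x1 convolution,
per-layer freeze flags for staged training, and guided backpropagation all
need access below the level a high-level framework exposes.

Conventions: activations are float32 arrays in NCHW layout; convolutions
support 'same' (TF-style, possibly asymmetric) and 'valid' padding.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Global switch flipped by the saliency module: when True, ReLU backward
# passes only positive gradients through positive activations.
GUIDED_BACKPROP = [False]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer: forward/backward plus a trainability flag."""

    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # (kernel, stride) contributions for the receptive-field walk; composite
    # layers override to yield their internal chain.
    def geometry(self):
        return []

    def sublayers(self):
        yield self


def _pad_amounts(size: int, k: int, s: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding="same",
                 bias=True, rng=None, name="conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.w = Param(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)),
                       f"{name}.w")
        self.b = Param(np.zeros(out_ch), f"{name}.b") if bias else None
        self.name = name

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def geometry(self):
        return [(self.kernel, self.stride)]

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        ph = _pad_amounts(x.shape[2], k, s, self.padding)
        pw = _pad_amounts(x.shape[3], k, s, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw)) if (ph != (0, 0) or pw != (0, 0)) else x
        self._xp, self._pads, self._xshape = xp, (ph, pw), x.shape
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.tensordot(win, self.w.data, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        return out

    def backward(self, dout):
        k, s = self.kernel, self.stride
        xp = self._xp
        ho, wo = dout.shape[2], dout.shape[3]
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # dW[o,c,a,b] = sum_{n,i,j} dout[n,o,i,j] * win[n,c,i,j,a,b]
        self.w.grad += np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        # gw[n,i,j,c,a,b] = sum_o dout[n,o,i,j] w[o,c,a,b]
        gw = np.tensordot(dout.transpose(0, 2, 3, 1), self.w.data, axes=([3], [0]))
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                dxp[:, :, a:a + ho * s:s, b:b + wo * s:s] += \
                    gw[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        (pt, pb), (pl, pr) = self._pads
        h, w = self._xshape[2], self._xshape[3]
        return dxp[:, :, pt:pt + h, pl:pl + w]


class MaxPool2d(Layer):
    trainable = False

    def __init__(self, kernel=2, stride=None, padding="valid", name="pool"):
        self.kernel = kernel
        self.stride = stride or kernel
        self.padding = padding
        self.name = name

    def geometry(self):
        return [(self.kernel, self.stride)]

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        ph = _pad_amounts(x.shape[2], k, s, self.padding)
        pw = _pad_amounts(x.shape[3], k, s, self.padding)
        if ph != (0, 0) or pw != (0, 0):
            xp = np.pad(x, ((0, 0), (0, 0), ph, pw), constant_values=-np.inf)
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=4)
        self._shapes = (x.shape, xp.shape, (ph, pw))
        return flat.max(axis=4)

    def backward(self, dout):
        k, s = self.kernel, self.stride
        xshape, xpshape, (ph, pw) = self._shapes
        n, c, ho, wo = dout.shape
        dxp = np.zeros(xpshape, dtype=dout.dtype)
        ai, bi = np.divmod(self._arg, k)
        ni, ci, ii, ji = np.indices((n, c, ho, wo), sparse=False)
        np.add.at(dxp, (ni, ci, ii * s + ai, ji * s + bi), dout)
        return dxp[:, :, ph[0]:ph[0] + xshape[2], pw[0]:pw[0] + xshape[3]]


class ReLU(Layer):
    trainable = False

    def __init__(self, name="relu"):
        self.name = name

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        dx = dout * self._mask
        if GUIDED_BACKPROP[0]:
            dx = np.maximum(dx, 0)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.9, eps=1e-5, name="bn"):
        self.gamma = Param(np.ones(ch), f"{name}.gamma")
        self.beta = Param(np.zeros(ch), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.name = name

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, std, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dout * g / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx / std[None, :, None, None]


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N,C,H,W) -> (N,C)."""

    trainable = False

    def __init__(self, name="gap"):
        self.name = name

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    trainable = False

    def __init__(self, name="flatten"):
        self.name = name

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None, name="fc"):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.w = Param(rng.normal(0.0, scale, (in_features, out_features)),
                       f"{name}.w")
        self.b = Param(np.zeros(out_features), f"{name}.b")
        self.in_features, self.out_features = in_features, out_features
        self.name = name

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class Softmax(Layer):
    """Softmax over the last axis of a (N, d) score matrix."""

    trainable = False

    def __init__(self, name="softmax"):
        self.name = name

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class ChannelSoftmax(Layer):
    """Per-cell softmax across channels of an (N,C,H,W) map."""

    trainable = False

    def __init__(self, name="csoftmax"):
        self.name = name

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))


class BottleneckUnit(Layer):
    """Residual bottleneck: 1x1 -> 3x3 -> 1x1 convolutions (each with batch
    norm) plus an identity shortcut; a 1x1 projection shortcut is used when
    the stride or channel count changes."""

    def __init__(self, in_ch, depths, stride=1, rng=None, name="bneck"):
        l, m, n = depths
        self.name = name
        self.conv1 = Conv2d(in_ch, l, 1, stride, "same", bias=False, rng=rng,
                            name=f"{name}.c1")
        self.bn1 = BatchNorm2d(l, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(l, m, 3, 1, "same", bias=False, rng=rng,
                            name=f"{name}.c2")
        self.bn2 = BatchNorm2d(m, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv3 = Conv2d(m, n, 1, 1, "same", bias=False, rng=rng,
                            name=f"{name}.c3")
        self.bn3 = BatchNorm2d(n, name=f"{name}.bn3")
        if stride != 1 or in_ch != n:
            self.proj = Conv2d(in_ch, n, 1, stride, "same", bias=False, rng=rng,
                               name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(n, name=f"{name}.projbn")
        else:
            self.proj = self.proj_bn = None
        self.relu_out = ReLU()
        self.out_ch = n
        self.stride = stride

    def params(self):
        out = []
        for lay in self._main() + self._short():
            out.extend(lay.params())
        return out

    def _main(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                self.relu2, self.conv3, self.bn3]

    def _short(self):
        return [l for l in (self.proj, self.proj_bn) if l is not None]

    def sublayers(self):
        for lay in self._main() + self._short() + [self.relu_out]:
            yield lay

    def geometry(self):
        # Effective spatial footprint of the main path: 1x1/s, 3x3, 1x1.
        return [(1, self.stride), (3, 1), (1, 1)]

    def forward(self, x, train=False):
        h = x
        for lay in self._main():
            h = lay.forward(h, train)
        s = x
        if self.proj is not None:
            s = self.proj_bn.forward(self.proj.forward(s, train), train)
        return self.relu_out.forward(h + s, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        ds = d
        if self.proj is not None:
            ds = self.proj.backward(self.proj_bn.backward(d))
        dh = d
        for lay in reversed(self._main()):
            dh = lay.backward(dh)
        return dh + ds

    @property
    def trainable(self):
        return self.conv1.trainable

    @trainable.setter
    def trainable(self, flag):
        for lay in self._main() + self._short():
            lay.trainable = flag


class FcTopShortcut(Layer):
    """Two FC layers on a flattened pooled heatmap with an additive shortcut
    from the flattened heatmap straight to the d-way output scores."""

    def __init__(self, in_features, fc1, fc2, n_out, rng=None, name="fctop"):
        self.fc1 = Dense(in_features, fc1, rng=rng, name=f"{name}.fc1")
        self.r1 = ReLU()
        self.fc2 = Dense(fc1, fc2, rng=rng, name=f"{name}.fc2")
        self.r2 = ReLU()
        self.out = Dense(fc2, n_out, rng=rng, name=f"{name}.out")
        self.short = Dense(in_features, n_out, rng=rng, name=f"{name}.short")
        self.name = name

    def params(self):
        out = []
        for lay in (self.fc1, self.fc2, self.out, self.short):
            out.extend(lay.params())
        return out

    def sublayers(self):
        for lay in (self.fc1, self.r1, self.fc2, self.r2, self.out, self.short):
            yield lay

    def forward(self, x, train=False):
        h = self.r1.forward(self.fc1.forward(x, train), train)
        h = self.r2.forward(self.fc2.forward(h, train), train)
        return self.out.forward(h, train) + self.short.forward(x, train)

    def backward(self, dout):
        ds = self.short.backward(dout)
        dh = self.fc2.backward(self.r2.backward(self.out.backward(dout)))
        return self.fc1.backward(self.r1.backward(dh)) + ds

    @property
    def trainable(self):
        return self.fc1.trainable

    @trainable.setter
    def trainable(self, flag):
        for lay in (self.fc1, self.fc2, self.out, self.short):
            lay.trainable = flag


class Sequential:
    """An ordered layer chain; the unit the rest of the package manipulates."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False, stop_before=None):
        for lay in self.layers if stop_before is None else self.layers[:stop_before]:
            x = lay.forward(x, train)
        return x

    def backward(self, dout, start_after=None):
        layers = self.layers if start_after is None else self.layers[:start_after]
        for lay in reversed(layers):
            dout = lay.backward(dout)
        return dout

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def leaf_layers(self):
        for lay in self.layers:
            yield from lay.sublayers()


def weighted_groups(net: Sequential) -> list[list[Layer]]:
    """Group layers for freeze scoping: each convolution or dense layer forms
    a weighted group together with any batch-norm layer that follows it."""
    groups: list[list[Layer]] = []
    for lay in net.layers:
        if isinstance(lay, (BottleneckUnit, FcTopShortcut)):
            subs = [s for s in lay.sublayers() if isinstance(s, (Conv2d, Dense, BatchNorm2d))]
            cur: list[Layer] = []
            for s in subs:
                if isinstance(s, (Conv2d, Dense)):
                    if cur:
                        groups.append(cur)
                    cur = [s]
                else:
                    cur.append(s)
            if cur:
                groups.append(cur)
        elif isinstance(lay, (Conv2d, Dense)):
            groups.append([lay])
        elif isinstance(lay, BatchNorm2d) and groups:
            groups[-1].append(lay)
    return groups


def set_trainable(net: Sequential, flag: bool):
    for lay in net.layers:
        lay.trainable = flag


class Adam:
    """Adam over the trainable parameters of a network, with optional L2
    weight decay folded into the gradient."""

    def __init__(self, net: Sequential, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.0):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def _trainable_params(self):
        for lay in self.net.leaf_layers():
            if getattr(lay, "trainable", False):
                yield from lay.params()

    def zero_grad(self):
        for lay in self.net.layers:
            for p in lay.params():
                p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p in self._trainable_params():
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases/BN
                g = g + self.weight_decay * p.data
            m, v = self.state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.state[id(p)] = (m, v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_xent_grad(probs: np.ndarray, onehot: np.ndarray,
                      sample_weights: np.ndarray | None = None):
    """Cross-entropy loss and its gradient w.r.t. the pre-softmax scores."""
    n = probs.shape[0]
    w = np.ones(n, dtype=np.float32) if sample_weights is None else sample_weights
    eps = 1e-12
    loss = -(w * (onehot * np.log(probs + eps)).sum(axis=1)).sum() / n
    grad = (probs - onehot) * w[:, None] / n
    return loss, grad


def get_weights(net: Sequential) -> list[np.ndarray]:
    return [p.data.copy() for p in net.params()]


def set_weights(net: Sequential, weights: list[np.ndarray]):
    for p, w in zip(net.params(), weights, strict=True):
        p.data[...] = w


def snapshot_state(net: Sequential):
    """Copy of all parameters plus batch-norm running statistics."""
    params = [p.data.copy() for p in net.params()]
    bn = [(lay.running_mean.copy(), lay.running_var.copy())
          for lay in net.leaf_layers() if isinstance(lay, BatchNorm2d)]
    return params, bn


def restore_state(net: Sequential, state):
    params, bn = state
    set_weights(net, params)
    bns = [lay for lay in net.leaf_layers() if isinstance(lay, BatchNorm2d)]
    for lay, (mean, var) in zip(bns, bn, strict=True):
        lay.running_mean[...] = mean
        lay.running_var[...] = var


def weight_checksum(layers) -> float:
    """Cheap fingerprint used to assert freeze integrity."""
    total = 0.0
    for lay in layers:
        for p in lay.params():
            total += float(np.abs(p.data).sum())
    return total
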