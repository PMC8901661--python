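"""Minimal numpy CNN used by the spectrogram classifier.

Three 3x3 conv blocks (conv - ReLU - 2x2 max pool), a fully connected
hidden layer (the penultimate layer whose activations feed the t-SNE
maps) and a softmax output, trained with minibatch SGD + momentum and a
stepped learning-rate schedule.  Convolutions are im2col matrix products;
everything is float32 and seeded, so training is deterministic for a
given seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _im2col(x, k=3, pad=1):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    i = 0
    for dy in range(k):
        for dx in range(k):
            patch = xp[:, :, dy:dy + h, dx:dx + w]
            cols[:, i * c:(i + 1) * c, :] = patch.reshape(n, c, h * w)
            i += 1
    return cols


def _col2im(cols, shape, k=3, pad=1):
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    i = 0
    for dy in range(k):
        for dx in range(k):
            xp[:, :, dy:dy + h, dx:dx + w] += cols[:, i * c:(i + 1) * c, :].reshape(n, c, h, w)
            i += 1
    return xp[:, :, pad:pad + h, pad:pad + w]


class _Conv:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)

    def forward(self, x):
        self.x_shape, self.cols = x.shape, _im2col(x)
        n, _, h, w = x.shape
        out = np.einsum("fk,nkp->nfp", self.W, self.cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, g):
        n, f, h, w = g.shape
        gf = g.reshape(n, f, h * w)
        self.gW = np.einsum("nfp,nkp->fk", gf, self.cols) / n
        self.gb = gf.sum(axis=2).mean(axis=0)
        gcols = np.einsum("fk,nfp->nkp", self.W, gf)
        return _col2im(gcols, self.x_shape)

    params = property(lambda self: [("W", self.W), ("b", self.b)])


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask


class _Pool2:
    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        self.x_shape = x.shape
        out = xr.max(axis=(3, 5))
        self.mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, g):
        n, c, h, w = self.x_shape
        h2, w2 = h // 2, w // 2
        gr = self.mask * g[:, :, :, None, :, None]
        out = np.zeros(self.x_shape, g.dtype)
        out[:, :, :h2 * 2, :w2 * 2] = gr.reshape(n, c, h2 * 2, w2 * 2)
        return out


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, np.float32)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self.x.T @ g / g.shape[0]
        self.gb = g.mean(axis=0)
        return g @ self.W.T


class SmallCNN:
    """conv(8)-conv(16)-conv(32) with pooling, FC hidden, softmax output."""

    def __init__(self, input_hw=(48, 48), n_classes=2, hidden=64,
                 filters=(8, 16, 32), seed=0):
        rng = np.random.default_rng(seed)
        self.input_hw = tuple(input_hw)
        self.n_classes = int(n_classes)
        chans = (1,) + tuple(filters)
        self.convs = [_Conv(chans[i], chans[i + 1], rng) for i in range(len(filters))]
        self.relus = [_ReLU() for _ in filters]
        self.pools = [_Pool2() for _ in filters]
        h, w = input_hw
        for _ in filters:
            h, w = h // 2, w // 2
        self.flat_dim = filters[-1] * h * w
        self.fc1 = _Dense(self.flat_dim, hidden, rng)
        self.fc1_relu = _ReLU()
        self.fc2 = _Dense(hidden, n_classes, rng)
        self._vel = {}

    # -- forward ---------------------------------------------------------
    def _features(self, x):
        h = x.astype(np.float32)
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        return h.reshape(h.shape[0], -1)

    def forward(self, x):
        self.hidden = self.fc1_relu.forward(self.fc1.forward(self._features(x)))
        return self.fc2.forward(self.hidden)

    def penultimate(self, x, batch=128):
        """Activations of the last hidden fully connected layer."""
        outs = []
        for i in range(0, x.shape[0], batch):
            self.forward(x[i:i + batch])
            outs.append(self.hidden.copy())
        return np.concatenate(outs)

    def predict_proba(self, x, batch=128):
        outs = []
        for i in range(0, x.shape[0], batch):
            z = self.forward(x[i:i + batch])
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs)

    def predict(self, x, batch=128):
        return np.argmax(self.predict_proba(x, batch), axis=1)

    # -- training --------------------------------------------------------
    def _layers_with_params(self):
        return self.convs + [self.fc1, self.fc2]

    def train_step(self, x, y, lr, momentum=0.9):
        z = self.forward(x)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(y.size), y] + 1e-12))
        g = p
        g[np.arange(y.size), y] -= 1.0
        g = self.fc2.backward(g.astype(np.float32))
        g = self.fc1.backward(self.fc1_relu.backward(g))
        g = g.reshape((-1,) + self._feature_shape())
        for conv, relu, pool in zip(self.convs[::-1], self.relus[::-1], self.pools[::-1]):
            g = conv.backward(relu.backward(pool.backward(g)))
        for li, layer in enumerate(self._layers_with_params()):
            for name in ("W", "b"):
                grad = getattr(layer, "g" + name)
                key = (li, name)
                v = self._vel.get(key, 0.0)
                v = momentum * v - lr * grad
                self._vel[key] = v
                setattr(layer, name, getattr(layer, name) + v)
        return float(loss)

    def _feature_shape(self):
        h, w = self.input_hw
        for _ in self.convs:
            h, w = h // 2, w // 2
        c = self.convs[-1].W.shape[0]
        return (c, h, w)

    # -- checkpointing ---------------------------------------------------
    def get_params(self):
        return [(l.W.copy(), l.b.copy()) for l in self._layers_with_params()]

    def set_params(self, params):
        for layer, (W, b) in zip(self._layers_with_params(), params):
            layer.W, layer.b = W.copy(), b.copy()
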