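"""Minimal NumPy convolutional network trainer.

Implements exactly the architecture family the classifier needs: a
stack of 3x3 convolution + ReLU + 2x2 max-pool blocks ending in global
average pooling (GAP) and a two-way dense head.  Keeping the trainer in
NumPy makes every run deterministic for a given seed and keeps the
pre-GAP feature maps and dense weights directly accessible for class
activation mapping.

Shapes follow the (N, C, H, W) convention.  Convolutions are stride-1,
zero-padded 'same'; weights use He-normal initialization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallConvNet", "SGD", "Adam", "softmax", "train_network"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(xp: np.ndarray) -> np.ndarray:
    # xp: (N, C, H+2, W+2) zero-padded -> (N, C*9, H*W)
    n, c, _, _ = xp.shape
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    h, w = win.shape[2], win.shape[3]
    return (
        win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w),
        (h, w),
    )


class _Conv3x3:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)

    def forward(self, x):
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols, (h, w) = _im2col(xp)
        self._cols = cols
        out = np.einsum("fk,nkp->nfp", self.W, cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, h, w)

    def backward(self, dout):
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.dW = np.einsum("nfp,nkp->fk", dflat, self._cols)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.W, dflat)
        # col2im: scatter-add the 9 taps back onto the padded image
        c_in = self._in_shape[1]
        dxp = np.zeros((n, c_in, h + 2, w + 2))
        dcols = dcols.reshape(n, c_in, 3, 3, h, w)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._counts = self._mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        g = dout[:, :, :, None, :, None] * self._mask / self._counts
        n, c, h, w = self._shape
        return g.reshape(n, c, h, w)


class SmallConvNet:
    """Conv backbone -> GAP -> 2-way dense head.

    Parameters
    ----------
    input_size : side length of the (square, single-channel) input.
    channels : per-block output channel counts; each block halves the
        spatial size, so ``input_size`` must be divisible by
        ``2**len(channels)``.
    seed : initialization seed.
    """

    n_classes = 2

    def __init__(self, input_size: int = 64, channels=(8, 16, 32), seed: int = 0):
        if input_size % (1 << len(channels)):
            raise ValueError("input_size must be divisible by 2**n_blocks")
        rng = np.random.default_rng(seed)
        self.input_size = int(input_size)
        self.channels = tuple(channels)
        self.convs = []
        c_prev = 1
        for c in channels:
            self.convs.append(_Conv3x3(c_prev, c, rng))
            c_prev = c
        self.relus = [_ReLU() for _ in channels]
        self.pools = [_MaxPool2() for _ in channels]
        # dense head: logits = features_gap @ w.T + b, w is (2, F)
        scale = np.sqrt(1.0 / c_prev)
        self.w = rng.normal(0.0, scale, size=(2, c_prev))
        self.b = np.zeros(2)

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, keep_features: bool = False):
        """x: (N, H, W) standardized images -> logits (N, 2)."""
        h = x[:, None, :, :]
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        if keep_features:
            self.features = h  # (N, F, h', w') pre-GAP maps
        self._feat_shape = h.shape
        gap = h.mean(axis=(2, 3))  # (N, F)
        self._gap_in = h
        self._gap = gap
        return gap @ self.w.T + self.b

    def backward(self, dlogits: np.ndarray):
        self.dw = dlogits.T @ self._gap
        self.db = dlogits.sum(axis=0)
        dgap = dlogits @ self.w  # (N, F)
        n, f, hh, ww = self._feat_shape
        dh = np.broadcast_to(
            dgap[:, :, None, None] / (hh * ww), self._feat_shape
        ).copy()
        for conv, relu, pool in zip(
            reversed(self.convs), reversed(self.relus), reversed(self.pools)
        ):
            dh = conv.backward(relu.backward(pool.backward(dh)))
        return dh

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self):
        out = []
        for i, conv in enumerate(self.convs):
            out.append((f"conv{i}.W", conv, "W", "dW"))
            out.append((f"conv{i}.b", conv, "b", "db"))
        out.append(("head.w", self, "w", "dw"))
        out.append(("head.b", self, "b", "db"))
        return out

    def state_dict(self) -> dict:
        state = {"input_size": self.input_size, "channels": np.array(self.channels)}
        for name, obj, attr, _ in self.parameters():
            state[name] = getattr(obj, attr)
        return state

    @classmethod
    def from_state(cls, state: dict) -> "SmallConvNet":
        net = cls(
            input_size=int(state["input_size"]),
            channels=tuple(int(c) for c in state["channels"]),
        )
        for name, obj, attr, _ in net.parameters():
            setattr(obj, attr, np.array(state[name]))
        return net

    # ---- inference ----------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-image standardization then batched forward pass.

        images: (N, H, W) raw frames; returns (N, 2) class probabilities
        ordered [before, after].
        """
        images = np.asarray(images, dtype=np.float64)
        out = []
        for i in range(0, len(images), batch_size):
            batch = standardize(images[i : i + batch_size])
            out.append(softmax(self.forward(batch)))
        return np.concatenate(out) if out else np.empty((0, 2))


def standardize(images: np.ndarray) -> np.ndarray:
    """Per-image zero-mean unit-variance normalization."""
    mu = images.mean(axis=(-2, -1), keepdims=True)
    sd = images.std(axis=(-2, -1), keepdims=True)
    return (images - mu) / np.where(sd > 0, sd, 1.0)


class SGD:
    def __init__(self, lr=0.05, momentum=0.9):
        self.lr, self.momentum = lr, momentum
        self.v = {}

    def step(self, params):
        for name, obj, attr, dattr in params:
            g = getattr(obj, dattr)
            v = self.v.get(name, 0.0)
            v = self.momentum * v - self.lr * g
            self.v[name] = v
            setattr(obj, attr, getattr(obj, attr) + v)


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params):
        self.t += 1
        for name, obj, attr, dattr in params:
            g = getattr(obj, dattr)
            m = self.m.get(name, 0.0) * self.b1 + (1 - self.b1) * g
            v = self.v.get(name, 0.0) * self.b2 + (1 - self.b2) * g * g
            self.m[name], self.v[name] = m, v
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            setattr(
                obj, attr, getattr(obj, attr) - self.lr * mh / (np.sqrt(vh) + self.eps)
            )


def _augment(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flips and 90-degree rotations (embryos have no canonical
    orientation)."""
    out = batch.copy()
    flip_h = rng.random(len(out)) < 0.5
    flip_v = rng.random(len(out)) < 0.5
    rot = rng.integers(0, 4, len(out))
    for i in range(len(out)):
        img = out[i]
        if flip_h[i]:
            img = img[:, ::-1]
        if flip_v[i]:
            img = img[::-1, :]
        out[i] = np.rot90(img, rot[i])
    return out


def train_network(
    net: SmallConvNet,
    images: np.ndarray,
    labels: np.ndarray,
    optimizer,
    epochs: int,
    batch_size: int = 32,
    augment: bool = True,
    seed: int = 0,
):
    """Cross-entropy training loop; returns the per-epoch mean loss."""
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n = len(images)
    rng = np.random.default_rng(seed)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            batch = images[idx]
            if augment:
                batch = _augment(batch, rng)
            batch = standardize(batch)
            y = labels[idx]
            logits = net.forward(batch)
            probs = softmax(logits)
            eps = 1e-12
            loss = -np.mean(np.log(probs[np.arange(len(y)), y] + eps))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged (loss={loss}); reduce the learning rate"
                )
            epoch_loss += loss * len(y)
            dlogits = probs.copy()
            dlogits[np.arange(len(y)), y] -= 1.0
            dlogits /= len(y)
            net.backward(dlogits)
            optimizer.step(net.parameters())
        losses.append(epoch_loss / n)
    return losses
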