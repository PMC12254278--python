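"""A compact convolutional network for binary classification of
trial-aligned calcium transients, implemented directly on numpy.

Architecture: two convolutional blocks (3x3 convolution with same padding,
batch normalization, ReLU, 2x2 max pooling), a fully connected layer with
two outputs, and a softmax readout.  Training uses stochastic gradient
descent with momentum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CalciumCNN"]


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patch matrix with same padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + h, dj:dj + w]
            cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, h * w)
            idx += 1
    return cols


def _col2im(cols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, idx * c:(idx + 1) * c, :
                                                   ].reshape(n, c, h, w)
            idx += 1
    return xp[:, :, p:p + h, p:p + w]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0, scale, (c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x)
        n, _, hw = self.cols.shape
        out = np.einsum("fk,nkp->nfp", self.w, self.cols) + self.b[None, :, None]
        return out.reshape(n, self.w.shape[0], x.shape[2], x.shape[3])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        d = dout.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,nkp->fk", d, self.cols) / n
        self.db = d.sum(axis=(0, 2)) / n
        dcols = np.einsum("fk,nfp->nkp", self.w, d)
        return _col2im(dcols, self.x_shape)

    def step(self, lr: float, momentum: float) -> None:
        self.vw = momentum * self.vw - lr * self.dw
        self.vb = momentum * self.vb - lr * self.db
        self.w += self.vw
        self.b += self.vb


class _BatchNorm:
    def __init__(self, c: int, eps: float = 1e-5, alpha: float = 0.1):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.vg = np.zeros(c)
        self.vb = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.eps = eps
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.alpha) * self.run_mean + self.alpha * mean
            self.run_var = (1 - self.alpha) * self.run_var + self.alpha * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)[None, :, None, None]
        self.xhat = (x - mean[None, :, None, None]) / self.std
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self.xhat).sum(axis=(0, 2, 3)) / dout.shape[0]
        self.dbeta = dout.sum(axis=(0, 2, 3)) / dout.shape[0]
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3), keepdims=True)
              ) / self.std
        return dx

    def step(self, lr: float, momentum: float) -> None:
        self.vg = momentum * self.vg - lr * self.dgamma
        self.vb = momentum * self.vb - lr * self.dbeta
        self.gamma += self.vg
        self.beta += self.vb


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self.in_shape = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self.arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self.arg[..., None], dout[..., None], axis=-1)
        dx_t = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self.in_shape, dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = dx_t.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self.x.T @ dout / dout.shape[0]
        self.db = dout.mean(axis=0)
        return dout @ self.w.T

    def step(self, lr: float, momentum: float) -> None:
        self.vw = momentum * self.vw - lr * self.dw
        self.vb = momentum * self.vb - lr * self.db
        self.w += self.vw
        self.b += self.vb


class CalciumCNN:
    """conv3x3(8)+BN+ReLU+pool2 -> conv3x3(16)+BN+ReLU+pool2 -> FC(2)."""

    def __init__(self, input_shape: tuple[int, int], seed: int = 0,
                 c1: int = 8, c2: int = 16):
        rng = np.random.default_rng(seed)
        h, w = input_shape
        self.conv1 = _Conv3x3(1, c1, rng)
        self.bn1 = _BatchNorm(c1)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv3x3(c1, c2, rng)
        self.bn2 = _BatchNorm(c2)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2()
        self.fc = _Dense(c2 * (h // 4) * (w // 4), 2, rng)
        self.rng = rng

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.pool1.forward(self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x), train)))
        h = self.pool2.forward(self.relu2.forward(
            self.bn2.forward(self.conv2.forward(h), train)))
        self.flat_shape = h.shape
        return self.fc.forward(h.reshape(h.shape[0], -1))

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits).reshape(self.flat_shape)
        d = self.conv2.backward(self.bn2.backward(
            self.relu2.backward(self.pool2.backward(d))))
        self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.pool1.backward(d))))

    def _step(self, lr: float, momentum: float) -> None:
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.fc):
            layer.step(lr, momentum)

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int = 100,
            lr: float = 0.01, momentum: float = 0.9,
            batch_size: int = 16) -> list[float]:
        """Train with SGD-momentum; returns the per-epoch training loss."""
        x = x[:, None, :, :] if x.ndim == 3 else x
        y = np.asarray(y, dtype=int)
        history = []
        n = x.shape[0]
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                if idx.size < 2:
                    continue      # batch norm needs more than one sample
                logits = self._forward(x[idx], train=True)
                p = self._softmax(logits)
                losses.append(float(-np.mean(
                    np.log(p[np.arange(idx.size), y[idx]] + 1e-12))))
                grad = p.copy()
                grad[np.arange(idx.size), y[idx]] -= 1.0
                self._backward(grad)
                self._step(lr, momentum)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = x[:, None, :, :] if x.ndim == 3 else x
        return self._softmax(self._forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)
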