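"""Minimal CNN engine for patch classification.

Implements exactly the layers the patch classifier needs — 3x3
convolutions (im2col + BLAS matmul), channel batch normalization, ReLU,
2x2 max pooling, dense layers, a logistic output head with binary
cross-entropy — together with Adam updates.  Everything is plain numpy and
fully deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

__all__ = ["PatchCNN"]


DTYPE = np.float32


def _im2col(xp: np.ndarray, k: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H+k-1, W+k-1) padded input -> (C*k*k, N*H*W) column matrix."""
    N, C, Hp, Wp = xp.shape
    H, W = Hp - k + 1, Wp - k + 1
    cols = np.empty((C, k * k, N, H, W), dtype=xp.dtype)
    xt = xp.transpose(1, 0, 2, 3)
    for i in range(k):
        for j in range(k):
            cols[:, i * k + j] = xt[:, :, i : i + H, j : j + W]
    return cols.reshape(C * k * k, N * H * W), (N, H, W)


class _Conv:
    def __init__(self, cin, cout, k, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k = k
        self.cin = cin
        self.params = [self.W, self.b]

    def forward(self, x):
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, _ = _im2col(xp, self.k)
        out = (self.W @ cols).reshape(-1, N, H, W).transpose(1, 0, 2, 3)
        self._cache = (cols, (N, C, H, W))
        return out + self.b[None, :, None, None]

    def backward(self, dy):
        cols, (N, C, H, W) = self._cache
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(-1, N * H * W)
        self.grads = [dyf @ cols.T, dy.sum(axis=(0, 2, 3))]
        dcols = (self.W.T @ dyf).reshape(C, self.k * self.k, N, H, W)
        p = self.k // 2
        dxp = np.zeros((C, N, H + 2 * p, W + 2 * p), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, i * self.k + j]
        return dxp[:, :, p : p + H, p : p + W].transpose(1, 0, 2, 3)


class _BatchNorm:
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads = [(dy * xhat).sum(axis=axes), dy.sum(axis=axes)]
        dxhat = dy * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=axes)[None, :, None, None]
            - xhat * (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        ) / std[None, :, None, None]
        return dx


class _ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Identity:
    params: list = []

    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class _MaxPool2:
    params: list = []

    def forward(self, x):
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : 2 * H2, : 2 * W2].reshape(N, C, H2, 2, W2, 2)
        flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._xshape
        H2, W2 = H // 2, W // 2
        dflat = np.zeros((N, C, H2, W2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        dx[:, :, : 2 * H2, : 2 * W2] = (
            dflat.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, 2 * H2, 2 * W2)
        )
        return dx


class _Dense:
    def __init__(self, nin, nout, rng):
        self.W = (rng.standard_normal((nout, nin)) * np.sqrt(2.0 / nin)).astype(DTYPE)
        self.b = np.zeros(nout, dtype=DTYPE)
        self.params = [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.grads = [dy.T @ self._x, dy.sum(axis=0)]
        return dy @ self.W


class PatchCNN:
    """Binary patch classifier: conv/BN/ReLU/pool blocks + dense head.

    Input patches are (C, H, W) shearlet coefficient windows; the output is
    a single edge/orientation probability through a logistic head.
    """

    def __init__(self, input_shape, conv_channels=(32, 64, 128, 256),
                 dense_units=1024, kernel_size=3, seed=0, pool_layers=(1, 3)):
        C, H, W = input_shape
        self.input_shape = tuple(input_shape)
        self.conv_channels = tuple(conv_channels)
        self.dense_units = int(dense_units)
        self.kernel_size = int(kernel_size)
        self.seed = int(seed)
        self.pool_layers = tuple(pool_layers)
        rng = np.random.default_rng(seed)
        self.blocks = []
        cin, h, w = C, H, W
        for bi, cout in enumerate(conv_channels):
            conv, bn = _Conv(cin, cout, kernel_size, rng), _BatchNorm(cout)
            pool = _MaxPool2() if bi in self.pool_layers else _Identity()
            self.blocks.append((conv, bn, _ReLU(), pool))
            cin = cout
            if bi in self.pool_layers:
                h, w = h // 2, w // 2
        self.flat_dim = cin * max(h, 1) * max(w, 1)
        self._final_side = max(h, 1)
        self.fc1 = _Dense(self.flat_dim, dense_units, rng)
        self.fc_relu = _ReLU()
        self.fc2 = _Dense(dense_units, 1, rng)
        self._adam_state = None

    # -- plumbing ---------------------------------------------------------
    def _layers(self):
        for conv, bn, relu, pool in self.blocks:
            yield conv
            yield bn
        yield self.fc1
        yield self.fc2

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x, train=False):
        h = np.asarray(x, dtype=DTYPE)
        for conv, bn, relu, pool in self.blocks:
            h = pool.forward(relu.forward(bn.forward(conv.forward(h), train)))
        h = h.reshape(h.shape[0], -1)
        h = self.fc_relu.forward(self.fc1.forward(h))
        return self.fc2.forward(h)[:, 0]

    def _backward(self, dlogits):
        dh = self.fc2.backward(dlogits[:, None])
        dh = self.fc1.backward(self.fc_relu.backward(dh))
        N = dh.shape[0]
        C = self.conv_channels[-1]
        side = self._final_side
        dh = dh.reshape(N, C, side, side)
        for conv, bn, relu, pool in reversed(self.blocks):
            dh = conv.backward(bn.backward(relu.backward(pool.backward(dh))))

    def predict_proba(self, x, batch_size=512):
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            z = self.forward_logits(x[i : i + batch_size], train=False)
            out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z))
        return out

    # -- training ---------------------------------------------------------
    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        layers = [l for l in self._layers()]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for l in layers for p in l.params],
                "v": [np.zeros_like(p) for l in layers for p in l.params],
            }
        st = self._adam_state
        st["t"] += 1
        i = 0
        for layer in layers:
            for p, g in zip(layer.params, layer.grads):
                if weight_decay and p.ndim >= 2:  # decay matrices, not biases/BN
                    p -= lr * weight_decay * p
                st["m"][i] = beta1 * st["m"][i] + (1 - beta1) * g
                st["v"][i] = beta2 * st["v"][i] + (1 - beta2) * g * g
                mhat = st["m"][i] / (1 - beta1 ** st["t"])
                vhat = st["v"][i] / (1 - beta2 ** st["t"])
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    def train_epoch(self, X, y, rng, lr=1e-3, batch_size=64, weight_decay=0.0):
        order = rng.permutation(len(X))
        total = 0.0
        for i in range(0, len(X), batch_size):
            idx = order[i : i + batch_size]
            xb, yb = X[idx], y[idx]
            z = self.forward_logits(xb, train=True)
            loss = np.mean(np.logaddexp(0.0, z) - yb * z)
            if not np.isfinite(loss):
                raise TrainingError("training diverged: non-finite loss")
            total += loss * len(idx)
            dz = (1.0 / (1.0 + np.exp(-z)) - yb) / len(idx)
            self._backward(dz)
            self._adam_step(lr, weight_decay=weight_decay)
        return total / len(X)

    # -- serialization ----------------------------------------------------
    def state_dict(self):
        state = {}
        for li, layer in enumerate(self._layers()):
            for pi, p in enumerate(layer.params):
                state[f"p_{li}_{pi}"] = p
        for li, (conv, bn, _, _) in enumerate(self.blocks):
            state[f"bn_mean_{li}"] = bn.running_mean
            state[f"bn_var_{li}"] = bn.running_var
        return state

    def load_state_dict(self, state):
        for li, layer in enumerate(self._layers()):
            for pi, p in enumerate(layer.params):
                p[...] = state[f"p_{li}_{pi}"]
        for li, (conv, bn, _, _) in enumerate(self.blocks):
            bn.running_mean[...] = state[f"bn_mean_{li}"]
            bn.running_var[...] = state[f"bn_var_{li}"]
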