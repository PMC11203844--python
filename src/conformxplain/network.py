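"""Minimal 1D convolutional network engine in numpy.

Layers expose explicit forward/backward passes and an epsilon-rule
relevance-propagation step (`relprop`), so the same object graph serves
training, gradient saliency, and layer-wise relevance propagation without a
deep-learning framework. Arrays are float32; sequence tensors have shape
(n, length, channels).
"""

from __future__ import annotations

import numpy as np

_EPS_FLOOR = 1e-12


def _stabilized(z, eps_scale):
    """z + eps * sign(z), with eps proportional to the mean |z|."""
    eps = max(eps_scale * float(np.abs(z).mean()), _EPS_FLOOR)
    return z + eps * np.where(z >= 0, 1.0, -1.0)


class Layer:
    trainable = False

    def params_and_grads(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def relprop(self, R, eps_scale):
        raise NotImplementedError(
            f"LRP rule not implemented for layer {type(self).__name__}")


class ElementwiseAffine(Layer):
    """Fixed per-feature affine map y = w * x + b (input standardization).

    Relevance passes through unchanged: the map is a per-feature monotone
    rescaling, so each feature keeps its share of the output relevance.
    """

    def __init__(self, w, b):
        self.w = np.asarray(w, dtype=np.float32)
        self.b = np.asarray(b, dtype=np.float32)

    def forward(self, x, training=False):
        self.x = x
        return self.w * x + self.b

    def backward(self, grad):
        return grad * self.w

    def relprop(self, R, eps_scale):
        return R


class Conv1D(Layer):
    """Valid-padding 1D convolution via im2col matrix multiplication."""

    trainable = True

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 use_bias=True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.use_bias = use_bias
        fan_in = kernel_size * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale,
                            size=(fan_in, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        pairs = [(self.W, self.dW)]
        if self.use_bias:
            pairs.append((self.b, self.db))
        return pairs

    def _im2col(self, x):
        n, L, C = x.shape
        k = self.kernel_size
        L_out = L - k + 1
        # windows: (n, L_out, C, k) view -> (n, L_out, k, C) copy
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
        return cols.reshape(n, L_out, k * C), L_out

    def forward(self, x, training=False):
        self.x_shape = x.shape
        cols, L_out = self._im2col(x)
        self.cols2 = cols.reshape(-1, cols.shape[-1])   # (n*L_out, k*C)
        z = self.cols2 @ self.W                          # flat GEMM
        self.z = z.reshape(x.shape[0], L_out, -1) + self.b
        return self.z

    def _col2im(self, dcols, dtype):
        n, L, C = self.x_shape
        k = self.kernel_size
        L_out = L - k + 1
        dcols = dcols.reshape(n, L_out, k, C)
        dx = np.zeros((n, L, C), dtype=dtype)
        for i in range(k):
            dx[:, i:i + L_out, :] += dcols[:, :, i, :]
        return dx

    def backward(self, grad):
        grad2 = grad.reshape(-1, grad.shape[-1])         # (n*L_out, F)
        self.dW[...] = self.cols2.T @ grad2
        self.db[...] = grad2.sum(axis=0)
        return self._col2im(grad2 @ self.W.T, grad.dtype)

    def relprop(self, R, eps_scale):
        s = (R / _stabilized(self.z, eps_scale)).reshape(-1, R.shape[-1])
        Rcols = self.cols2 * (s @ self.W.T)
        return self._col2im(Rcols, R.dtype)


class ReLU(Layer):
    def forward(self, x, training=False):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask

    def relprop(self, R, eps_scale):
        return R


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis.

    A trailing remainder shorter than the pool window is dropped. Relevance
    is routed winner-take-all to the argmax position of each window.
    """

    def __init__(self, pool_size):
        self.pool_size = pool_size

    def forward(self, x, training=False):
        n, L, C = x.shape
        p = self.pool_size
        L_out = L // p
        self.x_shape = x.shape
        xw = x[:, : L_out * p, :].reshape(n, L_out, p, C)
        self.argmax = xw.argmax(axis=2)          # (n, L_out, C)
        return xw.max(axis=2)

    def _scatter(self, values):
        n, L, C = self.x_shape
        p = self.pool_size
        L_out = L // p
        out = np.zeros((n, L_out, p, C), dtype=values.dtype)
        ni, li, ci = np.ogrid[:n, :L_out, :C]
        out[ni, li, self.argmax, ci] = values
        full = np.zeros((n, L, C), dtype=values.dtype)
        full[:, : L_out * p, :] = out.reshape(n, L_out * p, C)
        return full

    def backward(self, grad):
        return self._scatter(grad)

    def relprop(self, R, eps_scale):
        return self._scatter(R)


class Flatten(Layer):
    def forward(self, x, training=False):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)

    def relprop(self, R, eps_scale):
        return R.reshape(self.x_shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features, out_features, rng, use_bias=True):
        self.use_bias = use_bias
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale,
                            size=(in_features, out_features)).astype(
                                np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        pairs = [(self.W, self.dW)]
        if self.use_bias:
            pairs.append((self.b, self.db))
        return pairs

    def forward(self, x, training=False):
        self.x = x
        self.z = x @ self.W + self.b
        return self.z

    def backward(self, grad):
        self.dW[...] = self.x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def relprop(self, R, eps_scale):
        s = R / _stabilized(self.z, eps_scale)
        return self.x * (s @ self.W.T)


class Dropout(Layer):
    """Inverted dropout; identity at inference and for LRP."""

    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self.mask.astype(np.float32)

    def backward(self, grad):
        if self.mask is None:
            return grad
        return grad * self.mask.astype(np.float32)

    def relprop(self, R, eps_scale):
        return R


class SequentialNet:
    """A stack of layers ending in class logits."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_logits(self, x):
        return self.forward(x, training=False)

    def input_gradient(self, x, target_idx):
        """d logit[target] / d input, one row per sample."""
        logits = self.forward(x, training=False)
        grad = np.zeros_like(logits)
        grad[:, target_idx] = 1.0
        return self.backward(grad)

    def relprop(self, x, target_idx, eps_scale=1e-6):
        """Epsilon-rule LRP from the target logit down to the input.

        The softmax is excluded: relevance starts at the raw logit.
        """
        logits = self.forward(x, training=False)
        R = np.zeros_like(logits)
        R[:, target_idx] = logits[:, target_idx]
        for layer in reversed(self.layers):
            R = layer.relprop(R, eps_scale)
        return R, logits[:, target_idx]


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits, y_idx, sample_weights=None):
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    nll = -np.log(p[np.arange(n), y_idx] + eps)
    if sample_weights is None:
        sample_weights = np.ones(n, dtype=logits.dtype)
    loss = float((nll * sample_weights).mean())
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    grad *= (sample_weights / n)[:, None]
    return loss, grad.astype(logits.dtype)


class Adam:
    """Adam optimizer over (param, grad) pairs collected from the layers."""

    def __init__(self, net, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = [pg for layer in net.layers
                      for pg in layer.params_and_grads()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
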