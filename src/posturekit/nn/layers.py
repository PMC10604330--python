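"""NumPy sequence-model layers with manual backpropagation.

All layers operate on activations of shape ``(batch, time, features)``.
Each layer exposes ``forward(x, train)`` and ``backward(grad_out)``;
``backward`` accumulates parameter gradients (matching ``params``) and
returns the gradient with respect to the layer input.  Gradients are
exact (validated by finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid


class Layer:
    train_mode: bool = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map applied independently at every timestep."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        x2 = self._x.reshape(-1, self.W.shape[0])
        g2 = grad.reshape(-1, self.W.shape[1])
        self.gW += x2.T @ g2
        self.gb += g2.sum(axis=0)
        return grad @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=True):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class Dropout(Layer):
    """Inverted dropout: zero each activation with probability ``p``."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Per-feature normalization over the (batch x time) axis.

    Batch statistics in training, exponential running statistics at
    evaluation time.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, train=True):
        if train:
            flat = x.reshape(-1, x.shape[-1])
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat = self._xhat
        flatg = grad.reshape(-1, grad.shape[-1])
        flatx = xhat.reshape(-1, xhat.shape[-1])
        self.ggamma += (flatg * flatx).sum(axis=0)
        self.gbeta += flatg.sum(axis=0)
        if not self._train:
            return grad * (self.gamma * self._ivar)
        m = flatg.shape[0]
        dxhat = flatg * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=0)
            - flatx * (dxhat * flatx).mean(axis=0)
        ) * self._ivar
        return dx.reshape(grad.shape)


class LSTM(Layer):
    """Stacked LSTM; full backpropagation through time.

    Gate order in the packed weight matrices is (input, forget, output,
    cell candidate), so one sigmoid call covers the first three blocks.
    Forget-gate biases start at 1 so early training does not wash out
    the cell state.
    """

    def __init__(self, n_in: int, hidden: int, num_layers: int, rng: np.random.Generator):
        self.hidden = hidden
        self.num_layers = num_layers
        self.Wx, self.Wh, self.b = [], [], []
        for layer in range(num_layers):
            d = n_in if layer == 0 else hidden
            lim_x = np.sqrt(6.0 / (d + 4 * hidden))
            lim_h = np.sqrt(6.0 / (hidden + 4 * hidden))
            self.Wx.append(rng.uniform(-lim_x, lim_x, size=(d, 4 * hidden)))
            self.Wh.append(rng.uniform(-lim_h, lim_h, size=(hidden, 4 * hidden)))
            b = np.zeros(4 * hidden)
            b[hidden : 2 * hidden] = 1.0
            self.b.append(b)
        self.gWx = [np.zeros_like(w) for w in self.Wx]
        self.gWh = [np.zeros_like(w) for w in self.Wh]
        self.gb = [np.zeros_like(w) for w in self.b]

    def params(self):
        return [*self.Wx, *self.Wh, *self.b]

    def grads(self):
        return [*self.gWx, *self.gWh, *self.gb]

    def forward(self, x, train=True):
        H = self.hidden
        self._caches = []
        for layer in range(self.num_layers):
            N, T, _ = x.shape
            Wx, Wh, b = self.Wx[layer], self.Wh[layer], self.b[layer]
            pre = x @ Wx + b  # input contribution for all timesteps at once
            h = np.zeros((N, H))
            c = np.zeros((N, H))
            hs = np.empty((N, T, H))
            if train:
                gates = np.empty((N, T, 4 * H))
                cs = np.empty((N, T, H))
                tanh_cs = np.empty((N, T, H))
            for t in range(T):
                z = pre[:, t] + h @ Wh
                sig = _sigmoid(z[:, : 3 * H])
                i, f, o = sig[:, :H], sig[:, H : 2 * H], sig[:, 2 * H :]
                g = np.tanh(z[:, 3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                if train:
                    gates[:, t, : 3 * H] = sig
                    gates[:, t, 3 * H :] = g
                    cs[:, t] = c
                    tanh_cs[:, t] = tc
                h = o * tc
                c = c_new
                hs[:, t] = h
            if train:
                self._caches.append((x, gates, cs, tanh_cs, hs))
            x = hs
        return x

    def backward(self, grad):
        H = self.hidden
        for layer in range(self.num_layers - 1, -1, -1):
            x, gates, cs, tanh_cs, hs = self._caches[layer]
            N, T, _ = x.shape
            Wx, Wh = self.Wx[layer], self.Wh[layer]
            i = gates[..., :H]
            f = gates[..., H : 2 * H]
            o = gates[..., 2 * H : 3 * H]
            g = gates[..., 3 * H :]
            # elementwise backward factors, vectorized over all timesteps
            dh_to_dc = o * (1.0 - tanh_cs * tanh_cs)
            fi = g * i * (1.0 - i)
            ff = cs * f * (1.0 - f)
            fo = tanh_cs * o * (1.0 - o)
            fg = i * (1.0 - g * g)
            dz_all = np.empty((N, T, 4 * H))
            dh_next = np.zeros((N, H))
            dc_next = np.zeros((N, H))
            for t in range(T - 1, -1, -1):
                dh = grad[:, t] + dh_next
                dc = dh * dh_to_dc[:, t] + dc_next
                dz = dz_all[:, t]
                dz[:, :H] = dc * fi[:, t]
                dz[:, H : 2 * H] = dc * ff[:, t]
                dz[:, 2 * H : 3 * H] = dh * fo[:, t]
                dz[:, 3 * H :] = dc * fg[:, t]
                dh_next = dz @ Wh.T
                dc_next = dc * f[:, t]
            flat_dz = dz_all.reshape(-1, 4 * H)
            self.gWx[layer] += x.reshape(-1, x.shape[-1]).T @ flat_dz
            # h_{t-1} inputs to the recurrence: hs shifted right by one step
            self.gWh[layer] += hs[:, : T - 1].reshape(-1, H).T @ dz_all[:, 1:].reshape(-1, 4 * H)
            self.gb[layer] += flat_dz.sum(axis=0)
            grad = dz_all @ Wx.T
        return grad


class Softmax(Layer):
    """Row-wise softmax over the class axis (the last axis)."""

    def forward(self, x, train=True):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


class Sequential:
    """A layer pipeline sharing one RNG for stochastic layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
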