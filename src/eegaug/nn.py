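"""Layers, initialisation and Adam, built on :mod:`eegaug.autodiff`.

Weights are float32 by default and initialised from N(0, 0.02) as is
conventional for convolutional GANs; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_INIT_STD = 0.02


class Module:
    """Container with named parameters; submodules are discovered via attributes."""

    def parameters(self):
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{k}", v) for k, v in val.parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{k}", v) for k, v in item.parameters())
        return out

    def param_tensors(self):
        return [p for _, p in self.parameters()]

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.parameters()}

    def load_state_dict(self, state):
        for k, v in self.parameters():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k!r}: "
                                 f"{state[k].shape} vs {v.data.shape}")
            v.data[...] = state[k]

    def checksum(self):
        return float(sum(np.abs(v.data).sum() for _, v in self.parameters()))


def _init(rng, shape, std):
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in, n_out, rng, std=DEFAULT_INIT_STD):
        self.w = _init(rng, (n_in, n_out), std)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return x @ self.w + self.b


class Conv2d(Module):
    """Strided 2-D convolution via im2col."""

    def __init__(self, c_in, c_out, k, stride, pad, rng, std=DEFAULT_INIT_STD):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.w = _init(rng, (c_out, c_in * k * k), std)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        N, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = ad.im2col(x, k, k, s, s, p, p)          # (CKK, N*L)
        out = (self.w @ cols).reshape((self.c_out, N, Ho, Wo))
        out = ad.transpose(out, (1, 0, 2, 3))
        return out + self.b.reshape((1, self.c_out, 1, 1))


class ConvTranspose2d(Module):
    """Transposed convolution (adjoint of Conv2d) via col2im."""

    def __init__(self, c_in, c_out, k, stride, pad, rng, std=DEFAULT_INIT_STD):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.w = _init(rng, (c_in, c_out * k * k), std)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        N, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"ConvTranspose2d expected {self.c_in} channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        Ho = (H - 1) * s - 2 * p + k
        Wo = (W - 1) * s - 2 * p + k
        xf = ad.transpose(x, (1, 0, 2, 3)).reshape((C, N * H * W))
        cols = ad.transpose(self.w, (1, 0)) @ xf        # (c_out*k*k, N*H*W)
        out = ad.col2im(cols, N, (self.c_out, Ho, Wo), k, k, s, s, p, p)
        return out + self.b.reshape((1, self.c_out, 1, 1))


class LayerNorm(Module):
    """Normalises each sample over all non-batch axes; per-channel affine."""

    def __init__(self, n_channels, eps=1e-5):
        self.eps = eps
        self.g = Tensor(np.ones(n_channels, dtype=np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(n_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        shape = [1] * x.ndim
        shape[1] = -1
        return xn * self.g.reshape(tuple(shape)) + self.b.reshape(tuple(shape))


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        if len(grads) != len(self.params):
            raise ValueError("gradient/parameter count mismatch")
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits):
    m = Tensor(logits.data.max(axis=-1, keepdims=True))
    e = ad.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean negative log-likelihood; ``labels`` is an int vector."""
    m = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - m
    lse = ad.log(ad.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels)]
    return -picked.mean()
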