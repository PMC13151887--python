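"""Minimal neural-network primitives on top of HIPS autograd.

Parameters are plain (nested) dicts of numpy arrays; autograd differentiates
straight through them. This keeps the denoiser, property transformer and critic
dependency-light while still giving exact reverse-mode gradients for the PPO
and diffusion losses.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd import grad as agrad
from autograd.misc import flatten


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, scale, size=(n_in, n_out))


def linear_params(rng, n_in, n_out) -> dict:
    return {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}


def linear(p: dict, x):
    return anp.dot(x, p["W"]) + p["b"]


def mlp_params(rng, sizes) -> list:
    return [linear_params(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]


def mlp(params: list, x, act=anp.tanh):
    for p in params[:-1]:
        x = act(linear(p, x))
    return linear(params[-1], x)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def layer_norm(p: dict, x, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.var(x, axis=-1, keepdims=True)
    return p["g"] * (x - mu) / anp.sqrt(var + eps) + p["b"]


def layer_norm_params(dim: int) -> dict:
    return {"g": np.ones(dim), "b": np.zeros(dim)}


def sinusoidal_embedding(value: float, dim: int):
    """Interleaved sin/cos positional encoding of a scalar over `dim` slots.

    PE[2i] = sin(v / 10000^(2i/d)), PE[2i+1] = cos(v / 10000^(2i/d)).
    """
    if dim % 2 != 0:
        raise ValueError("encoding dimension must be even")
    i = anp.arange(dim // 2)
    freq = 1.0 / (10000.0 ** (2.0 * i / dim))
    ang = value * freq
    return anp.stack([anp.sin(ang), anp.cos(ang)], axis=-1).reshape(-1)


def global_norm_clip(flat_grad: np.ndarray, max_norm: float) -> np.ndarray:
    norm = np.linalg.norm(flat_grad)
    if norm > max_norm and norm > 0:
        return flat_grad * (max_norm / norm)
    return flat_grad


class Adam:
    """Adam on a flattened parameter tree with global gradient-norm clipping."""

    def __init__(self, params, lr: float, grad_clip: float = 0.5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        flat, self.unflatten = flatten(params)
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0
        self.lr = lr
        self.grad_clip = grad_clip
        self.b1, self.b2 = betas
        self.eps = eps

    def step(self, params, grads):
        flat_p, _ = flatten(params)
        flat_g, _ = flatten(grads)
        flat_g = global_norm_clip(np.nan_to_num(flat_g), self.grad_clip)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * flat_g
        self.v = self.b2 * self.v + (1 - self.b2) * flat_g**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        flat_p = flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return self.unflatten(flat_p)


def value_and_grad(fn):
    """(value, grad) of a scalar function of a parameter tree."""
    g = agrad(fn)

    def wrapped(params, *args):
        return fn(params, *args), g(params, *args)

    return wrapped
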