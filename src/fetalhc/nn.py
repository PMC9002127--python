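"""Neural-network layers and the SGD optimizer on top of the autodiff engine.

Conventions follow the usual framework layout: NCHW activations,
He-initialized convolutions, batch normalization with running statistics
for deterministic evaluation, and a momentum SGD optimizer.  The
multi-head self-attention block operates on the flattened spatial grid
with factorized learnable 2-D positional embeddings added to the
attention logits (a content + position scheme), and is shape-preserving
so it can replace a spatial convolution anywhere.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax, upsample2x

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "MHSA",
    "Sequential",
    "SGD",
    "upsample2x",
    "concat",
]


class Module:
    """Base class: parameter collection, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_modules(self, prefix: str = "") -> list[tuple[str, "Module"]]:
        out = [(prefix, self)]
        for k, v in self.__dict__.items():
            name = f"{prefix}.{k}" if prefix else k
            if isinstance(v, Module):
                out.extend(v.named_modules(name))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_modules(f"{name}[{i}]"))
        return out

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus buffers, in a stable order."""
        arrays: list[np.ndarray] = []
        for _, m in self.named_modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    arrays.append(v.data)
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(arrays):
            raise ValueError(f"state mismatch: model has {len(targets)} arrays, file has {len(arrays)}")
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, pad: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0, scale, (out_ch, in_ch, k, k)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(1.0 / in_f)
        self.weight = Tensor(rng.normal(0, scale, (in_f, out_f)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MHSA(Module):
    """Multi-head self-attention over the spatial grid of an NCHW map.

    Queries/keys/values come from 1x1 convolutions; factorized relative
    2-D positional embeddings (one vector per row and per column) are
    added to the content logits before the softmax.  Output has the same
    shape as the input, so the block is a drop-in replacement for a
    spatial convolution.
    """

    def __init__(self, ch: int, heads: int = 4, max_hw: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if ch % heads:
            raise ValueError("channels must divide evenly among heads")
        rng = rng or np.random.default_rng(0)
        self.heads = heads
        self.dk = ch // heads
        self.q = Conv2d(ch, ch, 1, bias=False, rng=rng)
        self.k = Conv2d(ch, ch, 1, bias=False, rng=rng)
        self.v = Conv2d(ch, ch, 1, bias=False, rng=rng)
        scale = 1.0 / math.sqrt(self.dk)
        self.pos_h = Tensor(rng.normal(0, scale, (max_hw, self.dk)).astype(np.float32), requires_grad=True)
        self.pos_w = Tensor(rng.normal(0, scale, (max_hw, self.dk)).astype(np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hw = h * w

        def split_heads(t: Tensor) -> Tensor:
            # (N, C, H, W) -> (N, heads, HW, dk)
            return t.reshape(n, self.heads, self.dk, hw).transpose(0, 1, 3, 2)

        q = split_heads(self.q(x))
        k = split_heads(self.k(x))
        v = split_heads(self.v(x))
        # positional embedding r(y, x) = pos_h[y] + pos_w[x], flattened to (HW, dk)
        r = (self.pos_h[:h].reshape(h, 1, self.dk) + self.pos_w[:w].reshape(1, w, self.dk)).reshape(hw, self.dk)
        logits = (q @ k.transpose(0, 1, 3, 2) + q @ r.transpose(1, 0)) * (1.0 / math.sqrt(self.dk))
        attn = softmax(logits, axis=-1)
        out = attn @ v  # (N, heads, HW, dk)
        return out.transpose(0, 1, 3, 2).reshape(n, c, h, w)


class Sequential(Module):
    def __init__(self, *blocks: Module):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class Adam:
    """Adam optimizer (diagonal adaptive moments), with optional grad clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, clip_norm: float | None = 50.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            norm = math.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 0.005, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            norm = math.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad * scale if scale != 1.0 else p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
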