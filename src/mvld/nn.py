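"""Transformer building blocks and the AdamW optimizer.

All modules are pre-norm transformers.  Attention layers return their
post-softmax attention probabilities alongside the output so that callers can
record them for distillation and for attention-guided masking.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, embedding, gelu, layer_norm, softmax


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02,
                 dtype=np.float32) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations, by resampling."""
    x = rng.standard_normal(shape, dtype=np.float32).astype(dtype) * std
    bound = 2.0 * std
    bad = np.abs(x) > bound
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()), dtype=np.float32).astype(dtype) * std
        bad = np.abs(x) > bound
    return x


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters ignore the no_grad context at creation


class Module:
    """Lightweight module container with recursive parameter discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def set_trainable(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag

    def state_dict(self) -> dict:
        return {name: p.data for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out), dtype=dtype))
        self.bias = Parameter(np.zeros(d_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32):
        self.weight = Parameter(np.ones(dim, dtype=dtype))
        self.bias = Parameter(np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias)


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Parameter(trunc_normal(rng, (num, dim), dtype=dtype))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; returns (output, attention probabilities)."""

    def __init__(self, dim: int, num_heads: int, rng, dtype=np.float32):
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.q = Linear(dim, dim, rng, dtype)
        self.k = Linear(dim, dim, rng, dtype)
        self.v = Linear(dim, dim, rng, dtype)
        self.out = Linear(dim, dim, rng, dtype)

    def _split(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor):
        B, Tq, _ = x_q.shape
        q = self._split(self.q(x_q))
        k = self._split(self.k(x_kv))
        v = self._split(self.v(x_kv))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)          # (B, h, Tq, Tk)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Tq, self.num_heads * self.head_dim)
        return self.out(ctx), attn


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng, dtype=np.float32):
        self.fc1 = Linear(dim, hidden, rng, dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-norm self-attention block."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float, rng, dtype=np.float32):
        self.norm1 = LayerNorm(dim, dtype)
        self.attn = MultiHeadAttention(dim, num_heads, rng, dtype)
        self.norm2 = LayerNorm(dim, dtype)
        self.mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng, dtype)

    def __call__(self, x: Tensor):
        h = self.norm1(x)
        a_out, attn = self.attn(h, h)
        x = x + a_out
        x = x + self.mlp(self.norm2(x))
        return x, attn


class CoAttentionBlock(Module):
    """One fusion layer: each stream runs self-attention, cross-attention to
    the other stream, and an MLP (all pre-norm)."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float, rng, dtype=np.float32):
        self.img_norm1 = LayerNorm(dim, dtype)
        self.img_self = MultiHeadAttention(dim, num_heads, rng, dtype)
        self.img_norm2 = LayerNorm(dim, dtype)
        self.img_cross = MultiHeadAttention(dim, num_heads, rng, dtype)
        self.img_norm3 = LayerNorm(dim, dtype)
        self.img_mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng, dtype)
        self.txt_norm1 = LayerNorm(dim, dtype)
        self.txt_self = MultiHeadAttention(dim, num_heads, rng, dtype)
        self.txt_norm2 = LayerNorm(dim, dtype)
        self.txt_cross = MultiHeadAttention(dim, num_heads, rng, dtype)
        self.txt_norm3 = LayerNorm(dim, dtype)
        self.txt_mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng, dtype)

    def __call__(self, img: Tensor, txt: Tensor):
        hi = self.img_norm1(img)
        ht = self.txt_norm1(txt)
        si_out, si = self.img_self(hi, hi)
        st_out, st = self.txt_self(ht, ht)
        img = img + si_out
        txt = txt + st_out
        hi = self.img_norm2(img)
        ht = self.txt_norm2(txt)
        ci_out, ci = self.img_cross(hi, ht)   # image queries, text keys
        ct_out, ct = self.txt_cross(ht, hi)   # text queries, image keys
        img = img + ci_out
        txt = txt + ct_out
        img = img + self.img_mlp(self.img_norm3(img))
        txt = txt + self.txt_mlp(self.txt_norm3(txt))
        records = {"image_self": si, "text_self": st,
                   "image_to_text": ci, "text_to_image": ct}
        return img, txt, records


class AdamW:
    """Decoupled weight decay Adam.  ``lr`` may be reassigned between steps."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m.{i}"] = m
            out[f"v.{i}"] = v
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m.{i}"]).copy()
            self.v[i] = np.asarray(state[f"v.{i}"]).copy()


def linear_warmup_decay(step: int, max_steps: int, base_lr: float,
                        warmup_frac: float) -> float:
    """Linear warm-up then linear decay to zero (step is 0-based)."""
    warmup = max(int(round(warmup_frac * max_steps)), 0)
    if warmup > 0 and step < warmup:
        return base_lr * (step + 1) / warmup
    if max_steps == warmup:
        return base_lr
    frac = (step - warmup) / max(max_steps - warmup, 1)
    return base_lr * max(0.0, 1.0 - frac)
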