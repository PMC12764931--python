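"""Neural building blocks: linear maps, embeddings, transformer blocks.

Modules hold named :class:`~spectradti.nn.autodiff.Tensor` parameters and can
snapshot/restore their values, which is what the first-order episodic
meta-learning loop uses to adapt a clone and roll back.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MLP",
    "MultiHeadAttention",
    "TransformerBlock",
    "sinusoidal_positions",
]


class Module:
    """Base class with recursive named-parameter bookkeeping."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{key}.{i}"] = v
        super().__setattr__(key, value)

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.parameters(prefix=f"{prefix}{name}."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    # -- state management (checkpointing / meta-learning inner loops) --------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        for k, v in state.items():
            params[k].data = v.astype(np.float32).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, 0.02, size=(n, d)).astype(np.float32), requires_grad=True)

    def __call__(self, index: np.ndarray) -> Tensor:
        return self.W.gather_rows(index)


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta


class MLP(Module):
    """Feed-forward stack with ReLU between layers and optional dropout."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                if self.dropout > 0 and rng is not None:
                    x = x.dropout(self.dropout, rng, self.training)
        return x


class MultiHeadAttention(Module):
    """Scaled dot-product attention over (batch, tokens, d) with optional
    additive logit bias (batch, tokens_q, tokens_k) and key padding mask."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        super().__init__()
        assert d % heads == 0, "hidden size must divide heads"
        self.d, self.heads, self.d_k = d, heads, d // heads
        self.Wq = Linear(d, d, rng, bias=False)
        self.Wk = Linear(d, d, rng, bias=False)
        self.Wv = Linear(d, d, rng, bias=False)
        self.Wo = Linear(d, d, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.d_k).swapaxes(1, 2)  # (b, h, t, d_k)

    def __call__(
        self,
        q: Tensor,
        k: Tensor,
        v: Tensor,
        bias: Tensor | None = None,
        key_mask: np.ndarray | None = None,
    ) -> Tensor:
        b, tq, _ = q.shape
        qh, kh, vh = self._split(self.Wq(q)), self._split(self.Wk(k)), self._split(self.Wv(v))
        logits = (qh @ kh.T) * (1.0 / math.sqrt(self.d_k))  # (b, h, tq, tk)
        if bias is not None:
            logits = logits + bias.reshape(b, 1, bias.shape[1], bias.shape[2]) * (
                1.0 / math.sqrt(self.d_k)
            )
        mask = None
        if key_mask is not None:
            mask = np.broadcast_to(key_mask[:, None, None, :], logits.shape)
        att = logits.softmax(axis=-1, mask=mask)
        out = (att @ vh).swapaxes(1, 2).reshape(b, tq, self.d)
        return self.Wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer block: attention + position-wise feed-forward."""

    def __init__(self, d: int, heads: int, ffn: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d, heads, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ffn, rng)
        self.ff2 = Linear(ffn, d, rng)
        self.dropout = dropout

    def __call__(
        self,
        x: Tensor,
        bias: Tensor | None = None,
        key_mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = self.norm1(x)
        a = self.attn(h, h, h, bias=bias, key_mask=key_mask)
        if rng is not None:
            a = a.dropout(self.dropout, rng, self.training)
        x = x + a
        h = self.norm2(x)
        f = self.ff2(self.ff1(h).relu())
        if rng is not None:
            f = f.dropout(self.dropout, rng, self.training)
        return x + f


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Standard fixed sinusoidal position encodings, shape (n, d)."""
    pos = np.arange(n, dtype=np.float32)[:, None]
    i = np.arange(d, dtype=np.float32)[None, :]
    angle = pos / np.power(10000.0, (2.0 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)
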