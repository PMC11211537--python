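"""Layer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d, instance_norm

__all__ = [
    "Module",
    "Conv3d",
    "InstanceNorm3d",
    "Linear",
    "MultiHeadSelfAttention3d",
]


class Module:
    """Base class: recursive parameter collection and train/eval state."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            items = value if isinstance(value, (list, tuple)) else [value]
            wrap = isinstance(value, (list, tuple))
            for i, item in enumerate(items):
                key = f"{name}.{i}" if wrap else name
                if isinstance(item, Tensor) and item.requires_grad:
                    state[key] = item.data.copy()
                elif isinstance(item, Module):
                    for sub, arr in item.state_dict().items():
                        state[f"{key}.{sub}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._named_parameters()
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch for keys: {sorted(missing)}")
        for key, param in own.items():
            arr = np.asarray(state[key])
            if arr.shape != param.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {param.data.shape}")
            param.data = arr.astype(param.data.dtype)

    def _named_parameters(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            items = value if isinstance(value, (list, tuple)) else [value]
            wrap = isinstance(value, (list, tuple))
            for i, item in enumerate(items):
                key = f"{name}.{i}" if wrap else name
                if isinstance(item, Tensor) and item.requires_grad:
                    named[key] = item
                elif isinstance(item, Module):
                    for sub, p in item._named_parameters().items():
                        named[f"{key}.{sub}"] = p
        return named

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Module):
    """Stride-1 "same" 3D convolution; odd kernels only."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = cin * kernel ** 3
        self.weight = Tensor(_he_init(rng, (cout, cin, kernel, kernel, kernel), fan_in, dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Per-case, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Tensor(_he_init(rng, (cin, cout), cin, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MultiHeadSelfAttention3d(Module):
    """Multi-head self-attention over the voxels of a 3D feature map.

    Content and position terms share the query: per head the attention
    logits are (q kᵀ + q posᵀ) / sqrt(d_head), softmaxed over key
    positions and applied to v; head outputs are concatenated and mixed
    by a final linear layer.  The position encoding is factorised as a
    sum of learned per-axis embeddings, so parameters grow with D+H+W
    rather than D·H·W.
    """

    def __init__(self, channels: int, grid: tuple[int, int, int], heads: int,
                 rng: np.random.Generator, dtype=np.float32):
        if channels % heads:
            raise ValueError(f"channel count {channels} not divisible by {heads} heads")
        self.heads = heads
        self.channels = channels
        self.grid = tuple(grid)
        self.wq = Linear(channels, channels, rng, dtype)
        self.wk = Linear(channels, channels, rng, dtype)
        self.wv = Linear(channels, channels, rng, dtype)
        self.wo = Linear(channels, channels, rng, dtype)
        scale = 1.0 / np.sqrt(channels)
        d, h, w = self.grid
        self.pos_d = Tensor((rng.standard_normal((d, 1, 1, channels)) * scale).astype(dtype),
                            requires_grad=True)
        self.pos_h = Tensor((rng.standard_normal((1, h, 1, channels)) * scale).astype(dtype),
                            requires_grad=True)
        self.pos_w = Tensor((rng.standard_normal((1, 1, w, channels)) * scale).astype(dtype),
                            requires_grad=True)

    def position_encoding(self) -> Tensor:
        d, h, w = self.grid
        return (self.pos_d + self.pos_h + self.pos_w).reshape(d * h * w, self.channels)

    def attend(self, x: Tensor, pos: Tensor) -> Tensor:
        """Attention on a sequence: x (N, L, C), pos (L, C)."""
        n, length, c = x.shape
        hd = c // self.heads
        q = self.wq(x).reshape(n, length, self.heads, hd).transpose(0, 2, 1, 3)
        k = self.wk(x).reshape(n, length, self.heads, hd).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(n, length, self.heads, hd).transpose(0, 2, 1, 3)
        p = pos.reshape(1, length, self.heads, hd).transpose(0, 2, 3, 1)  # (1, H, hd, L)
        kt = k.transpose(0, 1, 3, 2)
        logits = (q @ kt + q @ p) * (1.0 / np.sqrt(hd))
        attn = logits.softmax(axis=-1)
        z = attn @ v  # (N, H, L, hd)
        z = z.transpose(0, 2, 1, 3).reshape(n, length, c)
        return self.wo(z)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, D, H, W) with (D, H, W) == grid."""
        n, c, d, h, w = x.shape
        if (d, h, w) != self.grid:
            raise ValueError(f"feature grid {(d, h, w)} does not match attention grid {self.grid}")
        seq = x.reshape(n, c, d * h * w).transpose(0, 2, 1)
        out = self.attend(seq, self.position_encoding())
        return out.transpose(0, 2, 1).reshape(n, c, d, h, w)
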