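"""Neural-network layers built on the autograd tensor.

Conventions follow the common deep-learning layout: images are (N, C, H, W),
token sequences are (N, T, D).  Every layer is a :class:`Module`; parameters
are tensors with ``requires_grad=True`` registered by attribute assignment.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Dropout",
    "Activation",
    "GlobalAvgPool2d",
    "MLP",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "conv2d",
    "ACTIVATIONS",
]


ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "gelu": lambda t: t.gelu(),
    "swish": lambda t: t.swish(),
    "sigmoid": lambda t: t.sigmoid(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, oh: int, ow: int):
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of (N, C, H, W) input with (F, C, kh, kw) kernels."""
    xp = x.pad2d(padding)
    f, c, kh, kw = weight.shape
    cols, oh, ow = _im2col(xp.data, kh, kw, stride)
    n = cols.shape[0]
    w2 = weight.data.reshape(f, -1)
    out_data = np.einsum("fk,nko->nfo", w2, cols).reshape(n, f, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, f, 1, 1)

    parents = (xp, weight) if bias is None else (xp, weight, bias)

    def backward(g):
        g2 = g.reshape(n, f, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("nfo,nko->fk", g2, cols).reshape(weight.shape)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gcols = np.einsum("fk,nfo->nko", w2, g2)
            xp._accumulate(_col2im(gcols, xp.shape, kh, kw, stride, oh, ow))

    return x._make(out_data, parents, backward)


class Module:
    """Base class: tracks sub-modules and parameters, train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        # dedupe by identity: shared sub-modules (e.g. one backbone serving
        # both views) must contribute each parameter once
        out: list[Tensor] = []
        seen: set[int] = set()
        for p in self._params.values():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        for m in self._modules.values():
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in params.items():
            v.data[...] = state[k]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        # He-style fan-in init; bias zero
        self.weight = _param(rng, (in_features, out_features), np.sqrt(2.0 / in_features))
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel), np.sqrt(2.0 / fan_in))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Activation(Module):
    def __init__(self, name: str):
        super().__init__()
        if name not in ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}")
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        return ACTIVATIONS[self.name](x)


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class MLP(Module):
    """Fully connected stack with a shared activation between layers."""

    def __init__(self, in_features: int, widths: list[int], rng: np.random.Generator,
                 activation: str = "relu", final_activation: bool = True):
        super().__init__()
        if not widths:
            raise ValueError("widths must be non-empty")
        layers: list[Module] = []
        prev = in_features
        for i, w in enumerate(widths):
            layers.append(Linear(prev, w, rng))
            if final_activation or i < len(widths) - 1:
                layers.append(Activation(activation))
            prev = w
        self.net = Sequential(*layers)
        self.out_features = widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(z: Tensor) -> Tensor:  # (N,T,D) -> (N,H,T,hd)
            return z.reshape(n, t, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block: LN -> MHSA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, dropout: float,
                 rng: np.random.Generator, activation: str = "gelu"):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(dim)
        self.ff = Sequential(
            Linear(dim, hidden, rng), Activation(activation), Linear(hidden, dim, rng)
        )
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x)))
        x = x + self.drop2(self.ff(self.norm2(x)))
        return x
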