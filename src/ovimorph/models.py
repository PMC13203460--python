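"""The three image-tabular fusion architectures and their building blocks.

All three families share one input contract — a dorsal image, a lateral
image, and a tabular record (body condition score + size category) — and one
output contract: four unconstrained regression outputs (live weight, carcass
weight, fat mass, lean mass, kg).  That swappability is what the ablation
harness relies on.

Families
--------
``baseline_concat``
    Per-view convolutional backbone, global-average-pooled features of the
    two views channel-concatenated with an MLP encoding of the tabular
    record, then a fully connected head (feature-level fusion).
``attention_fusion``
    The backbone is extended with CBAM blocks (sequential channel then
    spatial gating) after each stage; the final feature map's spatial
    positions act as visual tokens and the tabular encoding is the *query*
    of a single-query cross-modal attention over them.
``token_fusion``
    Both views are cut into non-overlapping patches, linearly projected to
    tokens (plus positional and view-role embeddings), a dedicated tabular
    token is prepended, and the joint sequence runs through a transformer
    encoder; the tabular token's terminal state feeds the head.

The published capacities (ResNet18 / EfficientNet-B3 / ViT-Base at 224 px)
are available as named presets, but every architecture is size-configurable
and the defaults are desk-scale (64 px, tiny widths).
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Activation,
    Conv2d,
    Dropout,
    LayerNorm,
    Linear,
    MLP,
    Module,
    Sequential,
    Tensor,
    TransformerEncoderLayer,
    concat,
)
from .synth import SIZE_CATEGORIES

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_SD",
    "BACKBONE_PRESETS",
    "encode_tabular_raw",
    "TabularEncoder",
    "CBAM",
    "cbam_attend",
    "ConvBackbone",
    "scaled_dot_attention",
    "CrossModalFusion",
    "patchify",
    "PatchEmbed",
    "BaselineConcatNet",
    "AttentionFusionNet",
    "TokenFusionNet",
    "build_net",
    "forward_multitarget",
]

TARGETS = ("live_weight", "carcass_weight", "fat_mass", "lean_mass")
N_TARGETS = 4

# standard ImageNet channel statistics, the conventional input normalization
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_SD = np.array([0.229, 0.224, 0.225])

# channel widths per stride-2 stage; "tiny" variants are the test/default
# scale, the named rows echo the published backbone capacities in spirit
BACKBONE_PRESETS = {
    "tiny_cnn": (8, 16, 32, 64),
    "tiny_cnn_small": (8, 16, 32),
    "resnet18_like": (64, 128, 256, 512),
    "efficientnet_b3_like": (40, 96, 232, 384),
}


def encode_tabular_raw(bcs: float, size_category: str) -> np.ndarray:
    """Raw tabular features: scaled BCS ((bcs-1)/4) + size one-hot (3)."""
    if size_category not in SIZE_CATEGORIES:
        raise ValueError(f"unknown size category {size_category!r}")
    if not 1.0 <= bcs <= 5.0:
        raise ValueError("bcs must lie in [1, 5]")
    onehot = np.zeros(3)
    onehot[SIZE_CATEGORIES.index(size_category)] = 1.0
    return np.concatenate([[(bcs - 1.0) / 4.0], onehot])


class TabularEncoder(Module):
    """MLP over the raw tabular encoding; output size = last width."""

    IN_FEATURES = 4

    def __init__(self, widths, rng, activation="relu"):
        super().__init__()
        self.mlp = MLP(self.IN_FEATURES, list(widths), rng, activation)
        self.out_features = self.mlp.out_features

    def forward(self, x: Tensor) -> Tensor:
        return self.mlp(x)


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel gate: a shared two-layer bottleneck scores the average- and
    max-pooled channel descriptors; their sum is squashed by a sigmoid.
    Spatial gate: a convolution over the channel-wise mean and max maps.
    Both gates lie in (0, 1), so the block can only rescale, never amplify.
    """

    def __init__(self, channels: int, rng, reduction: int = 4, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial_kernel = spatial_kernel
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        gate_c = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * gate_c.reshape(n, c, 1, 1)
        sp_avg = x.mean(axis=1, keepdims=True)
        sp_max = x.max(axis=1, keepdims=True)
        # replicate padding keeps the gate translation-symmetric at borders
        maps = _pad_replicate(concat([sp_avg, sp_max], axis=1), self.spatial_kernel // 2)
        gate_s = self.spatial_conv(maps).sigmoid()
        return x * gate_s


def _pad_replicate(x: Tensor, p: int) -> Tensor:
    if p == 0:
        return x
    rows = [x[:, :, :1, :]] * p + [x] + [x[:, :, -1:, :]] * p
    x = concat(rows, axis=2)
    cols = [x[:, :, :, :1]] * p + [x] + [x[:, :, :, -1:]] * p
    return concat(cols, axis=3)


def cbam_attend(fmap: Tensor | np.ndarray, block: CBAM) -> Tensor:
    """Apply a CBAM block to a (N, C, H, W) or (C, H, W) feature map."""
    t = fmap if isinstance(fmap, Tensor) else Tensor(np.asarray(fmap, dtype=float))
    if t.ndim == 3:
        return block(t.reshape(1, *t.shape)).reshape(*t.shape)
    return block(t)


class ConvBackbone(Module):
    """Stack of stride-2 conv stages, optionally CBAM-extended per stage.

    The final stage's feature map is exposed both pooled (as a vector) and
    unpooled (as spatial tokens / the Grad-CAM layer).
    """

    def __init__(self, widths, rng, activation="relu", use_cbam=False):
        super().__init__()
        blocks = []
        prev = 3
        for w in widths:
            stage = [Conv2d(prev, w, 3, rng, stride=2, padding=1), Activation(activation)]
            if use_cbam:
                stage.append(CBAM(w, rng))
            blocks.append(Sequential(*stage))
            prev = w
        self.blocks = blocks
        self.out_channels = widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


def scaled_dot_attention(query: Tensor, keys: Tensor, values: Tensor):
    """Single-query attention.  query (N, 1, d); keys/values (N, T, d).

    Returns the attended value (N, d) and the attention weights (N, T),
    which are non-negative and sum to one across tokens.
    """
    if keys.shape[1] == 0:
        raise ValueError("empty visual token set")
    d = query.shape[-1]
    scores = (query @ keys.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))  # (N,1,T)
    weights = scores.softmax(axis=-1)
    out = (weights @ values).reshape(query.shape[0], d)
    return out, weights.data.reshape(keys.shape[0], keys.shape[1])


class CrossModalFusion(Module):
    """Tabular features query the visual tokens (keys/values); the attended
    visual summary is concatenated with the tabular vector."""

    def __init__(self, tab_dim: int, vis_dim: int, attn_dim: int, rng):
        super().__init__()
        self.wq = Linear(tab_dim, attn_dim, rng)
        self.wk = Linear(vis_dim, attn_dim, rng)
        self.wv = Linear(vis_dim, attn_dim, rng)
        self.out_features = attn_dim + tab_dim

    def forward(self, tab_vec: Tensor, visual_tokens: Tensor) -> Tensor:
        q = self.wq(tab_vec).reshape(tab_vec.shape[0], 1, -1)
        k, v = self.wk(visual_tokens), self.wv(visual_tokens)
        fused, _ = scaled_dot_attention(q, k, v)
        return concat([fused, tab_vec], axis=-1)


def patchify(images: Tensor, patch_size: int) -> Tensor:
    """(N, 3, S, S) -> (N, (S/p)^2, 3 p^2) non-overlapping patches, row-major."""
    n, c, s, s2 = images.shape
    if s != s2 or s % patch_size:
        raise ValueError("image must be square and divisible by patch_size")
    g = s // patch_size
    x = images.reshape(n, c, g, patch_size, g, patch_size)
    x = x.transpose(0, 2, 4, 1, 3, 5)
    return x.reshape(n, g * g, c * patch_size * patch_size)


class PatchEmbed(Module):
    """Linear patch projection plus learned positional and view embeddings."""

    def __init__(self, image_size: int, patch_size: int, embed_dim: int, rng):
        super().__init__()
        if image_size % patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        self.patch_size = patch_size
        self.n_patches = (image_size // patch_size) ** 2
        self.proj = Linear(3 * patch_size**2, embed_dim, rng)
        self.pos = Tensor(rng.normal(0, 0.02, (self.n_patches, embed_dim)), requires_grad=True)
        self.view_embed = Tensor(rng.normal(0, 0.02, (embed_dim,)), requires_grad=True)

    def forward(self, images: Tensor) -> Tensor:
        tokens = self.proj(patchify(images, self.patch_size))
        return tokens + self.pos + self.view_embed


def _head(in_features: int, widths, rng, activation: str) -> Module:
    layers: list[Module] = []
    prev = in_features
    for w in widths:
        layers += [Linear(prev, w, rng), Activation(activation)]
        prev = w
    layers.append(Linear(prev, N_TARGETS, rng))
    return Sequential(*layers)


class BaselineConcatNet(Module):
    """Feature-level fusion baseline: backbone features + tabular MLP,
    concatenated, then a fully connected head."""

    family = "baseline_concat"

    def __init__(self, rng, backbone="tiny_cnn", tabular_widths=(16, 32, 16),
                 head_widths=(64,), dropout=0.1, activation="relu",
                 shared_backbone=True):
        super().__init__()
        widths = BACKBONE_PRESETS[backbone] if isinstance(backbone, str) else tuple(backbone)
        self.backbone_d = ConvBackbone(widths, rng, activation)
        self.backbone_l = self.backbone_d if shared_backbone else ConvBackbone(widths, rng, activation)
        self.tabular = TabularEncoder(tabular_widths, rng, activation)
        feat = 2 * self.backbone_d.out_channels + self.tabular.out_features
        self.drop = Dropout(dropout, rng)
        self.head = _head(feat, head_widths, rng, activation)

    def feature_maps(self, dorsal: Tensor, lateral: Tensor):
        return self.backbone_d(dorsal), self.backbone_l(lateral)

    def forward(self, dorsal: Tensor, lateral: Tensor, tabular: Tensor) -> Tensor:
        fd, fl = self.feature_maps(dorsal, lateral)
        vec = concat([fd.mean(axis=(2, 3)), fl.mean(axis=(2, 3)), self.tabular(tabular)], axis=-1)
        return self.head(self.drop(vec))


class AttentionFusionNet(Module):
    """CBAM-extended backbone with tabular-query cross-modal attention."""

    family = "attention_fusion"

    def __init__(self, rng, backbone="tiny_cnn", tabular_widths=(32, 64, 32),
                 head_widths=(64,), attn_dim=32, dropout=0.1, activation="swish",
                 shared_backbone=True):
        super().__init__()
        widths = BACKBONE_PRESETS[backbone] if isinstance(backbone, str) else tuple(backbone)
        self.backbone_d = ConvBackbone(widths, rng, activation, use_cbam=True)
        self.backbone_l = self.backbone_d if shared_backbone else ConvBackbone(widths, rng, activation, use_cbam=True)
        self.tabular = TabularEncoder(tabular_widths, rng, activation)
        self.fuse = CrossModalFusion(self.tabular.out_features, self.backbone_d.out_channels, attn_dim, rng)
        self.drop = Dropout(dropout, rng)
        self.head = _head(self.fuse.out_features, head_widths, rng, activation)

    def feature_maps(self, dorsal: Tensor, lateral: Tensor):
        return self.backbone_d(dorsal), self.backbone_l(lateral)

    def forward(self, dorsal: Tensor, lateral: Tensor, tabular: Tensor) -> Tensor:
        fd, fl = self.feature_maps(dorsal, lateral)
        tokens = concat([_spatial_tokens(fd), _spatial_tokens(fl)], axis=1)
        fused = self.fuse(self.tabular(tabular), tokens)
        return self.head(self.drop(fused))


def _spatial_tokens(fmap: Tensor) -> Tensor:
    n, c, h, w = fmap.shape
    return fmap.reshape(n, c, h * w).transpose(0, 2, 1)


class TokenFusionNet(Module):
    """Transformer with token-level fusion: patch tokens of both views plus
    one tabular token in a single self-attention sequence; the tabular
    token's final state is read out by the regression head."""

    family = "token_fusion"

    def __init__(self, rng, image_size=64, patch_size=8, embed_dim=64, n_heads=4,
                 n_layers=2, mlp_ratio=2.0, tabular_widths=(64, 128, 64),
                 dropout=0.1, activation="gelu", fusion_mode="token"):
        super().__init__()
        if fusion_mode not in ("token", "concat"):
            raise ValueError(f"unknown fusion_mode {fusion_mode!r}")
        self.fusion_mode = fusion_mode
        self.embed_d = PatchEmbed(image_size, patch_size, embed_dim, rng)
        self.embed_l = PatchEmbed(image_size, patch_size, embed_dim, rng)
        self.tabular = TabularEncoder(tabular_widths, rng, activation)
        self.tab_proj = Linear(self.tabular.out_features, embed_dim, rng)
        self.tab_pos = Tensor(rng.normal(0, 0.02, (embed_dim,)), requires_grad=True)
        if fusion_mode == "concat":
            # plain learnable readout token so the ablation differs from the
            # full model in the fusion mechanism only
            self.cls = Tensor(rng.normal(0, 0.02, (embed_dim,)), requires_grad=True)
        self.encoder = Sequential(
            *[TransformerEncoderLayer(embed_dim, n_heads, mlp_ratio, dropout, rng, activation)
              for _ in range(n_layers)]
        )
        self.norm = LayerNorm(embed_dim)
        head_in = embed_dim if fusion_mode == "token" else 2 * embed_dim
        self.head = Linear(head_in, N_TARGETS, rng)

    def tokenize(self, dorsal: Tensor, lateral: Tensor, tabular: Tensor) -> Tensor:
        n = dorsal.shape[0]
        tab_token = (self.tab_proj(self.tabular(tabular)) + self.tab_pos).reshape(n, 1, -1)
        return concat([tab_token, self.embed_d(dorsal), self.embed_l(lateral)], axis=1)

    def forward_tokens(self, tokens: Tensor) -> Tensor:
        encoded = self.encoder(tokens)
        return self.head(self.norm(encoded[:, 0]))

    def forward(self, dorsal: Tensor, lateral: Tensor, tabular: Tensor) -> Tensor:
        if self.fusion_mode == "token":
            return self.forward_tokens(self.tokenize(dorsal, lateral, tabular))
        # ablation path: transformer over image tokens plus a plain readout
        # token; the tabular embedding joins only afterwards, by feature
        # concatenation, so self-attention never sees the covariates
        n = dorsal.shape[0]
        cls = (self.cls + Tensor(np.zeros((n, 1, self.cls.shape[0]))))
        tokens = concat([cls, self.embed_d(dorsal), self.embed_l(lateral)], axis=1)
        pooled = self.norm(self.encoder(tokens)[:, 0])
        tab = self.tab_proj(self.tabular(tabular))
        return self.head(concat([pooled, tab], axis=-1))


_FAMILIES = {
    "baseline_concat": BaselineConcatNet,
    "attention_fusion": AttentionFusionNet,
    "token_fusion": TokenFusionNet,
}


def build_net(family: str, rng: np.random.Generator, **kwargs) -> Module:
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    return _FAMILIES[family](rng, **kwargs)


def forward_multitarget(net: Module, dorsal, lateral, tabular) -> np.ndarray:
    """Run a network over numpy inputs and return the (N, 4) predictions."""
    net.eval()
    out = net(Tensor(np.asarray(dorsal, dtype=float)),
              Tensor(np.asarray(lateral, dtype=float)),
              Tensor(np.asarray(tabular, dtype=float)))
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("non-finite model output")
    return out.data
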