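"""Grad-CAM adapted to regression outputs, with heatmap overlays.

For a chosen regression target, the gradient of that output with respect to
a convolutional feature map is spatially averaged into per-channel weights;
the rectified weighted channel sum, normalized by its maximum (an all-zero
map stays zero rather than dividing by zero) and bilinearly upsampled to the
input resolution, is the attribution map.  Only the convolutional families
expose feature maps; transformer attention rollout is deliberately out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor
from .models import AttentionFusionNet, BaselineConcatNet

__all__ = ["Heatmap", "grad_cam", "grad_cam_estimator", "overlay_heatmap", "heatmap_to_csv"]


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    target_index: int
    layer_id: str
    view: str


def _cam_from_grads(fmap: np.ndarray, grads: np.ndarray, out_size: int) -> np.ndarray:
    # channel weights = spatial mean of d(output)/d(feature map)
    weights = grads.mean(axis=(1, 2))
    raw = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    zoom = out_size / raw.shape[0]
    up = ndimage.zoom(raw, zoom, order=1, grid_mode=True, mode="nearest")
    return np.clip(up, 0.0, 1.0)


def grad_cam(net, dorsal: np.ndarray, lateral: np.ndarray, tabular: np.ndarray,
             target_index: int, view: str = "dorsal") -> Heatmap:
    """Attribution map of one regression output over one view's final
    convolutional feature map.

    `net` must be a conv-family network (baseline or attention fusion);
    inputs are single samples (3, H, W) and (4,).
    """
    if not isinstance(net, (BaselineConcatNet, AttentionFusionNet)):
        raise TypeError("Grad-CAM requires a convolutional model family")
    if not 0 <= target_index <= 3:
        raise ValueError("target_index must be in 0..3")
    if view not in ("dorsal", "lateral"):
        raise ValueError(f"unknown view {view!r}")
    net.eval()
    d = Tensor(np.asarray(dorsal, dtype=float)[None])
    l = Tensor(np.asarray(lateral, dtype=float)[None])
    t = Tensor(np.asarray(tabular, dtype=float)[None])

    fd, fl = net.feature_maps(d, l)
    fmap = fd if view == "dorsal" else fl
    fmap.requires_grad = True  # retain the gradient at this interior node
    if fmap.ndim != 4 or fmap.shape[2] < 1:
        raise ValueError("chosen layer has no spatial extent")

    # finish the forward pass from the captured feature maps
    from .nn import concat
    from .models import _spatial_tokens

    if isinstance(net, BaselineConcatNet):
        vec = concat([fd.mean(axis=(2, 3)), fl.mean(axis=(2, 3)), net.tabular(t)], axis=-1)
        out = net.head(vec)
    else:
        tokens = concat([_spatial_tokens(fd), _spatial_tokens(fl)], axis=1)
        out = net.head(net.fuse(net.tabular(t), tokens))

    out.backward(np.eye(1, 4, target_index))
    grads = fmap.grad[0] if fmap.grad is not None else np.zeros(fmap.shape[1:])
    size = dorsal.shape[-1]
    values = _cam_from_grads(fmap.data[0], grads, size)
    return Heatmap(values=values, target_index=target_index,
                   layer_id="final_conv", view=view)


def grad_cam_estimator(estimator, dataset, index: int, target_index: int,
                       view: str = "dorsal") -> Heatmap:
    """Grad-CAM for one sample of an :class:`ArrayDataset` through a fitted
    conv-family estimator."""
    return grad_cam(estimator.nets_[0], dataset.dorsal[index],
                    dataset.lateral[index], dataset.tabular[index],
                    target_index, view)


def _blue_red(values: np.ndarray) -> np.ndarray:
    """Simple blue (low) -> red (high) colormap, (H, W) -> (H, W, 3)."""
    v = np.clip(values, 0.0, 1.0)
    r = np.clip(2.0 * v - 0.5, 0.0, 1.0)
    g = 1.0 - np.abs(2.0 * v - 1.0)
    b = np.clip(1.5 - 2.0 * v, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def overlay_heatmap(hm: Heatmap, pixels: np.ndarray, alpha: float) -> np.ndarray:
    """Blend the colour-mapped heatmap over an (H, W, 3) image at weight
    alpha; alpha 0 returns the image, alpha 1 the pure colormap."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if hm.values.shape != pixels.shape[:2]:
        raise ValueError("heatmap and image shapes differ")
    return (1.0 - alpha) * pixels + alpha * _blue_red(hm.values)


def heatmap_to_csv(hm: Heatmap, path) -> None:
    np.savetxt(path, hm.values, delimiter=",", fmt="%.6f")
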