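"""Grad-CAM attention maps for the fine-tuned classifier.

Gradient-weighted class activation mapping: the positive-class logit is
backpropagated to a chosen spatial layer of the encoder, the gradients
are averaged over space to give one weight per channel, and the
rectified weighted sum of the feature maps — upsampled to the input
size and max-normalized — highlights the image regions driving the
prediction. Used here to check that a trained classifier attends to the
lesion rather than to background texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .models import ClassifierModel
from .training import standardize_image

__all__ = ["CAMMap", "grad_cam", "default_target_layer", "render_overlay",
           "lesion_focus_ratio"]


class LayerError(ValueError):
    """The chosen layer does not produce spatial feature maps."""


@dataclass
class CAMMap:
    """Normalized class-activation heatmap at input resolution."""

    heatmap: np.ndarray  # (H, W) floats in [0, 1]
    target_layer: int
    predicted_class: int
    score: float


def default_target_layer(model: ClassifierModel) -> int:
    """Index of the last ReLU following a convolution in the encoder —
    the standard Grad-CAM target (last spatial block)."""
    layers = model.encoder.layers
    for idx in range(len(layers) - 1, -1, -1):
        if isinstance(layers[idx], nn.ReLU):
            return idx
    raise LayerError("encoder has no ReLU-terminated convolutional block")


def grad_cam(model: ClassifierModel, image: np.ndarray,
             layer: int | None = None, standardize: bool = True) -> CAMMap:
    """Grad-CAM heatmap of the positive-class logit for one image.

    Channel weights are the spatial means of the logit's gradient with
    respect to the target layer's feature maps; the CAM is the rectified
    weighted sum, bilinearly upsampled to the input size and min-max
    normalized (an all-zero CAM stays all-zero). Deterministic given
    fixed weights.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D grayscale image")
    if standardize:
        image = standardize_image(image)
    layer_idx = default_target_layer(model) if layer is None else int(layer)

    logit = model.forward(image[None], keep_activations=True)
    acts = model.encoder.activations[layer_idx + 1]  # activations[0] is the input
    if acts.ndim != 4:
        raise LayerError(f"layer {layer_idx} output has no spatial extent")
    score = float(nn.sigmoid(logit)[0])

    for p in model.params():
        p.grad[...] = 0.0
    dlogit = np.ones(1)
    dfeat = model.head.backward(dlogit[:, None])
    dacts = model.encoder.backward(dfeat, stop_at=layer_idx)

    weights = dacts[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    cam = resize(cam, image.shape, order=1, mode="edge", anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CAMMap(heatmap=cam, target_layer=layer_idx,
                  predicted_class=int(score >= 0.5), score=score)


def lesion_focus_ratio(cam: CAMMap, lesion_mask: np.ndarray) -> float:
    """Mean CAM value inside the lesion mask divided by the mean outside;
    > 1 means attention concentrates on the lesion."""
    mask = np.asarray(lesion_mask, dtype=bool)
    inside = cam.heatmap[mask].mean() if mask.any() else np.nan
    outside = cam.heatmap[~mask].mean() if (~mask).any() else np.nan
    return float(inside / (outside + 1e-12))


def render_overlay(image: np.ndarray, cam: CAMMap, out_path,
                   raw_path=None, alpha: float = 0.45) -> None:
    """Write an 8-bit PNG overlay (red = high attention, blue = low) and
    optionally the raw heatmap values as CSV."""
    import imageio.v3 as iio
    from matplotlib import colormaps

    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    heat = colormaps["jet"](cam.heatmap)[..., :3]
    overlay = (1 - alpha) * gray[..., None] + alpha * heat
    iio.imwrite(out_path, (np.clip(overlay, 0, 1) * 255).astype(np.uint8))
    if raw_path is not None:
        np.savetxt(raw_path, cam.heatmap, fmt="%.6f", delimiter=",")
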