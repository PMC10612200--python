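"""Grad-CAM saliency maps for the CNN models.

Channel importances are the spatial means of the gradient of the
poor-responder logit (pre-sigmoid) with respect to the chosen layer's
activations; the map is the ReLU of the importance-weighted activation
sum, bilinearly upsampled to 80 x 80 and max-normalized (an all-zero map
stays all-zero).  Any spatial layer — convolution, pooling or SE-block
output — can be targeted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .io_formats import AlignmentError, MultiSequencePatch, PATCH_SIZE
from .models import ShallowCnn


class LayerTypeError(ValueError):
    """Grad-CAM requested on a non-spatial layer."""


@dataclass
class Heatmap:
    values: np.ndarray  # (80, 80) in [0, 1]
    source_layer: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"heatmap must be {PATCH_SIZE} x {PATCH_SIZE}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


def grad_cam(model: ShallowCnn, patch: MultiSequencePatch | np.ndarray, layer_id: str) -> Heatmap:
    """Compute the Grad-CAM heatmap of ``layer_id`` for one patch."""
    x = patch.channels if isinstance(patch, MultiSequencePatch) else np.asarray(patch)
    pid = patch.patient_id if isinstance(patch, MultiSequencePatch) else ""
    model.net.layer(layer_id)  # raises KeyError for unknown layers
    conv1 = model.net.layer("conv1")
    skip_state, conv1.skip_input_grad = conv1.skip_input_grad, False
    try:
        model.logits(x[None], train=False, cache=True)
        act = model.net.activations[layer_id]
        if act.ndim != 4:
            raise LayerTypeError(f"layer {layer_id!r} is not spatial (shape {act.shape})")
        model.net.backward(np.ones((1, 1)), cache=True)
        grad = model.net.activation_grads[layer_id]
    finally:
        conv1.skip_input_grad = skip_state

    weights = grad[0].mean(axis=(1, 2))  # channel importances
    cam = np.maximum((weights[:, None, None] * act[0]).sum(axis=0), 0.0)
    cam = resize(cam, (PATCH_SIZE, PATCH_SIZE), order=1, mode="edge", anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, source_layer=layer_id, patient_id=pid)


def overlay(
    heatmap: Heatmap,
    patch: MultiSequencePatch | np.ndarray,
    channel: int = 0,
    alpha: float = 0.4,
    path: str | Path | None = None,
) -> np.ndarray:
    """Alpha-blend a jet-colored heatmap over one grayscale channel.

    Zero-activation pixels keep the base image (the blend weight scales
    with the heatmap value).  Returns an (80, 80, 3) float RGB image in
    [0, 1] and optionally writes it as a PNG.
    """
    from matplotlib import cm

    x = patch.channels if isinstance(patch, MultiSequencePatch) else np.asarray(patch)
    base = x[channel]
    if base.shape != heatmap.values.shape:
        raise AlignmentError(f"heatmap {heatmap.values.shape} vs patch {base.shape}")
    lo, hi = base.min(), base.max()
    gray = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
    rgb_base = np.stack([gray] * 3, axis=-1)
    rgb_heat = cm.jet(heatmap.values)[..., :3]
    w = (alpha * heatmap.values)[..., None]
    out = (1 - w) * rgb_base + w * rgb_heat
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(str(path), (np.clip(out, 0, 1) * 255).astype(np.uint8))
    return out


def heatmap_to_csv(heatmap: Heatmap, path: str | Path) -> None:
    np.savetxt(path, heatmap.values, delimiter=",", fmt="%.6f")
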