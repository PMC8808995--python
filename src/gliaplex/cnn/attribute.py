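"""Attribution maps for the profile-image CNN.

Three standard pixel-attribution methods, all computed from the network's
own gradients: saliency (absolute input gradient of the class logit),
integrated gradients over a zero baseline, and Grad-CAM on the fourth
convolutional layer.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import zoom as nd_zoom

from .model import GlialCNN

__all__ = ["saliency", "integrated_gradients", "grad_cam", "attribution_maps"]


def saliency(model: GlialCNN, image: np.ndarray, class_idx: int) -> np.ndarray:
    """|∂logit[class]/∂pixel| per channel, shape (C, H, W)."""
    grad = model.input_gradient(image[None], class_idx)
    return np.abs(grad[0])


def integrated_gradients(
    model: GlialCNN, image: np.ndarray, class_idx: int, steps: int = 50, baseline=None
) -> np.ndarray:
    """Integrated gradients from a baseline (default zeros) to the image.

    Midpoint Riemann sum over ``steps`` points, so the completeness
    identity attribution_sum ≈ logit(x) − logit(baseline) holds to within
    the quadrature error.
    """
    x = np.asarray(image, float)
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    alphas = (np.arange(steps) + 0.5) / steps
    batch = base[None] + alphas[:, None, None, None] * (x - base)[None]
    grads = model.input_gradient(batch, class_idx)
    return (x - base) * grads.mean(axis=0)


def grad_cam(model: GlialCNN, image: np.ndarray, class_idx: int, out_size: int = 64) -> np.ndarray:
    """Grad-CAM on the 4th conv layer's ReLU activations, upsampled to out_size².

    Channel weights are the spatial means of the gradients; the weighted
    activation sum is rectified, so the map is non-negative.
    """
    relu4 = model.conv4_index + 1  # activation after the 4th conv's ReLU
    _, captured = model.input_gradient(image[None], class_idx, capture_layer=relu4)
    acts, grads = captured  # (1, C, h, w) each
    weights = grads[0].mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    if cam.shape != (out_size, out_size):
        cam = nd_zoom(cam, (out_size / cam.shape[0], out_size / cam.shape[1]), order=1)
        cam = np.maximum(cam, 0.0)
    return cam


def attribution_maps(model: GlialCNN, image: np.ndarray, class_idx: int, ig_steps: int = 50) -> dict:
    """All three attribution maps for one (C, 64, 64) image."""
    return {
        "saliency": saliency(model, image, class_idx),
        "integrated_gradients": integrated_gradients(model, image, class_idx, steps=ig_steps),
        "grad_cam": grad_cam(model, image, class_idx, out_size=image.shape[-1]),
    }
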