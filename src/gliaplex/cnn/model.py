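"""The profile-image classifier: architecture, forward pass, preprocessing.

Architecture: [conv3×3 → ReLU → maxpool2×2 → dropout] × 3, a fourth
conv3×3 → ReLU, flatten, three hidden dense layers with ReLU, and a final
dense layer whose softmax gives the class probabilities. Inputs are
multi-channel 64×64 crops standardized per channel per image.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as nd_zoom

from .layers import Conv2D, Dense, Dropout, Flatten, MaxPool2, ReLU

__all__ = ["CnnConfig", "GlialCNN", "prepare_image", "softmax"]


@dataclass(frozen=True)
class CnnConfig:
    """Hyperparameters of the profile-image CNN.

    Defaults are desk-scale: small channel widths trainable in minutes on
    one CPU core. ``patience`` is the early-stopping window in epochs.
    """

    conv_channels: tuple[int, int, int, int] = (8, 8, 16, 16)
    dropout: tuple[float, float, float] = (0.1, 0.1, 0.1)
    hidden: tuple[int, int, int] = (64, 32, 16)
    optimizer: str = "adam"
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 10
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_channels) != 4 or len(self.dropout) != 3 or len(self.hidden) != 3:
            raise ValueError("need 4 conv widths, 3 dropout probabilities, 3 hidden sizes")
        if any(c <= 0 for c in self.conv_channels) or any(h <= 0 for h in self.hidden):
            raise ValueError("sizes must be positive")
        if any(not (0 <= p < 1) for p in self.dropout):
            raise ValueError("dropout probabilities must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def prepare_image(crop: np.ndarray, size: int = 64) -> np.ndarray:
    """Interpolate a (C, H, W) crop to (C, size, size) and standardize.

    Bilinear interpolation per channel, then per-channel z-scoring within
    the image; a constant channel maps to all zeros.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 3:
        raise ValueError("crop must be (channels, height, width)")
    c, h, w = crop.shape
    if (h, w) != (size, size):
        out = np.empty((c, size, size))
        for i in range(c):
            out[i] = nd_zoom(crop[i], (size / h, size / w), order=1, grid_mode=True, mode="nearest")
    else:
        out = crop.copy()
    for i in range(c):
        sd = out[i].std()
        if sd < 1e-12:
            out[i] = 0.0
        else:
            out[i] = (out[i] - out[i].mean()) / sd
    return out


class GlialCNN:
    """Four-conv CNN over multi-channel profile crops, softmax over classes."""

    def __init__(self, config: CnnConfig, n_channels: int, n_classes: int = 2):
        self.config = config
        self.n_channels = n_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        c1, c2, c3, c4 = config.conv_channels
        side = config.input_size // 8  # three 2×2 pools
        self.layers = [
            Conv2D(n_channels, c1, rng=rng),
            ReLU(),
            MaxPool2(),
            Dropout(config.dropout[0]),
            Conv2D(c1, c2, rng=rng),
            ReLU(),
            MaxPool2(),
            Dropout(config.dropout[1]),
            Conv2D(c2, c3, rng=rng),
            ReLU(),
            MaxPool2(),
            Dropout(config.dropout[2]),
            Conv2D(c3, c4, rng=rng),
            ReLU(),
            Flatten(),
            Dense(c4 * side * side, config.hidden[0], rng=rng),
            ReLU(),
            Dense(config.hidden[0], config.hidden[1], rng=rng),
            ReLU(),
            Dense(config.hidden[1], config.hidden[2], rng=rng),
            ReLU(),
            Dense(config.hidden[2], n_classes, rng=rng),
        ]
        #: index of the 4th convolution, for Grad-CAM
        self.conv4_index = 12
        self._rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))

    # -- parameters --------------------------------------------------------
    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def state_dict(self):
        return [p.copy() for p in self.params]

    def load_state_dict(self, state):
        for p, s in zip(self.params, state):
            p[...] = s

    def clone(self) -> "GlialCNN":
        return copy.deepcopy(self)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N, C, 64, 64)."""
        out = np.asarray(x, float)
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=self._rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.vstack(chunks)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch + full backward pass."""
        logits = self.forward(x, train=True)
        p = softmax(logits)
        n = len(y)
        loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def input_gradient(self, x: np.ndarray, class_idx: int, capture_layer: int | None = None):
        """∂logit[class]/∂input for a batch (eval mode, no dropout).

        Optionally captures the activation of layer ``capture_layer`` and
        the gradient flowing into it (used by Grad-CAM).
        """
        outs = []
        out = np.asarray(x, float)
        for layer in self.layers:
            out = layer.forward(out, train=False, rng=self._rng)
            outs.append(out)
        dlogits = np.zeros_like(out)
        dlogits[:, class_idx] = 1.0
        grad = dlogits
        captured = None
        for i in range(len(self.layers) - 1, -1, -1):
            if capture_layer is not None and i == capture_layer:
                captured = (outs[capture_layer], grad.copy())
            grad = self.layers[i].backward(grad)
        return (grad, captured) if capture_layer is not None else grad
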