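"""Convolutional image encoders.

An encoder maps an image to two things the decoder needs:

* a grid of ``n`` per-location feature vectors (rows ``h_j``) used by the
  additive-attention block, taken from the last convolutional map, and
* a single penultimate feature vector that, after a dropout + dense(ReLU)
  projection, becomes the pooled global vector injected into the LSTM once
  at step t = -1.

Two backbones are provided.  ``"vgg16"`` has the classic 16-layer shape
(stacks of 3x3 convolutions and 2x max-poolings, two 4096-wide dense
layers; the classifier head is removed so the penultimate 1x4096 vector is
the output).  ``"toy"`` is a small stack of the same building blocks sized
for 64x64 synthetic images.  Both run on seeded random weights unless a
weight file is supplied; the convolutional stack is frozen — only the
projection head (and everything downstream) trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

VGG16_CHANNELS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
VGG16_INPUT = 224
VGG16_FC_WIDTH = 4096


@dataclass
class EncoderConfig:
    backbone: str = "toy"
    d_out: int = 256               # width of the pooled/projected features
    dropout_p: float = 0.5
    weights_path: str | None = None
    toy_channels: tuple[int, ...] = (8, 16, 32)
    input_size: int = 64           # toy backbone: side length the dense head expects
    seed: int = 0


@dataclass
class FeatureGrid:
    """Attention input: ``locations`` is n x d (rows h_j), ``pooled`` is 1 x d_out."""

    locations: np.ndarray
    pooled: np.ndarray
    grid_shape: tuple[int, int] = (0, 0)   # (Hf, Wf) for heat-map upsampling

    def __post_init__(self) -> None:
        if self.locations.ndim != 2 or self.locations.shape[0] < 1:
            raise ValueError("locations must be an n x d matrix with n >= 1")
        if not (np.isfinite(self.locations).all() and np.isfinite(self.pooled).all()):
            raise ValueError("non-finite feature values")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an H x W x C float array scaled to [0, 1].

    8-bit and 16-bit images are supported; greyscale stays single-channel.
    """
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return np.clip(arr, 0.0, 1.0)


def _conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution; x is H x W x Cin, w is 3 x 3 x Cin x Cout."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # H x W x Cin x 3 x 3
    return np.tensordot(win, w, axes=([3, 4, 2], [0, 1, 2]))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


def _he(rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float64) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Backbone:
    """A frozen convolutional feature extractor.

    Calling :meth:`forward` returns ``(spatial, penultimate)`` where
    ``spatial`` is the last convolutional map (Hf x Wf x Cf) and
    ``penultimate`` is the flat feature vector feeding the projection head.
    Deterministic at fixed weights.
    """

    name: str
    spatial_channels: int
    penultimate_width: int
    input_channels: int
    min_size: int

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class ToyBackbone(Backbone):
    """Reduced stack of 3x3 conv + ReLU + 2x max-pool blocks.

    The penultimate vector is the flattened final map, so no fully
    connected weights are needed and any input size that survives the
    pooling budget works.
    """

    name = "toy"
    input_channels = 1

    def __init__(self, channels: tuple[int, ...] = (8, 16, 32), seed: int = 0,
                 input_size: int = 64):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.min_size = 2 ** len(self.channels)
        self.weights = []
        cin = self.input_channels
        for cout in self.channels:
            self.weights.append(_he(rng, (3, 3, cin, cout)))
            cin = cout
        self.spatial_channels = cin
        side = input_size // self.min_size
        self.penultimate_width = side * side * cin

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = image
        if x.shape[2] != 1:
            x = x.mean(axis=2, keepdims=True)
        if min(x.shape[:2]) < self.min_size:
            raise ValueError(
                f"image {x.shape[:2]} smaller than the pooling budget "
                f"({len(self.channels)} halvings)"
            )
        for w in self.weights:
            x = _maxpool2(np.maximum(_conv2d_same(x, w), 0.0))
        return x, x.reshape(-1)


class Vgg16Backbone(Backbone):
    """The 16-layer shape: 13 convolutions in 5 pooled blocks, then two
    4096-wide dense layers; the classifier softmax is removed and the second
    dense activation is the 1x4096 penultimate vector.

    Inputs are resized to 224x224 and greyscale is replicated to 3 channels.
    Weights are seeded random (float32) unless loaded from ``weights_path``.
    """

    name = "vgg16"
    input_channels = 3
    min_size = VGG16_INPUT

    def __init__(self, seed: int = 0, weights_path: str | None = None):
        rng = np.random.default_rng(seed)
        self.conv_weights: list[np.ndarray] = []
        cin = 3
        for block in VGG16_CHANNELS:
            for cout in block:
                self.conv_weights.append(_he(rng, (3, 3, cin, cout), np.float32))
                cin = cout
        self.spatial_channels = cin
        side = VGG16_INPUT // 2 ** len(VGG16_CHANNELS)  # 7
        flat = side * side * cin                         # 25088
        self.fc1 = _he(rng, (flat, VGG16_FC_WIDTH), np.float32)
        self.fc2 = _he(rng, (VGG16_FC_WIDTH, VGG16_FC_WIDTH), np.float32)
        self.penultimate_width = VGG16_FC_WIDTH
        if weights_path is not None:
            self._load(weights_path)

    def _load(self, path: str) -> None:
        arrs = np.load(path)
        self.conv_weights = [arrs[f"conv{i}"] for i in range(len(self.conv_weights))]
        self.fc1, self.fc2 = arrs["fc1"], arrs["fc2"]

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from skimage.transform import resize

        x = image
        if x.shape[2] == 1:
            x = np.repeat(x, 3, axis=2)
        if x.shape[:2] != (VGG16_INPUT, VGG16_INPUT):
            x = resize(x, (VGG16_INPUT, VGG16_INPUT), anti_aliasing=True)
        x = x.astype(np.float32)
        k = 0
        for block in VGG16_CHANNELS:
            for _ in block:
                x = np.maximum(_conv2d_same(x, self.conv_weights[k]), 0.0)
                k += 1
            x = _maxpool2(x)
        spatial = x.astype(np.float64)
        h = np.maximum(x.reshape(-1) @ self.fc1, 0.0)
        pen = np.maximum(h @ self.fc2, 0.0)
        return spatial, pen.astype(np.float64)


def build_backbone(config: EncoderConfig) -> Backbone:
    """Instantiate the configured feature extractor."""
    if config.backbone == "toy":
        return ToyBackbone(channels=config.toy_channels, seed=config.seed,
                           input_size=config.input_size)
    if config.backbone == "vgg16":
        return Vgg16Backbone(seed=config.seed, weights_path=config.weights_path)
    raise ValueError(f"unknown backbone {config.backbone!r}")


def project_features(
    penultimate: np.ndarray,
    spatial: np.ndarray,
    w_pool: np.ndarray,
    b_pool: np.ndarray,
    w_loc: np.ndarray,
    dropout_p: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> FeatureGrid:
    """Project raw backbone outputs into the decoder's feature space.

    ``pooled = ReLU(dense(dropout(penultimate)))`` of width ``d_out``;
    ``locations`` is a per-location linear projection of the spatial map.
    Dropout (inverted scaling) is active only in training mode, so
    evaluation-mode output is deterministic.
    """
    if not 0 <= dropout_p < 1:
        raise ValueError("dropout_p must lie in [0, 1)")
    if not (np.isfinite(penultimate).all() and np.isfinite(spatial).all()):
        raise ValueError("non-finite encoder output")
    pen = penultimate
    if training and dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = rng.random(pen.shape) >= dropout_p
        pen = pen * mask / (1.0 - dropout_p)
    pooled = np.maximum(pen @ w_pool + b_pool, 0.0)
    hf, wf, cf = spatial.shape
    locations = spatial.reshape(hf * wf, cf) @ w_loc
    return FeatureGrid(locations=locations, pooled=pooled[None, :], grid_shape=(hf, wf))
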