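"""M-scan preprocessing and multi-scale feature extraction.

The detector consumes K spatially-averaged feature vectors per M-scan,
one per stage of a convolutional feature pyramid.  M-scans are first
resized from 10x674 to 64x224 with bicubic interpolation (stretching the
temporal axis so the sequence dimension carries weight comparable to
depth) and z-scored with the standard ImageNet channel statistics.

Two extractors implement the pluggable interface:

* :class:`RandomPyramidExtractor` — a seeded, randomly initialised
  9-stage conv pyramid that is fully deterministic and needs no
  downloads; this is the default for tests and experiments here.
* :func:`pretrained_extractor` — the ImageNet EfficientNet-B0 pathway,
  exposed as an optional capability that raises
  :class:`CapabilityError` when the required deep-learning runtime or
  weights are unavailable (it never silently falls back).
"""

from __future__ import annotations

import abc
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "PREPROCESS_SHAPE",
    "CapabilityError",
    "FeatureExtractor",
    "FlattenExtractor",
    "RandomPyramidExtractor",
    "make_test_extractor",
    "pretrained_extractor",
    "preprocess",
    "extract_features",
    "save_features",
    "load_features",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)
#: (height, width) of the preprocessed image: A-scan axis 10 -> 64, depth 674 -> 224
PREPROCESS_SHAPE = (64, 224)


class CapabilityError(RuntimeError):
    """An optional capability (e.g. pretrained weights) is unavailable."""


def preprocess(m: np.ndarray, out_shape: tuple[int, int] = PREPROCESS_SHAPE) -> np.ndarray:
    """Resize an M-scan and normalise it for the feature extractor.

    Intensities are mapped to [0, 1], the ``(T, P)`` array is resized to
    ``out_shape`` (height x width) with bicubic interpolation, the gray
    channel is replicated to 3 channels, and each channel is z-scored
    with the ImageNet statistics.  Returns a ``(3, H, W)`` float32 array.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D (T, P) M-scan, got shape {m.shape}")
    scaled = m / 255.0
    img = resize(scaled, out_shape, order=3, mode="edge", preserve_range=True,
                 anti_aliasing=None)
    chans = (img[None, :, :] - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
    return chans.astype(np.float32)


class FeatureExtractor(abc.ABC):
    """K-stage feature pyramid returning one spatially-averaged vector per stage."""

    #: number of feature stages
    K: int
    #: per-stage feature dimensionality
    dims: tuple[int, ...]
    #: architecture + weights provenance
    identifier: str
    #: whether :func:`preprocess` must be applied before :meth:`extract`
    expects_preprocessed: bool = True

    @abc.abstractmethod
    def extract(self, img: np.ndarray) -> list[np.ndarray]:
        """Return the K per-stage spatial-average feature vectors."""

    def extract_batch(self, imgs) -> list[np.ndarray]:
        """Extract features for a sequence of inputs.

        Returns K arrays, the k-th of shape ``(n, dims[k])``.
        """
        per_stage: list[list[np.ndarray]] = [[] for _ in range(self.K)]
        for img in imgs:
            fs = self.extract(img)
            for k in range(self.K):
                per_stage[k].append(fs[k])
        return [np.stack(v) for v in per_stage]


class FlattenExtractor(FeatureExtractor):
    """Identity 'extractor': a single stage holding the flattened raw M-scan.

    Plugging this into the MahaAD machinery yields the Raw-MahaAD
    baseline (K=1 Gaussian on the raw signal).
    """

    expects_preprocessed = False

    def __init__(self, n_pixels: int):
        self.K = 1
        self.dims = (int(n_pixels),)
        self.identifier = f"flatten-{n_pixels}"

    def extract(self, img: np.ndarray) -> list[np.ndarray]:
        v = np.asarray(img, dtype=np.float64).ravel()
        if v.size != self.dims[0]:
            raise ValueError(f"expected {self.dims[0]} pixels, got {v.size}")
        return [v]


def _conv2d(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution; x (C, H, W_), W (O, C, 3, 3)."""
    C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # windows: (C, H, Wd, 3, 3)
    return np.tensordot(W, windows, axes=([1, 2, 3], [0, 3, 4]))


class RandomPyramidExtractor(FeatureExtractor):
    """Seeded 9-stage random convolutional feature pyramid.

    Each stage is a 3x3 convolution (He-initialised from a fixed-seed
    PCG64 stream) followed by ReLU; the stage feature vector is the
    spatial mean of the activation map.  The first five stages are
    followed by 2x2 average pooling, shrinking 64x224 down to 2x7.
    Random multi-scale conv features are untrained but still separate
    in-distribution from corrupted scans well enough to exercise the
    full detection pipeline deterministically on any machine.
    """

    CHANNELS = (8, 12, 16, 24, 32, 40, 48, 56, 64)
    POOL_STAGES = frozenset(range(5))

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.K = len(self.CHANNELS)
        self.dims = tuple(self.CHANNELS)
        self.identifier = f"random-pyramid-9/seed={seed}"
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        c_in = 3
        for c_out in self.CHANNELS:
            fan_in = c_in * 9
            W = rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
            self.weights.append(W.astype(np.float32))
            c_in = c_out

    def weights_checksum(self) -> str:
        h = hashlib.sha256()
        for W in self.weights:
            h.update(W.tobytes())
        return h.hexdigest()

    def extract(self, img: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(img, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError(f"expected a (3, H, W) preprocessed image, got {x.shape}")
        out = []
        for k, W in enumerate(self.weights):
            x = np.maximum(_conv2d(x, W), 0.0)
            out.append(x.mean(axis=(1, 2)).astype(np.float64))
            if k in self.POOL_STAGES:
                h, w = x.shape[1] // 2 * 2, x.shape[2] // 2 * 2
                x = x[:, :h, :w].reshape(x.shape[0], h // 2, 2, w // 2, 2).mean(axis=(2, 4))
        return out


def make_test_extractor(seed: int = 0) -> RandomPyramidExtractor:
    """Build the seeded 9-stage random-pyramid extractor (no downloads)."""
    return RandomPyramidExtractor(seed)


def pretrained_extractor(name: str = "efficientnet_b0"):
    """ImageNet-pretrained backbone pathway (optional capability).

    Requires a deep-learning runtime with downloadable pretrained
    weights, which this installation does not provide; the call raises
    :class:`CapabilityError` rather than silently substituting another
    extractor.
    """
    raise CapabilityError(
        f"pretrained extractor {name!r} requires a deep-learning runtime with "
        "ImageNet weights, which is not available in this installation; "
        "use make_test_extractor() for a deterministic offline pyramid"
    )


def extract_features(img: np.ndarray, extractor: FeatureExtractor) -> list[np.ndarray]:
    """Spatially-averaged per-stage feature vectors of one input."""
    return extractor.extract(img)


def save_features(path: str | os.PathLike, features: list[np.ndarray],
                  ids: list[str] | None = None, identifier: str = "") -> None:
    """Cache per-stage feature matrices as .npz with a JSON sidecar."""
    features = [np.asarray(f) for f in features]
    np.savez(path, **{f"stage_{k}": f for k, f in enumerate(features)})
    sidecar = {
        "K": len(features),
        "dims": [int(f.shape[-1]) for f in features],
        "ids": ids,
        "extractor": identifier,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_features(path: str | os.PathLike) -> list[np.ndarray]:
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as z:
        return [z[f"stage_{k}"] for k in range(len(z.files))]
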