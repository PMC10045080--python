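"""Pooling primitives, the backbone adapter contract, and a pseudo-backbone.

Deep feature extraction is pluggable: any object with a ``name``, an
``output_dim`` and an ``extract(img) -> vector`` method can feed the
reduction/fusion stages.  Pretrained convolutional networks can be wrapped
behind this contract; the package ships a deterministic *pseudo-backbone*
— a fixed bank of seeded random convolution kernels with rectification,
max pooling and global average pooling followed by a seeded random
projection — so the full pipeline runs and is testable with no downloaded
weights.  Its features are random but reproducible and image-dependent,
which is all the downstream PCA/fusion/classifier stages require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from histofusion.types import FeatureMatrix, validate_rgb_image

DEFAULT_DEEP_DIM = 4096


@dataclass
class PoolingConfig:
    """Window size k, stride p, and mode (max or average)."""

    k: int = 2
    p: int = 2
    mode: str = "max"

    def __post_init__(self) -> None:
        if self.k < 1 or self.p < 1:
            raise ValueError("window size and stride must be >= 1")
        if self.mode not in ("max", "average"):
            raise ValueError("mode must be 'max' or 'average'")


def pool2d(feature_map: np.ndarray, cfg: PoolingConfig) -> np.ndarray:
    """Window max / mean over a 2-D map at stride ``p`` with no padding."""
    x = np.asarray(feature_map, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("pool2d expects a 2-D map")
    if x.shape[0] < cfg.k or x.shape[1] < cfg.k:
        raise ValueError("pooling window larger than the map")
    windows = sliding_window_view(x, (cfg.k, cfg.k))[:: cfg.p, :: cfg.p]
    if cfg.mode == "max":
        return windows.max(axis=(2, 3))
    return windows.mean(axis=(2, 3))


def global_average_pool(maps: np.ndarray) -> np.ndarray:
    """Spatial mean of each of C equally-shaped maps -> length-C vector."""
    x = np.asarray(maps, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] == 0 or x.shape[2] == 0:
        raise ValueError("expected a C x H x W stack of non-empty maps")
    return x.mean(axis=(1, 2))


class BackboneAdapter(Protocol):
    """Contract for deep feature extractors: deterministic, fixed output_dim."""

    name: str
    output_dim: int

    def extract(self, img: np.ndarray) -> np.ndarray: ...


def _conv_bank(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid-mode convolution of a C_in x H x W stack with K x C_in x kh x kw kernels.

    Implemented as one im2col matrix product per call so a full kernel bank
    costs a single GEMM.
    """
    c_in, h, w = x.shape
    k, _, kh, kw = kernels.shape
    windows = sliding_window_view(x, (kh, kw), axis=(1, 2))  # C_in, H', W', kh, kw
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(-1, c_in * kh * kw)
    out = cols @ kernels.reshape(k, -1).T
    return out.T.reshape(k, h - kh + 1, w - kw + 1)


@dataclass
class PseudoBackbone:
    """Deterministic stand-in feature extractor built from seeded random kernels.

    Two convolution + ReLU + max-pool stages over the RGB image, global
    average pooling of both stages' maps, then a fixed seeded random
    projection to ``output_dim``.  Identical (seed, output_dim) always
    yields identical kernels, so extraction is a pure function of the
    image.
    """

    seed: int = 7
    output_dim: int = DEFAULT_DEEP_DIM
    name: str = "pseudo"
    stage1_kernels: int = 24
    stage2_kernels: int = 32

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self._k1 = rng.standard_normal((self.stage1_kernels, 3, 5, 5)) / np.sqrt(75)
        self._k2 = rng.standard_normal(
            (self.stage2_kernels, self.stage1_kernels, 3, 3)
        ) / np.sqrt(9 * self.stage1_kernels)
        n_pooled = self.stage1_kernels + self.stage2_kernels
        self._proj = rng.standard_normal((n_pooled, self.output_dim)) / np.sqrt(n_pooled)

    def extract(self, img: np.ndarray) -> np.ndarray:
        img = validate_rgb_image(img)
        x = img.astype(np.float64).transpose(2, 0, 1) / 255.0
        pool = PoolingConfig(k=2, p=2, mode="max")
        s1 = np.maximum(0.0, _conv_bank(x, self._k1))
        s1p = np.stack([pool2d(m, pool) for m in s1])
        s2 = np.maximum(0.0, _conv_bank(s1p, self._k2))
        s2p = np.stack([pool2d(m, pool) for m in s2])
        gap = np.concatenate([global_average_pool(s1p), global_average_pool(s2p)])
        return gap @ self._proj


def deep_feature_matrix(manifest, adapter: BackboneAdapter,
                        image_loader=None) -> FeatureMatrix:
    """Apply a backbone adapter to every manifest image, rows in manifest order.

    ``image_loader`` maps an image path to an RGB array; by default images
    are read from disk with Pillow.  An unreadable image aborts with the
    offending path identified.
    """
    if image_loader is None:
        from histofusion.synthetic import load_image as image_loader  # noqa: PLC0415
    rows = []
    for rec in manifest.records:
        try:
            img = image_loader(rec.image_path)
        except Exception as exc:  # identify the file in the failure
            raise RuntimeError(f"failed to read image {rec.image_path!r}: {exc}") from exc
        rows.append(adapter.extract(img))
    values = np.stack(rows)
    return FeatureMatrix(values=values, labels=manifest.labels,
                         feature_names=[f"{adapter.name}_{i}" for i in range(adapter.output_dim)],
                         source_tag=f"deep:{adapter.name}")


def deep_feature_matrix_from_images(images: Iterable[np.ndarray], labels,
                                    adapter: BackboneAdapter) -> FeatureMatrix:
    """Adapter applied to in-memory images (no disk round trip)."""
    values = np.stack([adapter.extract(img) for img in images])
    return FeatureMatrix(values=values, labels=np.asarray(labels),
                         feature_names=[f"{adapter.name}_{i}" for i in range(adapter.output_dim)],
                         source_tag=f"deep:{adapter.name}")
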