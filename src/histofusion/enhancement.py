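"""Image enhancement: gray-world color balance, neighborhood averaging, CLAHE.

The enhancement chain is applied to every image before feature extraction,
in fixed order: channel-mean (gray-world) color adjustment, then a
neighborhood averaging filter that suppresses acquisition noise, then
contrast-limited adaptive histogram equalization (CLAHE) to lift contrast
between tissue structures.  All intermediate arithmetic is in float; the
result is re-quantized to 8-bit once, after the full chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure

from histofusion.types import validate_rgb_image


@dataclass
class AverageFilterConfig:
    """Configuration for the sliding-window averaging filter.

    The default is a 4 x 4 window (16 pixels) whose center pixel is
    excluded from the average, so each output pixel is the mean of its
    N = 15 configured neighbors.  A conventional 3 x 3 / N = 9 mode is
    available via ``AverageFilterConfig(3, 3, include_center=True)``.
    For even window sizes the window is anchored with the center pixel
    one row/column in from the top-left of the window center block.
    """

    window_height: int = 4
    window_width: int = 4
    include_center: bool = False

    def __post_init__(self) -> None:
        if self.window_height < 1 or self.window_width < 1:
            raise ValueError("window dimensions must be positive")
        if self.n_pixels < 1:
            raise ValueError("averaging window must keep at least one pixel")

    @property
    def center(self) -> tuple[int, int]:
        return ((self.window_height - 1) // 2, (self.window_width - 1) // 2)

    @property
    def n_pixels(self) -> int:
        n = self.window_height * self.window_width
        return n if self.include_center else n - 1


@dataclass
class ClaheConfig:
    """CLAHE parameters: tile grid, clip limit (fraction of tile pixels), gray levels."""

    tiles_y: int = 8
    tiles_x: int = 8
    clip_limit: float = 0.01
    n_gray_levels: int = 256
    per_channel: bool = False  # default: equalize lightness, preserve chroma

    def __post_init__(self) -> None:
        if self.tiles_y < 1 or self.tiles_x < 1 or self.clip_limit <= 0:
            raise ValueError("invalid CLAHE configuration")


@dataclass
class EnhancementConfig:
    average: AverageFilterConfig = None  # type: ignore[assignment]
    clahe: ClaheConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.average is None:
            self.average = AverageFilterConfig()
        if self.clahe is None:
            self.clahe = ClaheConfig()


def gray_world_balance(img: np.ndarray) -> np.ndarray:
    """Scale each RGB channel so all channel means equal the global mean.

    Implements the gray-world color-constancy assumption: under neutral
    illumination the average scene color is gray, so each channel is
    multiplied by (global mean / channel mean) and clipped to [0, 255].
    An all-black channel cannot be rescaled; it is left untouched with a
    warning.  Returns a float array (quantization is deferred).
    """
    img = validate_rgb_image(img)
    x = img.astype(np.float64)
    channel_means = x.reshape(-1, 3).mean(axis=0)
    global_mean = channel_means.mean()
    out = np.empty_like(x)
    for c in range(3):
        if channel_means[c] == 0:
            warnings.warn(f"channel {c} has zero mean; gray-world scaling skipped")
            out[..., c] = x[..., c]
        else:
            out[..., c] = x[..., c] * (global_mean / channel_means[c])
    return np.clip(out, 0.0, 255.0)


def average_filter(img: np.ndarray, cfg: AverageFilterConfig | None = None) -> np.ndarray:
    """Replace every pixel by the mean of its N configured window neighbors.

    Applied independently per channel; borders use reflection padding.
    With the default config each output pixel is the mean of the 15
    non-center pixels of its 4 x 4 window.
    """
    if cfg is None:
        cfg = AverageFilterConfig()
    x = np.asarray(img, dtype=np.float64)
    spatial = x.shape[:2]
    if spatial[0] < cfg.window_height or spatial[1] < cfg.window_width:
        raise ValueError("averaging window larger than image")
    kernel = np.ones((cfg.window_height, cfg.window_width))
    if not cfg.include_center:
        kernel[cfg.center] = 0.0
    kernel /= cfg.n_pixels
    # ndimage places an even-size kernel's reference at size // 2; shift it
    # to the configured center position.
    origin = (cfg.center[0] - cfg.window_height // 2,
              cfg.center[1] - cfg.window_width // 2)
    if x.ndim == 2:
        return ndimage.correlate(x, kernel, mode="reflect", origin=origin)
    out = np.empty_like(x)
    for c in range(x.shape[2]):
        out[..., c] = ndimage.correlate(x[..., c], kernel, mode="reflect", origin=origin)
    return out


def clahe(img: np.ndarray, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile clipped-histogram equalization with bilinear interpolation
    between tile mappings.  By default the equalization is applied to the
    lightness channel of the CIELAB representation with chroma preserved;
    ``cfg.per_channel`` equalizes each RGB channel instead.  A constant
    image is returned unchanged (degenerate histogram maps to identity).
    Accepts float input in [0, 255]; returns float in the same range.
    """
    if cfg is None:
        cfg = ClaheConfig()
    x = np.asarray(img, dtype=np.float64)
    if x.min() == x.max():
        return x.copy()
    h, w = x.shape[:2]
    kernel_size = (max(1, h // cfg.tiles_y), max(1, w // cfg.tiles_x))

    def _eq(channel01: np.ndarray) -> np.ndarray:
        if channel01.min() == channel01.max():
            return channel01
        return exposure.equalize_adapthist(
            np.clip(channel01, 0.0, 1.0),
            kernel_size=kernel_size,
            clip_limit=cfg.clip_limit,
            nbins=cfg.n_gray_levels,
        )

    if x.ndim == 2:
        return _eq(x / 255.0) * 255.0
    if cfg.per_channel:
        out = np.stack([_eq(x[..., c] / 255.0) for c in range(3)], axis=-1)
        return out * 255.0
    lab = skcolor.rgb2lab(x / 255.0)
    lab[..., 0] = _eq(lab[..., 0] / 100.0) * 100.0
    rgb = skcolor.lab2rgb(lab)
    return np.clip(rgb, 0.0, 1.0) * 255.0


def enhance(img: np.ndarray, cfg: EnhancementConfig | None = None) -> np.ndarray:
    """Full enhancement chain: gray-world balance -> averaging filter -> CLAHE.

    Returns a uint8 image; quantization to integers happens once, here.
    """
    if cfg is None:
        cfg = EnhancementConfig()
    x = gray_world_balance(img)
    x = average_filter(x, cfg.average)
    x = clahe(x, cfg.clahe)
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)
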