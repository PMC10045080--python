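"""Synthetic five-class histology-like image generator.

Real lung/colon histology slides differ in stain color statistics and in
texture regime (glandular blob structure, smooth benign tissue, striped
stroma, speckled nuclei fields, dense cellular mosaics).  The generator
emulates exactly those axes — per-class base color, one of five texture
families, and additive noise — with a single ``separability`` dial in
[0, 1] that interpolates every class parameter between a common neutral
spec (classes indistinguishable, chance-level classification) and fully
distinct specs.  No biological realism is claimed; the point is that each
descriptor family (FCH color, GLCM co-occurrence, LBP micro-pattern, DWT
multi-scale energy) has signal to detect at separability 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from histofusion.types import DEFAULT_CLASS_NAMES, DatasetManifest, ManifestRecord

TEXTURES = ("checker", "stripes", "blobs", "speckle", "smooth")

#: Fully separated per-class parameters: (base RGB color, texture family,
#: texture period/scale in pixels).  Colors sit in the magenta/pink range
#: of H&E-stained tissue.
_CLASS_TARGETS = {
    "colon_aca": ((168, 104, 196), "blobs", 6.0),
    "colon_bnt": ((226, 182, 208), "smooth", 8.0),
    "lung_aca": ((196, 128, 168), "stripes", 7.0),
    "lung_bnt": ((208, 168, 216), "speckle", 5.0),
    "lung_scc": ((160, 120, 152), "checker", 6.0),
}
_NEUTRAL_COLOR = np.array([191.6, 140.4, 188.0])  # mean of the class colors
_NEUTRAL_TEXTURE = "smooth"


@dataclass
class ClassSpec:
    class_name: str
    base_color: tuple[float, float, float]
    texture: str
    period: float = 6.0
    pattern_amplitude: float = 40.0
    color_jitter: float = 6.0
    noise_std: float = 10.0
    separability: float = 1.0

    def __post_init__(self) -> None:
        if self.texture not in TEXTURES:
            raise ValueError(f"texture must be one of {TEXTURES}")


def default_class_specs(separability: float = 1.0) -> list[ClassSpec]:
    """Five class specs with parameter spread scaled by ``separability``.

    At 0 every class collapses onto the same neutral color with zero
    pattern amplitude (identical distributions); at 1 colors and texture
    families are fully distinct.
    """
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    specs = []
    for name in DEFAULT_CLASS_NAMES:
        color, texture, period = _CLASS_TARGETS[name]
        blended = _NEUTRAL_COLOR + separability * (np.asarray(color, float) - _NEUTRAL_COLOR)
        specs.append(ClassSpec(
            class_name=name,
            base_color=tuple(blended),
            texture=texture if separability > 0 else _NEUTRAL_TEXTURE,
            period=period,
            pattern_amplitude=40.0 * separability,
            separability=separability,
        ))
    return specs


def _pattern(texture: str, shape: tuple[int, int], period: float,
             rng: np.random.Generator) -> np.ndarray:
    """Zero-mean texture field, roughly unit amplitude."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if texture == "smooth":
        return np.zeros(shape)
    if texture == "checker":
        return np.where(((yy // period).astype(int) + (xx // period).astype(int)) % 2 == 0,
                        1.0, -1.0)
    if texture == "stripes":
        phi = rng.uniform(0, np.pi)
        return np.sin(2 * np.pi * (xx * np.cos(phi) + yy * np.sin(phi)) / period)
    if texture == "blobs":
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=period / 2.0)
        s = field.std()
        return field / s if s > 0 else field
    # speckle: sparse bright impulses lightly smoothed
    field = (rng.random(shape) < 1.0 / (period ** 2)).astype(np.float64)
    field = ndimage.gaussian_filter(field * (period ** 2), sigma=0.8)
    return field - field.mean()


def generate_image(spec: ClassSpec, size: int | tuple[int, int] = 64,
                   seed: int = 0) -> np.ndarray:
    """Render one class image: tinted texture pattern plus Gaussian noise.

    Deterministic given (spec, size, seed); output uint8 in [0, 255].
    """
    shape = (size, size) if isinstance(size, int) else tuple(size)
    if shape[0] < 32 or shape[1] < 32:
        raise ValueError("image size must be at least 32 x 32")
    rng = np.random.default_rng(seed)
    base = np.asarray(spec.base_color, dtype=np.float64)
    base = base + rng.normal(0.0, spec.color_jitter, size=3) * spec.separability
    pattern = _pattern(spec.texture, shape, spec.period, rng)
    # the pattern modulates luminance; chroma keeps the class tint
    img = base[None, None, :] + spec.pattern_amplitude * pattern[..., None]
    img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _image_seed(base_seed: int, class_idx: int, i: int) -> int:
    # order-independent deterministic per-image seed, kept below 2**31
    return (base_seed * 1_000_003 + class_idx * 10_007 + i) % (2 ** 31)


def generate_images(n_per_class: int, specs: list[ClassSpec] | None = None,
                    size: int = 64, seed: int = 7):
    """In-memory balanced dataset: (list of images, integer labels array)."""
    if specs is None:
        specs = default_class_specs()
    if n_per_class < 5:
        raise ValueError("n_per_class must be at least 5")
    images, labels = [], []
    for ci, spec in enumerate(specs):
        for i in range(n_per_class):
            images.append(generate_image(spec, size, _image_seed(seed, ci, i)))
            labels.append(ci)
    return images, np.asarray(labels, dtype=np.int64)


def generate_dataset(n_per_class: int, specs: list[ClassSpec] | None = None,
                     size: int = 64, seed: int = 7,
                     out_dir: str | Path = "fixtures") -> DatasetManifest:
    """Write a balanced PNG dataset plus ``manifest.csv``; returns the manifest.

    Regeneration with the same arguments produces byte-identical files.
    """
    from histofusion.dataset_io import save_manifest

    if specs is None:
        specs = default_class_specs()
    if n_per_class < 5:
        raise ValueError("n_per_class must be at least 5")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for ci, spec in enumerate(specs):
        cls_dir = out_dir / spec.class_name
        cls_dir.mkdir(exist_ok=True)
        for i in range(n_per_class):
            img = generate_image(spec, size, _image_seed(seed, ci, i))
            path = cls_dir / f"{spec.class_name}_{i:04d}.png"
            Image.fromarray(img).save(path)
            records.append(ManifestRecord(image_path=str(path), class_label=spec.class_name))
    manifest = DatasetManifest(records=records,
                               class_names=tuple(s.class_name for s in specs))
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/JPEG into an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
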