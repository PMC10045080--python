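"""Shared data containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used for every confusion matrix and report.
DEFAULT_CLASS_NAMES = ("colon_aca", "colon_bnt", "lung_aca", "lung_bnt", "lung_scc")

MIN_IMAGE_SIDE = 8


def validate_rgb_image(img: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 integer image with intensities in [0, 255].

    Returns the validated array (uint8 view or original).  Raises
    ``ValueError`` on shape or range violations; descriptors require
    images of at least 8 x 8 pixels.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < MIN_IMAGE_SIDE or img.shape[1] < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image must be at least {MIN_IMAGE_SIDE} x {MIN_IMAGE_SIDE}, got {img.shape[:2]}"
        )
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img


@dataclass
class ManifestRecord:
    image_path: str
    class_label: str
    split: str | None = None  # one of train / validation / test, or None


@dataclass
class DatasetManifest:
    """An ordered list of (image path, class label) records with optional split tags."""

    records: list[ManifestRecord]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = set(self.class_names)
        for rec in self.records:
            if rec.class_label not in names:
                raise ValueError(f"label {rec.class_label!r} not in class_names")
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image paths in manifest")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        """Integer class indices aligned with ``records``."""
        index = {name: i for i, name in enumerate(self.class_names)}
        return np.array([index[r.class_label] for r in self.records], dtype=np.int64)

    def subset(self, split: str) -> "DatasetManifest":
        recs = [r for r in self.records if r.split == split]
        return DatasetManifest(records=recs, class_names=self.class_names)

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-class record counts keyed by split (``None`` key when unsplit)."""
        out: dict[str, dict[str, int]] = {}
        for rec in self.records:
            key = rec.split if rec.split is not None else "all"
            out.setdefault(key, {}).setdefault(rec.class_label, 0)
            out[key][rec.class_label] += 1
        return out


@dataclass
class FeatureMatrix:
    """n_samples x dim feature matrix with aligned labels and provenance.

    The currency between extraction, reduction, fusion and classification
    stages.  ``labels`` are integer class indices into the class order the
    producing stage used; ``feature_names`` record per-column provenance.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] < 1:
            raise ValueError("feature dimension must be positive")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("row count of values must match labels length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal dim")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]
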