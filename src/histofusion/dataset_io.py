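"""Manifest reading/writing, stratified splitting, and the feature store.

Manifests are comma-delimited text files with header ``path,label[,split]``.
Feature matrices are stored as a portable ``.npz`` array container holding
values and labels, with a JSON sidecar (same path + ``.json``) carrying the
feature names and provenance tag so the store stays inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from histofusion.types import DatasetManifest, FeatureMatrix, ManifestRecord

VALID_SPLITS = ("train", "validation", "test")


def load_manifest(path: str | Path, expected_n_classes: int | None = None) -> DatasetManifest:
    """Read a delimited-text manifest with columns ``path,label[,split]``.

    Class names are the sorted set of labels found.  Raises on a missing
    file, missing columns, an empty manifest, duplicate paths, or — when
    ``expected_n_classes`` is given — a mismatching label count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("manifest is empty")
    class_names = tuple(sorted(df["label"].unique()))
    if expected_n_classes is not None and len(class_names) != expected_n_classes:
        raise ValueError(
            f"expected {expected_n_classes} classes, manifest has {len(class_names)}"
        )
    has_split = "split" in df.columns
    records = []
    for row in df.itertuples(index=False):
        split = getattr(row, "split", None) if has_split else None
        if isinstance(split, float) and np.isnan(split):
            split = None
        if split is not None and split not in VALID_SPLITS:
            raise ValueError(f"unknown split tag {split!r}")
        records.append(ManifestRecord(image_path=row.path, class_label=row.label, split=split))
    return DatasetManifest(records=records, class_names=class_names)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest back to delimited text (split column only when tagged)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    any_split = any(r.split is not None for r in manifest.records)
    data = {
        "path": [r.image_path for r in manifest.records],
        "label": [r.class_label for r in manifest.records],
    }
    if any_split:
        data["split"] = [r.split for r in manifest.records]
    pd.DataFrame(data).to_csv(path, index=False)


def split_dataset(
    manifest: DatasetManifest,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetManifest:
    """Two-level stratified split: test first, then validation within the rest.

    Per class, ``floor(n * test_fraction)`` records go to the test split,
    then ``floor(n_rest * validation_fraction)`` of the remaining records to
    validation; the remainder stays in train.  Records are shuffled per
    class with the given seed before slicing, so the assignment is a pure
    function of (manifest ordering, fractions, seed).  For 5000 per class
    at 0.2/0.2 this yields 3200 train / 800 validation / 1000 test.
    """
    if not (0 < test_fraction < 1) or not (0 < validation_fraction < 1):
        raise ValueError("fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    new_records = [ManifestRecord(r.image_path, r.class_label, None) for r in manifest.records]
    for cls in manifest.class_names:
        idx = [i for i, r in enumerate(manifest.records) if r.class_label == cls]
        n = len(idx)
        n_test = int(np.floor(n * test_fraction))
        n_val = int(np.floor((n - n_test) * validation_fraction))
        n_train = n - n_test - n_val
        if min(n_test, n_val, n_train) < 1:
            raise ValueError(
                f"class {cls!r} has too few samples ({n}) for one record per split"
            )
        order = rng.permutation(n)
        shuffled = [idx[j] for j in order]
        for i in shuffled[:n_test]:
            new_records[i].split = "test"
        for i in shuffled[n_test : n_test + n_val]:
            new_records[i].split = "validation"
        for i in shuffled[n_test + n_val :]:
            new_records[i].split = "train"
    return DatasetManifest(records=new_records, class_names=manifest.class_names)


def _store_paths(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    return path, Path(str(path) + ".json")


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist a feature matrix: ``.npz`` arrays plus a JSON descriptive sidecar."""
    store, sidecar_path = _store_paths(path)
    store.parent.mkdir(parents=True, exist_ok=True)
    if not np.all(np.isfinite(fm.values)):
        raise ValueError("refusing to save non-finite feature values")
    np.savez(store, values=fm.values, labels=fm.labels)
    sidecar = {"feature_names": fm.feature_names, "source_tag": fm.source_tag}
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> FeatureMatrix:
    """Load a feature matrix written by :func:`save_features` (lossless round trip)."""
    path, sidecar_path = _store_paths(path)
    with np.load(path) as data:
        values = data["values"]
        labels = data["labels"]
    if values.shape[0] != labels.shape[0]:
        raise ValueError("corrupted feature store: values/labels row mismatch")
    feature_names: list[str] = []
    source_tag = ""
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        feature_names = meta.get("feature_names", [])
        source_tag = meta.get("source_tag", "")
    return FeatureMatrix(values=values, labels=labels,
                         feature_names=feature_names, source_tag=source_tag)
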