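"""End-to-end pipeline: simulate -> enhance -> extract -> reduce -> train -> evaluate.

Convenience driver used by the examples, the CLI ``run`` command and the
acceptance checks.  Works entirely in memory on the synthetic dataset;
for image directories use the individual stage functions with a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histofusion import ann, enhancement, handcrafted
from histofusion.dataset_io import split_dataset
from histofusion.deep_features import PseudoBackbone, deep_feature_matrix_from_images
from histofusion.evaluation import ConfusionMatrix, MetricsReport, evaluate_predictions
from histofusion.reduction_fusion import (
    FusionModel, FusionSpec, cap_components, pca_fit, pca_transform,
)
from histofusion.synthetic import default_class_specs, generate_images
from histofusion.types import DEFAULT_CLASS_NAMES, DatasetManifest, FeatureMatrix, ManifestRecord


@dataclass
class PipelineResult:
    test_accuracy: float  # overall (micro) test accuracy, percent
    confusion: ConfusionMatrix
    report: MetricsReport
    history: ann.TrainingHistory
    train_regression_r: float
    n_train: int
    n_validation: int
    n_test: int
    feature_dim: int


def _standardize_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def run_pipeline(
    n_per_class: int = 100,
    size: int = 64,
    separability: float = 1.0,
    seed: int = 7,
    feature_set: str = "handcrafted",
    n_components: int = 455,
    hidden_units: int = 20,
    loss: str = "cross_entropy",
    max_fail: int = 6,
    max_epochs: int = 300,
    enhance: bool = True,
) -> PipelineResult:
    """Run the full classification pipeline on the synthetic dataset.

    ``feature_set`` selects the branch: ``handcrafted`` (244-dim),
    ``deep`` (pseudo-backbone, PCA-reduced), or ``fusion`` (PCA-reduced
    deep + handcrafted, the 699-style strategy).  Features are
    standardized on training statistics, PCA-reduced (component count
    capped at min(n_train - 1, dim)), and classified by the feed-forward
    network with validation-failure early stopping.
    """
    specs = default_class_specs(separability)
    images, labels = generate_images(n_per_class, specs, size=size, seed=seed)
    if enhance:
        images = [enhancement.enhance(img) for img in images]

    # stratified split over an in-memory manifest
    records = [ManifestRecord(f"mem://{i}", DEFAULT_CLASS_NAMES[labels[i]])
               for i in range(len(images))]
    manifest = split_dataset(
        DatasetManifest(records, DEFAULT_CLASS_NAMES), 0.2, 0.2, seed=seed)
    split_of = np.array([r.split for r in manifest.records])

    if feature_set == "handcrafted":
        fm = handcrafted.handcrafted_feature_matrix(images, labels)
    elif feature_set == "deep":
        fm = deep_feature_matrix_from_images(images, labels, PseudoBackbone(seed=seed))
    elif feature_set == "fusion":
        hand = handcrafted.handcrafted_feature_matrix(images, labels)
        deep = deep_feature_matrix_from_images(images, labels, PseudoBackbone(seed=seed))
        fm = _fuse_for_pipeline(deep, hand, split_of, n_components)
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")

    masks = {s: split_of == s for s in ("train", "validation", "test")}

    X, y = fm.values, fm.labels
    mu, sd = _standardize_fit(X[masks["train"]])
    Xs = (X - mu) / sd

    if feature_set != "fusion":  # fusion branch is already PCA-reduced
        k = cap_components(n_components, int(masks["train"].sum()), Xs.shape[1])
        pca = pca_fit(Xs[masks["train"]], k)
        Xs = pca_transform(pca, Xs)

    sets = {s: FeatureMatrix(values=Xs[m], labels=y[m], source_tag=s)
            for s, m in masks.items()}

    model = ann.ann_init(Xs.shape[1], hidden_units=hidden_units, seed=seed, loss=loss)
    model, history = ann.ann_train(model, sets["train"], sets["validation"],
                                   test=sets["test"], max_fail=max_fail,
                                   max_epochs=max_epochs)

    scores_tr, _ = ann.ann_predict(model, sets["train"])
    reg_r = ann.regression_r(ann.one_hot(sets["train"].labels, 5), scores_tr)

    scores, pred = ann.ann_predict(model, sets["test"])
    cm, report = evaluate_predictions(sets["test"].labels, pred, scores=scores)
    accuracy = 100.0 * np.trace(cm.counts) / cm.total
    return PipelineResult(
        test_accuracy=float(accuracy), confusion=cm, report=report,
        history=history, train_regression_r=float(reg_r),
        n_train=int(masks["train"].sum()), n_validation=int(masks["validation"].sum()),
        n_test=int(masks["test"].sum()), feature_dim=Xs.shape[1],
    )


def _fuse_for_pipeline(deep: FeatureMatrix, hand: FeatureMatrix,
                       split_of: np.ndarray, n_components: int) -> FeatureMatrix:
    train = split_of == "train"
    spec = FusionSpec(strategy="cnn_plus_handcrafted",
                      branch_components=(n_components, hand.dim))
    sub = lambda fm, m: FeatureMatrix(values=fm.values[m], labels=fm.labels[m],
                                      feature_names=fm.feature_names,
                                      source_tag=fm.source_tag)
    fusion = FusionModel.fit(spec, [sub(deep, train), sub(hand, train)])
    return fusion.transform([deep, hand])
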