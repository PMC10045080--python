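"""PCA dimensionality reduction and the three feature-fusion strategies.

PCA is fitted on the training split only and then applied to validation
and test data, so no test information leaks into the basis.  Three fusion
strategies combine feature branches (row-aligned feature matrices over the
same samples):

* ``merge_after_pca`` — reduce each branch with its own PCA, concatenate
  (two 455-component deep branches give 910 columns);
* ``merge_before_pca`` — concatenate the raw branches, then one PCA
  (740 components at the reference settings);
* ``cnn_plus_handcrafted`` — concatenate a PCA-reduced deep branch with
  the raw handcrafted branch (455 + 244 = 699 columns), after scaling
  each branch to unit overall variance so neither drowns the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from histofusion.types import FeatureMatrix

FUSION_STRATEGIES = ("separate", "merge_after_pca", "merge_before_pca",
                     "cnn_plus_handcrafted")


@dataclass
class PCAModel:
    """Mean + orthonormal component basis + explained variances (descending)."""

    mean: np.ndarray
    components: np.ndarray  # n_components x dim
    explained_variance: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")


def pca_fit(train: FeatureMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Covariance PCA by SVD of the centered training matrix.

    ``n_components`` must not exceed min(n_samples - 1, dim).  The sign of
    each component is fixed so its largest-magnitude loading is positive,
    making the basis deterministic.  ``explained_variance`` uses the
    unbiased (n - 1) normalization, so its full-rank sum equals the total
    variance of the centered data.
    """
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, dtype=np.float64)
    n, d = X.shape
    max_comp = min(n - 1, d)
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("zero-variance input: PCA undefined")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    components = vt[:n_components]
    # deterministic sign convention: largest-|loading| entry positive
    for row in components:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    explained = (s[:n_components] ** 2) / (n - 1)
    return PCAModel(mean=mean, components=components,
                    explained_variance=explained, n_components=n_components)


def pca_transform(model: PCAModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """(X - mean) projected onto the component basis."""
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    if V.shape[1] != model.mean.shape[0]:
        raise ValueError("dimension mismatch between data and PCA model")
    return (V - model.mean) @ model.components.T


def pca_inverse_transform(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map scores back to the original space (exact at full rank)."""
    return np.asarray(Z) @ model.components + model.mean


def cap_components(requested: int, n_samples: int, dim: int) -> int:
    """Clamp a requested component count to the feasible min(n - 1, dim)."""
    return max(1, min(requested, n_samples - 1, dim))


@dataclass
class FusionSpec:
    """Fusion strategy plus per-branch PCA component targets."""

    strategy: str = "merge_after_pca"
    branch_components: tuple[int, ...] = (455, 455)
    merged_components: int = 740

    def __post_init__(self) -> None:
        if self.strategy not in FUSION_STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def expected_dim(self) -> int:
        if self.strategy == "separate":
            return self.branch_components[0]
        if self.strategy == "merge_after_pca":
            return sum(self.branch_components)
        if self.strategy == "merge_before_pca":
            return self.merged_components
        raise ValueError("cnn_plus_handcrafted dim depends on the handcrafted branch")


def _branch_scale(X: np.ndarray) -> float:
    """Scale factor giving a branch unit overall (mean per-feature) variance."""
    v = X.var(axis=0, ddof=0).mean()
    return 1.0 / np.sqrt(v) if v > 0 else 1.0


@dataclass
class FusionModel:
    """Fitted fusion transform: per-branch PCA models and scaling.

    Fit on training branches only, then applied to any row-aligned set of
    branches (validation/test).  ``cnn_plus_handcrafted`` expects branch 0
    to be the deep branch (PCA-reduced) and branch 1 the raw handcrafted
    branch; both are scaled to unit overall variance using training
    statistics.
    """

    spec: FusionSpec
    pca_models: list = field(default_factory=list)
    scales: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)

    @classmethod
    def fit(cls, spec: FusionSpec, train_branches: list[FeatureMatrix]) -> "FusionModel":
        _check_alignment(train_branches)
        model = cls(spec=spec)
        n = train_branches[0].n_samples
        if spec.strategy in ("separate", "merge_after_pca"):
            for fm, k in zip(train_branches, spec.branch_components):
                k = cap_components(k, n, fm.dim)
                model.pca_models.append(pca_fit(fm, k))
        elif spec.strategy == "merge_before_pca":
            pooled = np.hstack([fm.values for fm in train_branches])
            k = cap_components(spec.merged_components, n, pooled.shape[1])
            model.pca_models.append(pca_fit(pooled, k))
        elif spec.strategy == "cnn_plus_handcrafted":
            deep, hand = train_branches
            k = cap_components(spec.branch_components[0], n, deep.dim)
            pca = pca_fit(deep, k)
            model.pca_models.append(pca)
            model.scales = [_branch_scale(pca_transform(pca, deep)),
                            _branch_scale(hand.values)]
        return model

    def transform(self, branches: list[FeatureMatrix]) -> FeatureMatrix:
        _check_alignment(branches)
        spec = self.spec
        labels = branches[0].labels
        if spec.strategy == "separate":
            Z = pca_transform(self.pca_models[0], branches[0])
            names = [f"{branches[0].source_tag}_pc{i}" for i in range(Z.shape[1])]
        elif spec.strategy == "merge_after_pca":
            parts, names = [], []
            for fm, pca in zip(branches, self.pca_models):
                Z = pca_transform(pca, fm)
                parts.append(Z)
                names += [f"{fm.source_tag}_pc{i}" for i in range(Z.shape[1])]
            Z = np.hstack(parts)
        elif spec.strategy == "merge_before_pca":
            pooled = np.hstack([fm.values for fm in branches])
            Z = pca_transform(self.pca_models[0], pooled)
            names = [f"merged_pc{i}" for i in range(Z.shape[1])]
        else:  # cnn_plus_handcrafted
            deep, hand = branches
            Zd = pca_transform(self.pca_models[0], deep) * self.scales[0]
            Zh = hand.values * self.scales[1]
            Z = np.hstack([Zd, Zh])
            names = ([f"{deep.source_tag}_pc{i}" for i in range(Zd.shape[1])]
                     + list(hand.feature_names))
        return FeatureMatrix(values=Z, labels=labels, feature_names=names,
                             source_tag=f"fused:{spec.strategy}")


def _check_alignment(branches: list[FeatureMatrix]) -> None:
    if not branches:
        raise ValueError("at least one branch required")
    n = branches[0].n_samples
    for fm in branches[1:]:
        if fm.n_samples != n:
            raise ValueError("branch row counts differ")
        if not np.array_equal(fm.labels, branches[0].labels):
            raise ValueError("branch labels are not row-aligned")
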