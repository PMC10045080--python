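"""Deep feature extraction (pseudo-backbone) and the three fusion strategies.

Uses small sample counts, so PCA component targets are capped at
min(n_train - 1, dim); at full scale (>= 456 samples per branch) the
fused dimensions are 910, 740 and 699.
"""

from histofusion import default_class_specs, PseudoBackbone
from histofusion.deep_features import deep_feature_matrix_from_images
from histofusion.handcrafted import handcrafted_feature_matrix
from histofusion.reduction_fusion import FusionModel, FusionSpec
from histofusion.synthetic import generate_images

images, labels = generate_images(8, default_class_specs(1.0), size=32, seed=5)
deep_a = deep_feature_matrix_from_images(images, labels, PseudoBackbone(seed=7))
deep_b = deep_feature_matrix_from_images(images, labels, PseudoBackbone(seed=8))
hand = handcrafted_feature_matrix(images, labels)
print(f"deep branches: {deep_a.values.shape} each; handcrafted: {hand.values.shape}")

for spec, branches in [
    (FusionSpec("merge_after_pca", branch_components=(15, 15)), [deep_a, deep_b]),
    (FusionSpec("merge_before_pca", merged_components=25), [deep_a, deep_b]),
    (FusionSpec("cnn_plus_handcrafted", branch_components=(15,)), [deep_a, hand]),
]:
    fused = FusionModel.fit(spec, branches).transform(branches)
    print(f"{spec.strategy:22s} -> {fused.n_samples} x {fused.dim}")

# merge_after_pca concatenates per-branch PCA scores; merge_before_pca
# concatenates raw branches then fits one basis; cnn_plus_handcrafted keeps
# the handcrafted branch raw next to the PCA-reduced deep branch.
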