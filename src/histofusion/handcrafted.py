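"""Handcrafted texture and color descriptors.

Four descriptor families are extracted from each (enhanced) image and
concatenated into a single 244-dimensional handcrafted vector:

* **DWT** (12): single-level Haar wavelet decomposition; mean, variance and
  standard deviation of each subband (LL, LH, HL, HH).
* **LBP** (203): local binary pattern codes with P = 15 circularly sampled
  neighbors, histogrammed into 203 equal-width bins over the code range.
* **FCH** (16): fuzzy color histogram — each pixel spreads fractional
  membership over 16 color bin centers obtained by seeded fuzzy c-means.
* **GLCM** (13): gray-level co-occurrence matrices at distance d for the
  four standard angles, summarized by the 13 classical Haralick
  statistics averaged over angles.

LBP, FCH, GLCM and the Haralick statistics are implemented here directly;
the wavelet transform is delegated to PyWavelets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

GLCM_ANGLES = (0, 45, 90, 135)
#: (row, col) step per unit distance for each supported angle, in matrix
#: coordinates (rows increasing downward), matching the widely used
#: scikit-image convention; symmetrization makes the direction sign moot.
_ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

HARALICK_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance grayscale (0.2989 R + 0.5870 G + 0.1140 B), float in [0, 255]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    return img[..., :3] @ GRAY_WEIGHTS


# ---------------------------------------------------------------------------
# DWT subband statistics
# ---------------------------------------------------------------------------

@dataclass
class DWTConfig:
    wavelet: str = "haar"
    levels: int = 1

    def __post_init__(self) -> None:
        if self.levels != 1:
            raise ValueError("only single-level decomposition is supported")


DWT_SUBBANDS = ("LL", "LH", "HL", "HH")
DWT_STATS = ("mean", "variance", "std")


def dwt_features(gray: np.ndarray, cfg: DWTConfig | None = None) -> np.ndarray:
    """12 statistics from a single-level 2-D Haar decomposition.

    Returns ``[mean, variance, std]`` for each of LL, LH, HL, HH in that
    fixed order (orthonormal convention: the LL of a constant image c has
    mean 2c).  Images with an odd height/width are cropped by one pixel.
    """
    if cfg is None:
        cfg = DWTConfig()
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("grayscale image of at least 2 x 2 required")
    g = g[: g.shape[0] - g.shape[0] % 2, : g.shape[1] - g.shape[1] % 2]
    ll, (lh, hl, hh) = pywt.dwt2(g, cfg.wavelet)
    out = []
    for band in (ll, lh, hl, hh):
        out.extend([band.mean(), band.var(), band.std()])
    return np.asarray(out)


def dwt_feature_names() -> list[str]:
    return [f"dwt_{b}_{s}" for b in DWT_SUBBANDS for s in DWT_STATS]


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------

@dataclass
class LBPConfig:
    """LBP sampling and binning parameters.

    ``P`` neighbors are sampled on the radius-``R`` circle counter-clockwise
    from angle 0 with bilinear interpolation; codes in [0, 2^P - 1] are
    histogrammed into ``n_bins`` equal-width bins.
    """

    P: int = 15
    R: float = 2.0
    n_bins: int = 203

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("P must be at least 4")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.R <= 0:
            raise ValueError("radius must be positive")

    @property
    def code_max(self) -> int:
        return 2 ** self.P - 1

    def offsets(self) -> np.ndarray:
        """(P, 2) array of (row, col) sampling offsets, CCW from angle 0."""
        p = np.arange(self.P)
        theta = 2.0 * np.pi * p / self.P
        dr = -self.R * np.sin(theta)
        dc = self.R * np.cos(theta)
        # snap near-integer offsets so axis-aligned samples are exact
        dr = np.where(np.abs(dr - np.rint(dr)) < 1e-8, np.rint(dr), dr)
        dc = np.where(np.abs(dc - np.rint(dc)) < 1e-8, np.rint(dc), dc)
        return np.stack([dr, dc], axis=1)


def lbp_code_from_neighbors(neighbors: np.ndarray, center: float) -> int:
    """Code = sum of s(g_p - g_c) * 2^p with s(x) = 1 for x >= 0 (ties count as 1)."""
    bits = np.asarray(neighbors, dtype=np.float64) >= float(center)
    return int(np.sum(bits * (1 << np.arange(len(bits), dtype=np.int64))))


def _bilinear(gray: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    r1 = min(r0 + 1, gray.shape[0] - 1)
    c1 = min(c0 + 1, gray.shape[1] - 1)
    val = ((1 - fr) * (1 - fc) * gray[r0, c0] + (1 - fr) * fc * gray[r0, c1]
           + fr * (1 - fc) * gray[r1, c0] + fr * fc * gray[r1, c1])
    # round away float noise so ties against the center are exact
    return np.round(val, 8)


def lbp_code(gray: np.ndarray, cfg: LBPConfig, pixel: tuple[int, int]) -> int:
    """LBP code of a single pixel (must be at least R from every border)."""
    g = np.asarray(gray, dtype=np.float64)
    r, c = pixel
    rad = int(np.ceil(cfg.R))
    if not (rad <= r < g.shape[0] - rad and rad <= c < g.shape[1] - rad):
        raise ValueError("pixel too close to the border for the configured radius")
    samples = np.array([_bilinear(g, r + dr, c + dc) for dr, dc in cfg.offsets()])
    return lbp_code_from_neighbors(samples, g[r, c])


def lbp_code_map(gray: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Codes for every valid (interior) pixel, vectorized over the image."""
    if cfg is None:
        cfg = LBPConfig()
    g = np.asarray(gray, dtype=np.float64)
    rad = int(np.ceil(cfg.R))
    h, w = g.shape
    if h <= 2 * rad or w <= 2 * rad:
        raise ValueError("image too small for the configured LBP radius")
    center = g[rad : h - rad, rad : w - rad]
    codes = np.zeros_like(center, dtype=np.int64)
    for p, (dr, dc) in enumerate(cfg.offsets()):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        r1 = r0 + 1 if fr > 0 else r0
        c1 = c0 + 1 if fc > 0 else c0
        def shifted(dy: int, dx: int) -> np.ndarray:
            return g[rad + dy : h - rad + dy, rad + dx : w - rad + dx]
        sample = ((1 - fr) * (1 - fc) * shifted(r0, c0)
                  + (1 - fr) * fc * shifted(r0, c1)
                  + fr * (1 - fc) * shifted(r1, c0)
                  + fr * fc * shifted(r1, c1))
        codes += (np.round(sample, 8) >= center).astype(np.int64) << p
    return codes


def lbp_features(gray: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Normalized histogram (sums to 1) of LBP codes over equal-width bins."""
    if cfg is None:
        cfg = LBPConfig()
    codes = lbp_code_map(gray, cfg)
    if codes.size == 0:
        raise ValueError("no valid pixels for LBP")
    hist, _ = np.histogram(codes.ravel(), bins=cfg.n_bins, range=(0, cfg.code_max))
    return hist / codes.size


def lbp_feature_names(cfg: LBPConfig | None = None) -> list[str]:
    cfg = cfg or LBPConfig()
    return [f"lbp_bin_{i:03d}" for i in range(cfg.n_bins)]


# ---------------------------------------------------------------------------
# Fuzzy color histogram
# ---------------------------------------------------------------------------

@dataclass
class FCHConfig:
    """Fuzzy color histogram: 16 RGB bin centers, fuzziness exponent m > 1.

    When ``bin_centers`` is not supplied, the centers are obtained by
    seeded fuzzy c-means over a fixed 4 x 4 x 4 RGB lattice, making them a
    deterministic function of the seed alone (not of any image).
    """

    n_bins: int = 16
    m: float = 2.0
    bin_centers: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzziness m must exceed 1")
        if self.bin_centers is not None:
            self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
            if self.bin_centers.shape != (self.n_bins, 3):
                raise ValueError("bin_centers must be (n_bins, 3)")
            if len(np.unique(self.bin_centers, axis=0)) != self.n_bins:
                raise ValueError("bin_centers must be distinct")


def _rgb_lattice(points_per_axis: int = 4) -> np.ndarray:
    step = 256.0 / points_per_axis
    axis = (np.arange(points_per_axis) + 0.5) * step
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)


def fuzzy_cmeans(data: np.ndarray, n_clusters: int, m: float = 2.0, seed: int = 0,
                 max_iter: int = 300, tol: float = 1e-8) -> np.ndarray:
    """Plain fuzzy c-means returning the (n_clusters, dim) center matrix.

    Seeded initialization picks distinct data points as starting centers,
    so the result is deterministic given (data, seed).
    """
    data = np.asarray(data, dtype=np.float64)
    rng = np.random.default_rng(seed)
    centers = data[rng.choice(len(data), size=n_clusters, replace=False)].copy()
    expo = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _memberships_from_d2(d2, expo)
        um = u ** m
        new_centers = (um.T @ data) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers


def _memberships_from_d2(d2: np.ndarray, expo: float) -> np.ndarray:
    """Memberships u_ik from squared distances; exact hits get full membership."""
    u = np.zeros_like(d2)
    zero_rows = (d2 <= 1e-24).any(axis=1)
    if zero_rows.any():
        hits = d2[zero_rows] <= 1e-24
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    nz = ~zero_rows
    if nz.any():
        inv = d2[nz] ** (-expo / 2.0)  # (1/d)^expo evaluated on squared distances
        u[nz] = inv / inv.sum(axis=1, keepdims=True)
    return u


def default_fch_centers(cfg: FCHConfig) -> np.ndarray:
    return fuzzy_cmeans(_rgb_lattice(), cfg.n_bins, m=cfg.m, seed=cfg.seed)


def fch_features(img: np.ndarray, cfg: FCHConfig | None = None) -> np.ndarray:
    """Fuzzy color histogram: per-pixel membership mass over the color bins.

    Each pixel contributes membership u_k proportional to (1/d_k^2)^(1/(m-1))
    to every bin center; memberships per pixel sum to one, so the returned
    histogram (the mean membership vector) also sums to one.  A pixel lying
    exactly at a center belongs fully to that center.
    """
    if cfg is None:
        cfg = FCHConfig()
    centers = cfg.bin_centers if cfg.bin_centers is not None else default_fch_centers(cfg)
    pixels = np.asarray(img, dtype=np.float64).reshape(-1, 3)
    d2 = ((pixels[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    u = _memberships_from_d2(d2, 2.0 / (cfg.m - 1.0))
    return u.mean(axis=0)


def fch_feature_names(cfg: FCHConfig | None = None) -> list[str]:
    cfg = cfg or FCHConfig()
    return [f"fch_bin_{i:02d}" for i in range(cfg.n_bins)]


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

@dataclass
class GLCMConfig:
    distance: int = 1
    levels: int = 8
    angles: tuple[int, ...] = GLCM_ANGLES


@dataclass
class GLCMMatrix:
    probabilities: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool = True


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize [0, 255] intensities to ``levels`` gray levels."""
    g = np.asarray(gray, dtype=np.float64)
    q = np.floor(g * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(gray: np.ndarray, d: int = 1, angle: int = 0, levels: int = 8,
                prequantized: bool = False) -> GLCMMatrix:
    """Symmetric, normalized co-occurrence matrix at offset (d, angle).

    Each ordered pixel pair at the offset is counted in both directions
    (symmetrization) and the counts are normalized to probabilities.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    q = np.asarray(gray, dtype=np.int64) if prequantized else quantize_gray(gray, levels)
    dr, dc = (_ANGLE_OFFSETS[angle][0] * d, _ANGLE_OFFSETS[angle][1] * d)
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("image too small for the requested offset")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    counts += counts.T.copy()  # symmetrize: count each pair in both directions
    return GLCMMatrix(probabilities=counts / counts.sum(), levels=levels,
                      distance=d, angle=angle, symmetric=True)


def _haralick_13(p: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence statistics of one normalized GLCM.

    Entropies use log base 2 with 0*log 0 = 0; correlation and the first
    information measure of correlation return 0 when their denominators
    vanish (degenerate single-level images).
    """
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to probabilities")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (np.arange(L) * px).sum()
    mu_y = (np.arange(L) * py).sum()
    var_x = (((np.arange(L) - mu_x) ** 2) * px).sum()
    var_y = (((np.arange(L) - mu_y) ** 2) * py).sum()

    # distributions of the index sum and absolute difference
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    asm = float((p ** 2).sum())
    contrast = float(((np.arange(L) ** 2) * p_diff).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    k_sum = np.arange(2 * L - 1)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = ent(p_sum)
    entropy = ent(p)
    k_diff = np.arange(L)
    mu_diff = (k_diff * p_diff).sum()
    difference_variance = float(((k_diff - mu_diff) ** 2 * p_diff).sum())
    difference_entropy = ent(p_diff)

    hx, hy = ent(px), ent(py)
    outer = px[:, None] * py[None, :]
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    m2 = outer > 0
    hxy2 = float(-(outer[m2] * np.log2(outer[m2])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([asm, contrast, correlation, variance, idm, sum_average,
                     sum_variance, sum_entropy, entropy, difference_variance,
                     difference_entropy, imc1, imc2])


def haralick_features(glcms: list[GLCMMatrix]) -> np.ndarray:
    """13 Haralick statistics, each averaged over the supplied angle matrices."""
    if not glcms:
        raise ValueError("at least one GLCM required")
    return np.mean([_haralick_13(g.probabilities) for g in glcms], axis=0)


def glcm_features(gray: np.ndarray, cfg: GLCMConfig | None = None) -> np.ndarray:
    """Angle-averaged Haralick features of one grayscale image."""
    if cfg is None:
        cfg = GLCMConfig()
    q = quantize_gray(gray, cfg.levels)
    glcms = [glcm_matrix(q, d=cfg.distance, angle=a, levels=cfg.levels, prequantized=True)
             for a in cfg.angles]
    return haralick_features(glcms)


def glcm_feature_names() -> list[str]:
    return [f"glcm_{n}" for n in HARALICK_NAMES]


# ---------------------------------------------------------------------------
# Combined handcrafted vector
# ---------------------------------------------------------------------------

@dataclass
class HandcraftedConfig:
    dwt: DWTConfig = field(default_factory=DWTConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    fch: FCHConfig = field(default_factory=FCHConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)


def handcrafted_vector(img: np.ndarray, cfg: HandcraftedConfig | None = None) -> np.ndarray:
    """Concatenated [DWT(12) | LBP(203) | FCH(16) | GLCM(13)] descriptor (244)."""
    if cfg is None:
        cfg = HandcraftedConfig()
    gray = to_grayscale(img)
    return np.concatenate([
        dwt_features(gray, cfg.dwt),
        lbp_features(gray, cfg.lbp),
        fch_features(img, cfg.fch),
        glcm_features(gray, cfg.glcm),
    ])


def handcrafted_feature_names(cfg: HandcraftedConfig | None = None) -> list[str]:
    cfg = cfg or HandcraftedConfig()
    return (dwt_feature_names() + lbp_feature_names(cfg.lbp)
            + fch_feature_names(cfg.fch) + glcm_feature_names())


def handcrafted_feature_matrix(images, labels, cfg: HandcraftedConfig | None = None):
    """Stack per-image handcrafted vectors into a FeatureMatrix."""
    from histofusion.types import FeatureMatrix

    cfg = cfg or HandcraftedConfig()
    # resolve the FCH centers once so every image shares the same bins
    if cfg.fch.bin_centers is None:
        cfg = HandcraftedConfig(
            dwt=cfg.dwt, lbp=cfg.lbp, glcm=cfg.glcm,
            fch=FCHConfig(n_bins=cfg.fch.n_bins, m=cfg.fch.m, seed=cfg.fch.seed,
                          bin_centers=default_fch_centers(cfg.fch)),
        )
    values = np.stack([handcrafted_vector(img, cfg) for img in images])
    return FeatureMatrix(values=values, labels=np.asarray(labels),
                         feature_names=handcrafted_feature_names(cfg),
                         source_tag="handcrafted")
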