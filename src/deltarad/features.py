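"""The 255-entry per-lesion delta-radiomics feature vector.

Per phase volume (pre, post1, post2, post3) within the tumor mask:

* 4 first-order histogram features: mean, sd, kurtosis, skewness;
* 5 Haralick features (energy, entropy, correlation, contrast, homogeneity)
  from a pooled 3-D gray-level co-occurrence matrix;
* 2 Gabor edge summaries (mean response magnitude at 0 and 90 degrees,
  bandwidth 1.414);
* 10 Haralick features computed on the two Gabor magnitude maps;

21 features per phase, 84 per exam, plus one intra-tumor cluster entropy
per exam = 85.  Both exams give 170, and 85 deltas (post-treatment minus
pre-treatment) complete the 255-entry vector.  Names follow
``{timing}_{phase}_{feature}`` with timing in {bef, af, diff}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage.filters import gabor_kernel
from sklearn.cluster import KMeans

from .core import PHASE_NAMES, TIMING_AFTER, TIMING_BEFORE, DCESeries, TumorMask

#: 13 unique 3-D direction vectors at chessboard distance 1 (half of the
#: 26-neighborhood; co-occurrences are accumulated symmetrically).
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off
    for off in product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)

HARALICK_NAMES = ("energy", "entropy", "correlation", "contrast", "homogeneity")

#: Canonical per-phase feature order: 4 first-order + 5 Haralick + 2 Gabor
#: edge summaries + 10 Haralick-on-Gabor = 21.
PER_PHASE_FEATURES: tuple[str, ...] = (
    "mean", "sd", "kurtosis", "skewness",
    *HARALICK_NAMES,
    "gab0", "gab90",
    *(f"gab0_{h}" for h in HARALICK_NAMES),
    *(f"gab90_{h}" for h in HARALICK_NAMES),
)


@dataclass
class TextureConfig:
    """Texture-feature extraction parameters.

    ``gabor_bandwidth`` and ``gabor_angles`` are fixed by the feature
    scheme (bandwidth 1.414, angles 0 and 90 degrees); the remaining knobs
    are implementation choices.
    """

    glcm_levels: int = 32
    gabor_bandwidth: float = 1.414
    gabor_frequency: float = 0.25       #: cycles per voxel, axial plane
    gabor_angles: tuple[float, float] = (0.0, 90.0)
    cluster_count_range: tuple[int, int] = (1, 6)
    local_window: int = 3               #: sliding-window size for local textures
    local_levels: int = 8               #: gray levels for local windows
    cluster_max_voxels: int = 250       #: subsample cap for spectral clustering
    cluster_phase: int = 1              #: phase used for cluster entropy (post1)
    random_state: int = 0

    def __post_init__(self) -> None:
        if len(self.gabor_angles) != 2:
            raise ValueError("exactly two Gabor angles are required")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")


def feature_names(timing: str) -> list[str]:
    """The 85 canonical feature names of one exam timing."""
    names = [
        f"{timing}_{phase}_{feat}"
        for phase in PHASE_NAMES
        for feat in PER_PHASE_FEATURES
    ]
    names.append(f"{timing}_clusterentropy")
    return names


def all_feature_names() -> list[str]:
    """The canonical 255-entry feature name list (bef, af, diff blocks)."""
    return (
        feature_names(TIMING_BEFORE)
        + feature_names(TIMING_AFTER)
        + feature_names("diff")
    )


def intensity_feature_names() -> list[str]:
    """The 12 MRI mean-intensity features excluded from model variant 3."""
    return [
        f"{timing}_{phase}_mean"
        for timing in (TIMING_BEFORE, TIMING_AFTER, "diff")
        for phase in PHASE_NAMES
    ]


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean, sd, kurtosis and skewness of the masked intensities.

    Sample standard deviation (ddof=1); excess (Fisher) kurtosis.  For a
    degenerate (constant) region skewness and kurtosis are returned as 0.
    """
    v = np.asarray(volume, dtype=float)[np.asarray(mask, dtype=bool)]
    if v.size < 4:
        raise ValueError("mask must contain at least 4 voxels")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(_skew(v))
        kurt = float(_kurtosis(v, fisher=True))
    return {"mean": float(v.mean()), "sd": sd, "kurtosis": kurt, "skewness": skew}


# ---------------------------------------------------------------------------
# co-occurrence matrix and Haralick features
# ---------------------------------------------------------------------------

def quantize(volume: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization of masked intensities into ``levels`` bins."""
    v = np.asarray(volume, dtype=float)
    m = np.asarray(mask, dtype=bool)
    q = np.zeros(v.shape, dtype=np.int64)
    vals = v[m]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q[m] = np.minimum(
            ((v[m] - lo) / (hi - lo) * levels).astype(np.int64), levels - 1
        )
    return q


def glcm(
    volume: np.ndarray, mask: np.ndarray, config: TextureConfig | None = None
) -> np.ndarray:
    """Pooled symmetric 3-D gray-level co-occurrence matrix.

    Masked intensities are min-max quantized; co-occurrences over the 13
    unique distance-1 directions (both orderings) are accumulated into a
    single matrix restricted to voxel pairs lying inside the mask, then
    normalized to sum to 1.
    """
    config = config or TextureConfig()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    L = config.glcm_levels
    q = quantize(volume, m, L)
    counts = _accumulate_pairs(q, m, L, GLCM_OFFSETS)
    total = counts.sum()
    if total == 0:
        # no in-mask pairs (e.g. a single isolated voxel): degenerate matrix
        lvl = int(q[m][0])
        counts[lvl, lvl] = 1.0
        total = 1.0
    return counts / total


def _accumulate_pairs(q, valid, levels, offsets) -> np.ndarray:
    counts = np.zeros(levels * levels, dtype=np.float64)
    for off in offsets:
        src, dst = _offset_slices(q.shape, off)
        ok = valid[src] & valid[dst]
        if not ok.any():
            continue
        a = q[src][ok]
        b = q[dst][ok]
        counts += np.bincount(a * levels + b, minlength=levels * levels)
        counts += np.bincount(b * levels + a, minlength=levels * levels)
    return counts.reshape(levels, levels)


def _offset_slices(shape, off):
    src, dst = [], []
    for o, s in zip(off, shape):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def haralick5(P: np.ndarray) -> dict[str, float]:
    """Energy, entropy, correlation, contrast and homogeneity of a GLCM.

    * energy       = sum p^2
    * entropy      = -sum p log2 p  (0 log 0 := 0)
    * contrast     = sum (i - j)^2 p
    * homogeneity  = sum p / (1 + |i - j|)
    * correlation  = sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j),
      defined as 0 when either marginal variance vanishes.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    nz = P > 0
    energy = float((P**2).sum())
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * P).sum()) / np.sqrt(var_i * var_j)
        )
    return {
        "energy": energy,
        "entropy": entropy,
        "correlation": correlation,
        "contrast": contrast,
        "homogeneity": homogeneity,
    }


# ---------------------------------------------------------------------------
# Gabor edge features
# ---------------------------------------------------------------------------

_KERNEL_CACHE: dict[tuple[float, float, float], tuple[np.ndarray, np.ndarray]] = {}


def _gabor_kernels(frequency: float, angle_deg: float, bandwidth: float):
    key = (frequency, angle_deg, bandwidth)
    if key not in _KERNEL_CACHE:
        k = gabor_kernel(
            frequency, theta=np.deg2rad(angle_deg), bandwidth=bandwidth
        )
        kr = np.real(k)
        kr = kr - kr.sum() / kr.size  # zero DC: constant input gives no edge response
        _KERNEL_CACHE[key] = (kr, np.imag(k))
    return _KERNEL_CACHE[key]


def gabor_magnitude(
    volume: np.ndarray, angle_deg: float, config: TextureConfig
) -> np.ndarray:
    """Slice-wise Gabor response magnitude map (axial plane, reflect-padded)."""
    kr, ki = _gabor_kernels(config.gabor_frequency, angle_deg, config.gabor_bandwidth)
    out = np.empty_like(np.asarray(volume, dtype=float))
    for z in range(volume.shape[2]):
        sl = volume[:, :, z].astype(float)
        re = ndimage.convolve(sl, kr, mode="reflect")
        im = ndimage.convolve(sl, ki, mode="reflect")
        out[:, :, z] = np.hypot(re, im)
    return out


def gabor_features(
    volume: np.ndarray, mask: np.ndarray, config: TextureConfig | None = None
) -> dict[str, float]:
    """12 Gabor features: 2 edge summaries + 10 Haralick-on-Gabor.

    For each of the two angles the filter magnitude map is computed
    slice-wise in the axial plane; the edge summary is the mean magnitude
    within the mask, and the 5 Haralick features are computed from the
    quantized magnitude map.
    """
    config = config or TextureConfig()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    bbox = ndimage.find_objects(m.astype(np.int8))[0]
    kr, _ = _gabor_kernels(
        config.gabor_frequency, config.gabor_angles[0], config.gabor_bandwidth
    )
    in_plane = (bbox[0].stop - bbox[0].start, bbox[1].stop - bbox[1].start)
    if min(in_plane) < max(kr.shape):
        warnings.warn(
            "mask is thinner than the Gabor filter support; "
            "responses rely on reflective padding",
            stacklevel=2,
        )
    sub_vol = np.asarray(volume, dtype=float)[bbox]
    sub_mask = m[bbox]
    out: dict[str, float] = {}
    for angle in config.gabor_angles:
        tag = f"gab{int(round(angle))}"
        mag = gabor_magnitude(sub_vol, angle, config)
        out[tag] = float(mag[sub_mask].mean())
        har = haralick5(glcm(mag, sub_mask, config))
        for h, val in har.items():
            out[f"{tag}_{h}"] = val
    return out


# ---------------------------------------------------------------------------
# intra-tumor cluster entropy
# ---------------------------------------------------------------------------

def _local_haralick(
    q: np.ndarray, valid: np.ndarray, centers: np.ndarray, window: int, levels: int
) -> np.ndarray:
    """5 Haralick features of the local window around each center voxel."""
    half = window // 2
    feats = np.empty((len(centers), 5))
    shape = q.shape
    for n, (x, y, z) in enumerate(centers):
        sl = tuple(
            slice(max(0, c - half), min(s, c + half + 1))
            for c, s in zip((x, y, z), shape)
        )
        counts = _accumulate_pairs(q[sl], valid[sl], levels, GLCM_OFFSETS)
        total = counts.sum()
        if total == 0:
            lvl = int(q[x, y, z])
            counts[lvl, lvl] = 1.0
            total = 1.0
        h = haralick5(counts / total)
        feats[n] = [h[k] for k in HARALICK_NAMES]
    return feats


def _self_tuning_affinity(X: np.ndarray, k: int = 7) -> np.ndarray:
    """Affinity with local scaling: A_ij = exp(-d_ij^2 / (sigma_i sigma_j))
    where sigma_i is the distance from i to its k-th nearest neighbor.

    Coincident points (distance 0) carry no scale information, so sigma is
    taken from the k-th nearest neighbor at *positive* distance; otherwise
    duplicated feature rows would drive sigma to zero and disconnect every
    distinct value into its own clique.
    """
    D = squareform(pdist(X))
    n = len(X)
    kk = min(k, n - 1)
    pos = np.where(D > 1e-12, D, np.inf)
    sorted_pos = np.sort(pos, axis=1)
    sigma = sorted_pos[:, kk - 1]
    short = ~np.isfinite(sigma)
    if short.any():
        largest = np.where(np.isfinite(sorted_pos), sorted_pos, 0.0).max(axis=1)
        sigma[short] = largest[short]
    sigma = np.maximum(sigma, 1e-12)
    A = np.exp(-(D**2) / np.outer(sigma, sigma))
    np.fill_diagonal(A, 0.0)
    return A


def _eigengap_k(A: np.ndarray, k_range: tuple[int, int]) -> tuple[int, np.ndarray]:
    """Cluster count by the largest eigengap of the normalized Laplacian."""
    d = A.sum(axis=1)
    d = np.maximum(d, 1e-12)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(len(A)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    evals, evecs = eigh(L)
    k_min, k_max = k_range
    k_max = min(k_max, len(A) - 1)
    gaps = {k: evals[k] - evals[k - 1] for k in range(max(1, k_min), k_max + 1)}
    best_k = max(gaps, key=gaps.get)
    return best_k, evecs


def cluster_entropy(
    series: DCESeries,
    mask: np.ndarray | TumorMask,
    config: TextureConfig | None = None,
) -> float:
    """Shannon entropy of texture-homogeneous intra-tumor sub-regions.

    Per-voxel local Haralick features (5 textures over a sliding window)
    are clustered with self-tuning spectral clustering (local scaling,
    cluster count by eigengap); the statistic is the entropy of the
    cluster-size proportions, ``-sum (n_k/n) log2 (n_k/n)``.  A homogeneous
    tumor yields a single cluster and entropy 0.  For large tumors a
    seed-controlled subsample of voxels is clustered.
    """
    config = config or TextureConfig()
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if m.sum() < config.local_window**3:
        raise ValueError(
            f"mask must contain at least local_window^3 = "
            f"{config.local_window**3} voxels"
        )
    bbox = ndimage.find_objects(m.astype(np.int8))[0]
    vol = np.asarray(series.phase(config.cluster_phase), dtype=float)[bbox]
    sub_mask = m[bbox]
    q = quantize(vol, sub_mask, config.local_levels)

    rng = np.random.default_rng(config.random_state)
    centers = np.argwhere(sub_mask)
    if len(centers) > config.cluster_max_voxels:
        idx = rng.choice(len(centers), config.cluster_max_voxels, replace=False)
        centers = centers[np.sort(idx)]

    X = _local_haralick(q, sub_mask, centers, config.local_window, config.local_levels)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return 0.0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    if np.max(pdist(X)) < 1e-10:
        return 0.0
    A = _self_tuning_affinity(X)
    k, evecs = _eigengap_k(A, config.cluster_count_range)
    if k <= 1:
        return 0.0
    emb = evecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=config.random_state)
    labels = km.fit_predict(emb)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# per-exam and per-lesion assembly
# ---------------------------------------------------------------------------

def phase_features(
    volume: np.ndarray, mask: np.ndarray, config: TextureConfig | None = None
) -> dict[str, float]:
    """The 21 per-phase features in canonical order."""
    config = config or TextureConfig()
    out = dict(first_order(volume, mask))
    out.update(haralick5(glcm(volume, mask, config)))
    out.update(gabor_features(volume, mask, config))
    return {name: out[name] for name in PER_PHASE_FEATURES}


def exam_features(
    series: DCESeries,
    mask: np.ndarray | TumorMask,
    config: TextureConfig | None = None,
) -> dict[str, float]:
    """The 85 features of one exam: 21 per phase + 1 cluster entropy.

    Names carry the exam's timing prefix (``bef`` or ``af``).
    """
    config = config or TextureConfig()
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    timing = series.exam_timing
    out: dict[str, float] = {}
    for phase in PHASE_NAMES:
        vol = series.phase(phase)
        for feat, val in phase_features(vol, m, config).items():
            out[f"{timing}_{phase}_{feat}"] = val
    # a region too small to support the sliding window has no sub-regional
    # heterogeneity: its cluster entropy is 0 by convention
    if m.sum() < config.local_window**3:
        out[f"{timing}_clusterentropy"] = 0.0
    else:
        out[f"{timing}_clusterentropy"] = cluster_entropy(series, m, config)
    assert list(out) == feature_names(timing)
    return out


def assemble_lesion_vector(
    pre_feats: dict[str, float], post_feats: dict[str, float]
) -> dict[str, float]:
    """Combine pre-/post-treatment exam features and their deltas.

    ``diff_x = af_x - bef_x`` for each of the 85 per-exam features, giving
    the canonical 255-entry vector.
    """
    bef_names = feature_names(TIMING_BEFORE)
    af_names = feature_names(TIMING_AFTER)
    if list(pre_feats) != bef_names or list(post_feats) != af_names:
        raise ValueError("feature names do not match the canonical exam layout")
    out = dict(pre_feats)
    out.update(post_feats)
    for b, a in zip(bef_names, af_names):
        out["diff" + b[len(TIMING_BEFORE):]] = post_feats[a] - pre_feats[b]
    if not all(np.isfinite(v) for v in out.values()):
        raise ValueError("non-finite feature value")
    assert list(out) == all_feature_names()
    return out


def extract_lesion_features(
    pre_exam: DCESeries,
    post_exam: DCESeries,
    mask_pre: np.ndarray | TumorMask,
    mask_post: np.ndarray | TumorMask,
    config: TextureConfig | None = None,
) -> dict[str, float]:
    """Full 255-entry feature vector of one lesion from its two exams."""
    return assemble_lesion_vector(
        exam_features(pre_exam, mask_pre, config),
        exam_features(post_exam, mask_post, config),
    )
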