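"""Per-voxel 57-feature texture descriptors for the EZ slab, and PCA reduction.

Five feature families per VOI voxel, in a fixed column order:

====  =======================================================================
cols  feature
====  =======================================================================
1     normalized intensity (min-max over the volume's VOI voxels)
2     5x5x5 block mean
3     5x5x5 block standard deviation (population)
4-5   mean absolute intensity difference over the 13 directions, step 1 and 2
6-18  3D GLCM contrast, one per direction
19-31 3D GLCM correlation
32-44 3D GLCM energy
45-57 3D GLCM homogeneity
====  =======================================================================

The 13 directions are the half-axes of the 26-neighbourhood, parameterized
by ``(alpha1, alpha2)`` where ``alpha1`` is the angle between the X-axis and
the direction's X–Y-plane projection and ``alpha2`` the angle from the
Z-axis (``alpha2 = 90°`` is in-plane, ``alpha2 = 0`` is pure z).

GLCMs are built per 5x5x5 block (cropped at volume borders) at offset
distance one grid step, accumulated symmetrically and normalized to
probabilities; grey levels are ``n_levels`` equal bins of the VOI-normalized
intensity.  All features are computed on the normalized intensity volume;
feature standardization inside :func:`fit_pca` makes the affine choice
immaterial downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA

from .volume_model import OCTVolume, VoxelMask

__all__ = [
    "N_FEATURES",
    "N_DIRECTIONS",
    "direction_offsets",
    "normalize_intensity",
    "block_stats",
    "abs_diff_feature",
    "glcm",
    "glcm_props",
    "FeatureMatrix",
    "extract_features",
    "PcaModel",
    "fit_pca",
    "apply_pca",
]

N_FEATURES = 57
N_DIRECTIONS = 13
_BLOCK_RADIUS = 2  # 5x5x5 blocks

#: (alpha1, alpha2) in degrees.  The first twelve pairs are the classic
#: listing; the thirteenth, (-45, 45), completes the 26-neighbourhood
#: half-axes (it is the unique half-axis the twelve leave uncovered).
_ANGLE_PAIRS = (
    (0, 90), (45, 90), (90, 90), (135, 90),
    (0, 45), (180, 45), (90, 45), (-90, 45),
    (0, 0), (45, 45), (135, 45), (-135, 45),
    (-45, 45),
)


def direction_offsets() -> list:
    """The 13 co-occurrence direction offsets as integer (dx, dy, dz) triples.

    Pairwise neither equal nor antiparallel; together with their negations
    they cover the full 26-neighbourhood.
    """
    offsets = []
    for a1, a2 in _ANGLE_PAIRS:
        r1, r2 = np.deg2rad(a1), np.deg2rad(a2)
        vec = (np.sin(r2) * np.cos(r1), np.sin(r2) * np.sin(r1), np.cos(r2))
        offsets.append(tuple(int(np.sign(v)) if abs(v) > 0.25 else 0 for v in vec))
    assert len(set(offsets)) == N_DIRECTIONS
    for i, a in enumerate(offsets):
        for b in offsets[i + 1:]:
            assert a != tuple(-c for c in b), "antiparallel directions"
    return offsets


def normalize_intensity(values) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant input maps to all zeros."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _block_slices(centre, shape, radius=_BLOCK_RADIUS):
    return tuple(
        slice(max(0, c - radius), min(n, c + radius + 1))
        for c, n in zip(centre, shape)
    )


def block_stats(vol, centre, radius: int = _BLOCK_RADIUS):
    """Mean and population std of the (edge-cropped) block around ``centre``."""
    arr = vol.intensities if isinstance(vol, OCTVolume) else np.asarray(vol, float)
    block = arr[_block_slices(tuple(centre), arr.shape, radius)]
    return float(block.mean()), float(block.std())


def abs_diff_feature(vol, centre, step: int) -> float:
    """Mean |I(v) - I(v + step*d)| over the 13 directions, neighbours clamped."""
    arr = vol.intensities if isinstance(vol, OCTVolume) else np.asarray(vol, float)
    c = np.asarray(centre)
    total = 0.0
    for d in direction_offsets():
        nb = np.clip(c + step * np.asarray(d), 0, np.asarray(arr.shape) - 1)
        total += abs(arr[tuple(c)] - arr[tuple(nb)])
    return total / N_DIRECTIONS


def glcm(block, direction, n_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of a quantized block.

    Pairs at offset ``direction`` (one grid step) with both members inside
    the block are accumulated in both orientations and normalized to sum 1.
    A block/direction with no interior pairs yields the all-zero matrix
    (the degenerate flag).
    """
    block = np.asarray(block)
    if block.min() < 0 or block.max() >= n_levels:
        raise ValueError("block levels must lie in [0, n_levels)")
    d = np.asarray(direction, dtype=int)
    counts = np.zeros((n_levels, n_levels))
    for p in itertools.product(*(range(n) for n in block.shape)):
        q = tuple(np.asarray(p) + d)
        if all(0 <= qi < ni for qi, ni in zip(q, block.shape)):
            a, b = int(block[p]), int(block[q])
            counts[a, b] += 1
            counts[b, a] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_props(p: np.ndarray):
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM.

    The all-zero (degenerate) matrix maps to the constant-block convention
    ``(0, 0, 1, 1)``; any other non-normalized input is an error.
    Correlation of a zero-variance GLCM is defined as 0.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total == 0:
        return 0.0, 0.0, 1.0, 1.0
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"GLCM not normalized: sums to {total}")
    n = p.shape[0]
    g = np.arange(n, dtype=float)
    dx = g[:, None] - g[None, :]
    contrast = float((p * dx**2).sum())
    homogeneity = float((p / (1.0 + np.abs(dx))).sum())
    energy = float((p**2).sum())
    px, py = p.sum(axis=1), p.sum(axis=0)
    mx, my = (px * g).sum(), (py * g).sum()
    sx = np.sqrt((px * (g - mx) ** 2).sum())
    sy = np.sqrt((py * (g - my) ** 2).sum())
    if sx * sy <= 0:
        corr = 0.0
    else:
        corr = float(((g[:, None] - mx) * (g[None, :] - my) * p).sum() / (sx * sy))
    return contrast, corr, energy, homogeneity


@dataclass
class FeatureMatrix:
    """Per-voxel descriptors: ``values[i]`` belongs to voxel ``voxel_indices[i]``."""

    values: np.ndarray          # (n, 57)
    voxel_indices: np.ndarray   # (n, 3) int, x-major ordering
    columns: list

    def __post_init__(self):
        if self.values.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} columns, got {self.values.shape[1]}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _column_names():
    names = ["f01_norm_intensity", "f02_block_mean", "f03_block_std",
             "f04_absdiff_step1", "f05_absdiff_step2"]
    k = 6
    for prop in ("contrast", "correlation", "energy", "homogeneity"):
        for j in range(N_DIRECTIONS):
            names.append(f"f{k:02d}_glcm_{prop}_d{j:02d}")
            k += 1
    return names


def _pair_offsets(d, radius=_BLOCK_RADIUS):
    """Window-relative first-member offsets o with both o and o+d in the block."""
    ranges = []
    for dd in d:
        ranges.append(range(-radius + max(0, -dd), radius - max(0, dd) + 1))
    return np.array(list(itertools.product(*ranges)), dtype=int)


def extract_features(vol: OCTVolume, voi: VoxelMask, n_levels: int = 8,
                     absdiff_agg: str = "mean") -> FeatureMatrix:
    """Compute the full 57-feature descriptor for every VOI voxel.

    Vectorized over voxels; identical, voxel-by-voxel, to the per-operation
    definitions (:func:`block_stats`, :func:`abs_diff_feature`,
    :func:`glcm` + :func:`glcm_props`) applied to the normalized volume.
    """
    if voi.shape != vol.shape:
        raise ValueError("VOI shape does not match volume shape")
    coords = np.argwhere(voi.values)
    if coords.shape[0] == 0:
        raise ValueError("empty VOI")
    I = vol.intensities
    voi_vals = I[voi.values]
    lo, hi = voi_vals.min(), voi_vals.max()
    norm = (I - lo) / (hi - lo) if hi - lo > 0 else np.zeros_like(I)

    n = coords.shape[0]
    cx, cy, cz = coords[:, 0], coords[:, 1], coords[:, 2]
    out = np.empty((n, N_FEATURES))
    out[:, 0] = norm[cx, cy, cz]

    # block mean / std via NaN-padded sliding windows (edge blocks cropped)
    r = _BLOCK_RADIUS
    padded = np.pad(norm, r, mode="constant", constant_values=np.nan)
    windows = sliding_window_view(padded, (2 * r + 1,) * 3)[cx, cy, cz]
    flat = windows.reshape(n, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out[:, 1] = np.nanmean(flat, axis=1)
        out[:, 2] = np.nanstd(flat, axis=1)

    dirs = np.asarray(direction_offsets())
    shape = np.asarray(vol.shape)
    agg = {"mean": np.mean, "max": np.max, "sum": np.sum}[absdiff_agg]
    for col, step in ((3, 1), (4, 2)):
        nb = np.clip(coords[:, None, :] + step * dirs[None, :, :], 0, shape - 1)
        nbv = norm[nb[..., 0], nb[..., 1], nb[..., 2]]
        out[:, col] = agg(np.abs(out[:, 0:1] - nbv), axis=1)

    # quantize for the GLCMs: n_levels equal bins over the VOI's [0, 1] range
    q = np.minimum((np.clip(norm, 0.0, 1.0) * n_levels).astype(np.int64),
                   n_levels - 1)
    qpad = np.pad(q, r, mode="constant", constant_values=-1)

    L = n_levels
    g = np.arange(L, dtype=float)
    dlev = g[:, None] - g[None, :]
    w_con = dlev**2
    w_hom = 1.0 / (1.0 + np.abs(dlev))

    for j, d in enumerate(direction_offsets()):
        offs = _pair_offsets(d)
        ia = coords[:, None, :] + r + offs[None, :, :]
        ib = ia + np.asarray(d)[None, None, :]
        A = qpad[ia[..., 0], ia[..., 1], ia[..., 2]]
        B = qpad[ib[..., 0], ib[..., 1], ib[..., 2]]
        valid = (A >= 0) & (B >= 0)
        code = np.where(valid, A * L + B, L * L)
        flat_codes = (np.arange(n)[:, None] * (L * L + 1) + code).ravel()
        counts = np.bincount(flat_codes, minlength=n * (L * L + 1))
        counts = counts.reshape(n, L * L + 1)[:, : L * L].reshape(n, L, L)
        csym = (counts + counts.transpose(0, 2, 1)).astype(float)
        tot = csym.sum(axis=(1, 2))
        deg = tot == 0
        P = csym / np.where(deg, 1.0, tot)[:, None, None]

        contrast = (P * w_con).sum(axis=(1, 2))
        homog = (P * w_hom).sum(axis=(1, 2))
        energy = (P**2).sum(axis=(1, 2))
        px = P.sum(axis=2)
        py = P.sum(axis=1)
        mx = (px * g).sum(axis=1)
        my = (py * g).sum(axis=1)
        vx = (px * (g[None, :] - mx[:, None]) ** 2).sum(axis=1)
        vy = (py * (g[None, :] - my[:, None]) ** 2).sum(axis=1)
        cov = (
            P
            * (g[None, :, None] - mx[:, None, None])
            * (g[None, None, :] - my[:, None, None])
        ).sum(axis=(1, 2))
        sd = np.sqrt(vx * vy)
        corr = np.where(sd > 0, cov / np.where(sd > 0, sd, 1.0), 0.0)

        out[:, 5 + j] = np.where(deg, 0.0, contrast)
        out[:, 18 + j] = np.where(deg, 0.0, corr)
        out[:, 31 + j] = np.where(deg, 1.0, energy)
        out[:, 44 + j] = np.where(deg, 1.0, homog)

    return FeatureMatrix(out, coords, _column_names())


@dataclass
class PcaModel:
    """Standardization + first-10-components projection fitted on training voxels."""

    mean: np.ndarray                  # (57,)
    scale: np.ndarray                 # (57,)
    components: np.ndarray            # (10, 57), orthonormal rows
    explained_variance_ratio: np.ndarray  # (10,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(X: np.ndarray, n_components: int = 10) -> PcaModel:
    """Standardize features then fit PCA, keeping the first 10 components.

    Zero-variance columns pass through as zeros.  Warns if the kept
    components explain less than 90% of the (standardized) variance.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples to fit PCA, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    if evr.sum() < 0.90:
        warnings.warn(
            f"first {n_components} components explain only {evr.sum():.1%} "
            "of the variance (< 90%)",
            stacklevel=2,
        )
    return PcaModel(mean, scale, pca.components_.copy(), evr.copy())


def apply_pca(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project feature rows onto the model's principal components."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    return (X - model.mean) / model.scale @ model.components.T
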