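"""Pre-processing: denoise, segment 11 surfaces, smooth, flatten, extract the EZ VOI.

Denoising
    Each B-scan (X–Z slice) is smoothed independently by a fast bilateral
    filter — the classic range-sample approximation: the bilateral response
    is computed exactly on a small set of intensity samples (spacing a
    fraction of ``sigma_range``), each via two Gaussian convolutions, and
    pixels are linearly interpolated between the two bracketing samples.
    An optional spatial grid-downsampling factor trades accuracy for speed.

Surface segmentation
    Eleven ordered surfaces found one at a time by coarse-to-fine
    column-wise dynamic programming on a polarity-signed axial-gradient
    cost, with a per-column smoothness bound and hard min-separation bounds
    from the surfaces already found (search order: surface 1, surface 11,
    then 2..10 inside the established band).  This is a deliberately simple
    stand-in for full multi-scale 3D graph search with the same contract:
    smooth, strictly ordered surfaces.

Thin-plate-spline smoothing fits each surface on a subsampled knot grid
(knot values are local window means) and evaluates the spline on the full
grid; flattening shifts whole A-scans by integers so that surface 11 sits
at a common reference depth.  The EZ volume of interest is the half-open
slab ``[round(z7), round(z8))`` per column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import gaussian_filter, maximum_filter1d, uniform_filter, zoom

from .volume_model import OCTVolume, SurfaceSet, VoxelMask, round_half_deep

__all__ = [
    "BilateralParams",
    "GraphSearchParams",
    "bilateral_filter_volume",
    "segment_surfaces",
    "smooth_surfaces_tps",
    "flatten",
    "flatten_shifts",
    "shift_mask",
    "extract_voi",
]

_NEG = -1.0e15

#: Default gradient polarity of each surface for the package's layer model:
#: +1 where intensity increases with depth across the boundary
#: (dark-to-bright), -1 for bright-to-dark.
DEFAULT_POLARITY = (1, -1, 1, -1, 1, -1, 1, -1, 1, 1, -1)


@dataclass
class BilateralParams:
    """Fast-bilateral parameters.

    ``sigma_range=None`` adapts per slice to 10% of the slice dynamic range.
    ``spatial_factor``/``range_factor`` are the grid downsampling factors of
    the fast approximation (1 = finest); the range-sample spacing is
    ``range_factor * sigma_range / 2``.
    """

    sigma_spatial: float = 3.0
    sigma_range: float | None = None
    spatial_factor: int = 1
    range_factor: float = 1.0

    def __post_init__(self):
        if self.sigma_spatial <= 0:
            raise ValueError("sigma_spatial must be > 0")
        if self.sigma_range is not None and self.sigma_range <= 0:
            raise ValueError("sigma_range must be > 0")
        if self.spatial_factor < 1 or self.range_factor < 1:
            raise ValueError("downsampling factors must be >= 1")


@dataclass
class GraphSearchParams:
    """Surface-search parameters.

    smoothness
        Maximum |dz| (voxels) between adjacent columns within a B-scan.
    min_separation / max_separation
        Axial separation bounds (voxels) between consecutive surfaces;
        scalars apply to every layer, or a 10-tuple gives per-layer bounds
        (``max_separation=None`` leaves the upper side unconstrained).  The
        default caps each layer near its anatomical thickness — the EZ slab
        in particular is only a few voxels thick, which keeps surface 8 from
        drifting into the outer retina where disruption erases its gradient.
    levels
        Multi-resolution levels (1 = single full-resolution pass; coarser
        levels are lateral downsamplings).
    polarity
        11 signs, the expected axial gradient direction per surface.
    """

    smoothness: int = 2
    min_separation: int = 2
    max_separation: int | tuple | None = (12, 10, 11, 10, 10, 16, 8, 9, 9, 12)
    levels: int = 2
    polarity: tuple = DEFAULT_POLARITY

    def __post_init__(self):
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.polarity) != 11 or any(p not in (-1, 1) for p in self.polarity):
            raise ValueError("polarity must be 11 signs in {-1, +1}")
        if self.max_separation is not None and np.ndim(self.max_separation) == 1:
            if len(self.max_separation) != 10:
                raise ValueError("per-layer max_separation needs 10 entries")

    def max_sep_of(self, layer: int):
        """Upper separation bound across ``layer`` (0-based), or None."""
        if self.max_separation is None:
            return None
        if np.ndim(self.max_separation) == 0:
            return int(self.max_separation)
        return int(self.max_separation[layer])


# ---------------------------------------------------------------------------
# Bilateral filtering
# ---------------------------------------------------------------------------

def _bilateral_slice(img: np.ndarray, p: BilateralParams) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return img.copy()
    sigma_r = p.sigma_range if p.sigma_range is not None else 0.1 * (hi - lo)
    step = sigma_r * p.range_factor / 2.0
    n_samples = int(np.ceil((hi - lo) / step)) + 1
    samples = lo + np.arange(n_samples + 1) * step  # one past hi for interpolation

    f = p.spatial_factor
    responses = np.empty((n_samples + 1,) + img.shape)
    for k, r in enumerate(samples):
        w = np.exp(-((img - r) ** 2) / (2.0 * sigma_r**2))
        if f == 1:
            num = gaussian_filter(w * img, p.sigma_spatial, mode="constant")
            den = gaussian_filter(w, p.sigma_spatial, mode="constant")
        else:
            num = gaussian_filter((w * img)[::f, ::f], p.sigma_spatial / f,
                                  mode="constant")
            den = gaussian_filter(w[::f, ::f], p.sigma_spatial / f, mode="constant")
            scale = (img.shape[0] / num.shape[0], img.shape[1] / num.shape[1])
            num = zoom(num, scale, order=1, grid_mode=True, mode="nearest")
            den = zoom(den, scale, order=1, grid_mode=True, mode="nearest")
        responses[k] = num / np.maximum(den, 1e-300)

    pos = (img - lo) / step
    k0 = np.clip(np.floor(pos).astype(int), 0, n_samples - 1)
    frac = pos - k0
    out = np.take_along_axis(responses, k0[None], axis=0)[0] * (1 - frac) \
        + np.take_along_axis(responses, (k0 + 1)[None], axis=0)[0] * frac
    # convex-combination contract: never widen the slice's range
    return np.clip(out, lo, hi)


def bilateral_filter_volume(vol: OCTVolume, p: BilateralParams | None = None
                            ) -> OCTVolume:
    """Denoise each B-scan (X–Z slice) independently by fast bilateral filtering."""
    if p is None:
        p = BilateralParams()
    I = vol.intensities
    if not np.all(np.isfinite(I)):
        raise ValueError("bilateral filter: non-finite intensities")
    out = np.empty_like(I)
    for y in range(vol.ny):
        out[:, y, :] = _bilateral_slice(I[:, y, :], p)
    return OCTVolume(out, vol.voxel_size_um, id=vol.id)


# ---------------------------------------------------------------------------
# Surface segmentation
# ---------------------------------------------------------------------------

def _dp_path(cost: np.ndarray, lo: np.ndarray, hi: np.ndarray, bound: int):
    """Max-sum path z(x) with |z(x+1) - z(x)| <= bound and lo <= z <= hi.

    ``cost`` is (nx, nz); ``lo``/``hi`` are per-column inclusive bounds.
    Returns (path, total_cost).  Raises if no feasible path exists.
    """
    nx, nz = cost.shape
    z = np.arange(nz)
    valid = (z[None, :] >= lo[:, None]) & (z[None, :] <= hi[:, None])
    if not valid.any(axis=1).all():
        raise ValueError("surface search infeasible: empty z-band in some column")
    C = np.where(valid, cost, _NEG)
    dp = np.empty((nx, nz))
    dp[0] = C[0]
    size = 2 * bound + 1
    for i in range(1, nx):
        m = maximum_filter1d(dp[i - 1], size=size, mode="constant", cval=_NEG)
        dp[i] = np.where(C[i] > _NEG / 2, C[i] + m, _NEG)
    zi = int(np.argmax(dp[-1]))
    total = dp[-1, zi]
    if total < _NEG / 2:
        raise ValueError(
            "surface search infeasible: smoothness bound incompatible with "
            "the separation constraints"
        )
    path = np.empty(nx, dtype=int)
    path[-1] = zi
    for i in range(nx - 2, -1, -1):
        a = max(0, path[i + 1] - bound)
        b = min(nz, path[i + 1] + bound + 1)
        path[i] = a + int(np.argmax(dp[i, a:b]))
    return path, float(total)


def _gradient_cost(I: np.ndarray, polarity: int) -> np.ndarray:
    g = np.empty_like(I)
    g[..., 1:] = I[..., 1:] - I[..., :-1]
    g[..., 0] = 0.0
    return polarity * g


def _downsample_x(I: np.ndarray) -> np.ndarray:
    # lateral (x) downsampling only: halving z would smear sharp axial
    # gradient steps by an amount that depends on their parity
    nx = I.shape[0]
    I = I[: nx - nx % 2]
    return 0.5 * (I[0::2] + I[1::2])


def _find_surface(pyramid, polarity, lo2d, hi2d, p: GraphSearchParams):
    """Coarse-to-fine DP for one surface.  Bounds are (nx, ny) int arrays."""
    n_levels = len(pyramid)
    est = None  # (nx_l, ny) estimate from the coarser level
    for level in range(n_levels - 1, -1, -1):
        I = pyramid[level]
        nx_l, ny, nz_l = I.shape
        f = 2**level
        lo = np.clip(lo2d[: nx_l * f : f], 0, nz_l - 1)
        hi = np.clip(hi2d[: nx_l * f : f], 0, nz_l - 1)
        if est is not None:
            band = 2 * p.smoothness + 2
            up = np.repeat(est, 2, axis=0)[:nx_l]
            blo = np.maximum(lo, up - band)
            bhi = np.minimum(hi, up + band)
            # where the refinement band conflicts with the ordering bounds,
            # the ordering bounds win (band is only a heuristic)
            ok = blo <= bhi
            lo = np.where(ok, blo, lo)
            hi = np.where(ok, bhi, hi)
        cost = _gradient_cost(I, polarity)
        bound = p.smoothness * f  # coarse columns are f fine columns apart
        z = np.empty((nx_l, ny), dtype=int)
        for y in range(ny):
            z[:, y], _ = _dp_path(cost[:, y, :], lo[:, y], hi[:, y], bound)
        est = z
    return est


def segment_surfaces(vol: OCTVolume, p: GraphSearchParams | None = None
                     ) -> SurfaceSet:
    """Segment the 11 retinal surfaces.

    Each surface maximizes the summed polarity-signed axial gradient along
    its columns under the smoothness bound, solved coarse-to-fine; surfaces
    already found act as hard ordering bounds (min/max separation).
    Denoising the volume first is recommended but not enforced.
    """
    if p is None:
        p = GraphSearchParams()
    I = vol.intensities
    nx, ny, nz = I.shape
    d = p.min_separation
    if 10 * d + 2 >= nz:
        raise ValueError(
            f"min_separation={d} infeasible: 10 layers need {10 * d + 2} of "
            f"{nz} axial voxels"
        )

    pyramid = [I]
    for _ in range(p.levels - 1):
        nxt = _downsample_x(pyramid[-1])
        if nxt.shape[0] < 8:
            break
        pyramid.append(nxt)

    full = np.full((nx, ny), 0, dtype=int)
    z = np.zeros((11, nx, ny), dtype=float)

    z1 = _find_surface(pyramid, p.polarity[0], full + 1, full + nz - 2 - 10 * d, p)
    z[0] = z1
    z11 = _find_surface(pyramid, p.polarity[10], z1 + 10 * d, full + nz - 2, p)
    z[10] = z11
    for s in range(1, 10):
        lo = z[s - 1].astype(int) + d
        hi = z11 - (10 - s) * d
        max_sep = p.max_sep_of(s - 1)
        if max_sep is not None:
            hi = np.minimum(hi, z[s - 1].astype(int) + max_sep)
        if np.any(lo > hi):
            raise ValueError(
                f"separation constraints infeasible for surface {s + 1}"
            )
        z[s] = _find_surface(pyramid, p.polarity[s], lo, hi.astype(int), p)
    return SurfaceSet(z)


# ---------------------------------------------------------------------------
# Thin-plate-spline smoothing
# ---------------------------------------------------------------------------

def smooth_surfaces_tps(s: SurfaceSet, regularization: float = 0.0,
                        knots: tuple = (8, 8)) -> SurfaceSet:
    """Replace each surface by a TPS fit on a subsampled knot grid.

    Knot values are means over a centred window (noise suppression); the
    spline (polynomial part of degree 1, so planes are reproduced exactly)
    is evaluated on the full grid.  ``regularization -> inf`` tends to the
    best-fit plane.  Ordering is re-imposed afterwards by minimal axial
    shifts (a running maximum over surfaces).
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    nx, ny = s.grid_shape
    kx = int(min(knots[0], nx))
    ky = int(min(knots[1], ny))
    wx = max((nx // max(kx, 1)) // 2, 0)
    wy = max((ny // max(ky, 1)) // 2, 0)
    px = np.unique(np.round(np.linspace(wx, nx - 1 - wx, kx)).astype(int))
    py = np.unique(np.round(np.linspace(wy, ny - 1 - wy, ky)).astype(int))

    sx = max(nx - 1, 1)
    sy = max(ny - 1, 1)
    kcoords = np.stack(
        [np.repeat(px, len(py)) / sx, np.tile(py, len(px)) / sy], axis=1
    )
    gx, gy = np.meshgrid(np.arange(nx) / sx, np.arange(ny) / sy, indexing="ij")
    gcoords = np.stack([gx.ravel(), gy.ravel()], axis=1)

    out = np.empty_like(s.z_of)
    for k in range(s.n_surfaces):
        surf = s.z_of[k]
        local = uniform_filter(surf, size=(2 * wx + 1, 2 * wy + 1), mode="nearest")
        vals = local[np.repeat(px, len(py)), np.tile(py, len(px))]
        rbf = RBFInterpolator(
            kcoords, vals, kernel="thin_plate_spline",
            smoothing=regularization, degree=1,
        )
        out[k] = rbf(gcoords).reshape(nx, ny)
    out = np.maximum.accumulate(out, axis=0)
    return SurfaceSet(np.maximum(out, 0.0))


# ---------------------------------------------------------------------------
# Flattening and VOI extraction
# ---------------------------------------------------------------------------

def flatten_shifts(s: SurfaceSet) -> np.ndarray:
    """Integer per-column shifts that bring surface 11 to its median depth."""
    z11 = round_half_deep(s.z_of[10])
    return z11 - int(np.median(z11))


def shift_mask(mask: VoxelMask, shifts: np.ndarray) -> VoxelMask:
    """Apply flattening shifts to a mask; voxels shifted in from outside are False."""
    nz = mask.shape[2]
    src = np.arange(nz)[None, None, :] + shifts[:, :, None]
    inside = (src >= 0) & (src < nz)
    gathered = np.take_along_axis(mask.values, np.clip(src, 0, nz - 1), axis=2)
    return VoxelMask(gathered & inside, role=mask.role)


def flatten(vol: OCTVolume, s: SurfaceSet):
    """Shift every A-scan by an integer so surface 11 lies at a common depth.

    Out-of-range voxels are padded with the A-scan's edge value.  Returns
    the flattened volume and consistently shifted surfaces; the shifts
    themselves are available via :func:`flatten_shifts` (needed to
    co-register e.g. ground-truth masks).
    """
    s.validate_for(vol)
    sh = flatten_shifts(s)
    nz = vol.nz
    idx = np.clip(np.arange(nz)[None, None, :] + sh[:, :, None], 0, nz - 1)
    flat = np.take_along_axis(vol.intensities, idx, axis=2)
    new_surf = SurfaceSet(np.clip(s.z_of - sh[None, :, :], 0.0, nz - 1))
    return OCTVolume(flat, vol.voxel_size_um, id=vol.id), new_surf


def extract_voi(vol: OCTVolume, s: SurfaceSet) -> VoxelMask:
    """EZ volume of interest: voxels with z in [round(z7), round(z8)) per column.

    Columns where the rounded surfaces coincide keep the single voxel at
    ``round(z7)`` so every column contributes at least one voxel.
    """
    s.validate_for(vol)
    nz = vol.nz
    b7 = np.clip(round_half_deep(s.z_of[6]), 0, nz - 1)
    b8 = np.clip(round_half_deep(s.z_of[7]), 0, nz)
    b8 = np.maximum(b8, b7 + 1)
    z = np.arange(nz)[None, None, :]
    mask = (z >= b7[:, :, None]) & (z < b8[:, :, None])
    return VoxelMask(mask, role="voi")
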