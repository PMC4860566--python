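"""Core containers and I/O for SD-OCT volumes, binary masks, and layer surfaces.

Coordinate convention used throughout the package
-------------------------------------------------
Arrays are indexed ``(x, y, z)``, 0-based, where

* ``x`` is the lateral position within a B-scan,
* ``y`` is the B-scan index (slow scan axis),
* ``z`` is the axial depth, increasing toward the choroid (downward in the
  usual clinical display).

A *B-scan* is the X–Z slice ``vol.intensities[:, y, :]``; an *A-scan* is the
depth profile ``vol.intensities[x, y, :]``.

Volumes are stored on disk as multipage TIFF (one page per B-scan, page
order = ``y``, page layout ``(z, x)``) or as NIfTI-1, with a JSON sidecar
``{"voxel_size_um": [dx, dy, dz], "id": "..."}`` carrying the physical voxel
size in micrometres. Intensities are read as reals without rescaling.

Layer surfaces are stored at sub-voxel (floating point) precision. Voxel
membership tests round half toward the deeper surface, i.e. ``floor(z + 0.5)``
(see :func:`round_half_deep`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "OCTVolume",
    "SurfaceSet",
    "VoxelMask",
    "EnFaceImage",
    "round_half_deep",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_surfaces",
    "write_surfaces",
    "disruption_volume",
]

N_SURFACES = 11

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def round_half_deep(z):
    """Round surface positions to voxel indices, half toward deeper ``z``.

    ``floor(z + 0.5)`` so that e.g. 9.5 -> 10 (the deeper voxel), matching
    the package-wide membership convention for sub-voxel surfaces.
    """
    return np.floor(np.asarray(z, dtype=float) + 0.5).astype(int)


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid with its physical voxel size.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Real-valued reflectivities in their native range (no rescaling).
    voxel_size_um : tuple of float
        ``(dx, dy, dz)`` in micrometres, all positive.
    id : str
        Free-form label (eye/scan identifier).
    """

    intensities: np.ndarray
    voxel_size_um: tuple
    id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (x, y, z); got ndim={self.intensities.ndim}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities: non-finite values present")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(
                f"voxel_size_um: all three sizes must be positive, got {self.voxel_size_um}"
            )

    @property
    def nx(self) -> int:
        return self.intensities.shape[0]

    @property
    def ny(self) -> int:
        return self.intensities.shape[1]

    @property
    def nz(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclass
class SurfaceSet:
    """Eleven ordered retinal surfaces over the en face grid.

    ``z_of`` has shape ``(11, nx, ny)``; ``z_of[s]`` is the sub-voxel axial
    position of surface ``s + 1`` (surface 1 the shallowest, surface 11 the
    bottom of the RPE).  Ordering ``z_of[s] <= z_of[s+1]`` is checked on
    construction.
    """

    z_of: np.ndarray

    def __post_init__(self):
        self.z_of = np.asarray(self.z_of, dtype=float)
        if self.z_of.ndim != 3 or self.z_of.shape[0] != N_SURFACES:
            raise ValueError(
                f"z_of must have shape (11, nx, ny); got {self.z_of.shape}"
            )
        if not np.all(np.isfinite(self.z_of)):
            raise ValueError("surface positions must be finite")
        if np.any(self.z_of < 0):
            raise ValueError("surface positions must be non-negative")
        diffs = np.diff(self.z_of, axis=0)
        if np.any(diffs < -1e-9):
            s = int(np.argwhere(np.min(diffs, axis=(1, 2)) < -1e-9)[0][0])
            raise ValueError(
                f"surface ordering violated between surfaces {s + 1} and {s + 2}"
            )

    @property
    def n_surfaces(self) -> int:
        return self.z_of.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.z_of.shape[1:]

    def validate_for(self, vol: OCTVolume) -> None:
        """Check en-face congruence with ``vol`` and range ``[0, nz - 1]``."""
        if self.grid_shape != (vol.nx, vol.ny):
            raise ValueError(
                f"surface grid {self.grid_shape} does not match volume en-face "
                f"shape {(vol.nx, vol.ny)}"
            )
        if np.any(self.z_of > vol.nz - 1 + 1e-9):
            raise ValueError("surface positions exceed nz - 1")

    def shifted(self, dz) -> "SurfaceSet":
        """Return a copy with all surfaces moved up by ``dz`` (scalar or (nx, ny))."""
        dz = np.asarray(dz, dtype=float)
        if dz.ndim == 2:
            dz = dz[None, :, :]
        return SurfaceSet(self.z_of - dz)


@dataclass
class VoxelMask:
    """Binary 3D mask congruent with an :class:`OCTVolume`.

    ``role`` tags intent: ``"voi"`` (the EZ slab), ``"disruption"`` (detected),
    or ``"ground_truth"``.
    """

    values: np.ndarray
    role: str = "voi"

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D; got ndim={self.values.ndim}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class EnFaceImage:
    """A 2D real image on the ``(x, y)`` en face grid."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"en face image must be 2D; got ndim={self.values.ndim}")

    @property
    def shape(self) -> tuple:
        return self.values.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _is_nifti(path: Path) -> bool:
    name = str(path)
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _read_metadata(metadata_path) -> dict:
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {metadata_path}")
    with open(metadata_path) as fh:
        meta = json.load(fh)
    if "voxel_size_um" not in meta:
        raise ValueError(f"metadata {metadata_path}: missing field voxel_size_um")
    vs = meta["voxel_size_um"]
    if len(vs) != 3 or any(float(v) <= 0 for v in vs):
        raise ValueError(
            f"metadata {metadata_path}: voxel_size_um must be three positive "
            f"reals, got {vs}"
        )
    return meta


def _array_from_file(path: Path) -> np.ndarray:
    """Load a (x, y, z) array from TIFF (pages = B-scans, page = (z, x)) or NIfTI."""
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).astype(float)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected 3D NIfTI, got ndim={arr.ndim}")
        return arr
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:  # single B-scan
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a multipage TIFF stack, got ndim={pages.ndim}")
    # pages: (ny, nz, nx) -> (nx, ny, nz)
    return np.transpose(pages, (2, 0, 1)).astype(float)


def _array_to_file(arr: np.ndarray, path: Path, voxel_size_um) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag([v / 1000.0 for v in voxel_size_um] + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))
    else:
        pages = np.transpose(np.asarray(arr, dtype=np.float64), (1, 2, 0))
        tifffile.imwrite(str(path), pages, photometric="minisblack")


def read_volume(path, metadata_path) -> OCTVolume:
    """Read an :class:`OCTVolume` from TIFF/NIfTI plus its JSON sidecar.

    Raises with the offending field named on missing files, malformed
    sidecars, or non-positive voxel sizes.
    """
    meta = _read_metadata(metadata_path)
    arr = _array_from_file(Path(path))
    if "shape" in meta and tuple(meta["shape"]) != arr.shape:
        raise ValueError(
            f"metadata shape {tuple(meta['shape'])} does not match volume shape {arr.shape}"
        )
    return OCTVolume(arr, tuple(meta["voxel_size_um"]), id=str(meta.get("id", "")))


def write_volume(vol: OCTVolume, path, metadata_path) -> None:
    """Write ``vol`` such that :func:`read_volume` inverts it exactly."""
    path = Path(path)
    _array_to_file(vol.intensities, path, vol.voxel_size_um)
    metadata_path = Path(metadata_path)
    metadata_path.parent.mkdir(parents=True, exist_ok=True)
    with open(metadata_path, "w") as fh:
        json.dump(
            {"voxel_size_um": list(vol.voxel_size_um), "id": vol.id,
             "shape": list(vol.shape)},
            fh, indent=2, sort_keys=True,
        )


def write_mask(mask: VoxelMask, path, voxel_size_um=(1.0, 1.0, 1.0)) -> None:
    _array_to_file(mask.values.astype(np.float64), Path(path), voxel_size_um)


def read_mask(path, role: str = "voi") -> VoxelMask:
    arr = _array_from_file(Path(path))
    return VoxelMask(arr > 0.5, role=role)


def write_surfaces(surfaces: SurfaceSet, path) -> None:
    """Serialize surfaces as a float TIFF stack of shape (11, nx, ny) or CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        s, x, y = np.meshgrid(
            np.arange(surfaces.n_surfaces),
            np.arange(surfaces.grid_shape[0]),
            np.arange(surfaces.grid_shape[1]),
            indexing="ij",
        )
        data = np.column_stack(
            [s.ravel(), x.ravel(), y.ravel(), surfaces.z_of.ravel()]
        )
        header = "surface,x,y,z"
        np.savetxt(str(path), data, delimiter=",", header=header, comments="",
                   fmt=["%d", "%d", "%d", "%.17g"])
    else:
        tifffile.imwrite(str(path), surfaces.z_of.astype(np.float64),
                         photometric="minisblack")


def read_surfaces(path) -> SurfaceSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"surface file not found: {path}")
    if path.suffix.lower() == ".csv":
        data = np.loadtxt(str(path), delimiter=",", skiprows=1)
        s = data[:, 0].astype(int)
        x = data[:, 1].astype(int)
        y = data[:, 2].astype(int)
        z_of = np.zeros((s.max() + 1, x.max() + 1, y.max() + 1))
        z_of[s, x, y] = data[:, 3]
        return SurfaceSet(z_of)
    return SurfaceSet(tifffile.imread(str(path)).astype(float))


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def disruption_volume(mask: VoxelMask, voxel_size_um) -> float:
    """Physical volume of a binary mask in mm^3.

    ``count(true) * dx * dy * dz * 1e-9`` — the disrupted-voxel count times
    the voxel resolution, converted from um^3 to mm^3. Full precision kept.
    """
    dx, dy, dz = (float(v) for v in voxel_size_um)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"voxel_size_um must be positive, got {(dx, dy, dz)}")
    return float(mask.count()) * dx * dy * dz * 1e-9
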