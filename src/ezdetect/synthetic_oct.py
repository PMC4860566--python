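"""Seeded OCT-like phantom generator with known ground truth.

The phantom emulates the structures the disruption-detection pipeline relies
on, without attempting wave-optics realism:

* ten stacked retinal layers with distinct mean reflectivities, the
  ellipsoid-zone band (layer 7) ranking among the two brightest,
* smoothly undulating surface geometry plus a radial-Gaussian foveal dip of
  the inner surfaces,
* low-intensity disruption blobs planted inside the EZ band (between
  surfaces 7 and 8),
* vessel shadow columns attenuating everything deeper than surface 4,
* multiplicative gamma speckle (mean 1), applied last.

Everything is deterministic given the seed, and the generator returns its
own construction records (surfaces, masks, blob bookkeeping, class
imbalance) so downstream stages can be tested against exact truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .volume_model import (
    OCTVolume,
    SurfaceSet,
    VoxelMask,
    round_half_deep,
)

__all__ = ["PhantomConfig", "GroundTruth", "PhantomEye", "generate_phantom",
           "generate_cohort"]

#: Mean reflectivities of the 10 layers (NFL ... RPE), vitreous above and
#: choroid below.  Layer 7 is the EZ band and is the brightest (the NFL and
#: RPE complex are the next most reflective, as in real scans); boundary
#: contrasts are chosen so the vitreous->NFL step is the strongest
#: dark-to-bright gradient and the RPE->choroid step the strongest
#: bright-to-dark one, mirroring the saliency ranking segmentation relies on.
DEFAULT_REFLECTIVITY = (0.85, 0.25, 0.52, 0.18, 0.42, 0.20, 0.90, 0.30, 0.60, 0.80)

#: Layer thicknesses in voxels for the default 128-deep grid; the EZ band
#: (index 6) is deliberately thin.
DEFAULT_THICKNESS = (8, 6, 7, 6, 6, 12, 4, 5, 5, 8)

# Foveal dip weight per surface (inner surfaces sink, outer fixed).
_DIP_WEIGHT = np.array([1.0, 0.85, 0.70, 0.55, 0.40, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass
class PhantomConfig:
    """All tunables of the phantom.  Defaults define the study conditions.

    The default grid is 128 x 32 x 128 voxels covering a 6 x 6 mm macular
    scan (voxel 46.88 x 187.5 x 13.125 um^3), a 4x/4x/3.75x down-scaling of
    the native 512 x 128 x 480 acquisition so full-pipeline tests run in
    minutes.  Disruption blobs are isotropic in en-face *pixel* units with
    radii 7-10 px so that detected components survive the radius-5 disk
    morphological cleanup; the resulting default non-disrupted:disrupted
    imbalance within the EZ is of order 10:1 at this grid scale (~100:1 at
    the native grid for the same physical blob sizes).
    """

    nx: int = 128
    ny: int = 32
    nz: int = 128
    voxel_size_um: tuple = (46.88, 187.5, 13.125)
    layer_reflectivity: tuple = DEFAULT_REFLECTIVITY
    vitreous_reflectivity: float = 0.02
    choroid_reflectivity: float = 0.10
    layer_thickness_vox: tuple = DEFAULT_THICKNESS
    surface1_depth: float = 28.0
    #: sinusoid amplitudes (voxels) along x and y
    undulation_amplitude: tuple = (3.0, 2.0)
    #: sinusoid periods across the scan along x and y
    undulation_periods: tuple = (1.5, 1.0)
    fovea_depth: float = 8.0
    #: dip sigma as a fraction of nx (x voxels); y sigma scaled to physical isotropy
    fovea_sigma_frac: float = 0.15
    n_disruptions: int = 2
    disruption_radius: tuple = (7.0, 10.0)
    #: disrupted EZ intensity = drop * EZ reflectivity
    disruption_drop: float = 0.3
    n_vessels: int = 3
    vessel_width: float = 3.0
    vessel_attenuation: float = 0.45
    speckle_family: str = "gamma"
    #: std of the (mean-1) multiplicative speckle; 0 disables noise
    speckle_scale: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) <= 0:
            raise ValueError("extents must be positive")
        if len(self.layer_reflectivity) != 10 or not all(
            0.0 <= r <= 1.0 for r in self.layer_reflectivity
        ):
            raise ValueError("layer_reflectivity must be 10 values in [0, 1]")
        if len(self.layer_thickness_vox) != 10:
            raise ValueError("layer_thickness_vox must have 10 entries")
        if not (0.0 < self.disruption_drop <= 1.0):
            raise ValueError("disruption_drop must be in (0, 1]")
        if not (0.0 < self.vessel_attenuation < 1.0):
            raise ValueError("vessel_attenuation must be in (0, 1)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if self.speckle_family not in ("gamma",):
            raise ValueError(f"unknown speckle family {self.speckle_family!r}")


@dataclass
class GroundTruth:
    """Exact construction records of one phantom."""

    surfaces: SurfaceSet
    disruption_mask: VoxelMask
    vessel_map: np.ndarray  # (nx, ny) bool
    blob_records: list = field(default_factory=list)  # dicts: cx, cy, radius, n_columns

    def ez_voxel_counts(self) -> tuple:
        """(disrupted, non_disrupted) voxel counts inside the EZ band."""
        b7 = round_half_deep(self.surfaces.z_of[6])
        b8 = round_half_deep(self.surfaces.z_of[7])
        total = int(np.maximum(b8 - b7, 1).sum())
        dis = self.disruption_mask.count()
        return dis, total - dis

    def ez_imbalance(self) -> float:
        """Non-disrupted : disrupted ratio within the EZ (inf if no disruption)."""
        dis, non = self.ez_voxel_counts()
        return float("inf") if dis == 0 else non / dis


@dataclass
class PhantomEye:
    """One cohort member: phantom volume plus truth and bookkeeping."""

    volume: OCTVolume
    truth: GroundTruth
    id: str
    group: str  # "trauma" | "normal"
    seed: int


def _build_surfaces(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    x = np.arange(cfg.nx)[:, None]
    y = np.arange(cfg.ny)[None, :]
    ax, ay = cfg.undulation_amplitude
    fx, fy = cfg.undulation_periods
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    undulation = ax * np.sin(2 * np.pi * fx * x / cfg.nx + phx) + ay * np.sin(
        2 * np.pi * fy * y / cfg.ny + phy
    )

    dx, dy, _ = cfg.voxel_size_um
    sx = cfg.fovea_sigma_frac * cfg.nx
    sy = max(sx * dx / dy, 1.0)  # physical isotropy on the anisotropic grid
    cx, cy = (cfg.nx - 1) / 2.0, (cfg.ny - 1) / 2.0
    dip = cfg.fovea_depth * np.exp(
        -((x - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2))
    )

    base = cfg.surface1_depth + np.concatenate(
        [[0.0], np.cumsum(cfg.layer_thickness_vox)]
    )
    z_of = base[:, None, None] + undulation[None] + _DIP_WEIGHT[:, None, None] * dip[None]

    if np.any(np.diff(z_of, axis=0) <= 0):
        raise ValueError(
            "surface geometry violates ordering: foveal dip too deep for the "
            "configured layer thicknesses"
        )
    if np.any(z_of < 1) or np.any(z_of > cfg.nz - 2):
        raise ValueError(
            "surface geometry out of range: amplitudes/depths too large for nz"
        )
    return z_of


def _vessel_map(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random-walk vessel paths crossing the en face plane along y."""
    vmap = np.zeros((cfg.nx, cfg.ny), dtype=bool)
    x_idx = np.arange(cfg.nx)[:, None]
    for _ in range(cfg.n_vessels):
        x0 = rng.uniform(5, cfg.nx - 5)
        steps = rng.normal(0.0, 1.2, size=cfg.ny)
        path = x0 + np.cumsum(steps)
        # light smoothing of the walk keeps curvature gentle
        kernel = np.array([0.25, 0.5, 0.25])
        path = np.convolve(np.pad(path, 1, mode="edge"), kernel, mode="valid")
        path = np.clip(path, 1, cfg.nx - 2)
        vmap |= np.abs(x_idx - path[None, :]) <= cfg.vessel_width / 2.0
    return vmap


def _plant_disruptions(cfg, rng, vessel_map):
    """Sample en-face blobs, rejection-sampled away from vessel shadows.

    Vessel shadows occlude the EZ signal, so truth under a vessel would be
    ill-defined (and the detection pipeline discards everything under
    vessels by design); keeping blobs clear of vessels keeps the labels
    unambiguous.
    """
    x = np.arange(cfg.nx)[:, None]
    y = np.arange(cfg.ny)[None, :]
    footprint = np.zeros((cfg.nx, cfg.ny), dtype=bool)
    records = []
    vx, vy = np.nonzero(vessel_map)
    for _ in range(cfg.n_disruptions):
        r = rng.uniform(*cfg.disruption_radius)
        blob = None
        for _attempt in range(200):
            cx = rng.uniform(r, cfg.nx - 1 - r)
            cy = rng.uniform(r * 0.5, cfg.ny - 1 - r * 0.5)
            if vx.size:
                d2 = (vx - cx) ** 2 + (vy - cy) ** 2
                if d2.min() < (r + cfg.vessel_width / 2.0 + 3.0) ** 2:
                    continue
            blob = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
            break
        if blob is None:  # crowded plane: place the last draw regardless
            blob = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        footprint |= blob
        records.append(
            {"cx": float(cx), "cy": float(cy), "radius": float(r),
             "n_columns": int(blob.sum())}
        )
    return footprint, records


def generate_phantom(cfg: PhantomConfig):
    """Render one phantom.

    Returns
    -------
    (OCTVolume, GroundTruth)
        Deterministic given ``cfg.seed``.  Layer ``s`` occupies
        ``z in [surface s, surface s+1)`` (round-half-deep boundaries);
        disruption blobs replace the EZ-band intensity by
        ``drop * EZ reflectivity``; vessel columns attenuate everything
        deeper than surface 4; speckle is applied last, multiplicatively.
    """
    rng = np.random.default_rng(cfg.seed)
    z_of = _build_surfaces(cfg, rng)
    bounds = round_half_deep(z_of)  # (11, nx, ny) int

    z_idx = np.arange(cfg.nz)
    # number of surfaces at or above each voxel -> region index 0..11
    region = (z_idx[None, None, :] >= bounds[:, :, :, None]).sum(axis=0)
    lut = np.array(
        [cfg.vitreous_reflectivity, *cfg.layer_reflectivity, cfg.choroid_reflectivity]
    )
    vol = lut[region]

    vessel_map = _vessel_map(cfg, rng) if cfg.n_vessels > 0 else np.zeros(
        (cfg.nx, cfg.ny), dtype=bool
    )

    disruption = np.zeros((cfg.nx, cfg.ny, cfg.nz), dtype=bool)
    blob_records = []
    if cfg.n_disruptions > 0:
        footprint, blob_records = _plant_disruptions(cfg, rng, vessel_map)
        ez = (z_idx[None, None, :] >= bounds[6][:, :, None]) & (
            z_idx[None, None, :] < bounds[7][:, :, None]
        )
        disruption = ez & footprint[:, :, None]
        ez_refl = cfg.layer_reflectivity[6]
        vol = np.where(disruption, cfg.disruption_drop * ez_refl, vol)

    if cfg.n_vessels > 0:
        below_inner = z_idx[None, None, :] >= bounds[3][:, :, None]
        shadow = vessel_map[:, :, None] & below_inner
        vol = np.where(shadow, vol * cfg.vessel_attenuation, vol)

    if cfg.speckle_scale > 0:
        shape = 1.0 / cfg.speckle_scale**2
        vol = vol * rng.gamma(shape, 1.0 / shape, size=vol.shape)

    volume = OCTVolume(vol, cfg.voxel_size_um, id=f"phantom-{cfg.seed}")
    truth = GroundTruth(
        surfaces=SurfaceSet(z_of),
        disruption_mask=VoxelMask(disruption, role="ground_truth"),
        vessel_map=vessel_map,
        blob_records=blob_records,
    )
    return volume, truth


def generate_cohort(n_trauma: int, n_normal: int, cfg_template: PhantomConfig,
                    seed: int):
    """Generate a reproducible cohort of phantom eyes.

    Trauma eyes use ``cfg_template`` as-is (``n_disruptions`` must be >= 1);
    normal eyes get ``n_disruptions = 0`` and hence empty disruption masks.
    Per-eye seeds are derived from the master ``seed`` via
    ``numpy.random.SeedSequence`` spawning.
    """
    if n_trauma < 0 or n_normal < 0:
        raise ValueError("cohort sizes must be non-negative")
    children = np.random.SeedSequence(seed).spawn(n_trauma + n_normal)
    eyes = []
    for i, child in enumerate(children):
        eye_seed = int(child.generate_state(1)[0] % (2**31))
        trauma = i < n_trauma
        cfg = dataclasses.replace(
            cfg_template,
            seed=eye_seed,
            n_disruptions=cfg_template.n_disruptions if trauma else 0,
        )
        if trauma and cfg.n_disruptions < 1:
            raise ValueError("trauma phantoms require n_disruptions >= 1")
        vol, truth = generate_phantom(cfg)
        group = "trauma" if trauma else "normal"
        idx = i if trauma else i - n_trauma
        eye_id = f"{group}_{idx:02d}"
        vol.id = eye_id
        eyes.append(PhantomEye(vol, truth, eye_id, group, eye_seed))
    return eyes
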