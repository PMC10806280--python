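"""Synthetic two-point Dixon phantoms with known ground truth.

A phantom emulates one acquisition slab: a water-dominant noisy background
with a single bright-fat target structure whose geometry mimics one of the
four marrow regions —

* ``spine``       — a stack of separated bright blocks (vertebra-like),
* ``femoral_head``— a sphere,
* ``total_hip``   — a sphere with a short neck cylinder,
* ``diaphysis``   — a thin axial tube of only a few voxels per slice.

Fat and water channel intensities are constructed so that the fat fraction
``100·fat/(fat+water)`` inside the target equals the configured value
*exactly* in the noiseless case (interior intensity is a power of two, so
the ratio involves no rounding).  Additive Gaussian noise, clipped at zero,
is applied per channel.

Geometry defaults follow the acquisition this emulates: 44 axial slices at
4.5 mm thickness with 2.2 mm in-plane resolution at full scale, and a
scaled-down ``(24, 48, 48)`` grid for desk-scale tests.  Full-scale default
target sizes use the cohort mean segmentation volumes in voxels (spine 2244,
total hip 1248, femoral head 810, diaphysis 100).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .volumes import LabelMask, RegionLabel, Volume3D

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "FOREGROUND_INTENSITY",
    "BACKGROUND_INTENSITY",
]

# Interior (target) and background total signal intensity.  The interior
# value is a power of two so noiseless fat fractions are exact.
FOREGROUND_INTENSITY = 512.0
BACKGROUND_INTENSITY = 128.0

#: Cohort-mean segmentation volumes (voxels) used as full-scale targets.
FULL_SCALE_TARGETS = {
    RegionLabel.SPINE: 2244,
    RegionLabel.FEMORAL_HEAD: 810,
    RegionLabel.TOTAL_HIP: 1248,
    RegionLabel.DIAPHYSIS: 100,
}

TEST_SCALE_TARGETS = {
    RegionLabel.SPINE: 300,
    RegionLabel.FEMORAL_HEAD: 150,
    RegionLabel.TOTAL_HIP: 200,
    RegionLabel.DIAPHYSIS: 100,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic slab."""

    shape: tuple[int, int, int] = (44, 168, 224)
    spacing: tuple[float, float, float] = (2.2, 2.2, 4.5)
    region: RegionLabel = RegionLabel.SPINE
    target_size_voxels: int = 2244
    true_ff_percent: float = 80.0
    background_ff_percent: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0
    centre_voxel: tuple[int, int, int] | None = None  # (z, y, x); default = volume centre
    swap_channels: bool = False  # emulate a fat-water swap artefact

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_ff_percent <= 100.0):
            raise ValueError("true_ff_percent must be in [0, 100]")
        if not (0.0 <= self.background_ff_percent <= 100.0):
            raise ValueError("background_ff_percent must be in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_size_voxels < 1:
            raise ValueError("target_size_voxels must be >= 1")
        object.__setattr__(self, "region", RegionLabel(self.region))

    @classmethod
    def test_scale(
        cls,
        region: RegionLabel = RegionLabel.DIAPHYSIS,
        shape: tuple[int, int, int] = (24, 48, 48),
        **kw,
    ) -> "PhantomConfig":
        region = RegionLabel(region)
        kw.setdefault("target_size_voxels", TEST_SCALE_TARGETS[region])
        return cls(shape=shape, region=region, **kw)


@dataclass
class PhantomSample:
    """One generated phantom with its ground truth."""

    fat: Volume3D
    water: Volume3D
    truth_mask: LabelMask
    truth_centre_normalized: tuple[float, float, float]  # (x, y, z) in [-1, 1]
    config: PhantomConfig

    @property
    def truth_centre_zyx(self) -> np.ndarray:
        x, y, z = self.truth_centre_normalized
        return np.array([z, y, x])


# --------------------------------------------------------------------- #
# region geometry builders
# --------------------------------------------------------------------- #
def _spine_blocks(shape, centre, target):
    nz = shape[0]
    n_blocks = 6 if nz >= 40 else 4
    per = target / n_blocks
    gap = 1
    dz_max = max(2, (nz - 2 - (n_blocks - 1) * gap) // n_blocks)
    dz = min(max(2, round(per ** (1.0 / 3.0))), dz_max)
    side = max(2, round(math.sqrt(per / dz)))
    extent_z = n_blocks * dz + (n_blocks - 1) * gap
    mask = np.zeros(shape, dtype=bool)
    z0 = centre[0] - extent_z // 2
    y0 = centre[1] - side // 2
    x0 = centre[2] - side // 2
    for i in range(n_blocks):
        zs = z0 + i * (dz + gap)
        mask[zs : zs + dz, y0 : y0 + side, x0 : x0 + side] = True
    return mask, (extent_z, side, side)


def _ball(shape, centre, radius, anisotropy=(1.0, 1.0, 1.0)):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - centre[0]) * anisotropy[0]) ** 2
        + ((yy - centre[1]) * anisotropy[1]) ** 2
        + ((xx - centre[2]) * anisotropy[2]) ** 2
    )
    return d2 <= radius**2


def _sphere(shape, centre, target):
    r = (3.0 * target / (4.0 * math.pi)) ** (1.0 / 3.0)
    e = int(2 * math.ceil(r) + 1)
    return _ball(shape, centre, r), (e, e, e)


def _hip(shape, centre, target):
    sphere_target = 0.8 * target
    r = (3.0 * sphere_target / (4.0 * math.pi)) ** (1.0 / 3.0)
    mask = _ball(shape, centre, r)
    neck_r = max(1.2, r / 3.0)
    neck_len = max(3, int(round(r)))
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    inplane = np.sqrt((zz - centre[0]) ** 2 + (xx - centre[2]) ** 2 + 0.0 * yy)
    y_hi = centre[1] + int(math.floor(r)) + neck_len
    neck = (inplane <= neck_r) & (yy >= centre[1]) & (yy <= y_hi)
    mask = mask | neck
    e = int(2 * math.ceil(r) + 1)
    return mask, (e, e + neck_len, e)


def _tube(shape, centre, target):
    r_xy = 1.6  # 9 voxels per axial slice
    per_slice = 9
    length = max(3, int(round(target / per_slice)))
    length = min(length, shape[0] - 2)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    inplane = np.sqrt((yy - centre[1]) ** 2 + (xx - centre[2]) ** 2 + 0.0 * zz)
    z0 = centre[0] - length // 2
    mask = (inplane <= r_xy) & (zz >= z0) & (zz < z0 + length)
    return mask, (length, 2 * math.ceil(r_xy) + 1, 2 * math.ceil(r_xy) + 1)


_BUILDERS = {
    RegionLabel.SPINE: _spine_blocks,
    RegionLabel.FEMORAL_HEAD: _sphere,
    RegionLabel.TOTAL_HIP: _hip,
    RegionLabel.DIAPHYSIS: _tube,
}


def region_extent(region: RegionLabel, shape, target: int):
    """Approximate bounding-box extent (z, y, x) of a region's target."""
    _, extent = _BUILDERS[RegionLabel(region)](
        tuple(shape), tuple(s // 2 for s in shape), target
    )
    return extent


def _build_mask(cfg: PhantomConfig) -> np.ndarray:
    centre = cfg.centre_voxel or tuple(s // 2 for s in cfg.shape)
    mask, _ = _BUILDERS[cfg.region](cfg.shape, tuple(int(c) for c in centre), cfg.target_size_voxels)
    if not mask.any():
        raise ValueError("target produced an empty mask; target size too small for the grid")
    border = (
        mask[0].any()
        or mask[-1].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )
    if border:
        raise ValueError(
            f"{cfg.region.value} target (size {cfg.target_size_voxels}) does not fit "
            f"inside shape {cfg.shape} with a 1-voxel background margin"
        )
    return mask


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Generate one phantom; deterministic for a fixed config (incl. seed)."""
    mask = _build_mask(cfg)
    ff = cfg.true_ff_percent / 100.0
    bg_ff = cfg.background_ff_percent / 100.0
    fat = np.where(mask, ff * FOREGROUND_INTENSITY, bg_ff * BACKGROUND_INTENSITY)
    water = np.where(
        mask, FOREGROUND_INTENSITY - ff * FOREGROUND_INTENSITY, BACKGROUND_INTENSITY - bg_ff * BACKGROUND_INTENSITY
    )
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        fat = np.clip(fat + rng.normal(0.0, cfg.noise_sd, cfg.shape), 0.0, None)
        water = np.clip(water + rng.normal(0.0, cfg.noise_sd, cfg.shape), 0.0, None)
    if cfg.swap_channels:
        fat, water = water, fat

    com = np.argwhere(mask).mean(axis=0)  # (z, y, x) voxel coordinates
    norm = [
        (2.0 * com[a] / (cfg.shape[a] - 1) - 1.0) if cfg.shape[a] > 1 else 0.0
        for a in range(3)
    ]
    centre_xyz = (norm[2], norm[1], norm[0])
    return PhantomSample(
        fat=Volume3D(fat, cfg.spacing),
        water=Volume3D(water, cfg.spacing),
        truth_mask=LabelMask(mask.astype(np.uint8), cfg.spacing),
        truth_centre_normalized=centre_xyz,
        config=cfg,
    )


def dataset_jitter_box(cfg: PhantomConfig, size_jitter: float = 0.2):
    """Maximum integer centre offset per axis keeping the target inside."""
    worst = int(math.ceil(cfg.target_size_voxels * (1.0 + size_jitter)))
    extent = region_extent(cfg.region, cfg.shape, worst)
    box = []
    for ax in range(3):
        free = (cfg.shape[ax] - extent[ax]) // 2 - 2
        box.append(max(0, free))
    return tuple(box)


def generate_dataset(
    n: int,
    cfg: PhantomConfig,
    seed: int = 0,
    size_jitter: float = 0.2,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms from a template config.

    Target positions are jittered uniformly over the largest box that keeps
    the target inside the volume, and target sizes by ±``size_jitter``.
    Fully reproducible under the master ``seed``; each sample records its own
    derived seed in its config echo.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(2 * n, dtype=np.uint32)
    box = dataset_jitter_box(cfg, size_jitter)
    base_centre = tuple(s // 2 for s in cfg.shape)
    samples = []
    for i in range(n):
        child_seed = int(children[2 * i] % (2**31))
        rng = np.random.default_rng(int(children[2 * i + 1]))
        offset = [rng.integers(-box[a], box[a] + 1) if box[a] > 0 else 0 for a in range(3)]
        factor = rng.uniform(1.0 - size_jitter, 1.0 + size_jitter)
        sample_cfg = dataclasses.replace(
            cfg,
            seed=child_seed,
            centre_voxel=tuple(int(base_centre[a] + offset[a]) for a in range(3)),
            target_size_voxels=max(1, int(round(cfg.target_size_voxels * factor))),
        )
        samples.append(generate_phantom(sample_cfg))
    return samples
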