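"""Two-point Dixon fat-fraction mapping and per-VOI BMFF extraction.

The fat fraction of a voxel is ``FF = 100 · fat / (fat + water)`` computed
from the vendor fat and water channel intensities.  Voxels with zero total
signal carry no information and are recorded as missing (NaN), never as 0,
so they cannot bias region means downward.

Before mapping, a 3x3 in-plane mean filter ("nearest-neighbour smoothing")
may be applied to each channel to suppress isolated noise spikes; slices
are thick relative to the in-plane resolution, so smoothing does not cross
slices.  Edge voxels are averaged over their available neighbours only.

For BMFF extraction the segmentation is eroded by a single boundary voxel
*in plane* (4-connected cross, one iteration) so measurements come from
marrow rather than the bone interface — except for the diaphysis, whose
cross-section of only a few voxels per slice would not survive erosion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, RegionLabel, Volume3D

__all__ = [
    "FfMap",
    "BmffRecord",
    "smooth_volume",
    "compute_ff",
    "erode_inplane",
    "extract_bmff",
]

# one axial slice: 4-connected cross, no through-slice extent
_CROSS_INPLANE = np.array([[[0, 1, 0], [1, 1, 1], [0, 1, 0]]], dtype=bool)
_MEAN_KERNEL = np.ones((1, 3, 3))


@dataclass
class FfMap:
    """Per-voxel fat-fraction map in percent; NaN marks missing voxels."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.2, 2.2, 4.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        defined = self.data[~np.isnan(self.data)]
        if defined.size and (defined.min() < 0 or defined.max() > 100):
            raise ValueError("defined fat-fraction values must lie in [0, 100]")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BmffRecord:
    """Mean fat fraction of one VOI."""

    region: RegionLabel
    mean_ff: float
    voxels_used: int
    eroded: bool

    def __post_init__(self) -> None:
        if self.voxels_used < 1:
            raise ValueError("a reported BMFF mean needs >= 1 usable voxel")
        if self.eroded != (self.region != RegionLabel.DIAPHYSIS):
            raise ValueError("erosion must be applied to every region except the diaphysis")


def smooth_volume(vol: Volume3D) -> Volume3D:
    """3x3 in-plane mean filter; edge voxels use their available neighbours."""
    data = vol.data
    if data.min() < 0:
        raise ValueError("intensities must be non-negative")
    sums = ndimage.convolve(data, _MEAN_KERNEL, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(data), _MEAN_KERNEL, mode="constant", cval=0.0)
    return Volume3D(sums / counts, vol.spacing)


def compute_ff(fat: Volume3D, water: Volume3D) -> FfMap:
    """``FF = 100 · fat / (fat + water)``; zero-signal voxels are missing.

    Any smoothing is the caller's responsibility and must be applied to the
    channels *before* this call.
    """
    if fat.shape != water.shape:
        raise ValueError(f"fat and water shapes differ: {fat.shape} vs {water.shape}")
    if fat.data.min() < 0 or water.data.min() < 0:
        raise ValueError("intensities must be non-negative")
    total = fat.data + water.data
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, 100.0 * fat.data / np.where(total > 0, total, 1.0), np.nan)
    return FfMap(ff, fat.spacing)


def erode_inplane(mask: LabelMask) -> LabelMask:
    """One-voxel in-plane binary erosion (4-connected cross), per axial slice."""
    eroded = ndimage.binary_erosion(
        mask.data.astype(bool), structure=_CROSS_INPLANE, border_value=0
    )
    return LabelMask(eroded.astype(np.uint8), mask.spacing)


def extract_bmff(ff: FfMap, mask: LabelMask, region: RegionLabel) -> BmffRecord:
    """Mean FF under the (region-conditionally eroded) mask.

    Raises
    ------
    ValueError
        If no usable voxel remains; the message advises falling back to the
        un-eroded mask explicitly.
    """
    region = RegionLabel(region)
    if ff.shape != mask.shape:
        raise ValueError(f"FF map and mask shapes differ: {ff.shape} vs {mask.shape}")
    erode = region != RegionLabel.DIAPHYSIS
    work = erode_inplane(mask) if erode else mask
    usable = (work.data > 0) & ~np.isnan(ff.data)
    n = int(usable.sum())
    if n == 0:
        raise ValueError(
            f"no usable voxels for {region.value} after "
            f"{'erosion' if erode else 'masking'}; consider re-running with the "
            "un-eroded mask"
        )
    return BmffRecord(
        region=region,
        mean_ff=float(ff.data[usable].mean()),
        voxels_used=n,
        eroded=erode,
    )
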