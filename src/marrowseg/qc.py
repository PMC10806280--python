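"""Segmentation error-checking and cohort-level output classification.

Rules applied to every automatic segmentation before it is trusted for
fat-fraction analysis:

* single-voxel connected components (26-connectivity) are removed;
* internal cavities are filled (6-connectivity hole filling); physically
  disjoint components are retained and treated as one VOI downstream;
* a segmentation whose centre of mass lies more than 3 standard deviations
  from the reference mean on *any* axis is flagged as an outlier;
* outputs are classified as ``Empty`` (no voxels), ``Small`` (volume more
  than 2.5 SD below the reference mean, strict inequality) or ``OK``.

Reference statistics (mean/SD of volume and per-axis centre of mass) are
computed from a training/reference set of masks with sample SD (ddof=1).
Volumes are counted in voxels, which is also the unit the thresholds use;
mm^3 values are derivable through each mask's spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, RegionLabel

__all__ = [
    "QcStatus",
    "RegionStats",
    "QcResult",
    "remove_single_voxel_components",
    "join_discontinuous_voi",
    "component_count",
    "check_com_outlier",
    "classify_output",
    "compute_region_stats",
    "run_qc",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class QcStatus(str, Enum):
    OK = "OK"
    SMALL = "Small"
    EMPTY = "Empty"


@dataclass(frozen=True)
class RegionStats:
    """Reference distribution of a region's segmentations."""

    region: RegionLabel
    mean_volume: float
    sd_volume: float
    mean_com: tuple[float, float, float]  # (z, y, x) voxel coordinates
    sd_com: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.sd_volume < 0 or any(s < 0 for s in self.sd_com):
            raise ValueError("standard deviations must be >= 0")


@dataclass
class QcResult:
    status: QcStatus
    volume: int
    com_outlier: bool | None  # None when the mask is empty (COM undefined)
    notes: str = ""


def remove_single_voxel_components(mask: LabelMask) -> LabelMask:
    """Drop every 26-connected component consisting of exactly one voxel."""
    data = mask.data.astype(bool)
    labels, n = ndimage.label(data, structure=_STRUCT_26)
    if n == 0:
        return LabelMask(data.astype(np.uint8), mask.spacing)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= 2
    keep[0] = False
    return LabelMask(keep[labels].astype(np.uint8), mask.spacing)


def join_discontinuous_voi(mask: LabelMask) -> LabelMask:
    """Fill internal cavities; disjoint components are kept (one VOI).

    Hole filling uses the 6-connected structure, so diagonal leaks do not
    spuriously close open structures.  No voxels are ever removed.
    """
    filled = ndimage.binary_fill_holes(mask.data.astype(bool))
    return LabelMask(filled.astype(np.uint8), mask.spacing)


def component_count(mask: LabelMask) -> int:
    """Number of 26-connected components."""
    _, n = ndimage.label(mask.data.astype(bool), structure=_STRUCT_26)
    return int(n)


def check_com_outlier(mask: LabelMask, stats: RegionStats) -> bool:
    """True iff the centre of mass is > 3 SD from the reference mean on any axis."""
    com = mask.centre_of_mass()  # raises on empty mask
    for ax in range(3):
        if abs(com[ax] - stats.mean_com[ax]) > 3.0 * stats.sd_com[ax]:
            return True
    return False


def classify_output(mask: LabelMask, stats: RegionStats) -> QcResult:
    """Classify a segmentation output as OK / Small / Empty."""
    volume = mask.voxel_count
    if volume == 0:
        return QcResult(status=QcStatus.EMPTY, volume=0, com_outlier=None,
                        notes="no output generated")
    outlier = check_com_outlier(mask, stats)
    threshold = stats.mean_volume - 2.5 * stats.sd_volume
    if volume < threshold:
        return QcResult(status=QcStatus.SMALL, volume=volume, com_outlier=outlier,
                        notes="volume > 2.5 SD below the reference mean")
    return QcResult(status=QcStatus.OK, volume=volume, com_outlier=outlier)


def compute_region_stats(masks: list[LabelMask], region: RegionLabel) -> RegionStats:
    """Sample mean/SD (ddof=1) of voxel volumes and per-axis centres of mass."""
    if len(masks) < 2:
        raise ValueError("need >= 2 reference masks to compute statistics")
    volumes = []
    coms = []
    for m in masks:
        if m.voxel_count == 0:
            raise ValueError("reference masks must be non-empty")
        volumes.append(m.voxel_count)
        coms.append(m.centre_of_mass())
    volumes = np.asarray(volumes, dtype=float)
    coms = np.asarray(coms, dtype=float)
    return RegionStats(
        region=RegionLabel(region),
        mean_volume=float(volumes.mean()),
        sd_volume=float(volumes.std(ddof=1)),
        mean_com=tuple(coms.mean(axis=0)),
        sd_com=tuple(coms.std(axis=0, ddof=1)),
    )


def run_qc(mask: LabelMask, stats: RegionStats) -> tuple[LabelMask, QcResult]:
    """Apply the cleanup rules, then classify the cleaned mask."""
    cleaned = remove_single_voxel_components(mask)
    cleaned = join_discontinuous_voi(cleaned)
    return cleaned, classify_output(cleaned, stats)
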