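"""Segmentation thresholds for calcium scoring.

Noncontrast CT uses the conventional fixed cutoff of 130 HU.  On
contrast-enhanced CT the blood pool itself exceeds 130 HU, so a
patient-specific threshold is derived from the contrast attenuation inside
the aortic lumen: the mean attenuation plus three standard deviations is
measured in two axial regions of interest (at the celiac trunk and just
above the aortic bifurcation) and the higher of the two values is used.

ROIs are circles (center in grid coordinates, radius in mm) or simple
polygons (grid coordinates) on a single axial slice.  Voxel membership is
decided by voxel-center inclusion, with boundary points included.  ROIs are
expected to be drawn inside the lumen — the aortic wall is never part of
the attenuation sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import shapely

from .ct_io import CTVolume
from .errors import BoundsError, DegenerateROIError, ValidationError

__all__ = [
    "RegionOfInterest",
    "ROIStats",
    "ROIThreshold",
    "ThresholdResult",
    "roi_mask",
    "roi_statistics",
    "patient_specific_threshold",
    "fixed_threshold",
    "NONCONTRAST_THRESHOLD_HU",
]

#: Conventional calcium threshold on noncontrast CT.
NONCONTRAST_THRESHOLD_HU = 130.0


@dataclass(frozen=True)
class RegionOfInterest:
    """An axial ROI: a circle or a simple polygon on one slice.

    ``circle`` is ``(cx, cy, r_mm)`` with the center in in-plane grid
    coordinates and the radius in mm; ``polygon`` is an ``(m, 2)`` array of
    in-plane grid coordinates.  Exactly one of the two must be given.
    """

    slice_index: int
    circle: tuple[float, float, float] | None = None
    polygon: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if (self.circle is None) == (self.polygon is None):
            raise ValidationError("give exactly one of circle= or polygon=")
        if self.circle is not None:
            cx, cy, r = self.circle
            if r <= 0:
                raise ValidationError(f"circle radius must be > 0, got {r}")
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            object.__setattr__(self, "polygon", poly)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValidationError("polygon must be an (m>=3, 2) array")
            if not shapely.Polygon(poly).is_valid:
                raise ValidationError("polygon must be simple (non-self-intersecting)")


class ROIStats(NamedTuple):
    mean: float
    sd: float
    n_voxels: int


class ROIThreshold(NamedTuple):
    label: str
    mean_hu: float
    sd_hu: float
    mean_plus_ksd: float
    n_voxels: int


@dataclass(frozen=True)
class ThresholdResult:
    """A segmentation threshold and the per-ROI statistics behind it.

    ``mode`` is ``"patient_specific"`` (max over ROIs of mean + k*SD) or
    ``"fixed_130"`` (the noncontrast convention, no ROIs).
    """

    selected_threshold: float
    mode: str
    per_roi: tuple[ROIThreshold, ...] = ()
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.mode == "patient_specific":
            if not self.per_roi:
                raise ValidationError("patient_specific threshold needs >= 1 ROI")
            expected = max(r.mean_plus_ksd for r in self.per_roi)
            if self.selected_threshold != expected:
                raise ValidationError(
                    "selected_threshold must equal the max per-ROI mean + k*SD"
                )
        elif self.mode == "fixed_130":
            if self.selected_threshold != NONCONTRAST_THRESHOLD_HU:
                raise ValidationError("fixed_130 mode requires threshold 130 HU")
        else:
            raise ValidationError(f"unknown threshold mode {self.mode!r}")


def roi_mask(volume: CTVolume, roi: RegionOfInterest) -> np.ndarray:
    """Boolean in-plane membership mask of ``roi`` on its slice.

    Raises :class:`~lacs.errors.BoundsError` if the ROI extends outside the
    volume extent.
    """
    nx, ny, nz = volume.shape
    if not 0 <= roi.slice_index < nz:
        raise BoundsError(
            f"ROI {roi.label!r}: slice_index {roi.slice_index} outside [0, {nz})"
        )
    sx, sy, _ = volume.spacing
    ix = np.arange(nx, dtype=float)
    iy = np.arange(ny, dtype=float)
    if roi.circle is not None:
        cx, cy, r = roi.circle
        if cx - r / sx < 0 or cx + r / sx > nx - 1 or cy - r / sy < 0 or cy + r / sy > ny - 1:
            raise BoundsError(f"ROI {roi.label!r}: circle extends outside the grid")
        dx = (ix[:, None] - cx) * sx
        dy = (iy[None, :] - cy) * sy
        return dx * dx + dy * dy <= r * r  # boundary inclusive
    poly = roi.polygon
    assert poly is not None
    if poly[:, 0].min() < 0 or poly[:, 0].max() > nx - 1 or poly[:, 1].min() < 0 or poly[:, 1].max() > ny - 1:
        raise BoundsError(f"ROI {roi.label!r}: polygon extends outside the grid")
    geom = shapely.Polygon(poly)
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    inside = shapely.intersects_xy(geom, gx.ravel(), gy.ravel())
    return inside.reshape(nx, ny)


def roi_statistics(volume: CTVolume, roi: RegionOfInterest) -> ROIStats:
    """Mean and sample SD (n-1 denominator) of HU over the ROI's voxels.

    Voxels are included when their centers fall inside the ROI shape
    (boundary inclusive).  ROIs covering fewer than two voxels raise
    :class:`~lacs.errors.DegenerateROIError` since the SD is undefined.
    """
    mask = roi_mask(volume, roi)
    values = volume.intensities[:, :, roi.slice_index][mask]
    n = int(values.size)
    if n < 2:
        raise DegenerateROIError(
            f"ROI {roi.label!r} covers {n} voxel(s); need >= 2 for an SD"
        )
    return ROIStats(float(np.mean(values)), float(np.std(values, ddof=1)), n)


def patient_specific_threshold(
    volume: CTVolume,
    roi_upper: RegionOfInterest,
    roi_lower: RegionOfInterest,
    sd_multiplier: float = 3.0,
) -> ThresholdResult:
    """Patient-specific contrast threshold: max over both ROIs of mean + k*SD.

    ``sd_multiplier`` defaults to 3 (mean + 3 SD); a 2-SD variant is a
    matter of passing ``sd_multiplier=2``.  The function is symmetric in its
    two ROI arguments.
    """
    if sd_multiplier <= 0:
        raise ValidationError("sd_multiplier must be > 0")
    entries = []
    for roi in (roi_upper, roi_lower):
        try:
            stats = roi_statistics(volume, roi)
        except (BoundsError, DegenerateROIError) as exc:
            raise type(exc)(f"ROI {roi.label!r}: {exc}") from exc
        entries.append(
            ROIThreshold(
                roi.label,
                stats.mean,
                stats.sd,
                stats.mean + sd_multiplier * stats.sd,
                stats.n_voxels,
            )
        )
    selected = max(e.mean_plus_ksd for e in entries)
    return ThresholdResult(
        selected_threshold=selected,
        mode="patient_specific",
        per_roi=tuple(entries),
        sd_multiplier=float(sd_multiplier),
    )


def fixed_threshold() -> ThresholdResult:
    """The fixed 130 HU noncontrast threshold."""
    return ThresholdResult(
        selected_threshold=NONCONTRAST_THRESHOLD_HU, mode="fixed_130"
    )
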