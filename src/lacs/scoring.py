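"""Calcium scores: volume score, length-adjusted score (LACS) and Agatston.

The length-adjusted calcium score normalizes the total segmented calcium
volume by the arterial segment length measured along the center lumen line:

    LACS = volume score (mm^3) / centerline length (cm)      [mm^3/cm]

so that scores are comparable across arterial segments of different
lengths.  On contrast-enhanced CT the patient-specific threshold sits far
above 130 HU and partial-volume lesion shells are lost, biasing the score
low; a multiplicative correction factor (default 1.9, estimable from paired
data via :func:`lacs.agreement_stats.correction_factor`) converts a
contrast-derived LACS to its noncontrast equivalent.

The classical Agatston score is provided as a comparator: per axial slice,
each in-plane 8-connected lesion of area >= 1 mm^2 contributes
area x weight, where the weight is 1/2/3/4 for a maximum density of
130-199 / 200-299 / 300-399 / >= 400 HU; slice contributions are summed.
No slice-thickness renormalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .calcium_segmentation import CalciumMask, LesionSet
from .ct_io import CTVolume
from .errors import ValidationError

__all__ = [
    "Centerline",
    "ScoreReport",
    "centerline_length",
    "centerline_from_mask",
    "lacs",
    "corrected_lacs",
    "volume_score",
    "agatston_score",
    "risk_category",
    "DEFAULT_CORRECTION_FACTOR",
]

#: Contrast -> noncontrast LACS conversion factor applied in contrast mode.
DEFAULT_CORRECTION_FACTOR = 1.9


@dataclass(frozen=True)
class Centerline:
    """An ordered polyline of physical positions (mm) through the lumen."""

    points: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("centerline needs >= 2 points of shape (n, 3)")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValidationError("consecutive centerline points must be distinct")

    @property
    def length_cm(self) -> float:
        return centerline_length(self.points)


def centerline_length(points: np.ndarray) -> float:
    """Arc length of a 3-D polyline, mm in -> cm out."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("need >= 2 points of shape (n, 3)")
    mm = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return mm / 10.0


def centerline_from_mask(lumen_mask: np.ndarray, volume: CTVolume) -> Centerline:
    """Center lumen line from a lumen mask: one point per axial slice.

    Each slice containing lumen voxels contributes the physical position of
    its in-plane centroid; slices without lumen voxels are skipped and the
    polyline connects across the gap.  Suited to the near-vertical abdominal
    aorta; not a general 3-D skeletonization.
    """
    lumen = np.asarray(lumen_mask).astype(bool)
    if lumen.shape != volume.shape:
        raise ValidationError("lumen mask shape differs from volume shape")
    sx, sy, sz = volume.spacing
    ox, oy, oz = volume.origin
    points = []
    for k in range(lumen.shape[2]):
        xs, ys = np.nonzero(lumen[:, :, k])
        if xs.size == 0:
            continue
        points.append(
            (ox + xs.mean() * sx, oy + ys.mean() * sy, oz + k * sz)
        )
    if len(points) < 2:
        raise ValidationError(
            "lumen mask must be non-empty on at least two axial slices"
        )
    return Centerline(np.asarray(points))


def lacs(volume_score_mm3: float, length_cm: float) -> float:
    """Length-adjusted calcium score: volume (mm^3) / length (cm)."""
    if length_cm <= 0:
        raise ValidationError(f"length_cm must be > 0, got {length_cm}")
    if volume_score_mm3 < 0:
        raise ValidationError("volume score must be >= 0")
    return volume_score_mm3 / length_cm


def corrected_lacs(
    lacs_contrast: float, correction_factor: float = DEFAULT_CORRECTION_FACTOR
) -> float:
    """Noncontrast-equivalent LACS: contrast LACS x correction factor."""
    if correction_factor <= 0:
        raise ValidationError("correction factor must be > 0")
    if lacs_contrast < 0:
        raise ValidationError("LACS must be >= 0")
    return lacs_contrast * correction_factor


def volume_score(lesions: LesionSet, spacing: tuple[float, float, float]) -> float:
    """Total calcium volume in mm^3: sum of voxel counts x voxel volume."""
    voxel_vol = float(np.prod(spacing))
    return sum(l.voxel_count for l in lesions.lesions) * voxel_vol


def _agatston_weight(max_hu: float) -> int:
    if max_hu >= 400:
        return 4
    if max_hu >= 300:
        return 3
    if max_hu >= 200:
        return 2
    return 1


def agatston_score(volume: CTVolume, mask: CalciumMask) -> float:
    """Classical Agatston score of a calcium mask (see module docstring)."""
    if mask.mask.shape != volume.shape:
        raise ValidationError("mask shape differs from volume shape")
    sx, sy, _ = volume.spacing
    pixel_area = sx * sy
    structure = np.ones((3, 3), dtype=bool)  # in-plane 8-connectivity
    total = 0.0
    for k in range(volume.shape[2]):
        labels, n = ndimage.label(mask.mask[:, :, k], structure=structure)
        if not n:
            continue
        counts = np.bincount(labels.ravel())[1:]
        max_hu = ndimage.labeled_comprehension(
            volume.intensities[:, :, k],
            labels,
            np.arange(1, n + 1),
            np.max,
            float,
            np.nan,
        )
        for count, hu in zip(counts, np.atleast_1d(max_hu)):
            area = count * pixel_area
            if area >= 1.0:  # minimum lesion area 1 mm^2
                total += area * _agatston_weight(float(hu))
    return total


def risk_category(agatston: float) -> str:
    """Coronary-risk bin of an Agatston score.

    0 -> ``very_low``; (0, 100] -> ``low``; (100, 400] -> ``increased``;
    > 400 -> ``increased_likelihood`` (boundaries inclusive in the lower
    bin).
    """
    if agatston < 0:
        raise ValidationError("Agatston score must be >= 0")
    if agatston == 0:
        return "very_low"
    if agatston <= 100:
        return "low"
    if agatston <= 400:
        return "increased"
    return "increased_likelihood"


@dataclass(frozen=True)
class ScoreReport:
    """Full scoring result for one volume/segmentation."""

    volume_score_mm3: float
    length_cm: float
    lacs_mm3_per_cm: float
    corrected_lacs_mm3_per_cm: float | None
    lesion_count: int
    agatston: float | None
    threshold_used: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("contrast", "noncontrast"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if abs(self.lacs_mm3_per_cm - self.volume_score_mm3 / self.length_cm) > 1e-9:
            raise ValidationError("LACS must equal volume score / length")

    def to_dict(self) -> dict:
        return asdict(self)


def score_report(
    lesions: LesionSet,
    centerline: Centerline,
    mode: str,
    threshold_used: float,
    volume: CTVolume | None = None,
    mask: CalciumMask | None = None,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
) -> ScoreReport:
    """Assemble a :class:`ScoreReport` from a filtered lesion set.

    The corrected LACS is reported only in contrast mode; the Agatston
    comparator is computed when both ``volume`` and ``mask`` are given.
    """
    vol = volume_score(lesions, lesions.spacing)
    length = centerline.length_cm
    score = lacs(vol, length)
    corrected = corrected_lacs(score, correction_factor) if mode == "contrast" else None
    aga = agatston_score(volume, mask) if volume is not None and mask is not None else None
    return ScoreReport(
        volume_score_mm3=vol,
        length_cm=length,
        lacs_mm3_per_cm=score,
        corrected_lacs_mm3_per_cm=corrected,
        lesion_count=len(lesions.lesions),
        agatston=aga,
        threshold_used=threshold_used,
        mode=mode,
    )
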