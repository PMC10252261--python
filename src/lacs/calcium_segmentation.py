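"""Threshold segmentation and 3-D lesion labeling of arterial calcium.

A voxel is calcium when its HU is at or above the segmentation threshold
(inclusive, matching the Agatston convention at 130 HU) and, when an aortic
region mask is supplied, lies inside that region — the programmatic analog
of restricting manual selection to the visible aortic lumen/wall so that
bone and other high-density structures are never counted.

Discrete lesions are maximal connected components of the calcium mask.
The default adjacency is the 26-neighborhood (faces, edges and vertices);
6-connectivity is available.  Lesions smaller than a minimum voxel count
(default 4) are discarded, the standard minimum-size rule for calcium
scoring.  The rule is applied per 3-D lesion by default; a per-axial-slice
variant is provided for workflows that treat each slice independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume
from .errors import ValidationError
from .thresholding import ThresholdResult

__all__ = [
    "CalciumMask",
    "Lesion",
    "LesionSet",
    "segment_calcium",
    "label_lesions",
    "filter_min_voxels",
    "apply_min_size_per_slice",
    "lesion_count",
    "CONNECTIVITY_STRUCTURES",
]

CONNECTIVITY_STRUCTURES = {
    "face": ndimage.generate_binary_structure(3, 1),  # 6-neighborhood
    "face_edge_vertex": ndimage.generate_binary_structure(3, 3),  # 26
}


@dataclass
class CalciumMask:
    """Binary calcium mask aligned voxel-for-voxel with its source volume.

    Carries the source HU grid and spacing so that lesion statistics
    (volume, maximum density) can be computed without re-threading the
    original volume.
    """

    mask: np.ndarray
    threshold_used: float
    region_restricted: bool
    spacing: tuple[float, float, float]
    hu: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.hu.shape:
            raise ValidationError("mask and source HU grid shapes differ")


@dataclass(frozen=True)
class Lesion:
    label_id: int
    voxel_count: int
    volume_mm3: float
    max_hu: float
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class LesionSet:
    """Labeled calcium lesions plus the labeling parameters that made them.

    ``labels`` is the 3-D label grid (0 = background, lesion ids contiguous
    from 1); ``spacing`` is inherited from the source mask.
    """

    lesions: tuple[Lesion, ...]
    connectivity: str
    min_voxels_applied: int
    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.lesions)

    @property
    def total_voxels(self) -> int:
        return sum(l.voxel_count for l in self.lesions)

    @property
    def total_volume_mm3(self) -> float:
        return sum(l.volume_mm3 for l in self.lesions)


def segment_calcium(
    volume: CTVolume,
    threshold: ThresholdResult | float,
    aortic_region: np.ndarray | None = None,
) -> CalciumMask:
    """Binary calcium mask: HU >= threshold, optionally region-restricted."""
    thr = (
        threshold.selected_threshold
        if isinstance(threshold, ThresholdResult)
        else float(threshold)
    )
    mask = volume.intensities >= thr
    restricted = aortic_region is not None
    if restricted:
        region = np.asarray(aortic_region).astype(bool)
        if region.shape != volume.shape:
            raise ValidationError(
                f"aortic region shape {region.shape} != volume shape {volume.shape}"
            )
        mask &= region
    return CalciumMask(
        mask=mask,
        threshold_used=thr,
        region_restricted=restricted,
        spacing=volume.spacing,
        hu=volume.intensities,
    )


def label_lesions(
    mask: CalciumMask, connectivity: str = "face_edge_vertex"
) -> LesionSet:
    """Partition the calcium mask into maximal connected components.

    Computes per-lesion voxel count, physical volume, maximum HU and the
    inclusive index bounding box.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValidationError(f"unknown connectivity {connectivity!r}")
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    labels, n = ndimage.label(mask.mask, structure=structure)
    voxel_vol = float(np.prod(mask.spacing))
    lesions = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        max_hu = ndimage.labeled_comprehension(
            mask.hu, labels, np.arange(1, n + 1), np.max, float, np.nan
        )
        slices = ndimage.find_objects(labels)
        for i in range(n):
            sl = slices[i]
            bbox = tuple((s.start, s.stop - 1) for s in sl)
            lesions.append(
                Lesion(
                    label_id=i + 1,
                    voxel_count=int(counts[i]),
                    volume_mm3=int(counts[i]) * voxel_vol,
                    max_hu=float(max_hu[i]),
                    bounding_box=bbox,  # type: ignore[arg-type]
                )
            )
    return LesionSet(
        lesions=tuple(lesions),
        connectivity=connectivity,
        min_voxels_applied=1,
        labels=labels,
        spacing=mask.spacing,
    )


def filter_min_voxels(lesions: LesionSet, min_voxels: int = 4) -> LesionSet:
    """Drop lesions below the minimum voxel count and relabel from 1.

    The default of 4 is the conventional minimum lesion size for calcium
    scoring.  Idempotent: filtering an already-filtered set is a no-op
    (beyond updating ``min_voxels_applied``).
    """
    if min_voxels < 1:
        raise ValidationError("min_voxels must be >= 1")
    keep = [l for l in lesions.lesions if l.voxel_count >= min_voxels]
    remap = np.zeros(len(lesions.lesions) + 1, dtype=lesions.labels.dtype)
    new_lesions = []
    for new_id, lesion in enumerate(keep, start=1):
        remap[lesion.label_id] = new_id
        new_lesions.append(replace(lesion, label_id=new_id))
    return LesionSet(
        lesions=tuple(new_lesions),
        connectivity=lesions.connectivity,
        min_voxels_applied=max(min_voxels, lesions.min_voxels_applied),
        labels=remap[lesions.labels],
        spacing=lesions.spacing,
    )


def apply_min_size_per_slice(
    mask: CalciumMask, min_voxels: int = 4
) -> CalciumMask:
    """Per-axial-slice variant of the minimum-size rule.

    Labels each axial slice independently (2-D 8-connectivity) and removes
    in-plane components smaller than ``min_voxels``; the caller then labels
    the cleaned mask in 3-D.
    """
    structure = np.ones((3, 3), dtype=bool)
    cleaned = mask.mask.copy()
    for k in range(cleaned.shape[2]):
        labels, n = ndimage.label(cleaned[:, :, k], structure=structure)
        if not n:
            continue
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        cleaned[:, :, k] &= ~np.isin(labels, small[small > 0])
    return CalciumMask(
        mask=cleaned,
        threshold_used=mask.threshold_used,
        region_restricted=mask.region_restricted,
        spacing=mask.spacing,
        hu=mask.hu,
    )


def lesion_count(lesions: LesionSet) -> int:
    """Number of lesions after filtering."""
    return len(lesions.lesions)
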