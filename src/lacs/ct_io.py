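"""Reading, writing and resampling of CT volumes.

The in-memory currency of the package is :class:`CTVolume`: a 3-D grid of
Hounsfield units (HU) with per-axis voxel spacing and a physical origin.
Grid axes follow a fixed internal convention,

* axis 0 (``x``): in-plane, left -> right,
* axis 1 (``y``): in-plane, posterior -> anterior,
* axis 2 (``z``): axial, inferior -> superior,

with the voxel-center convention: grid index ``i`` maps to physical
position ``origin + i * spacing`` (mm).  NIfTI volumes are reoriented to
this convention on load; DICOM series are assumed to be axial acquisitions
and are stacked in ascending slice position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import (
    AmbiguousSeriesError,
    FormatError,
    IOFailure,
    MissingRescaleError,
    ValidationError,
)

__all__ = [
    "CTVolume",
    "HU_MIN",
    "HU_MAX",
    "load_volume",
    "save_volume",
    "resample_slice_thickness",
]

#: Physically plausible HU range enforced on every CTVolume.
HU_MIN = -1100.0
HU_MAX = 4100.0


@dataclass
class CTVolume:
    """A 3-D CT image in Hounsfield units.

    Parameters
    ----------
    intensities
        3-D array of HU values, axes ``(x, y, z)`` per the module convention.
    spacing
        Per-axis voxel size in mm, ``(sx, sy, sz)``; all components > 0.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    axis_order
        Anatomical direction of increasing index on each grid axis.  Kept as
        a declaration; volumes are normalized to ``"RAS"`` on load.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "RAS"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"intensities must be 3-D, got ndim={self.intensities.ndim}"
            )
        if min(self.intensities.shape) < 1:
            raise ValidationError("every grid dimension must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        lo = float(self.intensities.min())
        hi = float(self.intensities.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValidationError(
                f"HU values [{lo}, {hi}] outside plausible range [{HU_MIN}, {HU_MAX}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (product of the spacing components)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map grid indices (possibly fractional) to physical mm positions."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of exceptions
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)  # normalize axes to RAS; idempotent
    data = np.asanyarray(img.dataobj)  # applies scl_slope/scl_inter if set
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data, tuple(float(z) for z in zooms), origin)


def _load_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # ignore non-DICOM files (DICOMDIR, txt, ...)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no DICOM image slices found in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise AmbiguousSeriesError(
            f"{path} mixes {len(uids)} DICOM series; supply a single-series directory"
        )
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise MissingRescaleError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; HU undefined"
            )
    # sort inferior -> superior on the z component of the patient position
    def _zpos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)
    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        # pixel_array is (rows, cols) = (y, x); transpose to (x, y)
        slices.append(hu.T)
    vol = np.stack(slices, axis=-1)
    ds0 = datasets[0]
    row_sp, col_sp = (float(v) for v in ds0.PixelSpacing)  # (dy, dx)
    if len(datasets) > 1:
        zs = np.diff([_zpos(ds) for ds in datasets])
        if np.ptp(zs) > 1e-3:
            raise FormatError("non-uniform DICOM slice spacing")
        sz = float(np.mean(zs))
    else:
        sz = float(getattr(ds0, "SliceThickness", 1.0))
    origin = (0.0, 0.0, 0.0)
    if "ImagePositionPatient" in ds0:
        origin = tuple(float(v) for v in ds0.ImagePositionPatient)
    return CTVolume(vol, (col_sp, row_sp, sz), origin)


def load_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a single-series DICOM directory.

    ``format`` may be ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred (directory -> DICOM series, file -> NIfTI).  DICOM stored values
    are converted to HU with the rescale slope/intercept; missing rescale
    tags raise :class:`~lacs.errors.MissingRescaleError` rather than passing
    stored values through silently.
    """
    p = Path(path)
    if not p.exists():
        raise IOFailure(f"{p} does not exist")
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(p)
    if format == "dicom_series":
        if not p.is_dir():
            raise FormatError(f"{p} is not a directory of DICOM slices")
        return _load_dicom_series(p)
    raise ValidationError(f"unknown format {format!r}")


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write ``volume`` to a NIfTI-1 file.

    Integer HU grids are stored as int16 so that ``load_volume(save_volume(v))``
    round-trips bit-exactly; floating-point grids are stored as float64.
    """
    p = Path(path)
    if not p.parent.exists():
        raise IOFailure(f"parent directory {p.parent} does not exist")
    data = volume.intensities
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(p))
    except Exception as exc:
        raise IOFailure(f"cannot write {p}: {exc}") from exc


def resample_slice_thickness(
    volume: CTVolume, new_z_spacing: float, method: str = "mean_binning"
) -> CTVolume:
    """Resample a volume to a new axial (z) spacing.

    ``mean_binning`` emulates a thick-slice reconstruction: each output slice
    is the arithmetic mean of all native slices whose centers fall in the
    half-open z-interval ``[k*new_z, (k+1)*new_z)`` measured from the first
    native slice center.  The in-plane grid is unchanged and the physical
    z-extent is preserved to within one output slice.  ``linear`` interpolates
    slice profiles at the new slice centers instead.
    """
    if new_z_spacing <= 0:
        raise ValidationError("new_z_spacing must be > 0")
    sx, sy, sz = volume.spacing
    nz = volume.shape[2]
    data = volume.intensities
    if method == "mean_binning":
        if new_z_spacing < sz - 1e-12:
            raise ValidationError(
                "mean_binning cannot upsample: new_z_spacing "
                f"{new_z_spacing} < native {sz}"
            )
        centers = np.arange(nz) * sz
        n_out = int(np.ceil(nz * sz / new_z_spacing))
        bins = np.floor(centers / new_z_spacing).astype(int)
        bins = np.clip(bins, 0, n_out - 1)
        out = np.empty(volume.shape[:2] + (n_out,), dtype=np.float64)
        keep = []
        for k in range(n_out):
            sel = bins == k
            if not sel.any():
                continue  # trailing bin past the last native center
            out[..., len(keep)] = data[..., sel].mean(axis=2)
            keep.append(k)
        out = out[..., : len(keep)]
        new_origin_z = volume.origin[2] + (new_z_spacing - sz) / 2.0
    elif method == "linear":
        old_z = np.arange(nz) * sz
        n_out = int(np.floor(old_z[-1] / new_z_spacing)) + 1 if nz > 1 else 1
        new_z = np.arange(n_out) * new_z_spacing
        out = np.empty(volume.shape[:2] + (n_out,), dtype=np.float64)
        for k, zq in enumerate(new_z):
            j = min(int(np.floor(zq / sz)), nz - 1) if nz > 1 else 0
            j2 = min(j + 1, nz - 1)
            t = 0.0 if j == j2 else (zq - old_z[j]) / sz
            out[..., k] = (1 - t) * data[..., j] + t * data[..., j2]
        new_origin_z = volume.origin[2]
    else:
        raise ValidationError(f"unknown resampling method {method!r}")
    return CTVolume(
        out,
        (sx, sy, float(new_z_spacing)),
        (volume.origin[0], volume.origin[1], float(new_origin_z)),
        volume.axis_order,
    )
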