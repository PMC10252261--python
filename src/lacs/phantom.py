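"""Synthetic paired contrast/noncontrast CT phantoms of an abdominal aorta.

The generator fabricates the geometry the scoring pipeline expects — a
straight (or polyline-axis) aortic lumen with a soft-tissue wall embedded
in a uniform background, carrying ellipsoidal calcified plaques — and
renders it twice per reconstruction: once with an opacified blood pool
(contrast phase) and once with unenhanced blood (noncontrast phase).  The
two volumes of a pair share every stochastic field (plaque texture, image
noise, the standardized lumen texture field) so that any score difference
between them is attributable to the blood-pool attenuation and the
segmentation threshold alone.

Image formation, per reconstruction (z spacing):

1. paint background, then wall, then lumen, then plaques, each by
   voxel-center inclusion in its geometric support;
2. isotropic Gaussian blur of configurable FWHM — a partial-volume /
   blooming surrogate, not a scanner PSF model;
3. additive Gaussian HU noise.

Ground truth is fixed before blur: the voxelized plaque volumes at each
reconstruction grid, plus the exact centerline polyline and its arc
length.  Plaques may not overlap (truth volumes must be unambiguous) and
must lie inside the grid.

Default condition emulated: an opacified aorta at ~350 HU mean blood-pool
attenuation with ~50 HU texture SD — so that mean + 3 SD lands near the
500 HU patient-specific thresholds typical of arterial-phase abdominal
CT — against a ~40 HU unenhanced blood pool, reconstructed at 0.75 mm and
2.0 mm slice thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, HU_MAX, HU_MIN
from .errors import ValidationError
from .thresholding import RegionOfInterest

__all__ = [
    "PlaqueSpec",
    "PhantomSpec",
    "ReconTruth",
    "PhantomReconstruction",
    "PhantomPair",
    "generate_phantom_pair",
    "ground_truth_volume",
    "default_rois",
    "random_phantom_spec",
    "score_phantom_phase",
    "generate_population",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PlaqueSpec:
    """One ellipsoidal calcified plaque.

    ``center`` and ``semi_axes`` are physical mm; ``hu_mean`` must be at
    least 130 HU (a calcification by definition), with optional per-voxel
    texture SD ``hu_sd``.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    hu_mean: float
    hu_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("plaque semi-axes must be > 0")
        if self.hu_mean < 130:
            raise ValidationError("plaque hu_mean must be >= 130 HU")
        if self.hu_sd < 0:
            raise ValidationError("plaque hu_sd must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a paired phantom.

    The axial grid is ``shape_xy`` at ``spacing_xy``; each entry of
    ``reconstructions`` (a z spacing in mm) produces its own grid covering
    ``z_extent_mm``.  ``axis_points`` (physical mm, ordered by z) defaults
    to a straight vertical axis through the grid center.
    """

    shape_xy: tuple[int, int] = (128, 128)
    spacing_xy: tuple[float, float] = (0.7, 0.7)
    z_extent_mm: float = 60.0
    reconstructions: tuple[float, ...] = (0.75, 2.0)
    lumen_radius_mm: float = 9.0
    wall_thickness_mm: float = 2.0
    wall_hu: float = 60.0
    background_hu: float = 30.0
    contrast_lumen: tuple[float, float] = (350.0, 50.0)
    noncontrast_lumen: tuple[float, float] = (40.0, 10.0)
    plaques: tuple[PlaqueSpec, ...] = ()
    blur_fwhm_mm: float = 1.4
    noise_sd_hu: float = 10.0
    seed: int = 0
    axis_points: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_xy) or self.z_extent_mm <= 0:
            raise ValidationError("spacing and z extent must be > 0")
        if not self.reconstructions or any(z <= 0 for z in self.reconstructions):
            raise ValidationError("reconstructions must be positive z spacings")
        if self.contrast_lumen[0] <= 130:
            raise ValidationError(
                "contrast blood pool must exceed 130 HU (the premise of "
                "patient-specific thresholding)"
            )
        if self.noncontrast_lumen[0] >= 130:
            raise ValidationError("noncontrast blood pool must be below 130 HU")
        if self.blur_fwhm_mm < 0 or self.noise_sd_hu < 0:
            raise ValidationError("blur FWHM and noise SD must be >= 0")

    @property
    def center_xy_mm(self) -> tuple[float, float]:
        nx, ny = self.shape_xy
        sx, sy = self.spacing_xy
        return ((nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy)

    def axis_xy_at(self, z: np.ndarray) -> np.ndarray:
        """In-plane (x, y) position of the lumen axis at height(s) z (mm)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if self.axis_points is None:
            cx, cy = self.center_xy_mm
            return np.column_stack([np.full_like(z, cx), np.full_like(z, cy)])
        pts = np.asarray(self.axis_points, dtype=float)
        return np.column_stack(
            [np.interp(z, pts[:, 2], pts[:, 0]), np.interp(z, pts[:, 2], pts[:, 1])]
        )


@dataclass(frozen=True)
class ReconTruth:
    """Exact ground truth of one reconstruction grid."""

    z_spacing: float
    plaque_voxel_counts: tuple[int, ...]
    plaque_volumes_mm3: tuple[float, ...]
    total_volume_mm3: float
    centerline_points: np.ndarray  # (nz, 3) physical mm
    centerline_length_cm: float


@dataclass(frozen=True)
class PhantomReconstruction:
    z_spacing: float
    contrast: CTVolume
    noncontrast: CTVolume
    region: np.ndarray  # aortic region mask (lumen + wall + plaques)
    lumen_mask: np.ndarray
    truth: ReconTruth


@dataclass(frozen=True)
class PhantomPair:
    """All reconstructions of one paired phantom, keyed by z spacing."""

    spec: PhantomSpec
    reconstructions: dict[float, PhantomReconstruction]

    def recon(self, z_spacing: float | None = None) -> PhantomReconstruction:
        if z_spacing is None:
            z_spacing = self.spec.reconstructions[0]
        if z_spacing not in self.reconstructions:
            raise ValidationError(
                f"no reconstruction at {z_spacing} mm; have "
                f"{sorted(self.reconstructions)}"
            )
        return self.reconstructions[z_spacing]


def _render_reconstruction(
    spec: PhantomSpec, z_spacing: float, rng: np.random.Generator
) -> PhantomReconstruction:
    nx, ny = spec.shape_xy
    sx, sy = spec.spacing_xy
    nz = max(int(round(spec.z_extent_mm / z_spacing)), 1)
    shape = (nx, ny, nz)

    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    zs = np.arange(nz) * z_spacing
    axis_xy = spec.axis_xy_at(zs)  # (nz, 2)

    dx = xs[:, None, None] - axis_xy[None, None, :, 0]  # (nx, 1, nz)
    dy = ys[None, :, None] - axis_xy[None, None, :, 1]  # (1, ny, nz)
    r2 = dx * dx + dy * dy
    lumen = r2 <= spec.lumen_radius_mm**2
    outer = r2 <= (spec.lumen_radius_mm + spec.wall_thickness_mm) ** 2

    # voxelize plaques by voxel-center inclusion; overlap and bounds checks
    plaque_masks = []
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    extent = (xs[-1], ys[-1], zs[-1])
    for p in spec.plaques:
        for c, a, hi in zip(p.center, p.semi_axes, extent):
            if c - a < 0 or c + a > hi:
                raise ValidationError(
                    f"plaque at {p.center} extends outside the grid "
                    f"(extent {extent} mm)"
                )
        m = (
            ((X - p.center[0]) / p.semi_axes[0]) ** 2
            + ((Y - p.center[1]) / p.semi_axes[1]) ** 2
            + ((Z - p.center[2]) / p.semi_axes[2]) ** 2
        ) <= 1.0
        plaque_masks.append(m)
    if plaque_masks:
        stack = np.sum(plaque_masks, axis=0)
        if np.any(stack > 1):
            raise ValidationError("plaques overlap; ground truth ambiguous")
        plaque_union = stack > 0
    else:
        plaque_union = np.zeros(shape, dtype=bool)

    # shared stochastic fields (standard normal), one draw per pair/recon
    lumen_field = rng.standard_normal(shape)
    plaque_field = rng.standard_normal(shape)
    noise_field = rng.standard_normal(shape)

    def compose(lumen_mean: float, lumen_sd: float) -> np.ndarray:
        img = np.full(shape, spec.background_hu, dtype=np.float64)
        img[outer] = spec.wall_hu
        img[lumen] = lumen_mean + lumen_sd * lumen_field[lumen]
        for p, m in zip(spec.plaques, plaque_masks):
            img[m] = p.hu_mean + p.hu_sd * plaque_field[m]
        if spec.blur_fwhm_mm > 0:
            sigma_vox = [
                spec.blur_fwhm_mm / _FWHM_TO_SIGMA / s for s in (sx, sy, z_spacing)
            ]
            img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
        if spec.noise_sd_hu > 0:
            img = img + spec.noise_sd_hu * noise_field
        return np.clip(img, HU_MIN, HU_MAX)

    cm, csd = spec.contrast_lumen
    nm, nsd = spec.noncontrast_lumen
    contrast = CTVolume(compose(cm, csd), (sx, sy, z_spacing))
    noncontrast = CTVolume(compose(nm, nsd), (sx, sy, z_spacing))

    voxel_vol = sx * sy * z_spacing
    counts = tuple(int(m.sum()) for m in plaque_masks)
    volumes = tuple(c * voxel_vol for c in counts)
    centerline = np.column_stack([axis_xy, zs])
    length_cm = (
        float(np.sum(np.linalg.norm(np.diff(centerline, axis=0), axis=1))) / 10.0
        if nz > 1
        else 0.0
    )
    truth = ReconTruth(
        z_spacing=z_spacing,
        plaque_voxel_counts=counts,
        plaque_volumes_mm3=volumes,
        total_volume_mm3=float(sum(volumes)),
        centerline_points=centerline,
        centerline_length_cm=length_cm,
    )
    return PhantomReconstruction(
        z_spacing=z_spacing,
        contrast=contrast,
        noncontrast=noncontrast,
        region=outer | plaque_union,
        lumen_mask=lumen,
        truth=truth,
    )


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Render the paired contrast/noncontrast volumes of ``spec``.

    Deterministic: two calls with the same spec (including seed) produce
    bit-identical volumes.  Each reconstruction uses an independent
    seed-derived stream; within a reconstruction the contrast and
    noncontrast volumes share all stochastic fields.
    """
    recons = {}
    for i, z in enumerate(spec.reconstructions):
        rng = np.random.default_rng([spec.seed, i])
        recons[z] = _render_reconstruction(spec, z, rng)
    return PhantomPair(spec=spec, reconstructions=recons)


def ground_truth_volume(pair: PhantomPair, z_spacing: float | None = None) -> float:
    """Total voxelized plaque volume (mm^3) at one reconstruction."""
    return pair.recon(z_spacing).truth.total_volume_mm3


def default_rois(
    spec: PhantomSpec, z_spacing: float | None = None, margin_mm: float = 2.5
) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Two lumen ROIs near the top and bottom of the phantom.

    Stand-ins for the celiac-trunk and aortic-bifurcation ROIs: circles
    centered on the lumen axis, ``margin_mm`` inside the lumen radius,
    placed two slices from either end of the stack (plaque-free zones for
    the default and population specs).
    """
    if z_spacing is None:
        z_spacing = spec.reconstructions[0]
    nz = max(int(round(spec.z_extent_mm / z_spacing)), 1)
    sx, sy = spec.spacing_xy
    r = spec.lumen_radius_mm - margin_mm
    if r <= 0:
        raise ValidationError("ROI margin leaves no lumen radius")
    rois = []
    for slice_index, label in ((nz - 3, "celiac trunk"), (2, "above bifurcation")):
        ax, ay = spec.axis_xy_at(np.array([slice_index * z_spacing]))[0]
        rois.append(
            RegionOfInterest(
                slice_index=int(slice_index),
                circle=(float(ax / sx), float(ay / sy), float(r)),
                label=label,
            )
        )
    return rois[0], rois[1]


def _place_plaques(
    spec_center: tuple[float, float],
    lumen_radius: float,
    z_extent: float,
    rng: np.random.Generator,
    n_large: int,
    n_small: int,
    large_hu: float = 800.0,
    small_hu: float = 800.0,
    hu_sd: float = 30.0,
) -> tuple[PlaqueSpec, ...]:
    """Random non-overlapping wall plaques: large (volume carriers) and
    small (lesions at the resolution limit)."""
    cx, cy = spec_center
    placed: list[tuple[np.ndarray, float]] = []
    plaques = []
    sizes = [("large",)] * n_large + [("small",)] * n_small
    for kind, in sizes:
        if kind == "large":
            a_xy = rng.uniform(2.5, 4.5)
            a_z = rng.uniform(2.0, 3.5)
        else:
            a_xy = rng.uniform(0.7, 1.0)
            a_z = rng.uniform(0.7, 1.0)
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi)
            zc = rng.uniform(0.2 * z_extent, 0.8 * z_extent)
            center = np.array(
                [
                    cx + lumen_radius * np.cos(theta),
                    cy + lumen_radius * np.sin(theta),
                    zc,
                ]
            )
            radius = max(a_xy, a_z)
            ok = all(
                np.linalg.norm(center - c0) > radius + r0 + 4.0
                for c0, r0 in placed
            )
            if ok:
                placed.append((center, radius))
                plaques.append(
                    PlaqueSpec(
                        center=tuple(center),
                        semi_axes=(a_xy, a_xy, a_z),
                        hu_mean=large_hu if kind == "large" else small_hu,
                        hu_sd=hu_sd,
                    )
                )
                break
        else:
            raise ValidationError("could not place plaques without overlap")
    return tuple(plaques)


def random_phantom_spec(
    seed: int,
    n_large: int | None = None,
    n_small: int | None = None,
    **overrides,
) -> PhantomSpec:
    """A randomized member of the phantom population.

    Draws 1–3 large and 2–6 small wall plaques at random positions
    (seed-determined); any :class:`PhantomSpec` field can be overridden.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec(**{k: v for k, v in overrides.items() if k != "plaques"})
    if n_large is None:
        n_large = int(rng.integers(1, 4))
    if n_small is None:
        n_small = int(rng.integers(2, 7))
    plaques = _place_plaques(
        base.center_xy_mm,
        base.lumen_radius_mm,
        base.z_extent_mm,
        rng,
        n_large=n_large,
        n_small=n_small,
    )
    fields = {**overrides, "plaques": plaques, "seed": seed}
    return PhantomSpec(**fields)


def score_phantom_phase(
    pair: PhantomPair,
    z_spacing: float | None = None,
    phase: str = "contrast",
    min_voxels: int = 4,
    connectivity: str = "face_edge_vertex",
    sd_multiplier: float = 3.0,
    correction_factor_value: float | None = None,
):
    """Run the full scoring pipeline on one phase of a phantom pair.

    Contrast phase: patient-specific threshold from the two default lumen
    ROIs; noncontrast phase: fixed 130 HU.  Segmentation is restricted to
    the aortic region; the centerline is derived from the lumen mask.
    Returns a :class:`~lacs.scoring.ScoreReport`.
    """
    from .calcium_segmentation import filter_min_voxels, label_lesions, segment_calcium
    from .scoring import (
        DEFAULT_CORRECTION_FACTOR,
        centerline_from_mask,
        score_report,
    )
    from .thresholding import fixed_threshold, patient_specific_threshold

    recon = pair.recon(z_spacing)
    if phase == "contrast":
        volume = recon.contrast
        upper, lower = default_rois(pair.spec, recon.z_spacing)
        thr = patient_specific_threshold(volume, upper, lower, sd_multiplier)
    elif phase == "noncontrast":
        volume = recon.noncontrast
        thr = fixed_threshold()
    else:
        raise ValidationError(f"unknown phase {phase!r}")
    mask = segment_calcium(volume, thr, recon.region)
    lesions = filter_min_voxels(label_lesions(mask, connectivity), min_voxels)
    centerline = centerline_from_mask(recon.lumen_mask, volume)
    factor = (
        DEFAULT_CORRECTION_FACTOR
        if correction_factor_value is None
        else correction_factor_value
    )
    return score_report(
        lesions,
        centerline,
        phase,
        thr.selected_threshold,
        correction_factor=factor,
    )


def generate_population(n: int, seed: int = 0, **overrides) -> list[PhantomPair]:
    """Generate ``n`` randomized paired phantoms (the synthetic cohort)."""
    root = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        s = int(root.integers(0, 2**31 - 1))
        pairs.append(generate_phantom_pair(random_phantom_spec(s, **overrides)))
    return pairs
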