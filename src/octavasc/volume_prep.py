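"""Surface referencing of angiographic volumes.

The cortical surface under a cranial window is neither flat nor exactly
perpendicular to the scanning beam, so depth below the surface — the
physiologically meaningful axial coordinate — must be recovered before any
depth-resolved analysis.  This module detects the surface, fits and removes
the tilt plane (so every A-line is referenced to depth 0 at the surface),
and produces en-face projections and contiguous axial depth bins.

Depth convention: 0-based micrometres below the fitted cortical surface,
half-open bins [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .angiograph import AngioVolume

__all__ = [
    "EnFaceImage",
    "detect_surface",
    "detilt",
    "project_enface",
    "bin_axially",
]


@dataclass
class EnFaceImage:
    """Axial projection of a depth slab onto the lateral plane."""

    pixels: np.ndarray
    depth_range_um: tuple[float, float]
    projection_kind: str = "max"
    pixel_um: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range_um
        if not lo < hi:
            raise ValueError("depth range must satisfy lo < hi")
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("projection pixels must be non-negative")


def detect_surface(
    volume: AngioVolume,
    threshold_rule: str = "otsu",
    smooth_um: float = 6.0,
    max_missing_fraction: float = 0.5,
) -> np.ndarray:
    """Per-(y, x) axial index of the first tissue voxel.

    The volume is smoothed axially, a global threshold separates the dark
    region above the surface from tissue, and the first supra-threshold
    index is taken per A-line.  Because bright vessels would dominate a
    plain two-class Otsu split on an angiogram, intensities are clipped at a
    robust upper percentile before thresholding so the split falls between
    air and tissue rather than between tissue and vessels.  Columns without
    a detection are filled by 2D median interpolation.
    """
    vox = volume.voxels
    if vox.size == 0 or float(vox.max()) == 0.0:
        raise ValueError("surface undetectable: empty or all-zero volume")
    sigma = smooth_um / volume.voxel_um[0]
    sm = ndimage.gaussian_filter1d(vox.astype(np.float32), sigma=sigma, axis=0)
    if threshold_rule == "otsu":
        clipped = np.minimum(sm, np.percentile(sm, 90.0))
        thr = float(threshold_otsu(clipped[:: max(sm.shape[0] // 64, 1)]))
    elif threshold_rule == "half-median":
        thr = 0.5 * float(np.median(sm[sm > 1e-4])) if (sm > 1e-4).any() else 0.0
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    above = sm > thr
    has = above.any(axis=0)
    missing = 1.0 - has.mean()
    if missing > max_missing_fraction:
        raise ValueError(
            f"surface undetectable: {missing:.0%} of A-lines have no "
            "supra-threshold voxel"
        )
    first = np.argmax(above, axis=0).astype(float)
    if not has.all():
        fill = ndimage.median_filter(np.where(has, first, 0.0), size=9)
        first = np.where(has, first, fill)
    # final smoothing knocks down per-column speckle jitter
    return ndimage.median_filter(first, size=5)


def _fit_plane(surface: np.ndarray) -> tuple[float, float, float]:
    """Least-squares plane z = a*y + b*x + c through the surface map."""
    ny, nx = surface.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([yy.ravel(), xx.ravel(), np.ones(surface.size)])
    coef, _, rank, _ = np.linalg.lstsq(A, surface.ravel(), rcond=None)
    if rank < 3:
        raise ValueError("plane fit rank-deficient")
    return float(coef[0]), float(coef[1]), float(coef[2])


def detilt(
    volume: AngioVolume, surface: np.ndarray | None = None
) -> AngioVolume:
    """Shift every A-line axially so the fitted surface plane becomes flat.

    A least-squares plane is fitted to the detected surface map; each column
    is resampled (linear interpolation) so the plane maps to a constant
    axial index.  After de-tilting, ``surface_z`` is a constant map and the
    depth coordinate means "um below the cortical surface".
    """
    if surface is None:
        surface = volume.surface_z
    if surface is None:
        surface = detect_surface(volume)
    a, b, c = _fit_plane(surface)
    nz, ny, nx = volume.voxels.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    plane = a * yy + b * xx + c
    z_ref = float(np.median(plane))
    shift = plane - z_ref  # positive: surface deeper than reference
    vox = volume.voxels
    out = np.zeros_like(vox)
    z_axis = np.arange(nz, dtype=np.float32)[:, None]
    x_idx = np.arange(nx)[None, :]
    for y in range(ny):
        zc = z_axis + shift[y][None, :].astype(np.float32)  # (nz, nx)
        k = np.floor(zc).astype(int)
        frac = zc - k
        k0 = np.clip(k, 0, nz - 1)
        k1 = np.clip(k + 1, 0, nz - 1)
        valid = ((zc >= -1e-6) & (zc <= nz - 1 + 1e-6)).astype(np.float32)
        plane_v = vox[:, y, :]
        out[:, y, :] = (
            (1.0 - frac) * plane_v[k0, x_idx] + frac * plane_v[k1, x_idx]
        ) * valid
    flat_surface = np.full((ny, nx), z_ref)
    return AngioVolume(
        voxels=np.clip(out, 0.0, 1.0).astype(np.float32),
        voxel_um=volume.voxel_um,
        surface_z=flat_surface,
        provenance={
            **volume.provenance,
            "detilt_plane": (a, b, c),
            "surface_ref_px": z_ref,
        },
    )


def fitted_tilt_deg(surface: np.ndarray, voxel_um: float) -> float:
    """Tilt angle (about the slow axis) implied by a surface map, degrees."""
    a, b, _ = _fit_plane(surface)
    return float(np.degrees(np.arctan(np.hypot(a, b))))


def _slab_indices(
    volume: AngioVolume, lo_um: float, hi_um: float
) -> tuple[int, int]:
    if volume.surface_z is None:
        raise ValueError("volume must be flattened (detilt) before projection")
    z0 = float(np.median(volume.surface_z))
    vz = volume.voxel_um[0]
    k_lo = int(np.floor(z0 + lo_um / vz))
    k_hi = int(np.floor(z0 + hi_um / vz))
    nz = volume.voxels.shape[0]
    k_lo = max(k_lo, 0)
    k_hi = min(k_hi, nz)
    if k_hi <= k_lo:
        raise ValueError(f"empty depth slab [{lo_um}, {hi_um}) after clipping")
    return k_lo, k_hi


def project_enface(
    volume: AngioVolume, lo_um: float, hi_um: float, kind: str = "max"
) -> EnFaceImage:
    """Project the depth slab [lo_um, hi_um) below the surface onto (y, x)."""
    if not 0 <= lo_um < hi_um:
        raise ValueError("need 0 <= lo_um < hi_um")
    k_lo, k_hi = _slab_indices(volume, lo_um, hi_um)
    slab = volume.voxels[k_lo:k_hi]
    if kind == "max":
        pix = slab.max(axis=0)
    elif kind == "mean":
        pix = slab.mean(axis=0)
    else:
        raise ValueError(f"unknown projection kind {kind!r}")
    return EnFaceImage(
        pixels=pix,
        depth_range_um=(lo_um, hi_um),
        projection_kind=kind,
        pixel_um=volume.voxel_um[1],
    )


def bin_axially(
    volume: AngioVolume,
    bin_um: float = 25.0,
    max_depth_um: float = 400.0,
    kind: str = "max",
) -> list[EnFaceImage]:
    """Contiguous half-open depth slabs [k*bin, (k+1)*bin) below the surface,
    each projected en face; covers 0..max_depth_um."""
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    n = int(np.ceil(max_depth_um / bin_um))
    out = []
    for k in range(n):
        lo = k * bin_um
        hi = min((k + 1) * bin_um, max_depth_um)
        try:
            out.append(project_enface(volume, lo, hi, kind=kind))
        except ValueError:
            # slab lies below the scanned depth: empty projection
            out.append(
                EnFaceImage(
                    pixels=np.zeros(volume.voxels.shape[1:], dtype=np.float32),
                    depth_range_um=(lo, hi),
                    projection_kind=kind,
                    pixel_um=volume.voxel_um[1],
                )
            )
    return out
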