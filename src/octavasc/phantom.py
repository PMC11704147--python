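"""Synthetic cortical vascular phantoms with ground truth.

The phantom emulates the salient features of a cranial-window OCT-A
acquisition over ~1 mm of mouse cortex: a tilted cortical surface, a dark
region above it, weakly decorrelating tissue below, bright tubular vessels
whose diameters follow a capillary-dominated mixture (lognormal mode near
6-8 um plus medium 15-20 um arterioles and large >20 um surface vessels),
multiplicative speckle, and multiple-scattering "projection tails" that
smear angiographic signal axially below each vessel.

Vessels are rendered with a radially Gaussian decorrelation profile whose
full width at half maximum equals the true diameter, so that FWHM diametry
has a well-defined ground truth.  Depth stratification places large vessels
preferentially near the surface.

Three generators are provided:

* :func:`build_phantom` — one ground-truthed angiographic volume,
* :func:`build_frame_stack` — repeated-amplitude B-scan frames with
  programmable intravascular speckle decorrelation, for testing the
  angiogram computation itself,
* :func:`build_study` / :func:`iter_study_volumes` — a multi-animal,
  four-timepoint dilation study with per-class effect factors, animal-level
  effect variability and small rigid inter-timepoint drift.

A fast branch-table-level simulator (:func:`simulate_track_table`) skips the
imaging entirely and is used for statistical calibration experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .angiograph import AngioVolume, FrameStack

__all__ = [
    "TIMEPOINTS",
    "CLASS_LABELS",
    "PhantomSpec",
    "GroundTruthBranch",
    "DilationScenario",
    "GenerationError",
    "build_phantom",
    "build_frame_stack",
    "build_study",
    "iter_study_volumes",
    "study_truth_table",
    "simulate_track_table",
    "sham_scenario",
    "low_intensity_scenario",
    "high_intensity_scenario",
]

#: Imaging timeline: baseline, 1 min after the first sonication, 10 min after
#: the first sonication, and 10 min after the second sonication.
TIMEPOINTS = ("pre", "post1_1min", "post1_10min", "post2_10min")

#: Diameter classes by baseline diameter in micrometres.
CLASS_LABELS = ("<15", "15-20", ">20")


class GenerationError(RuntimeError):
    """Raised when a phantom request is geometrically infeasible."""


def _default_depth_profile() -> dict:
    # (distribution, parameters in um below surface); large vessels are
    # weighted toward the surface, capillaries spread through the depth.
    # ranges leave room for the surface offset and tilt inside the default
    # 400-um axial grid
    return {
        "<15": ("uniform", (25.0, 300.0)),
        "15-20": ("beta", (1.2, 1.8, 25.0, 250.0)),
        ">20": ("beta", (1.0, 2.5, 15.0, 165.0)),
    }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic angiographic volume.

    ``domain_size_um`` is the (x, y, z) extent; the voxel grid is isotropic
    at ``voxel_um``.  Vessel counts are per diameter class (>20, 15-20 and
    <15 um).  Small-vessel diameters are lognormal with the given arithmetic
    mean and SD; medium diameters are uniform on [15, 20); large diameters
    are 20 um plus an exponential tail.  ``tail_strength`` scales the
    projection-artifact intensity relative to the parent vessel and
    ``speckle_cv`` is the coefficient of variation of the multiplicative
    speckle.
    """

    domain_size_um: tuple[float, float, float] = (600.0, 600.0, 400.0)
    voxel_um: float = 2.0
    n_large: int = 3
    n_medium: int = 3
    n_small: int = 24
    length_range_um: tuple[float, float] = (90.0, 260.0)
    small_diam_mean_um: float = 6.2
    small_diam_sd_um: float = 1.3
    depth_profile: dict = field(default_factory=_default_depth_profile)
    tilt_deg: float = 2.0
    tail_strength: float = 0.3
    tail_decay_um: float = 30.0
    speckle_cv: float = 0.2
    vessel_level: float = 0.6
    background_level: float = 0.12
    noise_floor: float = 0.004
    surface_z0_um: float = 50.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_large, self.n_medium, self.n_small) < 0:
            raise ValueError("vessel counts must be non-negative")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if not 0.0 <= self.tail_strength < 1.0:
            raise ValueError("tail_strength must lie in [0, 1)")
        if self.small_diam_mean_um < 5.0:
            raise ValueError(
                "small_diam_mean_um below the 5-um inclusion floor is not measurable"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel grid covering the domain."""
        x, y, z = self.domain_size_um
        v = self.voxel_um
        return (int(round(z / v)), int(round(y / v)), int(round(x / v)))


@dataclass
class GroundTruthBranch:
    """Exact geometry of one generated vessel branch.

    ``centerline_um`` holds ordered absolute (x, y, z) points in um;
    ``diameters_um`` maps timepoint label to the true diameter (a single
    'pre' entry for a one-timepoint phantom).  ``depth_um`` is the median
    centerline depth below the true (tilted) surface.
    """

    branch_id: str
    centerline_um: np.ndarray
    diameters_um: dict
    class_label: str
    depth_um: float

    def __post_init__(self) -> None:
        self.centerline_um = np.asarray(self.centerline_um, dtype=float)
        if self.centerline_um.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if any(d <= 0 for d in self.diameters_um.values()):
            raise ValueError("true diameters must be positive")
        if classify_diameter(self.diameters_um["pre"]) != self.class_label:
            raise ValueError("class_label inconsistent with pre diameter")

    @property
    def true_diameter_um(self) -> float:
        return self.diameters_um["pre"]


def classify_diameter(d_um: float, edges: tuple[float, float] = (15.0, 20.0)) -> str:
    lo, hi = edges
    if d_um < lo:
        return "<15"
    if d_um < hi:
        return "15-20"
    return ">20"


@dataclass
class DilationScenario:
    """Per-class multiplicative diameter effects over the imaging timeline.

    ``effect_by_class`` maps a class label to a dict of timepoint ->
    multiplicative factor on the baseline diameter.  The factor at 'pre' must
    be exactly 1.  ``inter_animal_sd`` is the SD of the animal-level
    multiplicative perturbation applied to the post-sonication factors,
    modelling between-animal variability of the response.
    """

    effect_by_class: dict
    n_animals: int = 10
    inter_animal_sd: float = 0.03
    timepoints: tuple[str, ...] = TIMEPOINTS
    max_drift_um: float = 5.0
    label: str = "custom"

    def __post_init__(self) -> None:
        for cls, factors in self.effect_by_class.items():
            if abs(factors.get("pre", 1.0) - 1.0) > 0:
                raise ValueError(f"'pre' factor for class {cls} must be exactly 1.0")
            if any(f <= 0 for f in factors.values()):
                raise ValueError("all effect factors must be positive")

    def factor(self, cls: str, timepoint: str) -> float:
        return float(self.effect_by_class.get(cls, {}).get(timepoint, 1.0))


def sham_scenario(n_animals: int = 3) -> DilationScenario:
    """No sonication: every factor 1.0, small physiological fluctuation."""
    eff = {c: {t: 1.0 for t in TIMEPOINTS} for c in CLASS_LABELS}
    return DilationScenario(
        effect_by_class=eff, n_animals=n_animals, inter_animal_sd=0.01, label="sham"
    )


def low_intensity_scenario(n_animals: int = 10) -> DilationScenario:
    """1 W/cm2 condition: ~17% small-vessel dilation at 1 min, persisting
    and growing modestly (1.17 / 1.23 / 1.27); larger classes unaffected."""
    eff = {
        "<15": {"pre": 1.0, "post1_1min": 1.17, "post1_10min": 1.23, "post2_10min": 1.27},
        "15-20": {"pre": 1.0, "post1_1min": 1.00, "post1_10min": 1.02, "post2_10min": 1.01},
        ">20": {"pre": 1.0, "post1_1min": 1.00, "post1_10min": 0.99, "post2_10min": 1.00},
    }
    return DilationScenario(
        effect_by_class=eff, n_animals=n_animals, inter_animal_sd=0.03, label="low"
    )


def high_intensity_scenario(n_animals: int = 10) -> DilationScenario:
    """10 W/cm2 condition: ~27% small-vessel dilation at 1 min."""
    eff = {
        "<15": {"pre": 1.0, "post1_1min": 1.27, "post1_10min": 1.30, "post2_10min": 1.32},
        "15-20": {"pre": 1.0, "post1_1min": 1.02, "post1_10min": 1.01, "post2_10min": 1.02},
        ">20": {"pre": 1.0, "post1_1min": 1.02, "post1_10min": 1.01, "post2_10min": 1.04},
    }
    return DilationScenario(
        effect_by_class=eff, n_animals=n_animals, inter_animal_sd=0.08, label="high"
    )


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------


def _sample_depth(rng: np.random.Generator, profile) -> float:
    kind, params = profile
    if kind == "uniform":
        lo, hi = params
        return float(rng.uniform(lo, hi))
    if kind == "beta":
        a, b, lo, span = params
        return float(lo + span * rng.beta(a, b))
    raise ValueError(f"unknown depth distribution {kind!r}")


def _truncated_lognormal_params(
    mean: float, sd: float, floor: float
) -> tuple[float, float]:
    """Underlying lognormal (mu, sigma) whose floor-truncated distribution
    has the requested arithmetic mean and SD.

    The capillary statistics of interest describe the measurable (>= 5 um)
    population, so the generator calibrates the untruncated parent so that
    the included population carries the stated moments.
    """
    from scipy.optimize import least_squares
    from scipy.stats import norm

    la = math.log(floor)

    def trunc_moments(params):
        mu, sg = params
        p = norm.sf((la - mu) / sg)
        m1 = math.exp(mu + sg * sg / 2.0) * norm.sf((la - mu - sg * sg) / sg) / p
        m2 = (
            math.exp(2.0 * mu + 2.0 * sg * sg)
            * norm.sf((la - mu - 2.0 * sg * sg) / sg)
            / p
        )
        return m1, math.sqrt(max(m2 - m1 * m1, 1e-12))

    def eqs(params):
        m1, s1 = trunc_moments(params)
        return (m1 - mean, s1 - sd)

    sigma0 = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
    mu0 = math.log(mean) - sigma0**2 / 2.0
    # bounded solve keeps the unimodal capillary-shaped root, not the
    # degenerate heavy-left-tail root that also matches the moments
    sol = least_squares(
        eqs,
        x0=(mu0, sigma0),
        bounds=((math.log(2.0), 0.02), (math.log(mean) + 0.5, 0.8)),
    )
    mu, sg = sol.x
    return float(mu), float(sg)


def _sample_diameters(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    # large: 20 um + exponential tail, emulating the long tail to >40 um
    for _ in range(spec.n_large):
        out.append((">20", 20.0 + min(float(rng.exponential(10.0)), 30.0)))
    for _ in range(spec.n_medium):
        out.append(("15-20", float(rng.uniform(15.0, 20.0))))
    if spec.n_small:
        mu, sg = _truncated_lognormal_params(
            spec.small_diam_mean_um, spec.small_diam_sd_um, floor=5.0
        )
        draws: list[float] = []
        while len(draws) < spec.n_small:
            batch = rng.lognormal(mean=mu, sigma=sg, size=spec.n_small)
            draws.extend(float(d) for d in batch if 5.0 <= d < 15.0)
        out.extend(("<15", d) for d in draws[: spec.n_small])
    return out


def _check_feasible(spec: PhantomSpec, diams: Sequence[tuple[str, float]]) -> None:
    """Reject requests whose projected vessel area would exceed half the field."""
    lx, ly, _ = spec.domain_size_um
    area = lx * ly
    mean_len = min(0.5 * sum(spec.length_range_um), 0.8 * min(lx, ly))
    cum = 0.0
    for cls in CLASS_LABELS[::-1]:  # large first
        cum += sum(d * mean_len for c, d in diams if c == cls)
        if cum / area > 0.5:
            raise GenerationError(
                f"vessel count infeasible for domain: class '{cls}' pushes "
                f"projected overlap fraction above 50%"
            )


def _make_centerline(
    spec: PhantomSpec, rng: np.random.Generator, step_um: float = 8.0
) -> np.ndarray:
    """A gently curved lateral path crossing the domain: straight direction
    plus a low-amplitude sinusoidal transverse wobble."""
    lx, ly, _ = spec.domain_size_um
    theta = rng.uniform(0.0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    center = np.array([rng.uniform(0.15 * lx, 0.85 * lx), rng.uniform(0.15 * ly, 0.85 * ly)])
    amp = rng.uniform(4.0, 12.0)
    lam = rng.uniform(200.0, 400.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    half = 1.2 * max(lx, ly)
    t = np.arange(-half, half + step_um, step_um)
    pts = center[None, :] + t[:, None] * d[None, :] + (
        amp * np.sin(2.0 * np.pi * t / lam + phase)
    )[:, None] * n[None, :]
    margin = 4.0
    inside = (
        (pts[:, 0] >= margin)
        & (pts[:, 0] <= lx - margin)
        & (pts[:, 1] >= margin)
        & (pts[:, 1] <= ly - margin)
    )
    # keep the longest contiguous run inside the domain
    if not inside.any():
        return pts[: 2]
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    best = max(runs, key=len)
    run = pts[best]
    # clip to a realistic junction-to-junction branch length
    target = rng.uniform(*spec.length_range_um)
    n_keep = max(int(target / step_um) + 1, 3)
    if run.shape[0] > n_keep:
        start = rng.integers(0, run.shape[0] - n_keep + 1)
        run = run[start : start + n_keep]
    return run


def _generate_truth(
    spec: PhantomSpec, rng: np.random.Generator, prefix: str = "b"
) -> list[GroundTruthBranch]:
    diams = _sample_diameters(spec, rng)
    _check_feasible(spec, diams)
    tan = math.tan(math.radians(spec.tilt_deg))
    truth: list[GroundTruthBranch] = []
    for i, (cls, d) in enumerate(diams):
        depth = _sample_depth(rng, spec.depth_profile[cls])
        xy = _make_centerline(spec, rng)
        if xy.shape[0] < 3:
            continue
        z = spec.surface_z0_um + tan * xy[:, 0] + depth
        cl = np.column_stack([xy, z])
        truth.append(
            GroundTruthBranch(
                branch_id=f"{prefix}{i:03d}",
                centerline_um=cl,
                diameters_um={"pre": d},
                class_label=cls,
                depth_um=depth,
            )
        )
    return truth


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------


def _point_segment_dist2(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min squared distance from each 2D point to each segment; returns the
    per-point minimum over segments."""
    ab = b - a  # (S, 2)
    ab2 = (ab * ab).sum(axis=1)  # (S,)
    ab2 = np.where(ab2 > 0, ab2, 1.0)
    # (P, S, 2) differences kept lazily via einsum-style expansion
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    diff = pts[:, None, :] - closest
    return (diff * diff).sum(axis=2).min(axis=1)


def _render_vessels(
    spec: PhantomSpec,
    truth: Sequence[GroundTruthBranch],
    timepoint: str = "pre",
    drift_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Noise-free vessel intensity volume: radial Gaussian tubes with
    FWHM equal to the true diameter, peak ``vessel_level``."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_um
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    ln2x4 = 4.0 * np.log(2.0)
    tan = math.tan(math.radians(spec.tilt_deg))
    chunk = 10  # segments per local rendering box
    for br in truth:
        d = br.diameters_um.get(timepoint, br.diameters_um["pre"])
        r_sup = 1.1 * d + 2.0 * v  # truncation radius, um
        inv_dd = ln2x4 / (d * d)
        xy = br.centerline_um[:, :2] + np.asarray(drift_um)[None, :]
        n_seg = xy.shape[0] - 1
        for s0 in range(0, n_seg, chunk):
            s1 = min(s0 + chunk, n_seg)
            part = xy[s0 : s1 + 1]
            seg_a, seg_b = part[:-1], part[1:]
            x_lo = max(int((part[:, 0].min() - r_sup) / v), 0)
            x_hi = min(int((part[:, 0].max() + r_sup) / v) + 2, nx)
            y_lo = max(int((part[:, 1].min() - r_sup) / v), 0)
            y_hi = min(int((part[:, 1].max() + r_sup) / v) + 2, ny)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            xs = (np.arange(x_lo, x_hi) + 0.5) * v
            ys = (np.arange(y_lo, y_hi) + 0.5) * v
            gx, gy = np.meshgrid(xs, ys)  # (NY, NX)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            d2 = _point_segment_dist2(pts, seg_a, seg_b)
            near = d2 <= r_sup * r_sup
            if not near.any():
                continue
            yy, xx = np.nonzero(near.reshape(gx.shape))
            d2n = d2[near]
            # centerline z follows the tilted plane at constant depth
            zc_um = spec.surface_z0_um + tan * gx.ravel()[near] + br.depth_um
            z_lo = max(int((zc_um.min() - r_sup) / v), 0)
            z_hi = min(int((zc_um.max() + r_sup) / v) + 2, nz)
            for k in range(z_lo, z_hi):
                dz = (k + 0.5) * v - zc_um
                vals = spec.vessel_level * np.exp(
                    -inv_dd * (d2n + dz * dz)
                ).astype(np.float32)
                row = vol[k, yy + y_lo, xx + x_lo]
                vol[k, yy + y_lo, xx + x_lo] = np.maximum(row, vals)
    return vol


def _apply_tails(spec: PhantomSpec, vessels: np.ndarray) -> np.ndarray:
    """Exponential axial decay of vessel signal below each vessel (multiple
    scattering).  Never exceeds tail_strength x the parent intensity."""
    if spec.tail_strength <= 0.0:
        return vessels
    decay = math.exp(-spec.voxel_um / spec.tail_decay_um)
    tail = np.zeros_like(vessels)
    for k in range(1, vessels.shape[0]):
        np.maximum(tail[k - 1] * decay, vessels[k - 1] * spec.tail_strength, out=tail[k])
    return np.maximum(vessels, tail)


def _surface_map_um(spec: PhantomSpec, nx: int) -> np.ndarray:
    tan = math.tan(math.radians(spec.tilt_deg))
    xs = (np.arange(nx) + 0.5) * spec.voxel_um
    return spec.surface_z0_um + tan * xs  # function of x only


def _finalize_volume(
    spec: PhantomSpec, vessels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    nz, ny, nx = vessels.shape
    v = spec.voxel_um
    surf_um = _surface_map_um(spec, nx)
    zs = (np.arange(nz) + 0.5) * v
    tissue = zs[:, None] >= surf_um[None, :]  # (nz, nx)
    background = (spec.background_level * tissue[:, None, :]).astype(np.float32)
    # vessel decorrelation rides on top of the tissue floor (additive), so a
    # lateral profile is Gaussian-plus-offset rather than a clipped Gaussian
    clean = _apply_tails(spec, vessels) + background
    if spec.speckle_cv > 0:
        # multiplicative speckle: unit-mean lognormal with the requested CV
        s2 = math.log(1.0 + spec.speckle_cv**2)
        z = rng.standard_normal(clean.shape, dtype=np.float32)
        clean = clean * np.exp(math.sqrt(s2) * z - s2 / 2.0, dtype=np.float32)
    if spec.noise_floor > 0:
        clean = clean + spec.noise_floor * rng.random(clean.shape, dtype=np.float32) * 2.0
    return np.clip(clean, 0.0, 1.0).astype(np.float32)


def build_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[AngioVolume, list[GroundTruthBranch]]:
    """Generate one ground-truthed angiographic volume.

    Returns the decorrelation-like volume (values in [0, 1]) and the exact
    geometry of every generated vessel branch.  Same spec and seed give
    byte-identical volumes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = _generate_truth(spec, rng)
    vessels = _render_vessels(spec, truth)
    vox = _finalize_volume(spec, vessels, rng)
    vol = AngioVolume(
        voxels=vox,
        voxel_um=(spec.voxel_um,) * 3,
        provenance={
            "kind": "synthetic_phantom",
            "tilt_deg": spec.tilt_deg,
            "surface_z0_um": spec.surface_z0_um,
            "n_branches": len(truth),
        },
    )
    return vol, truth


# ---------------------------------------------------------------------------
# repeated-frame stacks
# ---------------------------------------------------------------------------


def build_frame_stack(
    spec: PhantomSpec,
    n_repeats: int = 4,
    intra_vessel_decorr: float = 1.0,
    positions: Sequence[int] | None = None,
    inter_frame_shift_px: tuple[float, float] = (0.0, 0.0),
    additive_noise: float = 0.01,
    rng: np.random.Generator | None = None,
) -> list[FrameStack]:
    """Repeated-amplitude B-scan frames for selected slow-axis positions.

    Static (extravascular) voxels carry one fixed speckle realization across
    repeats plus small additive noise; intravascular voxels have a fraction
    ``intra_vessel_decorr`` of their speckle redrawn independently on every
    repeat.  A known subpixel inter-frame shift can be applied and is
    recorded in the stack metadata.
    """
    if n_repeats < 2:
        raise ValueError("decorrelation undefined for n_repeats < 2")
    if not 0.0 <= intra_vessel_decorr <= 1.0:
        raise ValueError("intra_vessel_decorr must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = _generate_truth(spec, rng)
    vessels = _render_vessels(spec, truth)
    nz, ny, nx = vessels.shape
    if positions is None:
        positions = range(ny)
    surf_um = _surface_map_um(spec, nx)
    zs = (np.arange(nz) + 0.5) * spec.voxel_um
    tissue = zs[:, None] >= surf_um[None, :]
    stacks: list[FrameStack] = []
    for y in positions:
        lumen = vessels[:, y, :] > 0.5 * spec.vessel_level
        refl = np.where(tissue, 0.5, 0.02) + 0.3 * lumen
        static = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=refl.shape)
        frames = []
        for n in range(n_repeats):
            s = static.copy()
            if intra_vessel_decorr > 0 and lumen.any():
                redraw = lumen & (rng.random(refl.shape) < intra_vessel_decorr)
                s[redraw] = rng.rayleigh(
                    scale=np.sqrt(2.0 / np.pi), size=int(redraw.sum())
                )
            frame = refl * s + additive_noise * rng.random(refl.shape)
            if n > 0 and any(inter_frame_shift_px):
                from scipy.ndimage import fourier_shift

                shift = (n * inter_frame_shift_px[0], n * inter_frame_shift_px[1])
                frame = np.fft.ifftn(fourier_shift(np.fft.fftn(frame), shift)).real
                frame = np.clip(frame, 0.0, None)
            frames.append(frame)
        stacks.append(
            FrameStack(
                frames=np.stack(frames),
                pixel_um=(spec.voxel_um, spec.voxel_um),
                position_index=int(y),
                metadata={
                    "inter_frame_shift_px": tuple(inter_frame_shift_px),
                    "intra_vessel_decorr": intra_vessel_decorr,
                    "lumen_mask": lumen,
                },
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# longitudinal studies
# ---------------------------------------------------------------------------


def _animal_seed(seed: int, animal: int, stage: int = 0) -> np.random.Generator:
    # Counter-based splitting: adding animals never perturbs earlier ones.
    return np.random.default_rng(np.random.SeedSequence([int(seed), animal, stage]))


def _animal_truth(
    spec: PhantomSpec, scenario: DilationScenario, seed: int, animal: int
) -> tuple[list[GroundTruthBranch], dict]:
    rng = _animal_seed(seed, animal, stage=0)
    base = _generate_truth(spec, rng, prefix=f"a{animal:02d}_b")
    for br in base:
        d0 = br.diameters_um["pre"]
        for t in scenario.timepoints:
            if t == "pre":
                continue
            a = 1.0 + rng.normal(0.0, scenario.inter_animal_sd)
            br.diameters_um[t] = max(d0 * scenario.factor(br.class_label, t) * a, 0.5)
    drifts = {"pre": (0.0, 0.0)}
    for t in scenario.timepoints:
        if t == "pre":
            continue
        ang = rng.uniform(0.0, 2.0 * np.pi)
        r = rng.uniform(0.0, scenario.max_drift_um)
        drifts[t] = (r * np.cos(ang), r * np.sin(ang))
    return base, drifts


def iter_study_volumes(
    spec: PhantomSpec, scenario: DilationScenario, seed: int = 0
) -> Iterator[tuple[int, str, AngioVolume, list[GroundTruthBranch], tuple[float, float]]]:
    """Lazily yield (animal, timepoint, volume, truth, drift_um) for a study.

    Each animal gets an independent phantom; at each timepoint every branch's
    diameter is scaled by its class factor times an animal-level perturbation,
    the geometry is held fixed (branches stay trackable), a small rigid
    lateral drift is applied, and speckle is redrawn (fresh acquisition).
    """
    for animal in range(scenario.n_animals):
        truth, drifts = _animal_truth(spec, scenario, seed, animal)
        for ti, t in enumerate(scenario.timepoints):
            rng_img = _animal_seed(seed, animal, stage=1 + ti)
            vessels = _render_vessels(spec, truth, timepoint=t, drift_um=drifts[t])
            vox = _finalize_volume(spec, vessels, rng_img)
            vol = AngioVolume(
                voxels=vox,
                voxel_um=(spec.voxel_um,) * 3,
                provenance={
                    "kind": "synthetic_study",
                    "animal": animal,
                    "timepoint": t,
                    "drift_um": drifts[t],
                    "tilt_deg": spec.tilt_deg,
                },
            )
            yield animal, t, vol, truth, drifts[t]


def build_study(
    spec: PhantomSpec, scenario: DilationScenario, seed: int = 0
) -> list[tuple[int, str, AngioVolume, list[GroundTruthBranch], tuple[float, float]]]:
    """Materialized version of :func:`iter_study_volumes` (memory-heavy)."""
    return list(iter_study_volumes(spec, scenario, seed))


def study_truth_table(
    spec: PhantomSpec, scenario: DilationScenario, seed: int = 0
) -> pd.DataFrame:
    """Ground-truth branch table of the study without rendering any volume."""
    rows = []
    for animal in range(scenario.n_animals):
        truth, _ = _animal_truth(spec, scenario, seed, animal)
        for br in truth:
            row = {
                "animal": animal,
                "branch_id": br.branch_id,
                "class": br.class_label,
                "depth_um": br.depth_um,
            }
            for t in scenario.timepoints:
                row[f"d_{t}"] = br.diameters_um[t]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_track_table(
    scenario: DilationScenario,
    n_branches_per_class: dict | None = None,
    measurement_cv: float = 0.03,
    persistent_cv: float = 0.04,
    small_diam_mean_um: float = 6.2,
    small_diam_sd_um: float = 1.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast branch-table-level study simulator (no imaging).

    Emulates the measured track table directly: true diameters per class,
    per-timepoint class effects with animal-level variability, and
    multiplicative measurement error split into a branch-persistent
    component (CV ``persistent_cv`` — segmentation and local-geometry biases
    that repeat at every timepoint and cancel in normalized diameters) and
    an independent per-measurement component (CV ``measurement_cv``).  Used
    for statistical calibration (e.g. type-I error of the paired t test
    under a sham scenario) where rendering volumes would be pointless.
    """
    if n_branches_per_class is None:
        n_branches_per_class = {"<15": 20, "15-20": 4, ">20": 3}
    rng = np.random.default_rng(seed)
    mu, sg = _truncated_lognormal_params(small_diam_mean_um, small_diam_sd_um, 5.0)
    rows = []
    for animal in range(scenario.n_animals):
        for cls, n in n_branches_per_class.items():
            if cls == "<15":
                d0 = rng.lognormal(mu, sg, size=n)
                bad = (d0 < 5.0) | (d0 >= 15.0)
                while bad.any():
                    d0[bad] = rng.lognormal(mu, sg, size=int(bad.sum()))
                    bad = (d0 < 5.0) | (d0 >= 15.0)
            elif cls == "15-20":
                d0 = rng.uniform(15.0, 20.0, size=n)
            else:
                d0 = 20.0 + rng.exponential(10.0, size=n)
            perturb = {
                t: 1.0 + rng.normal(0.0, scenario.inter_animal_sd)
                for t in scenario.timepoints
                if t != "pre"
            }
            for j, d in enumerate(d0):
                row = {"animal": animal, "branch_id": f"a{animal:02d}_{cls}_{j}", "class": cls}
                bias = 1.0 + rng.normal(0.0, persistent_cv)
                for t in scenario.timepoints:
                    f = 1.0 if t == "pre" else scenario.factor(cls, t) * perturb[t]
                    noise = 1.0 + rng.normal(0.0, measurement_cv)
                    row[f"d_{t}"] = max(d * f * bias * noise, 0.1)
                    row[f"matched_{t}"] = True
                rows.append(row)
    df = pd.DataFrame(rows)
    for t in scenario.timepoints:
        df[f"norm_{t}"] = df[f"d_{t}"] / df["d_pre"]
    df["norm_pre"] = 1.0
    return df
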