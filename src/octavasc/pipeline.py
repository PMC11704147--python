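"""End-to-end composition: angiogram volume -> branch tables -> statistics.

One function per granularity:

* :func:`analyze_volume` — surface-reference one angiographic volume,
  project it en face, segment branches, measure FWHM diameters and attribute
  depths;
* :func:`analyze_animal_volumes` — run all timepoints of one animal and
  track branches longitudinally;
* :func:`run_study` — simulate and analyze a whole multi-animal study in
  memory, returning the track table, pooled per-timepoint branch tables and
  the summary table builder inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .angiograph import AngioVolume
from .diametry import _initial_diameter_um, measure_branch
from .longitudinal import build_tracks, coregister_timepoints, tracks_to_table
from .phantom import (
    TIMEPOINTS,
    DilationScenario,
    PhantomSpec,
    iter_study_volumes,
)
from .vessel_seg import SegmentationParams, VesselBranch, classify_branch, segment_enface
from .volume_prep import EnFaceImage, detect_surface, detilt, project_enface

logger = logging.getLogger("octavasc")

__all__ = ["AnalyzedVolume", "analyze_volume", "analyze_animal_volumes", "run_study"]


@dataclass
class AnalyzedVolume:
    """Products of single-volume analysis."""

    flat: AngioVolume
    enface: EnFaceImage
    branches: list[VesselBranch]
    mask: np.ndarray
    branch_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _attribute_depths(
    flat: AngioVolume, branches: list[VesselBranch], max_depth_um: float
) -> None:
    """Branch depth = depth of the axial intensity maximum along the
    centerline (median over centerline points), um below the surface."""
    z0 = float(np.median(flat.surface_z))
    vz = flat.voxel_um[0]
    nz = flat.voxels.shape[0]
    k_lo = int(np.floor(z0))
    k_hi = min(int(np.floor(z0 + max_depth_um / vz)), nz)
    for b in branches:
        rr = np.clip(b.centerline_px[:, 0].round().astype(int), 0, flat.voxels.shape[1] - 1)
        cc = np.clip(b.centerline_px[:, 1].round().astype(int), 0, flat.voxels.shape[2] - 1)
        prof = flat.voxels[k_lo:k_hi, rr, cc]  # (nz_slab, n_points)
        if prof.size == 0:
            continue
        z_idx = prof.argmax(axis=0)
        b.depth_um = float(np.median(z_idx) * vz)


def branch_table(branches: list[VesselBranch]) -> pd.DataFrame:
    rows = []
    for b in branches:
        if b.mean_diameter_um is None:
            continue
        cls = classify_branch(b)
        if cls is None:
            continue
        rows.append(
            {
                "branch_id": b.branch_id,
                "mean_diameter_um": b.mean_diameter_um,
                "class": cls,
                "depth_um": b.depth_um,
                "length_um": b.length_um,
                "n_cross_sections": len(b.diameter_samples_um),
                "quality": b.quality,
            }
        )
    return pd.DataFrame(rows)


def analyze_volume(
    volume: AngioVolume,
    seg_params: SegmentationParams | None = None,
    depth_range_um: tuple[float, float] = (0.0, 400.0),
    id_prefix: str = "br",
) -> AnalyzedVolume:
    """Surface-reference, segment and measure one angiographic volume."""
    if seg_params is None:
        seg_params = SegmentationParams()
    surface = detect_surface(volume)
    flat = detilt(volume, surface)
    enface = project_enface(flat, depth_range_um[0], depth_range_um[1], kind="max")
    branches, mask = segment_enface(enface, seg_params, id_prefix=id_prefix)
    edt = ndimage.distance_transform_edt(mask)
    _attribute_depths(flat, branches, depth_range_um[1])
    # Diametry runs on a narrow mean projection centred at each branch's own
    # depth: the mean projector is width-unbiased (a max projection sharpens
    # wide profiles via extreme-value statistics), averages speckle, and
    # excludes crossing vessels at other depths.
    for b in branches:
        d_est = _initial_diameter_um(b, edt)
        if b.depth_um is None:
            measure_branch(enface, b, edt=edt)
            continue
        half = max(0.75 * d_est, 6.0)
        lo = max(b.depth_um - half, 0.0)
        hi = min(b.depth_um + half, depth_range_um[1])
        slab = project_enface(flat, lo, hi, kind="mean")
        measure_branch(slab, b, edt=edt)
    branches = [b for b in branches if b.mean_diameter_um is not None]
    av = AnalyzedVolume(flat=flat, enface=enface, branches=branches, mask=mask)
    av.branch_table = branch_table(branches)
    logger.info(
        "analyzed volume: %d branches measured (%d in table)",
        len(branches),
        len(av.branch_table),
    )
    return av


def analyze_animal_volumes(
    animal_id: int,
    volumes_by_timepoint: dict[str, AngioVolume],
    seg_params: SegmentationParams | None = None,
    depth_range_um: tuple[float, float] = (0.0, 400.0),
    tol_um: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, tuple[float, float]]]:
    """Analyze all timepoints of one animal and build its branch tracks.

    Returns (track table, per-timepoint branch tables, registration shifts
    in pixels).  Missing timepoints are analyzed where present.
    """
    analyzed: dict[str, AnalyzedVolume] = {}
    for t, vol in volumes_by_timepoint.items():
        analyzed[t] = analyze_volume(
            vol, seg_params, depth_range_um, id_prefix=f"a{animal_id:02d}_{t}_"
        )
    enfaces = {t: a.enface for t, a in analyzed.items()}
    shifts = coregister_timepoints(enfaces) if len(enfaces) > 1 else {"pre": (0.0, 0.0)}
    tracks = build_tracks(
        animal_id,
        {t: a.branches for t, a in analyzed.items()},
        shifts,
        tol_um=tol_um,
        timepoints=tuple(volumes_by_timepoint.keys()),
    )
    table = tracks_to_table(tracks, timepoints=TIMEPOINTS)
    per_tp = {}
    for t, a in analyzed.items():
        bt = a.branch_table.copy()
        bt["animal"] = animal_id
        bt["timepoint"] = t
        per_tp[t] = bt
    return table, per_tp, shifts


def run_study(
    spec: PhantomSpec,
    scenario: DilationScenario,
    seed: int = 0,
    seg_params: SegmentationParams | None = None,
    depth_range_um: tuple[float, float] = (0.0, 400.0),
) -> dict:
    """Simulate and analyze a full multi-animal study in memory.

    Volumes are generated lazily and discarded after analysis to bound
    memory.  Returns a dict with:

    ``track_table``     — all animals' branch tracks,
    ``branch_tables``   — per-timepoint pooled branch tables,
    ``truth``           — ground-truth branch table,
    ``shifts``          — per-animal registration shifts (px),
    ``drifts``          — per-animal true drifts (um).
    """
    track_parts: list[pd.DataFrame] = []
    branch_parts: dict[str, list[pd.DataFrame]] = {t: [] for t in scenario.timepoints}
    shifts_all: dict[int, dict] = {}
    drifts_all: dict[int, dict] = {}
    truth_rows: list[dict] = []
    truth_branches: dict[int, list] = {}
    pending: dict[str, AngioVolume] = {}
    current_animal: int | None = None

    def flush(animal: int) -> None:
        table, per_tp, shifts = analyze_animal_volumes(
            animal, pending, seg_params, depth_range_um
        )
        track_parts.append(table)
        for t, bt in per_tp.items():
            branch_parts[t].append(bt)
        shifts_all[animal] = shifts
        pending.clear()

    for animal, t, vol, truth, drift in iter_study_volumes(spec, scenario, seed):
        if current_animal is None:
            current_animal = animal
        if animal != current_animal:
            flush(current_animal)
            current_animal = animal
        pending[t] = vol
        drifts_all.setdefault(animal, {})[t] = drift
        if t == scenario.timepoints[0]:
            truth_branches[animal] = truth
            for br in truth:
                row = {
                    "animal": animal,
                    "branch_id": br.branch_id,
                    "class": br.class_label,
                    "depth_um": br.depth_um,
                }
                row.update({f"d_{tp}": br.diameters_um[tp] for tp in scenario.timepoints})
                truth_rows.append(row)
    if current_animal is not None and pending:
        flush(current_animal)

    track_table = (
        pd.concat(track_parts, ignore_index=True) if track_parts else pd.DataFrame()
    )
    branch_tables = {
        t: (pd.concat(parts, ignore_index=True) if parts else pd.DataFrame())
        for t, parts in branch_parts.items()
    }
    return {
        "track_table": track_table,
        "branch_tables": branch_tables,
        "truth": pd.DataFrame(truth_rows),
        "truth_branches": truth_branches,
        "shifts": shifts_all,
        "drifts": drifts_all,
        "condition": scenario.label,
    }


def vessel_tracking_recall(
    track_table: pd.DataFrame,
    truth_branches: dict[int, list],
    min_true_diameter_um: float = 8.0,
    tol_um: float = 5.0,
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> tuple[int, int]:
    """(n tracked through every timepoint, n eligible) at the vessel level.

    A true vessel counts as tracked when at least half of its centerline is
    covered (within ``tol_um``) by the union of branch tracks that were
    re-identified and measured at every timepoint — a long vessel may be
    followed as several junction-delimited fragments.
    """
    from scipy.spatial import cKDTree

    matched_cols = [f"matched_{t}" for t in timepoints]
    hit = tot = 0
    for animal, branches in truth_branches.items():
        sub = track_table[track_table["animal"] == animal]
        complete = sub[sub[matched_cols].all(axis=1)]
        pts_list = [cl for cl in complete["centerline_um"] if cl is not None]
        tree = cKDTree(np.vstack(pts_list)) if pts_list else None
        for tb in branches:
            if tb.true_diameter_um < min_true_diameter_um:
                continue
            tot += 1
            if tree is None:
                continue
            pts = tb.centerline_um[:, :2]
            tol_b = max(tol_um, 0.25 * tb.true_diameter_um)
            d, _ = tree.query(pts, distance_upper_bound=tol_b)
            if np.isfinite(d).mean() >= 0.5:
                hit += 1
    return hit, tot
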