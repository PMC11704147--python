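"""Longitudinal branch tracking across the sonication timeline.

Branches are tagged at baseline (pre-FUS) and re-identified at each later
timepoint: en-face images are rigidly co-registered (translation only — a
head-fixed cranial-window preparation drifts but does not rotate), and
branches are matched by centerline proximity, not by diameter, so a
dilating vessel keeps its identity.  Each track carries per-timepoint
diameters and normalized diameters (diameter divided by the pre-FUS
diameter); the diameter class is frozen at its baseline value so a vessel
cannot migrate between classes mid-study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

from .phantom import TIMEPOINTS
from .vessel_seg import VesselBranch, classify_branch
from .volume_prep import EnFaceImage

__all__ = [
    "BranchTrack",
    "coregister_timepoints",
    "match_branches",
    "build_tracks",
    "tracks_to_table",
    "per_animal_summary",
]


@dataclass
class BranchTrack:
    """One baseline branch followed across the imaging timeline."""

    branch_id: str
    animal_id: int
    class_label: str
    diameters_um: dict = field(default_factory=dict)
    normalized: dict = field(default_factory=dict)
    matched: dict = field(default_factory=dict)
    depth_um: float | None = None
    centerline_um: np.ndarray | None = None  # baseline (x, y) path


def coregister_timepoints(
    enfaces: dict[str, EnFaceImage],
    baseline: str = "pre",
    min_confidence: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Rigid translation of each later en-face image onto the baseline.

    Phase correlation with subpixel refinement; returns per-timepoint
    (row, col) shifts in pixels such that shifting the later image by the
    returned amount aligns it with baseline.  A correlation peak below the
    confidence floor produces a warning and an identity shift.
    """
    from scipy.ndimage import shift as ndshift

    ref = enfaces[baseline].pixels
    shifts: dict[str, tuple[float, float]] = {baseline: (0.0, 0.0)}
    for t, img in enfaces.items():
        if t == baseline:
            continue
        shift, _, _ = phase_cross_correlation(
            ref, img.pixels, upsample_factor=20, normalization=None
        )
        # confidence = image correlation after applying the estimated shift
        moved = ndshift(img.pixels, shift, order=1, mode="nearest")
        conf = float(np.corrcoef(ref.ravel(), moved.ravel())[0, 1])
        if not np.isfinite(conf) or conf < min_confidence:
            warnings.warn(
                f"co-registration at {t}: correlation below confidence floor, "
                "using identity shift"
            )
            shifts[t] = (0.0, 0.0)
        else:
            shifts[t] = (float(shift[0]), float(shift[1]))
    return shifts


def match_branches(
    baseline: list[VesselBranch],
    later: list[VesselBranch],
    shift_px: tuple[float, float] = (0.0, 0.0),
    tol_um: float = 5.0,
    min_overlap: float = 0.5,
    max_diameter_ratio: float = 2.0,
) -> dict[str, str]:
    """Greedy one-to-one matching of baseline branches onto a later set.

    For each candidate pair, the score is the fraction of baseline
    centerline points lying within ``tol_um`` of the (shift-corrected)
    later centerline.  Pairs below ``min_overlap`` stay unmatched; ties are
    broken by higher overlap, then by smaller diameter difference.
    Matching is geometry-driven — a uniformly dilated branch maps onto
    itself — but a pair whose diameters differ by more than
    ``max_diameter_ratio`` is rejected as a crossing-vessel confusion, since
    no physiological dose halves or doubles a vessel within minutes.
    """
    if not baseline or not later:
        return {}
    trees = []
    for lb in later:
        pts = (lb.centerline_px + np.asarray(shift_px)[None, :]) * lb.pixel_um
        trees.append(cKDTree(pts))
    candidates = []
    for bb in baseline:
        pts = bb.centerline_px * bb.pixel_um
        # the medial axis of a wide vessel jitters laterally with mask-edge
        # noise far more than a capillary's: widen the tolerance with width
        tol_b = max(tol_um, 0.25 * (bb.mean_diameter_um or 0.0))
        for j, (lb, tree) in enumerate(zip(later, trees)):
            d, _ = tree.query(pts, distance_upper_bound=tol_b)
            overlap = float(np.isfinite(d).mean())
            if overlap < min_overlap:
                continue
            if bb.mean_diameter_um and lb.mean_diameter_um:
                ratio = lb.mean_diameter_um / bb.mean_diameter_um
                if not (1.0 / max_diameter_ratio <= ratio <= max_diameter_ratio):
                    continue
            dd = abs((bb.mean_diameter_um or 0.0) - (lb.mean_diameter_um or 0.0))
            candidates.append((overlap, -dd, bb.branch_id, lb.branch_id))
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    mapping: dict[str, str] = {}
    used_later: set[str] = set()
    for overlap, _negdd, bid, lid in candidates:
        if bid in mapping or lid in used_later:
            continue
        mapping[bid] = lid
        used_later.add(lid)
    # second pass: when the baseline skeleton fragmented more finely than the
    # later one, two baseline fragments legitimately lie on one later branch;
    # leftovers may share an already-claimed partner
    for overlap, _negdd, bid, lid in candidates:
        if bid not in mapping:
            mapping[bid] = lid
    return mapping


def build_tracks(
    animal_id: int,
    branches_by_timepoint: dict[str, list[VesselBranch]],
    shifts_px: dict[str, tuple[float, float]],
    tol_um: float = 5.0,
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> list[BranchTrack]:
    """Tag baseline branches and follow them through all timepoints.

    Only baseline branches with a measured diameter >= the 5-um floor are
    tracked; the class label is frozen from the baseline diameter.
    Normalized diameters are defined only where the branch was re-identified
    and measured.  Tracks without a measurable baseline are excluded.
    """
    base = [
        b
        for b in branches_by_timepoint.get("pre", [])
        if b.mean_diameter_um is not None and classify_branch(b) is not None
    ]
    tracks: dict[str, BranchTrack] = {}
    for b in base:
        tracks[b.branch_id] = BranchTrack(
            branch_id=b.branch_id,
            animal_id=animal_id,
            class_label=classify_branch(b),
            diameters_um={"pre": b.mean_diameter_um},
            normalized={"pre": 1.0},
            matched={"pre": True},
            depth_um=b.depth_um,
            centerline_um=b.centerline_um(),
        )
    for t in timepoints:
        if t == "pre":
            continue
        later = branches_by_timepoint.get(t, [])
        later_by_id = {b.branch_id: b for b in later}
        mapping = match_branches(
            base, later, shifts_px.get(t, (0.0, 0.0)), tol_um=tol_um
        )
        for tr in tracks.values():
            lid = mapping.get(tr.branch_id)
            lb = later_by_id.get(lid) if lid is not None else None
            if lb is not None and lb.mean_diameter_um is not None:
                tr.matched[t] = True
                tr.diameters_um[t] = lb.mean_diameter_um
                tr.normalized[t] = lb.mean_diameter_um / tr.diameters_um["pre"]
            else:
                tr.matched[t] = False
    return list(tracks.values())


def tracks_to_table(
    tracks: list[BranchTrack], timepoints: tuple[str, ...] = TIMEPOINTS
) -> pd.DataFrame:
    """Long-lived flat track table: one row per track, columns per timepoint."""
    rows = []
    for tr in tracks:
        row = {
            "animal": tr.animal_id,
            "branch_id": tr.branch_id,
            "class": tr.class_label,
            "depth_um": tr.depth_um,
        }
        for t in timepoints:
            row[f"d_{t}"] = tr.diameters_um.get(t, np.nan)
            row[f"norm_{t}"] = tr.normalized.get(t, np.nan)
            row[f"matched_{t}"] = bool(tr.matched.get(t, False))
        row["centerline_um"] = tr.centerline_um
        rows.append(row)
    return pd.DataFrame(rows)


def per_animal_summary(
    table: pd.DataFrame,
    class_label: str | None = None,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    complete_case: bool = False,
) -> pd.DataFrame:
    """Per-animal mean normalized diameter per timepoint.

    The animal is the unit of analysis: branch-level normalized diameters
    are averaged (unweighted) within each animal.  ``complete_case`` keeps
    only tracks matched at every timepoint; the default analyzes each
    timepoint with whatever tracks were re-identified there.  Animals with
    no eligible track in the class are omitted.
    """
    df = table if class_label is None else table[table["class"] == class_label]
    if complete_case:
        ok = np.ones(len(df), dtype=bool)
        for t in timepoints:
            ok &= df[f"matched_{t}"].to_numpy(dtype=bool)
        df = df[ok]
    rows = []
    for animal, grp in df.groupby("animal"):
        row = {"animal": animal, "n_branches": len(grp)}
        any_val = False
        for t in timepoints:
            vals = grp.loc[grp[f"matched_{t}"], f"norm_{t}"].dropna()
            row[f"norm_{t}"] = float(vals.mean()) if len(vals) else np.nan
            any_val = any_val or bool(len(vals))
        if any_val:
            rows.append(row)
    return pd.DataFrame(rows)
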