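"""Top-hat enhancement, binarization, skeleton branch graph and classification."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octavasc.vessel_seg import (
    SegmentationParams,
    VesselBranch,
    binarize,
    classify_branch,
    diameter_histogram,
    segment_enface,
    skeletonize_and_graph,
    tophat_enhance,
)
from octavasc.volume_prep import EnFaceImage


def _image(pixels, pixel_um=2.0):
    return EnFaceImage(
        pixels=np.asarray(pixels, dtype=np.float32),
        depth_range_um=(0, 400),
        pixel_um=pixel_um,
    )


def _brute_force_opening(img, radius_px):
    """Exhaustive grayscale opening oracle: erosion (local min over the disk)
    followed by dilation (local max over the disk)."""
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    offsets = [(int(dy), int(dx)) for dy, dx in zip(yy.ravel(), xx.ravel())
               if dy * dy + dx * dx <= radius_px * radius_px]
    ny, nx = img.shape

    def local(op, src):
        out = np.empty_like(src)
        for i in range(ny):
            for j in range(nx):
                vals = [
                    src[i + dy, j + dx]
                    for dy, dx in offsets
                    if 0 <= i + dy < ny and 0 <= j + dx < nx
                ]
                out[i, j] = op(vals)
        return out

    return local(max, local(min, img))


class TestTophat:
    def test_constant_image_maps_to_zero(self):
        out = tophat_enhance(_image(np.full((32, 32), 7.0)))
        assert np.allclose(out.pixels, 0.0)

    def test_narrow_ridge_preserved(self):
        """A 4-px ridge survives a 6.7-um (2-px radius) top-hat within 5%,
        verified against a brute-force opening."""
        img = np.zeros((24, 40), dtype=np.float32)
        img[10:14, :] = 1.0
        out = tophat_enhance(_image(img), width_um=6.7)
        oracle = img - _brute_force_opening(img, radius_px=2)
        assert out.pixels[11, 20] >= 0.95
        assert np.allclose(out.pixels, oracle, atol=1e-6)

    def test_wide_plateau_interior_suppressed(self):
        img = np.zeros((60, 60), dtype=np.float32)
        img[10:50, 10:50] = 1.0
        out = tophat_enhance(_image(img), width_um=6.7)
        assert out.pixels[30, 30] == pytest.approx(0.0, abs=1e-6)

    def test_subpixel_element_rejected(self):
        with pytest.raises(ValueError, match="resampl"):
            tophat_enhance(_image(np.zeros((8, 8)), pixel_um=8.0), width_um=6.7)


class TestBinarize:
    def test_two_level_image_threshold_exact(self):
        img = np.zeros((40, 40), dtype=np.float32)
        img[5:20, 5:30] = 100.0
        mask = binarize(_image(img))
        assert (mask == (img > 0)).all()

    def test_all_background_warns_and_returns_empty(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            mask = binarize(_image(np.zeros((16, 16))))
        assert not mask.any()
        assert any("empty" in str(w.message) for w in rec)

    def test_phantom_enface_dice_against_truth(self):
        """Segmentation overlaps the true lumen mask with Dice >= 0.7."""
        from octavasc.phantom import PhantomSpec, _generate_truth, _render_vessels, build_phantom
        from octavasc.pipeline import analyze_volume

        spec = PhantomSpec(seed=7)
        vol, _ = build_phantom(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            av = analyze_volume(vol)
        clean = _render_vessels(spec, _generate_truth(spec, np.random.default_rng(7)))
        truth_mask = clean.max(axis=0) > 0.5 * spec.vessel_level
        inter = np.logical_and(av.mask, truth_mask).sum()
        dice = 2 * inter / (av.mask.sum() + truth_mask.sum())
        assert dice >= 0.7


class TestSkeleton:
    def test_straight_tube_single_branch(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[18:23, 5:95] = True
        branches = skeletonize_and_graph(mask, pixel_um=2.0)
        assert len(branches) == 1
        assert abs(branches[0].centerline_px.shape[0] - 90) <= 4

    def test_y_junction_gives_three_branches(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[38:43, 5:42] = True       # horizontal arm
        for k in range(35):            # two diagonal arms
            mask[40 - k // 2 : 43 - k // 2, 40 + k] = True
            mask[38 + k // 2 : 41 + k // 2, 40 + k] = True
        branches = skeletonize_and_graph(mask, pixel_um=2.0, prune_len_um=12.0)
        assert len(branches) == 3

    def test_spur_pruned(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[18:23, 5:95] = True
        mask[23:26, 50] = True  # 3-px spur
        branches = skeletonize_and_graph(mask, pixel_um=2.0, prune_len_um=10.0)
        assert len(branches) == 1

    def test_empty_mask_empty_result(self):
        assert skeletonize_and_graph(np.zeros((10, 10), dtype=bool)) == []

    def test_skeleton_partition(self):
        """Each non-junction skeleton pixel belongs to exactly one branch."""
        from skimage.morphology import skeletonize

        from octavasc.vessel_seg import _neighbor_count

        rng = np.random.default_rng(3)
        mask = np.zeros((80, 80), dtype=bool)
        mask[39:44, 5:75] = True
        mask[5:75, 39:44] = True
        mask[10:14, 10:60] = True
        branches = skeletonize_and_graph(mask, pixel_um=2.0, prune_len_um=0.0)
        skel = skeletonize(mask)
        nb = _neighbor_count(skel)
        counts = {}
        for b in branches:
            for p in map(tuple, b.centerline_px.astype(int)):
                counts[p] = counts.get(p, 0) + 1
        covered = 0
        for p in map(tuple, np.argwhere(skel)):
            deg = nb[p]
            if deg == 2:
                assert counts.get(p, 0) == 1, f"pixel {p} in {counts.get(p, 0)} branches"
            covered += counts.get(p, 0) >= 1
        # junction-clique interiors may stay unassigned; everything else is
        # covered, so coverage stays near-total
        assert covered / skel.sum() > 0.95


class TestClassify:
    @pytest.mark.parametrize(
        "d,label",
        [(6.20, "<15"), (14.999, "<15"), (15.0, "15-20"), (17.66, "15-20"),
         (19.999, "15-20"), (20.0, ">20"), (35.25, ">20")],
    )
    def test_half_open_edges(self, d, label):
        assert classify_branch(d) == label

    def test_below_floor_excluded(self):
        assert classify_branch(4.9) is None

    def test_unmeasured_branch_rejected(self):
        br = VesselBranch(branch_id="x", centerline_px=np.zeros((3, 2)))
        with pytest.raises(ValueError):
            classify_branch(br)

    @given(st.floats(min_value=5.0, max_value=80.0, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_labels_partition_diameter_axis(self, d):
        label = classify_branch(d)
        assert label == ("<15" if d < 15 else "15-20" if d < 20 else ">20")


class TestHistogram:
    def _branches(self, diams):
        out = []
        for i, d in enumerate(diams):
            b = VesselBranch(branch_id=str(i), centerline_px=np.zeros((3, 2)))
            b.mean_diameter_um = d
            out.append(b)
        return out

    def test_empty_gives_zero_counts(self):
        counts, _ = diameter_histogram([], bin_um=10.0)
        assert counts.sum() == 0

    def test_counting_example(self):
        counts, edges = diameter_histogram(self._branches([6, 6, 30]), bin_um=10.0)
        assert counts[0] == 2 and counts[3] == 1 and counts.sum() == 3

    def test_class_counts_invariant_under_rescaling(self):
        """Rescaling the en-face intensity must not change branch counts."""
        from octavasc.phantom import PhantomSpec, build_phantom
        from octavasc.volume_prep import detect_surface, detilt, project_enface

        vol, _ = build_phantom(PhantomSpec(seed=15))
        flat = detilt(vol, detect_surface(vol))
        ef = project_enface(flat, 0, 380)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1, _ = segment_enface(ef)
            scaled = EnFaceImage(ef.pixels * 0.37, ef.depth_range_um, ef.projection_kind, ef.pixel_um)
            b2, _ = segment_enface(scaled)
        assert len(b1) == len(b2)
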