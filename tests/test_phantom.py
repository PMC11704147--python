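"""Synthetic-phantom generator contracts and invariants."""

import numpy as np
import pytest
import scipy.stats as sps

from octavasc.angiograph import decorrelate
from octavasc.phantom import (
    DilationScenario,
    GenerationError,
    GroundTruthBranch,
    PhantomSpec,
    _truncated_lognormal_params,
    build_frame_stack,
    build_phantom,
    sham_scenario,
    study_truth_table,
)


class TestSpecValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_small=-1)

    def test_tail_strength_range(self):
        with pytest.raises(ValueError):
            PhantomSpec(tail_strength=1.0)

    def test_sub_floor_capillary_mean_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(small_diam_mean_um=4.0)

    def test_infeasible_density_names_class(self):
        with pytest.raises(GenerationError, match="<15"):
            spec = PhantomSpec(
                domain_size_um=(100, 100, 200), n_small=400, n_medium=0, n_large=0
            )
            build_phantom(spec)


class TestBuildPhantom:
    def test_empty_spec_gives_background_only(self):
        spec = PhantomSpec(
            n_large=0, n_medium=0, n_small=0, speckle_cv=0.0, noise_floor=0.0,
            domain_size_um=(100, 100, 200), tilt_deg=0.0,
        )
        vol, truth = build_phantom(spec)
        assert truth == []
        below = vol.voxels[int(spec.surface_z0_um / spec.voxel_um) + 1:]
        assert np.allclose(below, spec.background_level, atol=1e-6)

    def test_forced_tube_cross_section_fwhm(self):
        """A noise-free 10-um tube has a half-max width of 10 um +/- 1 voxel."""
        from octavasc.phantom import _finalize_volume, _render_vessels

        spec = PhantomSpec(
            n_large=0, n_medium=0, n_small=0, speckle_cv=0.0, noise_floor=0.0,
            tilt_deg=0.0, tail_strength=0.0, domain_size_um=(300, 300, 200),
        )
        cl = np.column_stack(
            [np.linspace(30, 270, 40), np.full(40, 150.0), np.full(40, 150.0)]
        )
        br = GroundTruthBranch(
            branch_id="t0", centerline_um=cl, diameters_um={"pre": 10.0},
            class_label="<15", depth_um=100.0,
        )
        vessels = _render_vessels(spec, [br])
        z = int(150 / spec.voxel_um)
        profile = vessels[z, :, 75]  # cross-section through the tube
        width_px = (profile >= 0.5 * profile.max()).sum()
        assert abs(width_px * spec.voxel_um - 10.0) <= spec.voxel_um

    def test_configured_sampler_mean_recovered(self):
        """Measurable (>= 5 um) small-vessel truth averages ~6.2 um."""
        spec = PhantomSpec(n_large=0, n_medium=0, n_small=60, seed=9)
        _, truth = build_phantom(spec)
        diams = np.array([b.true_diameter_um for b in truth])
        eligible = diams[diams >= 5.0]
        se = 1.3 / np.sqrt(len(eligible))
        assert abs(eligible.mean() - 6.2) <= 3 * se

    def test_truth_histogram_matches_sampler_cdf(self):
        """KS distance between drawn diameters and the configured truncated
        lognormal < 0.1 at n = 500."""
        mu, sg = _truncated_lognormal_params(6.2, 1.3, 5.0)
        rng = np.random.default_rng(11)
        draws = []
        while len(draws) < 500:
            x = rng.lognormal(mu, sg, 1000)
            draws.extend(x[x >= 5.0])
        draws = np.array(draws[:500])

        def cdf(x):
            base = sps.lognorm(s=sg, scale=np.exp(mu))
            p5 = base.cdf(5.0)
            return np.clip((base.cdf(x) - p5) / (1 - p5), 0, 1)

        ks = sps.kstest(draws, cdf).statistic
        assert ks < 0.1

    def test_tails_never_exceed_parent_intensity(self):
        from octavasc.phantom import _apply_tails

        spec = PhantomSpec(tail_strength=0.4, tail_decay_um=30.0)
        rng = np.random.default_rng(0)
        vessels = np.zeros((50, 8, 8), dtype=np.float32)
        vessels[10:14] = rng.random((4, 8, 8)).astype(np.float32)
        out = _apply_tails(spec, vessels)
        parent_max = vessels.max(axis=0)
        assert (out <= parent_max[None, :, :] + 1e-6).all()
        # and the tail decays below the vessel
        assert (out[20] <= spec.tail_strength * parent_max + 1e-6).all()

    def test_same_seed_byte_identical(self):
        a, _ = build_phantom(PhantomSpec(seed=4))
        b, _ = build_phantom(PhantomSpec(seed=4))
        assert a.voxels.tobytes() == b.voxels.tobytes()

    def test_different_seed_differs(self):
        a, _ = build_phantom(PhantomSpec(seed=4))
        b, _ = build_phantom(PhantomSpec(seed=5))
        assert a.voxels.tobytes() != b.voxels.tobytes()


class TestFrameStacks:
    def _spec(self):
        return PhantomSpec(
            domain_size_um=(200, 200, 200), n_large=1, n_medium=0, n_small=0,
            tilt_deg=0.0, seed=5,
        )

    def test_zero_decorr_no_noise_gives_identical_repeats(self):
        stacks = build_frame_stack(
            self._spec(), n_repeats=3, intra_vessel_decorr=0.0,
            positions=[50], additive_noise=0.0,
        )
        f = stacks[0].frames
        assert np.allclose(f[0], f[1]) and np.allclose(f[0], f[2])

    def test_full_decorr_lumen_beats_background(self):
        stacks = build_frame_stack(
            self._spec(), n_repeats=4, intra_vessel_decorr=1.0, positions=[50]
        )
        d = decorrelate(stacks[0])
        lumen = stacks[0].metadata["lumen_mask"]
        assert d[lumen].mean() > d[~lumen].mean()

    def test_shift_metadata_bookkeeping(self):
        stacks = build_frame_stack(
            self._spec(), n_repeats=2, intra_vessel_decorr=0.5,
            positions=[40], inter_frame_shift_px=(0.4, -0.3),
        )
        assert stacks[0].metadata["inter_frame_shift_px"] == (0.4, -0.3)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            build_frame_stack(self._spec(), n_repeats=1, intra_vessel_decorr=0.5)


class TestStudies:
    def test_sham_truth_diameters_identical_across_timepoints(self):
        sc = sham_scenario(2)
        sc = DilationScenario(
            effect_by_class=sc.effect_by_class, n_animals=2, inter_animal_sd=0.0,
            label="sham",
        )
        tt = study_truth_table(PhantomSpec(seed=1), sc, seed=1)
        for tp in ("post1_1min", "post1_10min", "post2_10min"):
            assert np.allclose(tt[f"d_{tp}"], tt["d_pre"])

    def test_configured_small_effect_recovered_in_truth(self):
        eff = {c: {t: 1.0 for t in ("pre", "post1_1min", "post1_10min", "post2_10min")}
               for c in ("<15", "15-20", ">20")}
        eff["<15"]["post1_1min"] = 1.17
        sc = DilationScenario(effect_by_class=eff, n_animals=4, inter_animal_sd=0.03)
        tt = study_truth_table(PhantomSpec(seed=2), sc, seed=2)
        small = tt[tt["class"] == "<15"]
        ratio = (small["d_post1_1min"] / small["d_pre"]).mean()
        assert ratio == pytest.approx(1.17, abs=3 * 0.03)

    def test_null_class_exactly_unity_without_perturbation(self):
        eff = {c: {t: 1.0 for t in ("pre", "post1_1min", "post1_10min", "post2_10min")}
               for c in ("<15", "15-20", ">20")}
        eff["<15"]["post1_1min"] = 1.3
        sc = DilationScenario(effect_by_class=eff, n_animals=2, inter_animal_sd=0.0)
        tt = study_truth_table(PhantomSpec(seed=3), sc, seed=3)
        large = tt[tt["class"] == ">20"]
        assert np.allclose(large["d_post1_1min"], large["d_pre"])

    def test_pre_factor_must_be_unity(self):
        with pytest.raises(ValueError, match="pre"):
            DilationScenario(effect_by_class={"<15": {"pre": 1.1}})

    def test_counter_seeding_stable_under_added_animals(self):
        """Adding animals never perturbs earlier animals' truth."""
        sc2 = sham_scenario(2)
        sc4 = sham_scenario(4)
        t2 = study_truth_table(PhantomSpec(seed=8), sc2, seed=8)
        t4 = study_truth_table(PhantomSpec(seed=8), sc4, seed=8)
        first_two = t4[t4["animal"] < 2].reset_index(drop=True)
        assert first_two.equals(t2.reset_index(drop=True))
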