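"""Generator correctness: determinism, mask geometry, transfer kinetics,
fluorescence conservation, bleaching, cohorts and line-scan scenes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import knockscope as ks
from knockscope.exceptions import ParameterError


class TestTransferredFraction:
    def test_zero_at_rapamycin_addition(self):
        assert ks.transferred_fraction(0.0, 0.95, 2.0) == 0.0

    def test_asymptote(self):
        assert ks.transferred_fraction(1e9, 0.95, 2.0) == pytest.approx(0.95)

    def test_closed_form_at_tau(self):
        # phi(tau) = 1 - 1/e for phi_max = 1
        assert ks.transferred_fraction(2.0, 1.0, 2.0) == pytest.approx(
            1.0 - np.exp(-1.0), abs=1e-12
        )

    @pytest.mark.parametrize("tau", [0.0, -1.0])
    def test_nonpositive_tau_rejected(self, tau):
        with pytest.raises(ParameterError):
            ks.transferred_fraction(1.0, 0.5, tau)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            ks.transferred_fraction(-0.1, 0.5, 2.0)

    @given(st.floats(0, 60), st.floats(0, 60))
    def test_monotone_in_time(self, t1, t2):
        lo, hi = sorted([t1, t2])
        assert ks.transferred_fraction(lo, 0.9, 2.0) <= ks.transferred_fraction(
            hi, 0.9, 2.0
        ) + 1e-15


class TestSceneGeometry:
    def test_seed_determinism(self):
        a = ks.generate_scene(seed=7)
        b = ks.generate_scene(seed=7)
        assert np.array_equal(a.spindle_mask, b.spindle_mask)
        assert np.array_equal(a.mito_mask, b.mito_mask)
        assert np.array_equal(a.cell_mask, b.cell_mask)
        assert a.amp == b.amp

    def test_mask_invariants(self, scene):
        assert not (scene.spindle_mask & scene.mito_mask).any()
        assert (scene.spindle_mask <= scene.cell_mask).all()
        assert (scene.mito_mask <= scene.cell_mask).all()
        # cytoplasm is the remainder of the cell
        recon = scene.spindle_mask | scene.mito_mask | scene.cytoplasm_mask
        assert np.array_equal(recon, scene.cell_mask)

    def test_zero_spindle_rejected(self):
        with pytest.raises(ParameterError):
            ks.generate_scene(spindle_semiaxes=(0.0, 5.0), seed=0)

    def test_tiny_image_rejected(self):
        with pytest.raises(ParameterError):
            ks.generate_scene(image_shape=(32, 32), seed=0)

    def test_fixed_preset_pixel_size_matches_roi_area(self):
        # 31 px x 0.0382 um/px squared ~ 1.4 um^2
        scene = ks.generate_scene(preset="fixed", seed=3)
        assert (31 * scene.pixel_size) ** 2 == pytest.approx(1.4, rel=0.01)


class TestRenderTimelapse:
    def test_determinism(self, scene):
        a = ks.render_timelapse(scene, [0.0, 5.0, 12.0])
        b = ks.render_timelapse(scene, [0.0, 5.0, 12.0])
        assert np.array_equal(a.data, b.data)

    def test_fluorescence_conservation_noiseless(self):
        scene = ks.generate_scene(seed=2, noise_sd=0.0, bleach_rate=0.0)
        movie = ks.render_timelapse(scene, [0.0, 2.0, 5.0, 12.0])
        totals = movie.data.sum(axis=(2, 3))  # (T, C)
        for ci in range(totals.shape[1]):
            assert totals[:, ci] == pytest.approx(totals[0, ci], rel=1e-12)

    def test_bleach_factor_exact(self):
        scene = ks.generate_scene(seed=2, noise_sd=0.0, bleach_rate=0.05)
        ref = ks.generate_scene(seed=2, noise_sd=0.0, bleach_rate=0.0)
        t = 10.0
        bleached = ks.render_timelapse(scene, [0.0, t]).data[1]
        unbleached = ks.render_timelapse(ref, [0.0, t]).data[1]
        assert np.allclose(bleached, unbleached * np.exp(-0.5), rtol=1e-12)

    def test_no_corerouting_when_uncoupled(self):
        scene = ks.generate_scene(seed=2, coupling=0.0, noise_sd=0.0,
                                  bleach_rate=0.0)
        movie = ks.render_timelapse(scene, [0.0, 6.0, 12.0])
        gt = movie.ground_truth["channels"]["partner"]["amplitude"]
        for comp in ("spindle", "cytoplasm", "mito"):
            assert len(set(gt[comp])) == 1
        # partner frames identical with no bleach and no noise
        pi = movie.channel_names.index("partner")
        assert np.array_equal(movie.data[0, pi], movie.data[2, pi])

    def test_kinetic_monotonicity(self, scene):
        times = [0.0, 1.0, 3.0, 6.0, 12.0]
        movie = ks.render_timelapse(scene, times)
        amp = movie.ground_truth["channels"]["target"]["amplitude"]
        assert np.all(np.diff(amp["spindle"]) <= 0)
        assert np.all(np.diff(amp["mito"]) >= 0)

    def test_empty_times_rejected(self, scene):
        with pytest.raises(ParameterError):
            ks.render_timelapse(scene, [])

    def test_times_must_start_at_zero(self, scene):
        with pytest.raises(ParameterError):
            ks.render_timelapse(scene, [1.0, 2.0])


class TestTimingCohort:
    def test_full_arrest_censors_every_anaphase(self):
        spec = ks.TimingCohortSpec(n_cells=50, arrest_prob=1.0, seed=3)
        df = ks.generate_timing_cohort(spec)
        assert df["censored_anaphase"].all()
        assert (df.loc[df["censored_anaphase"], "anaphase_min"] == 720.0).all()

    def test_delay_factor_scales_intervals(self):
        base = dict(n_cells=40, seed=9, movie_length=1e9)
        a = ks.generate_timing_cohort(ks.TimingCohortSpec(delay_factor=1.0, **base))
        b = ks.generate_timing_cohort(ks.TimingCohortSpec(delay_factor=2.0, **base))
        ia = a["anaphase_min"] - a["metaphase_min"]
        ib = b["anaphase_min"] - b["metaphase_min"]
        assert np.allclose(ib, 2.0 * ia)

    def test_lognormal_median_recovery(self):
        spec = ks.TimingCohortSpec(
            n_cells=1000, meta_to_ana=(20.0, 0.3), seed=11, movie_length=1e9
        )
        df = ks.generate_timing_cohort(spec)
        observed = (df["anaphase_min"] - df["metaphase_min"])[
            ~df["censored_anaphase"]
        ]
        assert np.median(observed) == pytest.approx(20.0, rel=0.05)

    def test_invalid_cohort_size(self):
        with pytest.raises(ParameterError):
            ks.TimingCohortSpec(n_cells=0)


class TestLinescanScene:
    def test_noiseless_recovery_is_exact(self):
        scene = ks.generate_linescan_scene(r_true=2.0, noise_sd=0.0, seed=4)
        res = ks.linescan_enrichment(
            scene.probe,
            scene.on_lines,
            scene.adjacent_lines,
            background=scene.background["probe"],
            pixel_size=scene.pixel_size,
        )
        assert res.enrichment == pytest.approx(2.0, abs=1e-9)

    def test_unenriched_probe_is_uniform(self):
        scene = ks.generate_linescan_scene(r_true=1.0, noise_sd=0.0, seed=4)
        res = ks.linescan_enrichment(
            scene.probe, scene.on_lines, scene.adjacent_lines,
            background=scene.background["probe"], pixel_size=scene.pixel_size,
        )
        assert res.enrichment == pytest.approx(1.0, abs=1e-9)

    def test_on_lines_lie_on_filaments_and_controls_off(self):
        scene = ks.generate_linescan_scene(seed=8)
        from skimage.draw import line

        for (p0, p1) in scene.on_lines:
            rr, cc = line(*p0, *p1)
            assert scene.filament_mask[rr, cc].all()
        for (p0, p1) in scene.adjacent_lines:
            rr, cc = line(*p0, *p1)
            assert not scene.filament_mask[rr, cc].any()

    def test_too_few_filaments_rejected(self):
        with pytest.raises(ParameterError):
            ks.generate_linescan_scene(n_filaments=2, seed=0)

    def test_oversized_scene_rejected(self):
        with pytest.raises(ParameterError):
            ks.generate_linescan_scene(image_shape=(64, 64),
                                       filament_length=10.0, seed=0)
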