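"""Design timeline, planted effects, BOLD simulation, rating simulator."""

import numpy as np
import pytest

from bmrsa.simulate import (DesignSpec, EffectSpec, attribute_signs,
                            build_timeline, default_effects, default_rois,
                            make_mask, plant_amplitudes, simulate_ratings,
                            simulate_run, simulate_subject, stimulus_regressors)


class TestTimeline:
    def test_run_length_matches_acquisition(self):
        tl = build_timeline(DesignSpec(), seed=0)
        assert tl.total_duration == 438.0          # 7 min 18 s
        assert tl.n_volumes == 219

    def test_each_stimulus_three_times_per_run(self):
        tl = build_timeline(DesignSpec(), seed=1)
        sids = [sid for sid, _, _ in tl.events if sid is not None]
        assert sorted(np.unique(sids, return_counts=True)[1].tolist()) == [3] * 8

    def test_same_seed_same_order(self):
        a = build_timeline(DesignSpec(), seed=7)
        b = build_timeline(DesignSpec(), seed=7)
        assert a.events == b.events

    def test_events_tile_run_without_gaps(self):
        tl = build_timeline(DesignSpec(), seed=2)
        t = 0.0
        for _, onset, dur in tl.events:
            assert onset == pytest.approx(t)
            t += dur
        assert t == pytest.approx(tl.total_duration)

    def test_durations_must_be_volume_multiples(self):
        with pytest.raises(ValueError, match="multiple of tr"):
            DesignSpec(block_duration=13.0)

    def test_block_count_tied_to_repetitions(self):
        with pytest.raises(ValueError, match="blocks_per_run"):
            DesignSpec(blocks_per_run=20)


class TestPlantedAmplitudes:
    def _mask_and_rois(self, shape=(8, 8, 8)):
        _, mask = make_mask(shape)
        return mask, default_rois(shape, size=3)

    def test_zero_effects_give_flat_baseline(self):
        mask, rois = self._mask_and_rois()
        eff = EffectSpec(grid_shape=(8, 8, 8), roi_masks=rois,
                         effect_size={a: 0.0 for a in rois})
        amp = plant_amplitudes(eff, mask, np.random.default_rng(0))
        np.testing.assert_array_equal(amp, eff.baseline)

    def test_facing_effect_is_pure_between_category_contrast(self):
        mask, rois = self._mask_and_rois()
        eff = EffectSpec(grid_shape=(8, 8, 8), roi_masks=rois,
                         effect_size={"facing": 1.0}, pattern_sd=0.0)
        amp = plant_amplitudes(eff, mask, np.random.default_rng(0))
        s = attribute_signs()["facing"]
        roi_v = rois["facing"][mask]
        within = amp[:, s > 0] - amp[:, s > 0][:, [0]]
        assert np.allclose(within, 0.0)
        between = amp[roi_v][:, s > 0].mean(1) - amp[roi_v][:, s < 0].mean(1)
        np.testing.assert_allclose(between, 2.0)
        outside = amp[~roi_v]
        np.testing.assert_array_equal(outside, eff.baseline)

    def test_interaction_modulates_contrast_by_partner_category(self):
        mask, rois = self._mask_and_rois()
        eff = EffectSpec(grid_shape=(8, 8, 8), roi_masks=rois,
                         effect_size={"gender": 1.0},
                         interaction={("gender", "emotion"): 0.5},
                         pattern_sd=0.0)
        amp = plant_amplitudes(eff, mask, np.random.default_rng(0))
        signs = attribute_signs()
        roi_v = (rois["gender"] | rois["emotion"])[mask]
        g, e = signs["gender"], signs["emotion"]
        v = amp[roi_v][0]
        contrast_happy = v[(g > 0) & (e < 0)].mean() - v[(g < 0) & (e < 0)].mean()
        contrast_sad = v[(g > 0) & (e > 0)].mean() - v[(g < 0) & (e > 0)].mean()
        assert abs(contrast_happy - contrast_sad) == pytest.approx(2.0)

    def test_overlapping_rois_need_explicit_rule(self):
        rois = default_rois((8, 8, 8), size=3)
        rois["gender"] = rois["facing"].copy()
        with pytest.raises(ValueError, match="overlap"):
            EffectSpec(grid_shape=(8, 8, 8), roi_masks=rois,
                       effect_size={"facing": 1, "gender": 1})

    def test_effect_without_roi_rejected(self):
        mask, rois = self._mask_and_rois()
        eff = EffectSpec(grid_shape=(8, 8, 8),
                         roi_masks={"facing": rois["facing"]},
                         effect_size={"facing": 1.0, "gender": 1.0})
        with pytest.raises(ValueError, match="without an ROI"):
            plant_amplitudes(eff, mask, np.random.default_rng(0))


class TestSimulateRun:
    def _noiseless_effects(self):
        return EffectSpec(grid_shape=(8, 8, 8), noise_sd=0.0, drift=0.0,
                          nuisance_coupling=0.0, baseline=0.0)

    def test_noiseless_signal_is_hrf_convolved_boxcar(self):
        tl = build_timeline(DesignSpec(), seed=0)
        eff = self._noiseless_effects()
        amp = np.zeros((3, 8))
        amp[0, 2] = 1.0
        series, _ = simulate_run(tl, amp, eff, np.random.default_rng(0))
        expected = stimulus_regressors(tl)[2]
        np.testing.assert_allclose(series[0], expected, atol=1e-6)
        np.testing.assert_allclose(series[1], 0.0, atol=1e-7)

    def test_signal_linear_in_amplitude(self):
        tl = build_timeline(DesignSpec(), seed=0)
        eff = self._noiseless_effects()
        one = np.zeros((1, 8)); one[0, 5] = 1.0
        two = np.zeros((1, 8)); two[0, 5] = 2.0
        s1, _ = simulate_run(tl, one, eff, np.random.default_rng(0))
        s2, _ = simulate_run(tl, two, eff, np.random.default_rng(0))
        np.testing.assert_allclose(s2, 2.0 * s1, atol=1e-5)

    def test_additivity_of_planted_effects(self):
        tl = build_timeline(DesignSpec(), seed=3)
        eff = self._noiseless_effects()
        a = np.zeros((2, 8)); a[0, 1] = 1.0
        b = np.zeros((2, 8)); b[1, 6] = 2.0
        sa, _ = simulate_run(tl, a, eff, np.random.default_rng(0))
        sb, _ = simulate_run(tl, b, eff, np.random.default_rng(0))
        sab, _ = simulate_run(tl, a + b, eff, np.random.default_rng(0))
        np.testing.assert_allclose(sab, sa + sb, atol=1e-5)

    def test_noise_lag1_autocorrelation_matches_ar1(self):
        tl = build_timeline(DesignSpec(), seed=0)
        eff = EffectSpec(grid_shape=(8, 8, 8), noise_sd=1.0, ar1=0.3,
                         drift=0.0, nuisance_coupling=0.0, baseline=0.0)
        amp = np.zeros((600, 8))
        series, _ = simulate_run(tl, amp, eff, np.random.default_rng(11))
        x = series.astype(float)
        x = x - x.mean(axis=1, keepdims=True)
        r1 = np.mean(np.sum(x[:, 1:] * x[:, :-1], axis=1)
                     / np.sum(x * x, axis=1))
        assert abs(r1 - 0.3) < 0.05

    def test_subject_simulation_is_seed_reproducible(self):
        design = DesignSpec()
        eff = default_effects(grid_shape=(8, 8, 8), roi_size=3)
        a = simulate_subject(design, eff, seed=5)
        b = simulate_subject(design, eff, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.runs, b.runs))
        np.testing.assert_array_equal(a.truth, b.truth)
        assert a.timelines[0].events == b.timelines[0].events


class TestRatings:
    def test_ninety_six_trials(self):
        rt = simulate_ratings(seed=0)
        assert len(rt.df) == 96

    def test_flat_observer_always_answers_midpoint(self):
        rt = simulate_ratings(slope=0.0, criterion_sd=0.0, seed=0)
        assert (rt.df["rating"] == 4).all()

    def test_extreme_slope_saturates_scale_by_category(self):
        rt = simulate_ratings(slope=10.0, criterion_sd=0.0, seed=0)
        assert set(rt.df["rating"]) == {1, 7}
        signs = attribute_signs()
        for _, row in rt.df.iterrows():
            s = signs[row["attribute"]][row["stimulus_id"]]
            assert row["rating"] == (7 if s > 0 else 1)

    def test_ratings_always_in_scale_range(self):
        rt = simulate_ratings(slope=3.0, criterion_sd=5.0, seed=1)
        assert rt.df["rating"].between(1, 7).all()
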