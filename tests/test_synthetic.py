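"""The traveling-wave swimmer forward model and study generator."""

import numpy as np
import pytest

from swimkin.exceptions import TrialRejected
from swimkin.midline import curvature
from swimkin.synthetic import (
    SwimmerParams,
    TrialDesign,
    default_study_design,
    emit_tracks,
    generate_midline_sequence,
    generate_study,
    render_silhouette,
)


class TestMidlineGeneration:
    def test_zero_amplitude_zero_speed_is_static_straight_segment(self):
        p = SwimmerParams(tail_amp_A=0.0, swim_speed_U=0.0, duration=1.5)
        mls = generate_midline_sequence(p)
        first = mls[0].points
        assert np.allclose(first[:, 1], first[0, 1])
        for ml in mls:
            np.testing.assert_allclose(ml.points, first)

    def test_tail_trace_oscillation_count_is_f_times_duration(self):
        p = SwimmerParams(wave_freq_f=2.5, duration=2.0, jitter_sd=0.0)
        mls = generate_midline_sequence(p)
        tail_y = np.array([ml.points[-1, 1] for ml in mls])
        zero = tail_y - tail_y.mean()
        crossings = np.sum(np.diff(np.sign(zero)) != 0)
        assert crossings in (9, 10, 11)  # 5 full oscillations

    def test_arc_length_is_one_body_length_every_frame(self):
        mls = generate_midline_sequence(SwimmerParams())
        lengths = np.array([ml.length for ml in mls])
        np.testing.assert_allclose(lengths, 300.0, rtol=1e-3)

    def test_fewer_than_three_cycles_refused(self):
        with pytest.raises(TrialRejected, match="3 cycles"):
            generate_midline_sequence(SwimmerParams(wave_freq_f=2.0, duration=1.0))

    def test_curvature_crest_speed_matches_f_lambda_dense_oracle(self):
        """Crest transit tracked on densely sampled analytic midlines equals
        f·λ within 2% in the small-amplitude regime (f=2 Hz, λ=0.5 BL →
        100 %BL/s)."""
        p = SwimmerParams(
            wave_freq_f=2.0,
            wavelength_lambda=0.5,
            tail_amp_A=0.05,
            duration=2.0,
            jitter_sd=0.0,
        )
        mls = generate_midline_sequence(p, n_points=2000)
        s = np.linspace(0, 1, 2000)
        target, times, pos = None, [], []
        for i in range(len(mls)):
            k = curvature(mls[i])
            v = k
            idx = (
                np.nonzero(
                    (v[1:-1] > v[:-2])
                    & (v[1:-1] > v[2:])
                    & (v[1:-1] > 0.1 * np.max(np.abs(k)))
                )[0]
                + 1
            )
            e = s[idx]
            if len(e) == 0:
                continue
            if target is None:
                cand = e[(e > 0.55) & (e < 0.72)]
                if len(cand):
                    target = cand[0]
                continue
            j = int(np.argmin(np.abs(e - target)))
            if abs(e[j] - target) > 0.05:
                continue
            target = e[j]
            times.append(i / p.fps)
            pos.append(target)
            if target > 0.99:
                break
        times, pos = np.array(times), np.array(pos)
        t75 = np.interp(0.75, pos, times)
        t95 = np.interp(0.95, pos, times)
        speed_bl = 0.2 / (t95 - t75)
        assert speed_bl == pytest.approx(
            p.wave_freq_f * p.wavelength_lambda, rel=0.02
        )

    def test_same_seed_bit_identical(self):
        p = SwimmerParams(rng_seed=99)
        a = emit_tracks(generate_midline_sequence(p), p)
        b = emit_tracks(generate_midline_sequence(p), p)
        for name in a.landmark_names:
            assert np.array_equal(a.xy[name], b.xy[name])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SwimmerParams(wave_freq_f=-1.0).validate()
        with pytest.raises(ValueError, match="fin"):
            SwimmerParams(fin_freq=None, fin_state="On").validate()


class TestRenderSilhouette:
    def test_straight_fish_constant_halfwidth_is_stadium(self):
        w = 10.0
        p = SwimmerParams(
            tail_amp_A=0.0,
            swim_speed_U=0.0,
            duration=1.5,
            body_halfwidth_profile=lambda s: np.full_like(np.asarray(s, float), w),
        )
        mls = generate_midline_sequence(p)
        stack = render_silhouette(mls, p, shape=(256, 1024))
        frame = stack.frames[0]
        cols = np.nonzero(frame.any(axis=0))[0]
        length = cols[-1] - cols[0] + 1
        assert length == pytest.approx(p.body_length_px + 2 * w, abs=3)
        rows = np.nonzero(frame.any(axis=1))[0]
        assert rows[-1] - rows[0] + 1 == pytest.approx(2 * w, abs=3)

    def test_foreground_is_8_connected(self, clean_params):
        from scipy import ndimage

        mls = generate_midline_sequence(clean_params)
        stack = render_silhouette(mls, clean_params)
        _, n = ndimage.label(stack.frames[0], structure=np.ones((3, 3), int))
        assert n == 1

    def test_zero_length_midline_rejected(self, clean_params):
        from swimkin.midline import Midline, MidlineSequence

        with pytest.raises(Exception):
            bad = MidlineSequence([Midline(np.zeros((1, 2)))], 500.0)
            render_silhouette(bad, clean_params)

    def test_out_of_bounds_error_names_frame(self, clean_params):
        mls = generate_midline_sequence(clean_params)
        with pytest.raises(ValueError, match="frame 0"):
            render_silhouette(mls, clean_params, shape=(256, 300))


class TestEmitTracks:
    def test_zero_jitter_nose_equals_head_point(self):
        p = SwimmerParams(jitter_sd=0.0)
        mls = generate_midline_sequence(p)
        track = emit_tracks(mls, p)
        heads = np.array([ml.points[0] for ml in mls])
        np.testing.assert_array_equal(track.xy["nose"], heads)

    def test_fins_off_distance_constant_over_time(self):
        p = SwimmerParams(fin_freq=None, fin_state="Off", jitter_sd=0.0)
        mls = generate_midline_sequence(p)
        track = emit_tracks(mls, p)
        from swimkin.kinematics import _fin_body_distance

        d = _fin_body_distance(track, "fin_right", mls).values
        assert np.ptp(d) < 0.6  # residual body-wave leakage only, no beat

    def test_jitter_magnitude_matches_rayleigh_mean(self):
        """With σ=1 px per axis, the 2D displacement |track − truth| is
        Rayleigh with mean σ√(π/2); Monte-Carlo over ≥10⁴ samples, 5%."""
        p = SwimmerParams(jitter_sd=1.0, duration=6.0, rng_seed=3)
        mls = generate_midline_sequence(p)
        track = emit_tracks(mls, p)
        dists = []
        for name, truth_idx in (("nose", 0), ("tail", -1)):
            truth = np.array([ml.points[truth_idx] for ml in mls])
            dists.append(np.linalg.norm(track.xy[name] - truth, axis=1))
        dists = np.concatenate(dists)
        assert len(dists) >= 6000
        assert dists.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.05)

    def test_confidence_in_unit_interval(self, default_track):
        for name in default_track.landmark_names:
            c = default_track.confidence[name]
            assert np.all((c > 0) & (c <= 1))


class TestGenerateStudy:
    def test_design_is_5_fish_8_conditions_2_trials(self):
        design = default_study_design()
        assert len(design) == 80
        conditions = {d.condition for d in design}
        assert len(conditions) == 8

    def test_zero_shifts_zero_sds_identical_params(self):
        trials, truth = generate_study(
            effect_spec={},
            seed=5,
            fish_sd={},
            trial_sd={},
            base_fin_off_prob=0.0,
        )
        f_vals = truth.wave_freq_f.unique()
        assert len(f_vals) == 1
        assert truth.swim_speed_U.nunique() == 1

    def test_viscosity_shift_appears_in_truth_means(self):
        trials, truth = generate_study(
            effect_spec={("viscosity", 40): {"wave_freq_f": 0.5}},
            seed=5,
            fish_sd={},
            trial_sd={},
        )
        diff = (
            truth[truth.viscosity == 40].wave_freq_f.mean()
            - truth[truth.viscosity == 1].wave_freq_f.mean()
        )
        assert diff == pytest.approx(0.5, abs=1e-9)

    def test_fish_intercept_variance_recovered_monte_carlo(self):
        """sd 0.2 Hz fish intercepts → between-fish variance of trial-mean f
        ≈ 0.04 Hz² over 200 replicate studies, within 15%."""
        vars_ = []
        for seed in range(200):
            _, truth = generate_study(
                effect_spec={},
                seed=seed,
                fish_sd={"wave_freq_f": 0.2},
                trial_sd={},
            )
            fish_means = truth.groupby("fish_id").wave_freq_f.mean()
            vars_.append(fish_means.var(ddof=1))
        assert np.mean(vars_) == pytest.approx(0.04, rel=0.15)

    def test_invalid_shift_names_trial(self):
        with pytest.raises(ValueError, match="fish1_v40"):
            generate_study(
                effect_spec={("viscosity", 40): {"wave_freq_f": -10.0}},
                seed=0,
                fish_sd={},
                trial_sd={},
            )

    def test_non_finite_shift_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            generate_study(effect_spec={("light", "dark"): {"tail_amp_A": np.nan}})

    def test_reproducible_from_seed(self):
        _, t1 = generate_study(seed=11)
        _, t2 = generate_study(seed=11)
        assert t1.equals(t2)

    def test_trial_design_rejects_unknown_levels(self):
        with pytest.raises(ValueError):
            TrialDesign("f1", 7, "light", "intact", 1)
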