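"""Front tracking, velocity fitting, and the supercooling association."""

import numpy as np
import pytest

from icelocus import (
    FrontTrack,
    TrackError,
    VideoParams,
    detect_onset,
    fit_droplet_circle,
    fit_velocity,
    generate_video,
    track_front,
    velocity_vs_supercooling,
)


def pipeline_velocity(params):
    stack, _ = generate_video(params)
    geom = fit_droplet_circle(stack)
    onset = detect_onset(stack, geom)
    track = track_front(stack, onset, geom)
    return fit_velocity(track), track


class TestTrackFront:
    def test_extent_advances_at_generator_rate(self):
        """At 5.9 cm/s and 2100 fps the front gains ~28.1 um per frame."""
        params = VideoParams(seed=31, onset_r_norm=0.0, front_velocity=5.9,
                             n_frames=40)
        (_, _), track = pipeline_velocity(params)
        steps = np.diff(track.extent_um[track.valid])
        assert steps.mean() == pytest.approx(28.1, abs=1.5)
        assert (np.diff(track.extent_um[track.valid]) > -1e-9).all()

    def test_static_stack_is_too_short(self):
        params = VideoParams(seed=32, onset_r_norm=0.3, n_frames=12)
        stack, _ = generate_video(params)
        geom = fit_droplet_circle(stack)
        onset = detect_onset(stack, geom)
        static = type(stack)(
            frames=np.repeat(stack.frames[:1], 12, axis=0),
            frame_rate=stack.frame_rate, pixel_size=stack.pixel_size,
        )
        with pytest.raises(TrackError, match="track too short"):
            track_front(static, onset, geom)

    def test_rim_contact_invalidates_frames(self):
        params = VideoParams(seed=33, onset_r_norm=0.0, front_velocity=8.0,
                             n_frames=50)
        (_, _), track = pipeline_velocity(params)
        v = track.valid
        # once the front touches the rim the mask stays false
        first_false = int(np.argmax(~v)) if (~v).any() else len(v)
        assert not v[first_false:].any()


class TestFitVelocity:
    @pytest.mark.parametrize("v_true", [1.0, 2.5, 5.9, 10.0])
    def test_recovers_generator_velocity_within_5pct(self, v_true):
        params = VideoParams(seed=int(v_true * 10), onset_r_norm=0.0,
                             front_velocity=v_true, n_frames=60)
        (v_est, stderr), _ = pipeline_velocity(params)
        assert v_est == pytest.approx(v_true, rel=0.05)
        assert stderr < 0.1 * v_true

    def test_exactly_linear_track(self):
        t = np.arange(10) / 2100.0
        v = 4.2  # cm/s -> um/s = 4.2e4
        track = FrontTrack(
            frame_index=np.arange(10), time_s=t, extent_um=4.2e4 * t,
            valid=np.ones(10, dtype=bool),
        )
        v_est, stderr = fit_velocity(track)
        assert v_est == pytest.approx(4.2)
        assert stderr == pytest.approx(0.0, abs=1e-9)

    def test_two_point_track_rejected(self):
        track = FrontTrack(
            frame_index=np.arange(2), time_s=np.array([0.0, 1.0]),
            extent_um=np.array([0.0, 10.0]), valid=np.ones(2, dtype=bool),
        )
        with pytest.raises(TrackError):
            fit_velocity(track)

    def test_invariant_under_joint_rescaling(self):
        """Same physical speed at different pixel size / frame rate."""
        a = VideoParams(seed=44, onset_r_norm=0.0, front_velocity=4.0,
                        pixel_size=7.5, frame_rate=2100.0, n_frames=50)
        b = VideoParams(seed=44, onset_r_norm=0.0, front_velocity=4.0,
                        pixel_size=15.0, frame_rate=1050.0, n_frames=50)
        (va, _), _ = pipeline_velocity(a)
        (vb, _), _ = pipeline_velocity(b)
        assert va == pytest.approx(vb, rel=0.05)
        assert va == pytest.approx(4.0, rel=0.05)


class TestVelocityVsSupercooling:
    def test_proportional_pairs_have_perfect_rank_correlation(self):
        dt = np.array([4.1, 6.0, 8.0, 10.2, 14.0, 17.2])
        v = 0.58 * dt
        report = velocity_vs_supercooling(v, dt)
        assert report["spearman_rho"] == pytest.approx(1.0)
        assert report["slope_cm_s_per_C"] == pytest.approx(0.58)

    def test_anchor_pair_included_verbatim(self):
        dt = [4.1, 10.2, 17.2]
        v = [2.0, 5.9, 9.5]
        report = velocity_vs_supercooling(v, dt)
        assert [10.2, 5.9] in report["pairs"]

    def test_shuffled_pairs_decorrelate(self):
        """Permutation oracle: breaking the pairing kills the correlation."""
        rng = np.random.default_rng(5)
        dt = np.linspace(4.0, 17.0, 200)
        v = 0.5 * dt + rng.normal(0, 0.1, 200)
        rho_paired = velocity_vs_supercooling(v, dt)["spearman_rho"]
        rhos = []
        for _ in range(20):
            rhos.append(
                velocity_vs_supercooling(rng.permutation(v), dt)["spearman_rho"]
            )
        assert rho_paired > 0.95
        assert abs(np.mean(rhos)) < 0.15

    def test_nonpositive_supercooling_rejected(self):
        with pytest.raises(ValueError):
            velocity_vs_supercooling([1.0, 2.0, 3.0], [5.0, -1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            velocity_vs_supercooling([1.0, 2.0], [5.0, 6.0])
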