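"""Generator correctness: distributions, kinematics, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icelocus import MechanismParams, VideoParams, generate_onsets, generate_video


class TestGenerateOnsets:
    def test_bulk_radii_are_uniform_in_volume(self, bulk_records):
        """r_norm^2 of bulk onsets is uniform on [0,1): KS distance is tiny."""
        records, _ = bulk_records
        vf = records["r_norm"].to_numpy() ** 2
        d, _ = stats.kstest(vf, "uniform")
        assert d < 0.005
        assert vf.mean() == pytest.approx(0.5, abs=0.005)

    def test_bulk_outermost_sector_holds_one_fifth(self, bulk_records):
        records, _ = bulk_records
        frac_outer = (records["r_norm"] ** 2 >= 0.8).mean()
        assert frac_outer == pytest.approx(0.2, abs=0.005)

    def test_pure_awi_onsets_stay_in_shell(self):
        params = MechanismParams(p_awi=1.0, shell_width=0.02, seed=3)
        records, truth = generate_onsets(params)
        assert (records["r_norm"] >= 0.98).all()
        assert (truth["mechanism_truth"] == "awi").all()

    def test_mixture_outermost_rate_matches_identity(self):
        """E[outermost freq] = p_awi + (1-p_awi)*0.2 for thin shells."""
        p_awi = 0.5
        params = MechanismParams(
            p_awi=p_awi, n_droplets=25_000, cycles_per_droplet=4, seed=9
        )
        records, _ = generate_onsets(params)
        observed = (records["r_norm"] ** 2 >= 0.8).mean()
        assert observed == pytest.approx(p_awi + (1 - p_awi) * 0.2, abs=0.01)

    def test_temperatures_center_on_t50(self):
        params = MechanismParams(
            t50=-6.5, t_sigma=0.5, n_droplets=2500, cycles_per_droplet=4, seed=2
        )
        records, _ = generate_onsets(params)
        assert records["temp_C"].mean() == pytest.approx(-6.5, abs=0.05)
        assert records["temp_C"].std() == pytest.approx(0.5, rel=0.05)

    def test_drift_shifts_later_cycles(self):
        params = MechanismParams(t_drift=-0.5, t_sigma=0.0, seed=1)
        records, _ = generate_onsets(params)
        by_cycle = records.groupby("cycle")["temp_C"].mean()
        assert np.allclose(np.diff(by_cycle), -0.5)

    def test_same_seed_reproduces_tables_exactly(self):
        params = MechanismParams(p_awi=0.3, seed=42)
        a, ta = generate_onsets(params)
        b, tb = generate_onsets(params)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_design_defaults_give_32_events(self):
        records, _ = generate_onsets(MechanismParams())
        assert len(records) == 32
        assert records["droplet_id"].nunique() == 8
        assert records["cycle"].nunique() == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_awi": 1.5},
            {"p_awi": -0.1},
            {"shell_width": 0.0},
            {"shell_width": 0.5},
            {"n_droplets": 0},
            {"t_sigma": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MechanismParams(**kwargs)


class TestGenerateVideo:
    def test_front_advance_per_frame(self):
        """5.9 cm/s at 2100 fps advances ~28.1 um per frame."""
        params = VideoParams(front_velocity=5.9, frame_rate=2100.0)
        assert params.advance_um_per_frame == pytest.approx(28.095, abs=0.01)

    def test_preonset_frames_differ_only_by_noise(self, freezing_video):
        params, stack, _ = freezing_video
        pre = stack.frames[: params.onset_frame].astype(float)
        for a, b in zip(pre, pre[1:]):
            diff = a - b
            assert np.abs(diff.mean()) < 1.0
            assert diff.std() < 4 * params.noise_sigma

    def test_frozen_disk_radius_follows_kinematics(self):
        """Onset at center: frozen radius after k frames is k*v/frame_rate."""
        params = VideoParams(
            seed=0, onset_r_norm=0.0, front_velocity=5.0, noise_sigma=0.0, n_frames=30
        )
        stack, truth = generate_video(params)
        cr, cc = truth.center_row_truth[0], truth.center_col_truth[0]
        rows, cols = np.mgrid[0 : stack.shape[0], 0 : stack.shape[1]]
        dist = np.hypot(rows - cr, cols - cc)
        for k in (5, 10, 20):
            frame = stack.frames[params.onset_frame + k].astype(float)
            base = stack.frames[0].astype(float)
            frozen = np.abs(frame - base) > 10
            expected_px = k * params.advance_um_per_frame / params.pixel_size
            assert dist[frozen].max() == pytest.approx(expected_px, abs=1.5)

    def test_same_seed_reproduces_stack_bytes(self):
        params = VideoParams(seed=8)
        a, _ = generate_video(params)
        b, _ = generate_video(params)
        assert a.frames.tobytes() == b.frames.tobytes()

    def test_instant_freeze_warns_but_renders(self):
        params = VideoParams(front_velocity=500.0, frame_rate=100.0, n_frames=8)
        with pytest.warns(UserWarning, match="first changed frame"):
            stack, _ = generate_video(params)
        assert len(stack) == 8

    def test_dendrite_mode_keeps_tip_speed(self):
        """Lobed fronts advance at the nominal velocity along lobe axes."""
        params = VideoParams(
            seed=5, onset_r_norm=0.0, dendrite_lobes=4, noise_sigma=0.0, n_frames=30
        )
        stack, truth = generate_video(params)
        cr, cc = truth.center_row_truth[0], truth.center_col_truth[0]
        rows, cols = np.mgrid[0 : stack.shape[0], 0 : stack.shape[1]]
        dist = np.hypot(rows - cr, cols - cc)
        k = 20
        frozen = np.abs(
            stack.frames[params.onset_frame + k].astype(float)
            - stack.frames[0].astype(float)
        ) > 10
        expected_px = k * params.advance_um_per_frame / params.pixel_size
        assert dist[frozen].max() == pytest.approx(expected_px, abs=1.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"front_velocity": -1.0},
            {"onset_r_norm": 1.2},
            {"onset_frame": 0},
            {"onset_frame": 40, "n_frames": 40},
        ],
    )
    def test_invalid_video_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VideoParams(**kwargs)
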