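"""Simulator: kinematic model, pixel projection, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from leafkin import leafsim
from leafkin.leafsim import SimScenario, simulate_pose, pose_to_pixels, render_sequence

from conftest import small_scenario


class TestScenarioValidation:
    def test_rejects_nonpositive_timing_and_scale(self):
        with pytest.raises(ValueError):
            SimScenario(duration_min=0)
        with pytest.raises(ValueError):
            SimScenario(frame_interval_min=-1)
        with pytest.raises(ValueError):
            SimScenario(mm_per_px=0)

    def test_rejects_dose_on_white_light(self):
        with pytest.raises(ValueError, match="dose"):
            SimScenario(treatment="WL", dose=0.5)

    def test_rejects_dose_outside_unit_interval(self):
        with pytest.raises(ValueError):
            SimScenario(treatment="FRw", dose=1.5)

    def test_rejects_unknown_yaml_keys(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("duration_min: 10\nnot_a_field: 3\n")
        with pytest.raises(ValueError, match="not_a_field"):
            leafsim.load_scenario(p)

    def test_yaml_round_trip(self, tmp_path):
        scen = small_scenario("FRt", seed=3, dose=0.5)
        p = tmp_path / "scen.yaml"
        leafsim.save_scenario(scen, p)
        assert leafsim.load_scenario(p) == scen


class TestPoseModel:
    def test_all_motion_terms_off_gives_constant_angle(self):
        scen = SimScenario(treatment="WL", dose=0.0, diurnal_amp_deg=0.0,
                           osc_amp_deg=0.0, duration_min=120)
        pose = simulate_pose(scen)
        assert np.allclose(pose["petiole_angle_deg"], scen.angle0_petiole_deg)
        assert np.allclose(pose["lamina_angle_deg"], scen.angle0_lamina_deg)

    def test_logistic_saturates_at_full_amplitude(self):
        # far beyond onset the ramp term approaches dose*H; residual is
        # bounded by the logistic tail H*exp(-k*(m - onset))
        scen = SimScenario(treatment="FRw", dose=1.0, osc_amp_deg=0.0,
                           duration_min=1440)
        pose = simulate_pose(scen)
        last = pose.iloc[-1]
        m = (last["zt_h"] - scen.treatment_start_zt_h) * 60.0
        expected = (scen.angle0_petiole_deg
                    + scen.diurnal_amp_deg * np.sin(2 * np.pi * last["zt_h"] / 24.0)
                    + scen.hyponasty_amp_deg)
        tail = scen.hyponasty_amp_deg * np.exp(
            -scen.hyponasty_rate_per_min * (m - scen.hyponasty_onset_min))
        # oscillation is off; night envelope contributes nothing here
        assert abs(last["petiole_angle_deg"] - expected) <= tail + 1e-9

    def test_petiole_growth_closed_form_at_24h(self):
        # hand computation: 5.0 mm + 24 h * 0.05 mm/h * 2.0 = 7.4 mm
        scen = leafsim.default_scenario("FRw", seed=7)
        pose = simulate_pose(scen)
        t = pose["t_min"].to_numpy()
        i = int(np.argmin(np.abs(t - 1439.0)))  # last frame of the 24-h run
        expected = 5.0 + (1439.0 / 60.0) * 0.05 * 2.0
        assert pose["petiole_len_mm"].iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_lamina_length_unaffected_by_dose(self):
        base = dict(duration_min=600)
        wl = simulate_pose(SimScenario(treatment="WL", dose=0.0, **base))
        fr = simulate_pose(SimScenario(treatment="FRw", dose=1.0, **base))
        assert np.array_equal(wl["lamina_len_mm"], fr["lamina_len_mm"])
        assert (fr["petiole_len_mm"].iloc[-1] > wl["petiole_len_mm"].iloc[-1])

    def test_lengths_positive_and_nondecreasing(self):
        pose = simulate_pose(small_scenario())
        for col in ("petiole_len_mm", "lamina_len_mm"):
            v = pose[col].to_numpy()
            assert (v > 0).all() and (np.diff(v) >= 0).all()

    def test_illumination_matches_photoperiod_arithmetic(self):
        scen = leafsim.default_scenario("WL", seed=0)
        pose = simulate_pose(scen)
        ztm = np.mod(pose["zt_h"].to_numpy(), 24.0)
        expected = np.where(
            (ztm >= scen.lights_on_zt_h) & (ztm < scen.lights_off_zt_h), "day", "night")
        assert (pose["illumination"].to_numpy() == expected).all()

    def test_angle_range_violation_rejected(self):
        scen = SimScenario(treatment="FRw", dose=1.0, angle0_petiole_deg=170.0,
                           hyponasty_amp_deg=30.0, duration_min=1440)
        with pytest.raises(ValueError, match="petiole angle"):
            simulate_pose(scen)


class TestPoseToPixels:
    def _single_pose(self, angle_p, len_p_mm, scen):
        return pd.DataFrame({
            "t_min": [0.0], "zt_h": [scen.start_zt_h],
            "petiole_angle_deg": [angle_p], "lamina_angle_deg": [0.0],
            "petiole_len_mm": [len_p_mm], "lamina_len_mm": [1.0],
            "illumination": ["day"],
        })

    def test_horizontal_segment(self):
        scen = SimScenario(mm_per_px=1.0)
        pose = self._single_pose(0.0, 50.0, scen)
        pix = pose_to_pixels(pose, scen, center_px=(100.0, 200.0))
        assert pix["jx"].iloc[0] == pytest.approx(150.0)
        assert pix["jy"].iloc[0] == pytest.approx(200.0)

    def test_vertical_segment_y_decreases_upward(self):
        scen = SimScenario(mm_per_px=1.0)
        pose = self._single_pose(90.0, 50.0, scen)
        pix = pose_to_pixels(pose, scen, center_px=(100.0, 200.0))
        assert pix["jx"].iloc[0] == pytest.approx(100.0)
        assert pix["jy"].iloc[0] == pytest.approx(150.0)

    def test_out_of_frame_error_names_first_offending_frame(self):
        scen = SimScenario(mm_per_px=1.0, image_w_px=120, image_h_px=100)
        pose = self._single_pose(0.0, 50.0, scen)
        with pytest.raises(ValueError, match="frame 0"):
            pose_to_pixels(pose, scen, center_px=(100.0, 50.0))

    def test_interframe_displacement_bounded_for_default_scenarios(self):
        # tracking is well-posed: landmarks move <= 3 px/frame
        for scen in (leafsim.default_scenario("FRw", 0),
                     leafsim.default_scenario("WL", 0),
                     leafsim.day_night_scenario("FRw", 0)):
            pix = pose_to_pixels(simulate_pose(scen), scen)
            for a, b in (("jx", "jy"), ("tx", "ty")):
                step = np.hypot(np.diff(pix[a]), np.diff(pix[b]))
                assert step.max() <= 3.0


class TestRendering:
    def test_frame_count_equals_duration_over_interval(self, sim_run):
        assert len(sim_run["frame_paths"]) == 60

    def test_night_frames_are_grayscale(self, sim_run):
        gt = sim_run["gt"]
        i = int(gt.index[gt["illumination"] == "night"][0])
        arr = np.asarray(Image.open(sim_run["frame_paths"][i])).astype(int)
        assert np.abs(arr[:, :, 0] - arr[:, :, 1]).max() == 0
        assert np.abs(arr[:, :, 1] - arr[:, :, 2]).max() == 0

    def test_day_frame_has_plant_at_ground_truth_junction(self, sim_run):
        gt = sim_run["gt"]
        arr = np.asarray(Image.open(sim_run["frame_paths"][0])).astype(int)
        x, y = int(round(gt["jx"][0])), int(round(gt["jy"][0]))
        bg = np.array(leafsim.DAY_BACKGROUND)
        assert np.abs(arr[y, x] - bg).max() > 40

    def test_ground_truth_round_trips_pose_exactly(self, sim_run):
        pose = simulate_pose(sim_run["scenario"])
        gt = sim_run["gt"]
        for col in ("petiole_angle_deg", "lamina_angle_deg",
                    "petiole_len_mm", "lamina_len_mm"):
            assert np.array_equal(gt[col].to_numpy(), pose[col].to_numpy())

    def test_rendering_is_bit_deterministic(self, tmp_path):
        scen = small_scenario(duration_min=5.0, noise_sd=4.0)
        pa, gta = render_sequence(scen, tmp_path / "a")
        pb, gtb = render_sequence(scen, tmp_path / "b")
        assert gta.read_bytes() == gtb.read_bytes()
        for a, b in zip(pa, pb):
            assert a.read_bytes() == b.read_bytes()

    def test_different_seed_changes_noisy_pixels_not_truth(self, tmp_path):
        s1 = small_scenario(duration_min=3.0, noise_sd=4.0, seed=1)
        s2 = small_scenario(duration_min=3.0, noise_sd=4.0, seed=2)
        pa, gta = render_sequence(s1, tmp_path / "a")
        pb, gtb = render_sequence(s2, tmp_path / "b")
        assert gta.read_bytes() == gtb.read_bytes()
        assert pa[0].read_bytes() != pb[0].read_bytes()
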