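"""Filtering, gait events, joint angles, Winter moments, cycle averaging."""

import numpy as np
import pytest

from gaitmet.inverse_dynamics import (
    CycleTrajectory,
    N_NODES,
    WINTER_SEGMENTS,
    average_cycles,
    filter_zero_phase,
    joint_angles_from_markers,
    joint_moments_winter,
    process_trial,
    resample_cycle,
    segment_cycles,
)
from gaitmet.synthetic import G, NoiseConfig, generate_cohort, generate_gait_trial


class TestFilter:
    def test_dc_passthrough(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(filter_zero_phase(x, fs=100, fc=6), x)

    @pytest.mark.parametrize("freq,max_attenuation", [(1.0, 0.01)])
    def test_passband(self, freq, max_attenuation):
        t = np.arange(0, 20, 0.01)
        x = np.sin(2 * np.pi * freq * t)
        y = filter_zero_phase(x, fs=100, fc=6)
        mid = slice(200, -200)
        gain = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert gain > 1 - max_attenuation

    def test_stopband(self):
        t = np.arange(0, 20, 0.01)
        x = np.sin(2 * np.pi * 30.0 * t)
        y = filter_zero_phase(x, fs=100, fc=6)
        assert np.abs(y[200:-200]).max() < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            filter_zero_phase(np.zeros(100), fs=10, fc=6)

    def test_zero_phase_symmetry(self):
        """Filtering a reversed signal then reversing matches the original."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(800)
        y1 = filter_zero_phase(x, fs=100, fc=6)
        y2 = filter_zero_phase(x[::-1], fs=100, fc=6)[::-1]
        np.testing.assert_allclose(y1, y2, atol=1e-10)


class TestSegmentation:
    def test_known_period_recovered(self):
        fs, period = 100.0, 1.2
        t = np.arange(0, 12, 1 / fs)
        phase = (t / period) % 1.0
        grf = np.where(phase < 0.6, 700 * np.sin(np.pi * phase / 0.6), 0.0)
        cycles = segment_cycles(grf, threshold=35.0)
        lengths = np.array([e - s for s, e in cycles])
        assert np.all(np.abs(lengths - period * fs) <= 1)

    def test_all_zero_grf(self):
        with pytest.warns(UserWarning):
            assert segment_cycles(np.zeros(1000), threshold=35.0) == []

    def test_constant_above_threshold(self):
        with pytest.warns(UserWarning):
            assert segment_cycles(np.full(1000, 700.0), threshold=35.0) == []

    def test_negative_grf_rejected(self):
        with pytest.raises(ValueError):
            segment_cycles(np.array([-5.0, 10.0]), threshold=1.0)


def _pose_markers(sigma_trunk, sigma_thigh, sigma_shank, foot_pitch,
                  n=5, hip=(0.0, 0.9)):
    """Build a constant pose from absolute segment orientations (rad)."""
    hip = np.tile(np.array(hip), (n, 1))
    knee = hip + 0.4 * np.stack([np.full(n, np.sin(sigma_thigh)),
                                 -np.full(n, np.cos(sigma_thigh))], axis=1)
    ankle = knee + 0.4 * np.stack([np.full(n, np.sin(sigma_shank)),
                                   -np.full(n, np.cos(sigma_shank))], axis=1)
    toe = ankle + 0.2 * np.stack([np.full(n, np.cos(foot_pitch)),
                                  np.full(n, np.sin(foot_pitch))], axis=1)
    shoulder = hip + 0.5 * np.stack([np.full(n, np.sin(sigma_trunk)),
                                     np.full(n, np.cos(sigma_trunk))], axis=1)
    return {("right", "hip"): hip, ("right", "knee"): knee,
            ("right", "ankle"): ankle, ("right", "toe"): toe,
            ("right", "shoulder"): shoulder}


class TestJointAngles:
    def test_reference_pose(self):
        markers = _pose_markers(0.0, 0.0, 0.0, 0.0)
        ang = joint_angles_from_markers(markers)
        for joint in ("hip", "knee", "ankle"):
            np.testing.assert_allclose(ang[joint], 0.0, atol=1e-12)

    def test_thirty_degree_knee_flexion(self):
        th = np.deg2rad(30.0)
        markers = _pose_markers(0.0, 0.0, -th, 0.0)
        ang = joint_angles_from_markers(markers)
        np.testing.assert_allclose(np.rad2deg(ang["knee"]), 30.0, atol=1e-10)
        np.testing.assert_allclose(ang["hip"], 0.0, atol=1e-12)

    def test_whole_body_rotation_invariance(self):
        base = joint_angles_from_markers(
            _pose_markers(0.05, 0.3, 0.1, -0.1))
        rot = np.deg2rad(10.0)
        # upward (trunk) orientations count rotations with the opposite
        # sign to the downward segment orientations
        rotated = joint_angles_from_markers(
            _pose_markers(0.05 - rot, 0.3 + rot, 0.1 + rot, -0.1 + rot))
        for joint in ("hip", "knee"):
            np.testing.assert_allclose(base[joint], rotated[joint], atol=1e-12)

    def test_coincident_markers_reported_with_frame(self):
        markers = _pose_markers(0.0, 0.0, 0.0, 0.0)
        markers[("right", "knee")] = markers[("right", "hip")].copy()
        with pytest.raises(ValueError, match="frame 0"):
            joint_angles_from_markers(markers)


class TestWinterMoments:
    mass, height, fs = 70.0, 1.75, 100.0

    def _static(self, cop_offset, fy):
        markers = _pose_markers(0.0, 0.0, 0.0, 0.0, n=20)
        ankle_x = markers[("right", "ankle")][0, 0]
        n = 20
        grf = {"fy": np.full(n, fy), "fx": np.zeros(n),
               "cop": np.full(n, ankle_x + cop_offset)}
        return joint_moments_winter(markers, grf, self.mass, self.height,
                                    self.fs)

    def test_cop_under_ankle_zero_ankle_moment(self):
        mom = self._static(0.0, 700.0)
        assert np.abs(mom["ankle"]).max() < 1.0

    def test_anterior_cop_gives_plantarflexion_moment(self):
        mom = self._static(0.10, 700.0)
        np.testing.assert_allclose(mom["ankle"], 70.0, atol=1.5)

    def test_gravity_only_statics_oracle(self):
        """Zero GRF, stationary limb: moments from segment weights alone."""
        sigma_thigh = 0.4
        markers = _pose_markers(0.0, sigma_thigh, 0.0, 0.0, n=20)
        n = 20
        grf = {"fy": np.zeros(n), "fx": np.zeros(n), "cop": np.zeros(n)}
        mom = joint_moments_winter(markers, grf, self.mass, self.height,
                                   self.fs)
        hip = markers[("right", "hip")][0]
        knee = markers[("right", "knee")][0]
        ankle = markers[("right", "ankle")][0]
        seg_lengths = {"foot": 0.152 * self.height,
                       "shank": 0.246 * self.height,
                       "thigh": 0.245 * self.height}
        # closed-form statics: M_z at the hip balances sum of m_i g x_i
        total = 0.0
        for seg, (p, d) in {"thigh": (hip, knee), "shank": (knee, ankle),
                            "foot": (ankle, ankle + np.array([0.2, 0.0]))}.items():
            pars = WINTER_SEGMENTS[seg]
            com = p + pars["com_frac"] * (d - p)
            total += pars["mass_frac"] * self.mass * G * (com[0] - hip[0])
        # CCW moment of gravity about hip is -total; internal hip moment
        # (Winter extension positive) balances it
        np.testing.assert_allclose(mom["hip"], -total, rtol=1e-6, atol=1e-9)

    def test_missing_anthropometry_rejected(self):
        markers = _pose_markers(0.0, 0.0, 0.0, 0.0, n=4)
        grf = {"fy": np.zeros(4), "fx": np.zeros(4), "cop": np.zeros(4)}
        with pytest.raises(ValueError):
            joint_moments_winter(markers, grf, 0.0, self.height, self.fs)


class TestAveraging:
    def test_identical_cycles_zero_sd(self):
        fs = 100.0
        x = np.tile(np.sin(np.linspace(0, 2 * np.pi, 120, endpoint=False)), 5)
        chans = {"right": {name: x for name in
                           ["angle_hip", "angle_knee", "angle_ankle",
                            "moment_hip", "moment_knee", "moment_ankle",
                            "grf_fy", "grf_fx"]}}
        cycles = {"right": [(0, 120), (120, 240), (240, 360)]}
        cyc = average_cycles(chans, cycles, fs)
        assert cyc.joint_angles.shape == (N_NODES, 3)
        np.testing.assert_allclose(cyc.sd["angle_hip"], 0.0, atol=1e-12)
        np.testing.assert_allclose(cyc.duration, 1.2)

    def test_antisymmetric_cycles_average_to_zero(self):
        fs = 100.0
        base = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        x = np.concatenate([base, -base])
        chans = {"right": {name: x for name in
                           ["angle_hip", "angle_knee", "angle_ankle",
                            "moment_hip", "moment_knee", "moment_ankle",
                            "grf_fy", "grf_fx"]}}
        cyc = average_cycles(chans, {"right": [(0, 100), (100, 200)]}, fs)
        np.testing.assert_allclose(cyc.joint_angles, 0.0, atol=1e-12)

    def test_noise_sd_recovered(self):
        rng = np.random.default_rng(1)
        fs, n_cycles, n_per = 100.0, 200, 100
        base = np.sin(np.linspace(0, 2 * np.pi, n_per, endpoint=False))
        x = np.tile(base, n_cycles) + rng.normal(0, 0.3, n_cycles * n_per)
        chans = {"right": {name: x for name in
                           ["angle_hip", "angle_knee", "angle_ankle",
                            "moment_hip", "moment_knee", "moment_ankle",
                            "grf_fy", "grf_fx"]}}
        cycles = {"right": [(i * n_per, (i + 1) * n_per)
                            for i in range(n_cycles)]}
        cyc = average_cycles(chans, cycles, fs)
        # per-node SD tracks the injected noise SD up to the variance
        # attenuation of linear resampling (factor sqrt(a^2 + (1-a)^2))
        assert 0.7 * 0.3 < np.median(cyc.sd["grf_fy"]) < 1.05 * 0.3

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError):
            average_cycles({"right": {}}, {"right": []}, 100.0)


class TestCycleTrajectory:
    def test_node_count_enforced(self):
        with pytest.raises(ValueError):
            CycleTrajectory(joint_angles=np.zeros((50, 3)),
                            joint_moments=np.zeros((50, 3)),
                            grf=np.zeros((50, 2)), duration=1.0)

    def test_positive_duration_enforced(self):
        with pytest.raises(ValueError):
            CycleTrajectory(joint_angles=np.zeros((100, 3)),
                            joint_moments=np.zeros((100, 3)),
                            grf=np.zeros((100, 2)), duration=0.0)


class TestProcessTrial:
    def test_template_periodicity_preserved(self):
        """The averaged cycle's endpoints stay periodic for template data."""
        subject = generate_cohort(1, seed=2)[0]
        trial = generate_gait_trial(subject, 1.3, 0.0, seed=3,
                                    noise=NoiseConfig.zero())
        cyc = process_trial(trial)
        for col in range(3):
            chan = cyc.joint_angles[:, col]
            wrap_gap = abs(chan[0] - (2 * chan[-1] - chan[-2]))
            assert wrap_gap < 0.1 * np.ptp(chan)
        assert cyc.duration == pytest.approx(trial.cycle_period, rel=0.02)
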