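import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

import myofuse as mf
from myofuse.emg import EMG_CHANNELS
from myofuse.synthetic import (
    IMAGING_MUSCLES,
    LATENT_MUSCLES,
    UnknownTaskError,
    _muscle_bands,
)

PHI = np.linspace(0.0, 1.0, 4096, endpoint=False)


class TestMakeTemplate:
    def test_deterministic(self):
        a = mf.make_template("level_walk", rng_seed=1)
        b = mf.make_template("level_walk", rng_seed=1)
        for joint in mf.JOINTS:
            np.testing.assert_array_equal(
                a.joint_angle(joint, PHI), b.joint_angle(joint, PHI)
            )
        for m in LATENT_MUSCLES:
            np.testing.assert_array_equal(
                a.activation(m, PHI), b.activation(m, PHI)
            )

    @pytest.mark.parametrize("task", mf.TASKS)
    def test_joint_ranges_physiologic(self, task):
        tpl = mf.make_template(task, rng_seed=1)
        for joint in mf.JOINTS:
            rng = tpl.joint_range(joint)
            assert 10.0 <= rng <= 90.0

    def test_knee_profiles_distinct_across_tasks(self):
        templates = {t: mf.make_template(t, rng_seed=1) for t in mf.TASKS}
        knees = {t: tpl.joint_angle("knee", PHI) for t, tpl in templates.items()}
        tasks = list(mf.TASKS)
        for i in range(len(tasks)):
            for j in range(i + 1, len(tasks)):
                diff = np.abs(knees[tasks[i]] - knees[tasks[j]]).max()
                assert diff >= 5.0, (tasks[i], tasks[j], diff)

    def test_profiles_periodic_and_nonnegative(self, level_template):
        # value + slope continuity across the phase wrap
        eps = 1e-6
        for joint in mf.JOINTS:
            f0 = level_template.joint_angle(joint, [0.0, eps])
            f1 = level_template.joint_angle(joint, [1.0 - eps, 1.0 - 2 * eps])
            assert abs(f0[0] - f1[0]) < 1e-3
            s0 = (f0[1] - f0[0]) / eps
            s1 = (f1[0] - f1[1]) / eps
            assert abs(s0 - s1) < max(1.0, 1e-3 * max(abs(s0), 1.0))
        for m in LATENT_MUSCLES:
            act = level_template.activation(m, PHI)
            assert np.all(act >= 0)

    def test_unknown_task_rejected(self):
        with pytest.raises(UnknownTaskError):
            mf.make_template("moonwalk", rng_seed=1)


class TestGenerateTrial:
    def test_heel_strike_fenceposts(self, level_template):
        trial = mf.generate_trial(level_template, n_strides=3, rng_seed=5)
        assert len(trial.heel_strikes) == 4
        assert np.all(np.diff(trial.heel_strikes) > 0)

    def test_stream_durations_consistent(self, small_trial):
        dur = small_trial.heel_strikes[-1]
        assert abs(small_trial.emg.duration_s - dur) <= 1 / 1200 + 1e-9
        kin_t = small_trial.kinematics["time_s"].to_numpy()
        assert abs((kin_t[-1] + 0.01) - dur) <= 0.01 + 1e-9
        assert abs(small_trial.ultrasound.duration_s - dur) <= 0.05 + 1e-9

    def test_zero_noise_angles_match_template(self, level_template):
        trial = mf.generate_trial(
            level_template, n_strides=3, noise_cfg=mf.NoiseConfig.zero(), rng_seed=5
        )
        t = trial.kinematics["time_s"].to_numpy()
        period = level_template.stride_period_s
        phi = (t % period) / period
        for joint in mf.JOINTS:
            expected = level_template.joint_angle(joint, phi)
            np.testing.assert_allclose(
                trial.kinematics[f"{joint}_angle"].to_numpy(), expected, atol=1e-9
            )

    def test_silent_muscle_mav_below_one_percent_of_fully_active(self):
        tpl = mf.make_template("level_walk", rng_seed=1)
        # TA silenced; VL pinned fully active (flat bump, amplitude 1)
        tpl.activation_bumps["TA"] = ()
        tpl.activation_bumps["VL"] = ((0.0, 0.0, 1.0),)
        trial = mf.generate_trial(tpl, n_strides=3, rng_seed=9)
        t = trial.emg.times
        hs = trial.heel_strikes
        in_stride = (t >= hs[0]) & (t < hs[1])
        ta = np.mean(np.abs(trial.emg.data[in_stride, EMG_CHANNELS.index("TA")]))
        vl = np.mean(np.abs(trial.emg.data[in_stride, EMG_CHANNELS.index("VL")]))
        assert ta < 0.01 * vl

    def test_determinism_bit_identical(self, level_template):
        a = mf.generate_trial(level_template, n_strides=3, rng_seed=5)
        b = mf.generate_trial(level_template, n_strides=3, rng_seed=5)
        np.testing.assert_array_equal(a.emg.data, b.emg.data)
        np.testing.assert_array_equal(a.ultrasound.frames, b.ultrasound.frames)
        np.testing.assert_array_equal(
            a.kinematics.to_numpy(), b.kinematics.to_numpy()
        )
        np.testing.assert_array_equal(a.heel_strikes, b.heel_strikes)

    def test_emg_spectrum_confined_to_band(self, small_trial):
        """Generated EMG power below 10 Hz and above 500 Hz each < 5%."""
        for j in range(8):
            f, pxx = sps.welch(
                small_trial.emg.data[:, j], fs=1200.0, nperseg=2048
            )
            total = np.trapezoid(pxx, f)
            low = np.trapezoid(pxx[f < 10], f[f < 10])
            high = np.trapezoid(pxx[f > 500], f[f > 500])
            assert low < 0.05 * total
            assert high < 0.05 * total

    def test_ultrasound_intensity_bounds(self, small_trial):
        assert small_trial.ultrasound.frames.min() >= 0
        assert small_trial.ultrasound.frames.max() <= 255

    def test_latent_recoverable_from_region_intensity(self, zero_noise_trial):
        """Zero noise: region mean intensity is monotone in activation."""
        frames = zero_noise_trial.ultrasound.frames
        t_us = zero_noise_trial.ultrasound.times
        lat_t = zero_noise_trial.latent["time_s"].to_numpy()
        bands = _muscle_bands(frames.shape[1])
        for m in IMAGING_MUSCLES:
            r0, r1 = bands[m]
            region_mean = frames[:, r0:r1, :].mean(axis=(1, 2))
            act = np.interp(t_us, lat_t, zero_noise_trial.latent[m].to_numpy())
            rho = stats.spearmanr(act, region_mean).statistic
            assert rho > 0.99, (m, rho)

    def test_invalid_args_rejected(self, level_template):
        with pytest.raises(ValueError):
            mf.generate_trial(level_template, n_strides=0, rng_seed=1)
        with pytest.raises(ValueError):
            mf.NoiseConfig(kinematic_noise_sd_deg=-1.0)


class TestGenerateDataset:
    def test_one_trial_per_task_and_determinism(self):
        cfg = mf.DatasetConfig().scaled(3, 2)
        a = mf.generate_dataset(cfg, rng_seed=7)
        b = mf.generate_dataset(cfg, rng_seed=7)
        assert set(a) == set(mf.TASKS)
        for task in a:
            np.testing.assert_array_equal(a[task].emg.data, b[task].emg.data)
            np.testing.assert_array_equal(
                a[task].ultrasound.frames, b[task].ultrasound.frames
            )

    def test_default_walk_strides_exceed_stair_strides(self):
        cfg = mf.DatasetConfig()
        assert (
            cfg.strides_per_task["level_walk"]
            > cfg.strides_per_task["stair_ascent"]
        )
        trials = mf.generate_dataset(mf.DatasetConfig().scaled(4, 2), rng_seed=1)
        assert trials["level_walk"].n_strides > trials["stair_ascent"].n_strides

    def test_empty_task_list_rejected(self):
        with pytest.raises(ValueError):
            mf.DatasetConfig(tasks=())


class TestFusionInformativeness:
    def test_coupling_routes_through_both_modalities(self):
        """Designed dependency: every joint has an imaging-only component;
        hip and ankle also depend on EMG-only muscles, so neither modality
        alone observes all kinematic variability."""
        C = mf.CouplingConfig().matrix()
        imaging_only = [LATENT_MUSCLES.index(m) for m in ("VM", "VI")]
        emg_only = [
            LATENT_MUSCLES.index(m)
            for m in EMG_CHANNELS
            if m not in IMAGING_MUSCLES
        ]
        for i, joint in enumerate(mf.JOINTS):
            assert C[i, imaging_only].sum() > 0, joint
        assert C[mf.JOINTS.index("hip"), emg_only].sum() > 0
        assert C[mf.JOINTS.index("ankle"), emg_only].sum() > 0
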