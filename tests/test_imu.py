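import numpy as np
import pytest
from scipy.signal import butter, freqz, periodogram as sp_periodogram

from hld import imu, quat, synthetic
from hld.imu import FilterConfig, GravityModel


CFG = FilterConfig(sample_rate=50.0)


class TestButterworthSplit:
    def test_dc_passes_low_pass(self):
        x = np.full(500, 3.7)
        low, high = imu.butterworth_split(x, CFG)
        inner = slice(50, -50)
        assert np.max(np.abs(low[inner] - 3.7)) < 1e-6
        assert np.max(np.abs(high[inner])) < 1e-6

    def test_deep_passband_sinusoid_preserved(self):
        f = 0.01 * CFG.fc_low
        t = np.arange(5000) / CFG.sample_rate
        x = np.sin(2 * np.pi * f * t)
        low, _ = imu.butterworth_split(x, CFG)
        inner = slice(500, -500)
        ratio = low[inner].std() / x[inner].std()
        assert ratio > 0.99

    def test_stopband_attenuation_matches_analytic_response(self, rng):
        """Filtered white-noise spectrum obeys the analytic |H|^4 of the
        zero-phase (forward-backward) Butterworth magnitude."""
        cfg = FilterConfig(order=4, fc_low=5.0, fc_high=5.0, sample_rate=50.0)
        x = rng.normal(size=16384)
        low, _ = imu.butterworth_split(x, cfg)
        freqs, pxx = sp_periodogram(low, fs=cfg.sample_rate)
        passband = pxx[(freqs > 0.2) & (freqs < 0.8 * cfg.fc_low)].mean()
        stop = pxx[freqs > 2 * cfg.fc_low].mean()
        assert stop / passband < 0.01
        # independent analytic check of the expected floor: |H(2 fc)|^4
        b, a = butter(4, cfg.fc_low / (cfg.sample_rate / 2), btype="low")
        w, h = freqz(b, a, worN=[2 * cfg.fc_low], fs=cfg.sample_rate)
        assert stop / passband < max(10 * np.abs(h[0]) ** 4, 1e-4)

    def test_short_series_rejected_with_length_message(self):
        with pytest.raises(ValueError, match="too short"):
            imu.butterworth_split(np.zeros(10), CFG)

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            imu.butterworth_split(np.zeros(100), FilterConfig(fc_low=30, sample_rate=50))


class TestChannelNorm:
    def test_all_zero_components(self):
        z = np.zeros((3, 10))
        assert np.array_equal(imu.channel_norm(z, z), np.zeros(10))

    def test_three_four_five_triangle(self):
        lpf = np.array([[3.0], [4.0], [0.0]])
        hpf = np.zeros((3, 1))
        assert imu.channel_norm(lpf, hpf)[0] == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        lpf = rng.normal(size=(3, 200))
        hpf = rng.normal(size=(3, 200))
        got = imu.channel_norm(lpf, hpf)
        # independently coded sqrt-of-sum-of-squares, sample by sample
        oracle = np.array(
            [
                np.sqrt(sum(lpf[c, i] ** 2 for c in range(3))
                        + sum(hpf[c, i] ** 2 for c in range(3)))
                for i in range(200)
            ]
        )
        assert np.allclose(got, oracle, atol=1e-12)

    def test_dominates_any_single_component_and_nonnegative(self, rng):
        lpf = rng.normal(size=(3, 100))
        hpf = rng.normal(size=(3, 100))
        out = imu.channel_norm(lpf, hpf)
        assert np.all(out >= 0)
        assert np.all(out + 1e-12 >= np.abs(np.vstack([lpf, hpf])).max(axis=0))

    def test_as_printed_sum_mode(self):
        lpf = np.ones((3, 4))
        hpf = np.ones((3, 4))
        assert np.allclose(imu.channel_norm(lpf, hpf, mode="as_printed_sum"), 6.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            imu.channel_norm(np.zeros((3, 5)), np.zeros((3, 6)))


class TestGravityEstimation:
    def test_noiseless_static(self):
        accel = np.tile([0.0, 0.0, 9.81], (100, 1))
        g = imu.estimate_gravity(accel)
        assert g.gm == pytest.approx(9.81, abs=1e-12)
        assert g.ga == pytest.approx(9.81, abs=1e-12)
        assert np.allclose(g.g_vec, [0, 0, 9.81])

    def test_two_point_arithmetic(self):
        g = imu.estimate_gravity(np.array([[0, 0, 9.7], [0, 0, 9.9]]))
        assert g.gm == pytest.approx(9.7)
        assert g.ga == pytest.approx(9.8)

    def test_monte_carlo_average_gravity(self):
        rng = np.random.default_rng(42)
        accel = np.tile([0.0, 0.0, 9.81], (1000, 1)) + rng.normal(0, 0.05, (1000, 3))
        g = imu.estimate_gravity(accel)
        assert abs(g.ga - 9.81) < 0.01

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            imu.estimate_gravity(np.zeros((0, 3)))


class TestRemoveGravity:
    def test_identity_orientation_subtracts_g_vec_exactly(self, rng):
        accel = rng.normal(size=(50, 3))
        g = GravityModel(gm=9.8, ga=9.81, g_vec=np.array([0.1, -0.2, 9.8]))
        q = np.tile(quat.IDENTITY, (50, 1))
        ori = imu.OrientationState(q=q, euler=np.zeros((50, 3)))
        out = imu.remove_gravity(accel, g, ori)
        assert np.allclose(out, accel - g.g_vec, atol=1e-12)

    def test_static_recording_with_exact_orientation_residual_zero(self):
        rec = synthetic.generate_recording(
            synthetic.ActivityScript([(0, 4, "lying")]),
            noise=synthetic.NoiseConfig.silent(), seed=1,
        )
        g = imu.estimate_gravity(rec.accel)
        ori = imu.OrientationState(q=rec.truth_quat, euler=np.zeros((len(rec.accel), 3)))
        out = imu.remove_gravity(rec.accel, g, ori)
        assert np.max(np.linalg.norm(out, axis=1)) < 1e-6

    def test_rotating_body_with_true_orientation(self, rotation_recording):
        rec = rotation_recording
        g = imu.estimate_gravity(rec.accel[:100])
        ori = imu.OrientationState(q=rec.truth_quat, euler=np.zeros((len(rec.accel), 3)))
        out = imu.remove_gravity(rec.accel, g, ori, anchor_index=0)
        # residual is the scripted oscillation, not gravity: during the
        # pure-turn span the turning amplitude bounds the residual
        turning = rec.imu_labels == "turning"
        amp = synthetic.ACTIVITY_DYNAMICS["turning"].amp
        assert np.max(np.linalg.norm(out[turning], axis=1)) < amp * 2.5 + 1e-3 * 9.81

    def test_missing_orientation_rejected(self):
        g = GravityModel(gm=9.8, ga=9.81, g_vec=np.array([0, 0, 9.8]))
        with pytest.raises(ValueError):
            imu.remove_gravity(np.zeros((5, 3)), g, None)


class TestMagneticCorrection:
    REF = np.array([22.0, 5.0, -43.0])

    def test_static_offset_recovered_exactly(self):
        offset = np.array([10.0, -3.0, 2.0])
        mag = np.tile(self.REF + offset, (200, 1))
        out = imu.remove_magnetic_error(mag, self.REF)
        assert np.allclose(out, self.REF, atol=1e-9)

    def test_clean_reference_unchanged(self):
        mag = np.tile(self.REF, (50, 1))
        assert np.allclose(imu.remove_magnetic_error(mag, self.REF), mag, atol=1e-9)

    def test_rotating_body_magnitude_spread_shrinks(self):
        noise = synthetic.NoiseConfig(0.0, 0.0, (0, 0, 0), 0.2, (6.0, -4.0, 3.0), 0.0)
        script = synthetic.ActivityScript([(0, 20, "turning")])
        rec = synthetic.generate_recording(script, noise=noise, seed=9)
        before = np.linalg.norm(rec.mag, axis=1)
        after = np.linalg.norm(imu.remove_magnetic_error(rec.mag, self.REF), axis=1)
        assert after.std() / after.mean() < before.std() / before.mean()

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            imu.remove_magnetic_error(np.ones((10, 3)), np.zeros(3))


class TestDWTDenoise:
    def test_zero_series_stays_zero(self):
        assert np.allclose(imu.dwt_denoise(np.zeros(256), CFG), 0.0)

    def test_smooth_ramp_untouched(self):
        x = np.linspace(0, 1, 512)
        assert np.max(np.abs(imu.dwt_denoise(x, CFG) - x)) < 1e-8

    def test_denoising_reduces_mse_on_noisy_ramp(self):
        rng = np.random.default_rng(7)
        clean = np.linspace(0, 10, 1024)
        noisy = clean + rng.normal(0, 0.5, 1024)
        den = imu.dwt_denoise(noisy, CFG)
        assert np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            imu.dwt_denoise(np.zeros(4), CFG)


class TestOrientationFusion:
    def test_static_fixed_point(self):
        n = 200
        gyro = np.zeros((n, 3))
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        st = imu.fuse_orientation(gyro, accel, None, CFG, q0=quat.IDENTITY)
        assert np.max(np.linalg.norm(st.q - quat.IDENTITY, axis=1)) < 1e-6

    def test_quaternion_norm_preserved_throughout(self, rotation_recording):
        rec = rotation_recording
        cfg = FilterConfig(sample_rate=rec.sample_rate)
        st = imu.fuse_orientation(rec.gyro, rec.accel, rec.mag, cfg)
        assert np.max(np.abs(np.linalg.norm(st.q, axis=1) - 1.0)) < 1e-9

    def test_constant_rate_rotation_integrates_to_90_degrees(self):
        cfg = FilterConfig(sample_rate=500.0, gd_step=0.0)
        n = 500
        gyro = np.tile([0.0, 0.0, np.pi / 2], (n, 1))
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        st = imu.fuse_orientation(gyro, accel, None, cfg, q0=quat.IDENTITY)
        axis, angle = quat.to_axis_angle(st.q[-1])
        assert np.degrees(angle) == pytest.approx(90.0, abs=0.5)
        assert np.allclose(axis, [0, 0, 1], atol=1e-6)

    def test_orientation_recovery_on_scripted_rotation(self, rotation_recording):
        rec = rotation_recording
        cfg = FilterConfig(sample_rate=rec.sample_rate)
        st = imu.fuse_orientation(rec.gyro, rec.accel, rec.mag, cfg)
        start = int(2 * rec.sample_rate)  # after convergence
        errs = [
            np.degrees(quat.angle_between(st.q[i], rec.truth_quat[i]))
            for i in range(start, len(st.q))
        ]
        assert np.mean(errs) < 5.0

    def test_non_unit_q0_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            imu.fuse_orientation(
                np.zeros((10, 3)), np.tile([0, 0, 9.81], (10, 1)), None, CFG,
                q0=np.array([2.0, 0, 0, 0]),
            )

    def test_nan_input_rejected(self):
        gyro = np.zeros((10, 3))
        gyro[3, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            imu.fuse_orientation(gyro, np.tile([0, 0, 9.81], (10, 1)), None, CFG)

    def test_gradient_matches_finite_differences(self, rng):
        """The analytic descent direction of the gravity/field objective
        agrees with central differences."""
        from hld.imu import _grad_correction

        for _ in range(10):
            q = quat.normalize(rng.normal(size=4))
            v_world = quat.normalize(rng.normal(size=3).reshape(1, -1)).ravel()
            v_meas = quat.normalize(rng.normal(size=3).reshape(1, -1)).ravel()
            grad = _grad_correction(q, v_world, v_meas)
            eps = 1e-7
            for k in range(4):
                qp, qm = q.copy(), q.copy()
                qp[k] += eps
                qm[k] -= eps

                def obj(qq):
                    u = quat.rotate_inv(
                        qq / 1.0, v_world
                    )  # un-normalized on purpose: objective is in raw coords
                    w, r = qq[0], qq[1:]
                    u = (w * w - r @ r) * v_world + 2 * (r @ v_world) * r - 2 * w * np.cross(r, v_world)
                    return 0.5 * np.sum((u - v_meas) ** 2)

                num = (obj(qp) - obj(qm)) / (2 * eps)
                assert grad[k] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestEulerAngles:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((1, 1, 1), (np.pi / 4, np.pi / 4, np.pi / 4)),
            ((1, 0, 1), (np.pi / 4, np.pi / 2, 0.0)),
            ((0, 1, 1), (np.pi / 2, np.pi / 4, np.pi / 2)),
        ],
    )
    def test_atan2_identities(self, v, expected):
        got = imu.euler_angles(np.array(v, dtype=float))
        assert np.allclose(got, expected, atol=1e-12)

    def test_scale_invariance(self, rng):
        for _ in range(25):
            v = rng.normal(size=3)
            c = float(rng.uniform(0.1, 100))
            assert np.allclose(
                imu.euler_angles(v), imu.euler_angles(c * v), atol=1e-12
            )

    def test_range_is_half_open_pi_interval(self, rng):
        for _ in range(100):
            ang = imu.euler_angles(rng.normal(size=3))
            assert np.all(ang > -np.pi) and np.all(ang <= np.pi)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            imu.euler_angles(np.zeros(3))


def test_preprocess_motion_full_chain(mixed_recording):
    rec = mixed_recording
    cfg = FilterConfig(sample_rate=rec.sample_rate)
    lying = np.nonzero(rec.imu_labels == "lying")[0]
    # skip the first second: the slerp into the lying pose is not static
    out = imu.preprocess_motion(
        rec.accel, rec.gyro, rec.mag, cfg,
        stationary_slice=slice(lying[0] + 50, lying[-1] + 1),
    )
    assert out["lin_accel"].shape == rec.accel.shape
    assert out["norm"].shape == (len(rec.accel),)
    assert np.max(np.abs(np.linalg.norm(out["orientation"].q, axis=1) - 1)) < 1e-9
    # gravity-free acceleration is small during the stationary span
    assert np.linalg.norm(out["lin_accel"][lying[len(lying) // 2]]) < 1.0
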