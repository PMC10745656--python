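import numpy as np
import pytest

from hld import features_vision as fv
from hld import synthetic, vision


class TestThermalMap:
    def test_identical_frames_zero(self):
        frames = np.tile(np.random.default_rng(0).uniform(0, 255, (8, 8)), (4, 1, 1))
        tm = fv.thermal_map(frames)
        assert np.allclose(tm.heat, 0.0)
        assert tm.summary == 0.0

    def test_single_pixel_change(self):
        frames = np.zeros((2, 16, 16))
        frames[1, 4, 7] = 100.0
        tm = fv.thermal_map(frames)
        assert tm.summary == pytest.approx(np.log(101.0))
        heat = tm.heat.copy()
        heat[4, 7] = 0.0
        assert np.allclose(heat, 0.0)

    def test_walking_hotter_than_standing(self):
        """More scene motion gives a strictly larger thermal summary;
        verified against a brute-force pixel loop."""
        walk = synthetic.generate_recording(
            synthetic.ActivityScript([(0, 5, "walking")]),
            noise=synthetic.NoiseConfig.silent(), seed=4,
        )
        stand = synthetic.generate_recording(
            synthetic.ActivityScript([(0, 5, "standing")]),
            noise=synthetic.NoiseConfig.silent(), seed=4,
        )
        tw = fv.thermal_map(walk.frames[:20])
        ts = fv.thermal_map(stand.frames[:20])
        assert tw.summary > ts.summary
        gray = walk.frames[:20].mean(axis=3)
        brute = np.zeros(gray.shape[1:])
        for i in range(len(gray) - 1):
            for r in range(gray.shape[1]):
                brute[r] += np.abs(gray[i + 1][r] - gray[i][r])
        assert np.allclose(tw.heat, brute, atol=1e-9)

    def test_monotone_in_any_single_difference(self):
        frames = np.zeros((2, 8, 8))
        frames[1, 2, 2] = 10.0
        base = fv.thermal_map(frames).summary
        frames[1, 2, 2] = 20.0
        assert fv.thermal_map(frames).summary > base

    def test_as_printed_ln_mode(self):
        frames = np.zeros((2, 4, 4))
        frames[1, 0, 0] = np.e
        tm = fv.thermal_map(frames, log_mode="as_printed_ln")
        assert tm.summary == pytest.approx(1.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            fv.thermal_map(np.zeros((1, 4, 4)))


class TestGGD:
    @pytest.mark.parametrize("theta", [0.8, 1.0, 2.0, 3.0])
    def test_shape_recovery_within_5_percent(self, theta):
        rng = np.random.default_rng(int(theta * 10))
        x = fv.sample_ggd(theta, 1.7, 100_000, rng)
        fit = fv.fit_ggd(x)
        assert abs(fit.theta - theta) / theta < 0.05

    def test_gaussian_shape_close_to_two(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 3.0, 100_000)
        fit = fv.fit_ggd(x)
        assert 1.9 <= fit.theta <= 2.1
        # Gaussian: std = sigma / sqrt(2)
        assert fit.sigma == pytest.approx(3.0 * np.sqrt(2), rel=0.05)

    def test_laplacian_shape_close_to_one(self):
        rng = np.random.default_rng(22)
        x = rng.laplace(0, 2.0, 100_000)
        fit = fv.fit_ggd(x)
        assert 0.93 <= fit.theta <= 1.07

    def test_scale_equivariance(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=5000)
        a, b = fv.fit_ggd(x), fv.fit_ggd(7.0 * x)
        assert b.theta == pytest.approx(a.theta, abs=1e-9)
        assert b.sigma == pytest.approx(7.0 * a.sigma, rel=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fv.fit_ggd(np.full(100, 3.3))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fv.fit_ggd(np.random.default_rng(0).normal(size=10))


class TestSaliency:
    def test_uniform_frame_constant_salience(self):
        frame = np.full((32, 32), 120.0)
        bank = fv.fit_ggd_bank(frame)
        sal = fv.saliency_map(frame, bank)
        assert np.allclose(sal, 1e-9)

    def test_bright_patch_is_salient(self, rng):
        frame = rng.normal(100.0, 2.0, (48, 48))
        frame[20:30, 20:30] += 80.0
        bank = fv.fit_ggd_bank(frame)
        sal = fv.saliency_map(frame, bank)
        r, c = np.unravel_index(sal.argmax(), sal.shape)
        assert 16 <= r < 34 and 16 <= c < 34  # inside the dilated footprint

    def test_brute_force_neg_log_p(self, rng):
        """Salience equals the sum of per-channel -log P before
        normalization, checked with an explicit per-pixel loop on a
        small frame."""
        frame = rng.normal(50.0, 10.0, (16, 16))
        bank = fv.fit_ggd_bank(frame)
        chans = fv.bandpass_stack(frame)
        raw = np.zeros((16, 16))
        for r in range(16):
            for c in range(16):
                for ch, p in zip(chans, bank):
                    th, sg = p.theta, p.sigma
                    import math

                    from scipy.special import gamma

                    pdf = th / (2 * sg * gamma(1.0 / th)) * math.exp(
                        -abs(ch[r, c] / sg) ** th
                    )
                    raw[r, c] += -math.log(pdf)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(fv.saliency_map(frame, bank), expected, atol=1e-9)

    def test_dc_offset_invariance(self, rng):
        frame = rng.normal(100.0, 15.0, (32, 32))
        bank = fv.fit_ggd_bank(frame)
        assert np.allclose(
            fv.saliency_map(frame, bank), fv.saliency_map(frame + 37.0, bank), atol=1e-8
        )

    def test_unfitted_bank_rejected(self):
        with pytest.raises(ValueError):
            fv.saliency_map(np.zeros((8, 8)), None)


def _skeleton_from_truth(landmarks):
    sk = vision.SkeletonPoints(
        points={c: [] for c in vision.CATEGORIES},
        sides={c: [] for c in vision.CATEGORIES},
        confidence={c: 1.0 for c in vision.CATEGORIES},
    )
    for i, name in enumerate(synthetic.LANDMARKS):
        cat = {
            "head": "head", "torso": "torso", "shoulder": "shoulders",
            "elbow": "elbows", "wrist": "wrists", "knee": "knees",
            "ankle": "ankles",
        }[name.split("_")[0]]
        side = "c" if cat in ("head", "torso") else name[-1]
        sk.points[cat].append(tuple(landmarks[i]))
        sk.sides[cat].append(side)
    return sk


class TestOrientationAngles:
    def test_right_angle(self):
        assert fv.angle_at_vertex((1, 0), (0, 1)) == pytest.approx(np.pi / 2)

    def test_collinear_zero(self):
        assert fv.angle_at_vertex((1, 0), (2, 0)) == pytest.approx(0.0)

    def test_agrees_with_acos_oracle(self, rng):
        for _ in range(50):
            u, v = rng.normal(size=2), rng.normal(size=2)
            got = fv.angle_at_vertex(u, v)
            oracle = np.arccos(
                np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
            )
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_quarter_angle(self):
        got = fv.angle_at_vertex((1, 0), (1, 1))
        assert got == pytest.approx(np.pi / 4, abs=1e-12)

    def test_similarity_invariance(self, rng):
        """Angles unchanged by translation, rotation and uniform scaling
        of the skeleton."""
        base = np.array(
            [synthetic._POSE[n] for n in synthetic.LANDMARKS], dtype=float
        ) * 40.0
        a = fv.orientation_angles(_skeleton_from_truth(base)).angles
        phi, s, t = 0.7, 2.3, np.array([11.0, -4.0])
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = (base @ R.T) * s + t
        b = fv.orientation_angles(_skeleton_from_truth(moved)).angles
        assert np.allclose(a, b, atol=1e-9)
        assert np.all((a >= 0) & (a <= np.pi))

    def test_all_points_missing_gives_empty(self):
        sk = vision.SkeletonPoints(
            points={c: [] for c in vision.CATEGORIES},
            sides={c: [] for c in vision.CATEGORIES},
            confidence={c: 0.0 for c in vision.CATEGORIES},
        )
        d = fv.orientation_angles(sk)
        assert not d.valid.any()
        assert np.allclose(d.vectorized, 0.0)


class TestSLIF:
    def test_spoke_zero_on_first_axis(self):
        d = fv.slif(np.zeros((64, 64)), (32, 32), N=8, M=2, ring_step=3.0)
        assert np.allclose(d.nodes[0, 0], (35.0, 32.0))
        assert np.allclose(d.nodes[1, 0], (38.0, 32.0))

    def test_quarter_turns_for_four_spokes(self):
        d = fv.slif(np.zeros((64, 64)), (30, 30), N=4, M=1, ring_step=5.0)
        offsets = d.nodes[0] - np.array([30.0, 30.0])
        assert np.allclose(offsets, [[5, 0], [0, 5], [-5, 0], [0, -5]], atol=1e-12)

    def test_constant_image_constant_samples(self):
        img = np.full((40, 40), 77.0)
        d = fv.slif(img, (20, 20), N=6, M=3, ring_step=2.0)
        assert np.allclose(d.samples, 77.0)
        assert d.in_frame.all()

    def test_angles_exact_and_rings_monotone(self):
        d = fv.slif(np.zeros((64, 64)), (32, 32), N=5, M=3, ring_step=2.0)
        center = np.array([32.0, 32.0])
        for n in range(5):
            vec = d.nodes[0, n] - center
            assert np.arctan2(vec[1], vec[0]) % (2 * np.pi) == pytest.approx(
                2 * np.pi * n / 5, abs=1e-9
            )
        radii = np.linalg.norm(d.nodes - center, axis=2)
        assert np.all(np.diff(radii, axis=0) > 0)

    def test_out_of_frame_nodes_flagged_zero(self):
        img = np.full((10, 10), 50.0)
        d = fv.slif(img, (1, 1), N=4, M=2, ring_step=3.0)
        assert (~d.in_frame).any()
        assert np.all(d.samples[~d.in_frame] == 0.0)

    def test_vectorized_order_m_outer(self):
        img = np.arange(100.0).reshape(10, 10)
        d = fv.slif(img, (5, 5), N=3, M=2, ring_step=1.0)
        assert np.array_equal(d.vectorized, d.samples.reshape(-1))
        assert len(d.vectorized) == 6

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            fv.slif(np.zeros((8, 8)), (4, 4), N=2, M=1)
        with pytest.raises(ValueError):
            fv.slif(np.zeros((8, 8)), (4, 4), N=4, M=0)
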