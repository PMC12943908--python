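import numpy as np
import pytest

from stridekit.mekf import (
    FilterConfig,
    FilterState,
    detect_zero_crossing,
    kf_predict,
    kf_update,
    run_mekf,
    sign_flip_correct,
    stride_length_from_states,
)


def textbook_kf(z, A, H, Q, R, x0, P0):
    """Independent reference Kalman filter (matrix form, explicit inverse)."""
    x, P = x0.reshape(3, 1), P0.copy()
    xs = []
    for zk in z:
        x = A @ x
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.array([[zk]]) - H @ x)
        P = (np.eye(3) - K @ H) @ P
        xs.append(x.copy())
    return np.hstack(xs).T  # (n, 3)


class TestPredict:
    def test_acceleration_propagates_into_velocity(self):
        cfg = FilterConfig(dt=0.02, Q=np.zeros((3, 3)))
        out = kf_predict(FilterState([0, 0, 1], np.zeros((3, 3))), cfg)
        np.testing.assert_allclose(out.x, [0, 0.02, 1])

    def test_matrix_product_oracle(self):
        cfg = FilterConfig(dt=0.02)
        out = kf_predict(FilterState([1, 2, 3], np.eye(3)), cfg)
        np.testing.assert_allclose(out.x, [1.04, 2.06, 3.0], atol=1e-12)

    def test_zero_fixed_point(self):
        cfg = FilterConfig(Q=np.zeros((3, 3)))
        out = kf_predict(FilterState(np.zeros(3), np.zeros((3, 3))), cfg)
        np.testing.assert_allclose(out.x, 0)
        np.testing.assert_allclose(out.P, 0)

    def test_no_half_dt2_term_by_default(self):
        # displacement is not coupled to acceleration in the printed form
        cfg = FilterConfig(dt=0.1, Q=np.zeros((3, 3)))
        out = kf_predict(FilterState([0, 0, 10], np.zeros((3, 3))), cfg)
        assert out.x[0] == 0.0
        full = FilterConfig(dt=0.1, Q=np.zeros((3, 3)), full_ca_transition=True)
        out2 = kf_predict(FilterState([0, 0, 10], np.zeros((3, 3))), full)
        assert out2.x[0] == pytest.approx(0.05)


class TestUpdate:
    def test_hand_evaluated_gain(self):
        cfg = FilterConfig(R=1.0)
        prior = FilterState(np.zeros(3), np.eye(3))
        post = kf_update(prior, z=2.0, cfg=cfg)
        np.testing.assert_allclose(post.x, [0, 0, 1.0], atol=1e-12)

    def test_zero_noise_limit_forces_a_to_z(self):
        cfg = FilterConfig(R=0.05, boost_factor=1e16)
        prior = FilterState([0, 0, 1.0], np.eye(3))
        post = kf_update(prior, z=5.0, cfg=cfg, boosted=True)
        assert post.x[2] == pytest.approx(5.0, abs=1e-9)

    def test_zero_innovation_keeps_mean(self):
        cfg = FilterConfig(R=0.3)
        prior = FilterState([0.4, -0.2, 1.5], np.eye(3) * 0.2)
        post = kf_update(prior, z=1.5, cfg=cfg)
        np.testing.assert_allclose(post.x, prior.x, atol=1e-14)

    def test_monotone_trust_in_boost_factor(self):
        # larger boost factor pulls the posterior acceleration closer to z
        prior_x, prior_P, z = [0, 0, 1.0], np.eye(3), 4.0
        gaps = []
        for bf in (1.0, 2.0, 10.0, 100.0):
            cfg = FilterConfig(R=0.5, boost_factor=bf)
            post = kf_update(FilterState(prior_x, prior_P), z, cfg, boosted=True)
            gaps.append(abs(post.x[2] - z))
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))


class TestRules:
    @pytest.mark.parametrize(
        "pair,expected",
        [((0.2, -0.1), True), ((0.3, 0.1), False), ((0.0, -0.1), False),
         ((-0.5, 0.5), True), ((0.0, 0.0), False)],
    )
    def test_zero_crossing_rule(self, pair, expected):
        assert detect_zero_crossing(*pair) is expected

    @pytest.mark.parametrize(
        "curr,prev,expected",
        [(-0.3, 0.5, 0.3), (0.3, 0.5, 0.3), (0.0, 0.5, 0.0), (0.4, -0.2, -0.4)],
    )
    def test_sign_flip_rule(self, curr, prev, expected):
        assert sign_flip_correct(curr, prev) == pytest.approx(expected)


class TestRunMekf:
    def test_plain_mode_matches_textbook_oracle(self, rng):
        cfg = FilterConfig(boost_factor=1.0, sign_flip_enabled=False)
        for _ in range(5):
            z = rng.normal(size=1000)
            states = run_mekf(z, cfg)
            ours = np.array([s.x for s in states])
            ref = textbook_kf(
                z, cfg.A, cfg.H, cfg.Q, np.array([[cfg.R]]), cfg.x0, cfg.P0
            )
            assert np.max(np.abs(ours - ref)) < 1e-10

    def test_constant_measurement_convergence(self):
        cfg = FilterConfig(Q=1e-4 * np.eye(3), R=0.01, sign_flip_enabled=False)
        c = 2.5
        states = run_mekf(np.full(600, c), cfg)
        assert abs(states[499].acceleration - c) < 1e-6

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            run_mekf(np.array([1.0]), FilterConfig())

    def test_covariance_stays_symmetric_psd(self, rng):
        cfg = FilterConfig()
        states = run_mekf(rng.normal(size=400), cfg)
        for s in states[::20]:
            assert np.max(np.abs(s.P - s.P.T)) < 1e-12
            assert np.min(np.linalg.eigvalsh(s.P)) > -1e-8

    def test_sign_flip_invariant_on_noisy_runs(self):
        cfg = FilterConfig()
        for seed in range(10):
            r = np.random.default_rng(seed)
            z = r.normal(size=300)
            p = np.array([s.displacement for s in run_mekf(z, cfg)])
            assert np.all(p[:-1] * p[1:] >= 0)

    def test_boost_speeds_reconvergence_after_transient(self):
        # step back to zero after a spike: the boosted filter forgets the
        # spike faster, leaving less spurious area under the a-state
        z = np.concatenate([np.full(5, 3.0), np.full(40, -0.5), np.full(40, 0.5)])
        slow = FilterConfig(boost_factor=1.0, sign_flip_enabled=False)
        fast = FilterConfig(boost_factor=10.0, boost_samples=3, sign_flip_enabled=False)
        a_slow = np.array([s.acceleration for s in run_mekf(z, slow)])
        a_fast = np.array([s.acceleration for s in run_mekf(z, fast)])
        err_slow = np.sum(np.abs(a_slow - z))
        err_fast = np.sum(np.abs(a_fast - z))
        assert err_fast < err_slow


class TestStrideLength:
    def test_endpoint_difference(self):
        P = np.zeros((3, 3))
        states = [FilterState([p, 0, 0], P) for p in np.linspace(0, 1.3, 10)]
        assert stride_length_from_states(states, FilterConfig()) == pytest.approx(1.3)

    def test_constant_trajectory_is_zero(self):
        P = np.zeros((3, 3))
        states = [FilterState([0.4, 0, 0], P)] * 5
        assert stride_length_from_states(states, FilterConfig()) == 0.0

    def test_too_short(self):
        P = np.zeros((3, 3))
        with pytest.raises(ValueError, match="3 states"):
            stride_length_from_states([FilterState([0, 0, 0], P)] * 2, FilterConfig())

    def test_calibration_scales_result(self):
        P = np.zeros((3, 3))
        states = [FilterState([p, 0, 0], P) for p in (0.0, 0.5, 1.0)]
        cfg = FilterConfig(calibration=2.0)
        assert stride_length_from_states(states, cfg) == pytest.approx(2.0)

    def test_noiseless_synthetic_stride_recovered(self):
        from stridekit.synthgait import generate_stride_profile

        z = generate_stride_profile(1.2, 1.0, 0.02)
        cfg = FilterConfig(
            R=1e-4, Q=np.diag([1e-8, 1e-6, 1.0]),
            x0=np.array([0, 0, z[0]]), sign_flip_enabled=False,
        )
        states = run_mekf(z, cfg)
        est = stride_length_from_states(states, cfg)
        assert est == pytest.approx(1.2, abs=0.05)


def test_filter_config_validation():
    with pytest.raises(ValueError, match="boost_factor"):
        FilterConfig(boost_factor=0.5)
    with pytest.raises(ValueError, match="R"):
        FilterConfig(R=0.0)
    with pytest.raises(ValueError, match="positive semi-definite"):
        FilterState([0, 0, 0], -np.eye(3))
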