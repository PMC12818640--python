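import numpy as np
import pytest

from rppgkit.errors import ConfigError
from rppgkit.rakf import (
    DEFAULT_Q_BPM2,
    KalmanState,
    RAKFConfig,
    adaptive_r,
    correct_outlier,
    kalman_gain,
    predict,
    reference_kalman,
    run_filter,
    update,
)


def cfg(**kw):
    return RAKFConfig(**kw)


class TestPredict:
    def test_published_constants(self):
        # random-walk prediction with R0=25, Q=2e-4 exactly as printed
        state = KalmanState(x_hat=70.0, p=25.0)
        x_prior, p_prior = predict(state, cfg(q=2e-4))
        assert (x_prior, p_prior) == (70.0, 25.0002)

    def test_zero_q_keeps_covariance(self):
        state = KalmanState(x_hat=70.0, p=4.0)
        # Q=0 is outside the config's validity; emulate with a tiny Q
        _, p_prior = predict(state, cfg(q=1e-300))
        assert p_prior == pytest.approx(4.0)

    def test_repeated_prediction_grows_p_linearly(self):
        c = cfg(q=0.5)
        p = 1.0
        for k in range(1, 6):
            _, p = predict(KalmanState(x_hat=60.0, p=p), c)
            assert p == pytest.approx(1.0 + 0.5 * k)


class TestAdaptiveR:
    def test_zero_residual_gives_r0(self):
        assert adaptive_r(0.0, cfg(r0=25.0, beta=10.0)) == 25.0

    @pytest.mark.parametrize("res", [10.0, -10.0])
    def test_residual_equal_beta_doubles_r0(self, res):
        assert adaptive_r(res, cfg(r0=25.0, beta=10.0)) == 50.0

    def test_monotone_in_abs_residual(self):
        c = cfg()
        grid = np.linspace(0.0, 50.0, 25)
        vals = [adaptive_r(r, c) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v >= c.r0 for v in vals)


class TestGain:
    def test_symmetric_point(self):
        assert kalman_gain(25.0, 25.0) == 0.5

    def test_vanishing_prior_covariance(self):
        assert kalman_gain(1e-12, 25.0) < 1e-10

    def test_adaptive_r_shrinks_gain(self):
        c = cfg()
        p = 10.0
        k_base = kalman_gain(p, c.r0)
        for res in (5.0, 15.0, 40.0):
            assert kalman_gain(p, adaptive_r(res, c)) < k_base

    def test_larger_residual_smaller_gain(self):
        c = cfg()
        gains = [kalman_gain(10.0, adaptive_r(r, c)) for r in np.linspace(0, 60, 20)]
        assert all(b < a for a, b in zip(gains, gains[1:]))


class TestOutlierCorrection:
    HIST = [70.0, 71.0, 72.0, 71.0, 70.0]

    def test_inlier_unchanged(self):
        z, replaced = correct_outlier(71.0, self.HIST, cfg())
        assert (z, replaced) == (71.0, False)

    def test_spike_replaced_by_median(self):
        # oracle: median 71; robust T_out = max(3*1.4826*MAD, 5) = 5 < |140-71|
        z, replaced = correct_outlier(140.0, self.HIST, cfg())
        assert (z, replaced) == (71.0, True)

    def test_empty_history_passthrough(self):
        z, replaced = correct_outlier(140.0, [], cfg())
        assert (z, replaced) == (140.0, False)

    def test_disabled_gate_passthrough(self):
        z, replaced = correct_outlier(140.0, self.HIST, cfg(handle_outliers=False))
        assert (z, replaced) == (140.0, False)


class TestUpdate:
    def test_zero_weight_keeps_prior(self):
        state = KalmanState(x_hat=70.0, p=25.0)
        c = cfg(use_weighting=True, alpha=1e-9)
        new, tr = update(state, 90.0, 1e-9, c)
        assert new.x_hat == pytest.approx(tr.x_prior, abs=1e-6)

    def test_hand_evaluated_step(self):
        # x_prior=75, P_prior=25.0002, z=80 -> residual 5, R=25*(1+0.5)=37.5,
        # K=25.0002/62.5002~=0.400, x_hat~=77.0, P=(1-K)*P_prior
        state = KalmanState(x_hat=75.0, p=25.0)
        new, tr = update(state, 80.0, 1.0, cfg(r0=25.0, q=2e-4, beta=10.0))
        assert tr.residual == pytest.approx(5.0)
        assert tr.r_adaptive == pytest.approx(37.5)
        assert tr.gain == pytest.approx(25.0002 / 62.5002, abs=1e-9)
        assert new.x_hat == pytest.approx(77.00003, abs=1e-4)
        assert new.p == pytest.approx((1 - tr.gain) * 25.0002, abs=1e-9)

    def test_covariance_contracts_and_stays_positive(self, rng):
        state = KalmanState(x_hat=70.0, p=25.0)
        c = cfg()
        for z in rng.normal(72, 5, 200):
            new, tr = update(state, float(z), 1.0, c)
            assert 0 < new.p <= tr.p_prior
            assert 0 < tr.gain < 1
            assert tr.r_adaptive >= c.r0
            state = new

    def test_matches_textbook_kalman_when_adaptation_off(self, rng):
        zs = rng.normal(70, 4, 300)
        c = cfg(adapt_r=False, use_weighting=False, handle_outliers=False)
        state = KalmanState(x_hat=float(zs[0]), p=c.r0)
        ours = []
        for z in zs[1:]:
            state, _ = update(state, float(z), 1.0, c)
            ours.append(state.x_hat)
        ref = reference_kalman(zs[1:], x0=float(zs[0]), p0=c.r0, q=c.q, r=c.r0)
        assert np.allclose(ours, ref, atol=1e-12)


class TestRunFilter:
    def test_constant_observations_converge(self):
        steps = run_filter([72.0] * 60, config=cfg())
        errs = [abs(s.x_hat - 72.0) for s, _ in steps]
        assert errs[-1] < 1e-9
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_empty_observations(self):
        assert run_filter([], config=cfg()) == []

    def test_variance_reduction_over_many_runs(self):
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            zs = 72.0 + rng.normal(0, 4, 80)
            steps = run_filter(zs, config=cfg())
            post = np.array([s.x_hat for s, _ in steps])
            if post[10:].var() < zs[10:].var():
                wins += 1
        assert wins >= 95

    def test_single_spike_absorbed(self):
        zs = [72.0] * 30
        zs[15] = 130.0  # +58 bpm artifact
        steps = run_filter(zs, config=cfg())
        post = np.array([s.x_hat for s, _ in steps])
        assert np.abs(post - 72.0).max() < 0.2 * 58.0
        assert steps[15][1].outlier_replaced

    def test_filtered_beats_raw_for_stationary_and_ramp(self):
        rng = np.random.default_rng(11)
        for truth in (np.full(120, 72.0), np.linspace(60, 90, 120)):
            zs = truth + rng.normal(0, 4, truth.size)
            steps = run_filter(zs, config=cfg())
            post = np.array([s.x_hat for s, _ in steps])
            assert np.abs(post - truth).mean() < np.abs(zs - truth).mean()

    def test_sq_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            run_filter([70.0, 71.0], sq_per_obs=[0.5], config=cfg())


def test_default_q_is_published_constant_in_bpm_units():
    assert DEFAULT_Q_BPM2 == pytest.approx(2e-4 * 3600.0)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        RAKFConfig(r0=-1.0)
    with pytest.raises(ConfigError):
        RAKFConfig(beta=0.0)
    with pytest.raises(ConfigError):
        RAKFConfig(alpha=1.2)
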