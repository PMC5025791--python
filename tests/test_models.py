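"""Encoding models: channels, feature detectors, fitting, and the
time-reversal integral properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rampasym import models, stimuli, synth
from rampasym.models import (
    ChannelParams,
    DEFAULT_CHANNELS,
    adaptation_dynamics,
    feature_detectors,
    fit_adaptation,
    fit_linear,
    fit_ln,
    fit_multilayer,
    make_channels,
    reversal_integral_oracle,
    train_test_split,
    trajectory_divergence,
    unexplained_variance,
)
from rampasym.stimuli import Quality, RampKind, StimulusSpec, render_envelope

RATE = 31.5


def random_envelope(seed, n=200):
    """Blocky random dB envelope with silent pads (identifiable design)."""
    rng = np.random.default_rng(seed)
    vals = np.zeros(n)
    vals[20:-40] = np.repeat(rng.uniform(40, 90, (n - 60) // 10 + 1), 10)[: n - 60]
    from rampasym.stimuli import StimulusEnvelope

    return StimulusEnvelope(vals, RATE, 20, n - 40, 0.0)


class TestChannels:
    def test_silence_maps_near_zero(self):
        sQ, sL = make_channels(np.zeros(10))
        assert sQ.max() < 1e-4
        assert sL.max() < 1e-4

    def test_saturation_at_loud_levels(self):
        sQ, sL = make_channels(np.full(5, 120.0))
        np.testing.assert_allclose(sQ, 1.0, atol=1e-4)
        np.testing.assert_allclose(sL, 1.0, atol=1e-4)

    @settings(deadline=None, max_examples=30)
    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_monotone_in_level(self, a, b):
        lo, hi = sorted((a, b))
        sQ, sL = make_channels(np.array([lo, hi]))
        assert sQ[0] <= sQ[1] + 1e-12
        assert sL[0] <= sL[1] + 1e-12

    def test_quiet_saturates_before_loud(self):
        sQ, sL = make_channels(np.array([60.0]))
        assert sQ[0] > 0.8
        assert sL[0] < 0.1


class TestFeatureDetectors:
    def test_constant_channels_have_silent_transients(self):
        s = np.full(80, 0.7)
        feats = feature_detectors(s, s, theta=0.0, rate=RATE)
        np.testing.assert_allclose(feats[2:], 0.0)
        np.testing.assert_allclose(feats[0], s)

    def test_rising_channel_silences_off_detectors(self):
        s = np.linspace(0, 1, 80)
        feats = feature_detectors(s, s, theta=0.0, rate=RATE)
        np.testing.assert_allclose(feats[4:], 0.0, atol=1e-12)
        assert feats[2].max() > 0

    def test_large_threshold_collapses_to_tonic_only(self):
        env = render_envelope(
            StimulusSpec(Quality.WHITE_NOISE, RampKind.UP_RAMP, 60, 85, 2.0),
            RATE, 0.3, 0.3,
        )
        sQ, sL = make_channels(env)
        peak_slope = max(
            feature_detectors(sQ, sL, 0.0, RATE)[2:].max(), 1.0
        )
        feats = feature_detectors(sQ, sL, theta=2 * peak_slope, rate=RATE)
        np.testing.assert_allclose(feats[2:], 0.0)


class TestLinearModel:
    def test_recovers_generating_kernel(self):
        rng = np.random.default_rng(0)
        h0 = rng.standard_normal(16) * np.exp(-np.arange(16) / 5)
        envs = [random_envelope(s) for s in range(3)]
        targets = np.stack(
            [np.convolve(e.values, h0)[: e.n_frames] for e in envs]
        )
        m = fit_linear(envs, targets, RATE, kernel_duration=16 / RATE)
        np.testing.assert_allclose(m.kernel, h0, atol=1e-8)
        pred = np.stack([m.predict(e) for e in envs])
        assert np.abs(pred - targets).max() < 1e-8

    def test_orthogonal_target_gives_zero_kernel(self):
        env = random_envelope(1)
        X = models.lagged_design(env.values, 8)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(env.n_frames)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # project out
        m = fit_linear([env], y[None, :], RATE, kernel_duration=8 / RATE)
        np.testing.assert_allclose(m.kernel, 0.0, atol=1e-8)

    def test_fitted_model_reversal_integrals_equal(self, ramp_envs):
        env2 = [e for e in ramp_envs if e.spec.duration == 2.0]
        rng = np.random.default_rng(3)
        h0 = rng.standard_normal(32)
        targets = np.stack([np.convolve(e.values, h0)[: e.n_frames] for e in env2])
        m = fit_linear(env2, targets, RATE)
        assert reversal_integral_oracle(m, env2) <= 1e-10


class TestAdaptation:
    def test_u_zero_is_identity(self):
        env = random_envelope(4)
        s_d = adaptation_dynamics(env.values, 0.0, 0.5, RATE)
        np.testing.assert_allclose(s_d, env.values)

    def test_constant_input_steady_state(self):
        c, u, tau = 0.8, 2.0, 0.5
        s = np.full(2000, c)
        s_d = adaptation_dynamics(s, u, tau, RATE, n_substeps=8)
        d_inf = u * c * tau / (1 + u * c * tau)
        assert s_d[-1] / c == pytest.approx(1 - d_inf, rel=1e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            adaptation_dynamics(np.ones(5), -1.0, 0.5, RATE)
        with pytest.raises(ValueError):
            adaptation_dynamics(np.ones(5), 1.0, 0.0, RATE)

    def test_full_support_integral_reversal_invariant(self, ramp_envs):
        env = next(e for e in ramp_envs if e.spec.duration == 2.0)
        x = DEFAULT_CHANNELS.quiet(env.values)
        _, i_f = adaptation_dynamics(x, 3.0, 0.4, RATE, return_integral=True)
        _, i_r = adaptation_dynamics(x[::-1].copy(), 3.0, 0.4, RATE,
                                     return_integral=True)
        assert abs(i_f - i_r) / (abs(i_f) + abs(i_r)) < 1e-12

    def test_grid_recovery_of_known_parameters(self):
        u_star, tau_star = 2.0, 0.5
        scale = DEFAULT_CHANNELS.quiet  # adaptation acts on channel output
        envs = [random_envelope(s) for s in range(2)]
        rng = np.random.default_rng(5)
        h0 = rng.standard_normal(10)
        targets = np.stack(
            [
                np.convolve(
                    adaptation_dynamics(scale(e.values), u_star, tau_star, RATE),
                    h0,
                )[: e.n_frames]
                for e in envs
            ]
        )
        m, ss = fit_adaptation(
            envs, targets, RATE, u_grid=[0.5, 2.0, 8.0],
            tau_grid=[0.1, 0.5, 2.0], kernel_duration=10 / RATE, scaling=scale,
        )
        assert (m.u, m.tau_a) == (u_star, tau_star)
        assert ss < 1e-12 * np.sum(targets**2)

    def test_linear_target_prefers_weak_adaptation(self):
        scale = DEFAULT_CHANNELS.quiet
        envs = [random_envelope(s) for s in range(2)]
        rng = np.random.default_rng(6)
        h0 = rng.standard_normal(10)
        targets = np.stack(
            [np.convolve(scale(e.values), h0)[: e.n_frames] for e in envs]
        )
        lin = fit_linear(envs, targets, RATE, kernel_duration=10 / RATE,
                         scaling=scale)
        resid_lin = sum(
            np.sum((lin.predict(e) - t) ** 2) for e, t in zip(envs, targets)
        )
        _, ss = fit_adaptation(
            envs, targets, RATE, u_grid=[1e-6, 1.0, 5.0],
            tau_grid=[0.2, 1.0], kernel_duration=10 / RATE, scaling=scale,
        )
        assert ss <= resid_lin + 1e-8 * np.sum(targets**2)

    def test_divergent_integration_raises(self):
        with pytest.raises(FloatingPointError):
            adaptation_dynamics(np.full(50, 90.0), 8.0, 2.0, RATE, n_substeps=1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation([random_envelope(0)], np.zeros((1, 200)), RATE,
                           u_grid=[], tau_grid=[1.0])


class TestLN:
    def test_identity_nonlinearity_reduces_to_linear_stage(self, wn_envs):
        rng = np.random.default_rng(7)
        hq = rng.standard_normal(20) * np.exp(-np.arange(20) / 6)
        hl = rng.standard_normal(20) * np.exp(-np.arange(20) / 6)
        targets = []
        for e in wn_envs[:6]:
            sQ, sL = make_channels(e)
            targets.append(
                np.convolve(sQ, hq)[: e.n_frames] + np.convolve(sL, hl)[: e.n_frames]
            )
        targets = np.stack(targets)
        m = fit_ln(wn_envs[:6], targets, RATE, kernel_duration=20 / RATE)
        pred = np.stack([m.predict(e)[0] for e in wn_envs[:6]])
        uv = unexplained_variance(pred, targets)
        assert uv < 1e-6
        nl = m.nonlinearities[0]
        assert nl.a >= 0 and nl.b >= 0

    def test_recovers_output_kink(self, wn_envs):
        rng = np.random.default_rng(8)
        hq = np.exp(-np.arange(20) / 6.0)
        hl = 0.5 * np.exp(-np.arange(20) / 4.0)
        lin = []
        for e in wn_envs[:8]:
            sQ, sL = make_channels(e)
            lin.append(
                np.convolve(sQ, hq)[: e.n_frames] + np.convolve(sL, hl)[: e.n_frames]
            )
        lin = np.stack(lin)
        x0 = np.median(lin)
        F = models.PiecewiseLinear(a=0.2, b=2.0, c=0.5, x0=x0)
        targets = F(lin)
        m = fit_ln(wn_envs[:8], targets, RATE, kernel_duration=20 / RATE)
        pred = np.stack([m.predict(e)[0] for e in wn_envs[:8]])
        assert unexplained_variance(pred, targets) < 0.01

    def test_identity_output_model_is_reversal_invariant(self, ramp_envs):
        env2 = [e for e in ramp_envs if e.spec.duration == 2.0]
        rng = np.random.default_rng(9)
        m = models.LNModel(
            channels=DEFAULT_CHANNELS,
            kernels_q=rng.standard_normal((1, 32)),
            kernels_l=rng.standard_normal((1, 32)),
            nonlinearities=[models.PiecewiseLinear(1.0, 1.0, 0.0, 0.0)],
            rate=RATE,
        )
        assert reversal_integral_oracle(m, env2) <= 1e-10


class TestMultilayer:
    def test_exact_recovery_of_theta_and_kernels(self, wn_envs):
        gen = synth.archetype_model(rate=RATE)
        targets = np.stack([gen.predict(e) for e in wn_envs], axis=1)[:6]
        m, ss = fit_multilayer(wn_envs, targets, RATE, theta_mode="fit")
        assert m.theta == pytest.approx(synth.GENERATIVE_THETA)
        pred = np.stack([m.predict(e) for e in wn_envs], axis=1)
        assert unexplained_variance(pred, targets) < 1e-6

    def test_nested_train_objective(self, wn_envs, archetype_targets):
        _, ss_fit = fit_multilayer(wn_envs, archetype_targets, RATE,
                                   theta_mode="fit")
        _, ss_zero = fit_multilayer(wn_envs, archetype_targets, RATE,
                                    theta_mode="zero")
        assert ss_fit <= ss_zero + 1e-9

    def test_unknown_theta_mode_rejected(self, wn_envs, archetype_targets):
        with pytest.raises(ValueError):
            fit_multilayer(wn_envs, archetype_targets, RATE, theta_mode="banana")


class TestEvaluation:
    def test_unexplained_variance_bounds(self):
        rng = np.random.default_rng(10)
        t = rng.random(50)
        assert unexplained_variance(t, t) == 0.0
        assert unexplained_variance(np.full(50, t.mean()), t) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            unexplained_variance(t, np.full(50, 2.0))

    def test_train_test_split_counts(self, wn_specs):
        train, test = train_test_split(wn_specs)
        assert (len(train), len(test)) == (12, 11)
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == list(range(23))

    def test_split_membership(self, wn_specs):
        train, test = train_test_split(wn_specs)
        for i in train:
            s = wn_specs[i]
            if s.kind == RampKind.CONSTANT:
                assert s.level_start in (50, 60, 70, 85)
            else:
                assert min(s.level_start, s.level_end) == 50
        for i in test:
            s = wn_specs[i]
            if s.kind == RampKind.CONSTANT:
                assert s.level_start in (55, 65, 80)
            else:
                assert min(s.level_start, s.level_end) == 60


class TestTrajectoryDivergence:
    def test_identical_predictions_have_zero_divergence(self):
        rng = np.random.default_rng(11)
        up = rng.random((13, 40))
        down = up + rng.random((13, 40))
        d_data, d_model = trajectory_divergence(up, down, up, up)
        np.testing.assert_allclose(d_model, 0.0, atol=1e-10)
        assert d_data.max() > 0

    def test_projection_bounded_by_full_distance(self):
        rng = np.random.default_rng(12)
        up = rng.random((13, 40))
        down = rng.random((13, 40))
        d_data, _ = trajectory_divergence(up, down, up, down)
        full = np.linalg.norm(up - down, axis=0)
        assert (d_data <= full + 1e-9).all()
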