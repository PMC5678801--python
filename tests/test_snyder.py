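"""Snyder filter: closed form, general implementation, ODE oracle, MSE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qbnoise import (EventStream, StateTrajectory, build_interrupted,
                     general_filter, general_filter_ode,
                     interrupted_closed_form, mse, sample_photons,
                     simulate_trajectory)
from qbnoise.light_models import MarkovLightModel
from qbnoise.snyder import InterruptedFilterConstants, SnyderDegeneracyError


class TestClosedFormConstants:
    def test_beta_two_values(self):
        c = InterruptedFilterConstants(2.0)
        assert c.A == pytest.approx(1.0)
        assert c.B == pytest.approx(np.sqrt(0.5))
        assert c.C == pytest.approx(0.0)
        assert c.floor == pytest.approx(1.0 - np.sqrt(0.5))

    def test_start_value_is_one(self):
        # A - B tanh(C) = 1 for any beta (the photon-at-zero condition)
        for beta in (0.1, 1.0, 7.3, 500.0):
            c = InterruptedFilterConstants(beta)
            assert c.A - c.B * np.tanh(c.C) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(beta=st.floats(1e-3, 1e3))
    def test_floor_in_unit_half_interval(self, beta):
        c = InterruptedFilterConstants(beta)
        assert 0.0 <= c.floor <= 0.5
        assert abs(c.A - 1.0) <= c.B + 1e-12

    def test_floor_monotone_in_beta(self):
        betas = np.logspace(-3, 3, 200)
        floors = [InterruptedFilterConstants(b).floor for b in betas]
        assert np.all(np.diff(floors) <= 1e-15)

    def test_small_beta_floor_half(self):
        assert InterruptedFilterConstants(1e-8).floor == pytest.approx(0.5,
                                                                       abs=1e-7)


class TestClosedFormFilter:
    def test_jump_to_one_after_every_event(self, interrupted_model,
                                           short_stream):
        _, photons = short_stream
        grid = np.arange(0.0, photons.T + 1, 1.0)
        out = interrupted_closed_form(interrupted_model.beta,
                                      interrupted_model.alpha, photons, grid)
        np.testing.assert_allclose(out.post_event_values(), 1.0, atol=1e-12)

    def test_long_gap_decays_to_floor(self, interrupted_model):
        beta, alpha = interrupted_model.beta, interrupted_model.alpha
        photons = EventStream(np.array([1.0]), 5e4)
        grid = np.arange(0.0, 5e4, 10.0)
        out = interrupted_closed_form(beta, alpha, photons, grid)
        floor = InterruptedFilterConstants(beta).floor
        assert out.x_hat[-1] == pytest.approx(floor, abs=1e-9)

    def test_posterior_normalised(self, interrupted_model, short_stream):
        _, photons = short_stream
        grid = np.arange(0.0, photons.T + 1, 1.0)
        out = interrupted_closed_form(interrupted_model.beta,
                                      interrupted_model.alpha, photons, grid)
        np.testing.assert_allclose(out.posterior.sum(axis=1), 1.0, atol=1e-9)


class TestGeneralFilter:
    def test_matches_closed_form(self, interrupted_model, short_stream):
        _, photons = short_stream
        grid = np.arange(0.0, photons.T + 1, 1.0)
        cf = interrupted_closed_form(interrupted_model.beta,
                                     interrupted_model.alpha, photons, grid)
        gf = general_filter(interrupted_model, photons, grid,
                            assume_event_at_zero=True)
        np.testing.assert_allclose(gf.x_hat, cf.x_hat, atol=1e-6)

    def test_matches_ode_oracle(self, interrupted_model, short_stream):
        _, photons = short_stream
        grid = np.arange(0.0, photons.T + 1, 2.0)
        gf = general_filter(interrupted_model, photons, grid)
        ode = general_filter_ode(interrupted_model, photons, grid)
        np.testing.assert_allclose(gf.x_hat, ode.x_hat, atol=1e-6)

    def test_no_event_limit_is_leading_eigenvector(self, interrupted_model):
        # with zero events the un-normalised flow converges to the
        # dominant eigenvector of R - Lambda; for the interrupted model
        # the mean converges to the closed-form floor A - B
        photons = EventStream(np.empty(0), 1e5)
        grid = np.arange(0.0, 1e5, 50.0)
        out = general_filter(interrupted_model, photons, grid)
        floor = InterruptedFilterConstants(interrupted_model.beta).floor
        assert out.x_hat[-1] == pytest.approx(floor, abs=1e-9)

    def test_single_state_chain(self):
        m = MarkovLightModel(np.array([0.7]), np.zeros((1, 1)), alpha=1.0,
                             k=1.0)
        photons = EventStream(np.array([5.0, 9.0]), 20.0)
        out = general_filter(m, photons, np.arange(0.0, 20.5, 1.0))
        np.testing.assert_allclose(out.posterior, 1.0)
        np.testing.assert_allclose(out.x_hat, 0.7)

    def test_event_with_no_emitting_mass_raises(self):
        # a model whose states all emit at rate zero can never explain
        # an observed event: the Bayes update is 0/0 and must raise
        m = MarkovLightModel(np.array([0.0, 0.0]),
                             np.array([[-0.05, 0.05], [0.05, -0.05]]),
                             alpha=1.0, k=0.05)
        photons = EventStream(np.array([5.0]), 20.0)
        with pytest.raises(SnyderDegeneracyError):
            general_filter(m, photons, np.arange(0.0, 20.5, 1.0))

    def test_posterior_rows_sum_to_one(self, short_stream, interrupted_model):
        _, photons = short_stream
        out = general_filter(interrupted_model, photons,
                             np.arange(0.0, photons.T + 1, 1.0))
        np.testing.assert_allclose(out.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out.x_hat >= 0.0) and np.all(out.x_hat <= 1.0)


class TestMSE:
    def _const_estimate(self, traj, value, dt=1.0):
        from qbnoise.snyder import FilterOutput
        t = np.union1d(np.arange(0.0, traj.T + dt, dt), traj.change_times)
        x = np.full(t.size, value)
        post = np.column_stack([1 - x, x])
        return FilterOutput(t, post, x, np.empty(0), np.array([0.0, 1.0]))

    def test_perfect_estimate_zero_error(self, interrupted_model):
        traj = simulate_trajectory(interrupted_model, 2000.0, seed=41)
        from qbnoise.snyder import FilterOutput
        base = np.arange(0.0, traj.T + 1, 1.0)
        changes = traj.change_times[1:]
        # duplicate rows at the truth's jumps: pre-jump value then
        # post-jump value, like the filters do at event discontinuities
        t = np.sort(np.concatenate([np.setdiff1d(base, changes),
                                    changes, changes]))
        x = traj.values_at(t, interrupted_model.state_values)
        first_dup = np.flatnonzero(np.diff(t) == 0.0)
        x[first_dup] = traj.values_at(t[first_dup] - 1e-9,
                                      interrupted_model.state_values)
        est = FilterOutput(t, np.column_stack([1 - x, x]), x, np.empty(0),
                           np.array([0.0, 1.0]))
        assert mse(traj, est) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_gives_quarter(self, interrupted_model):
        traj = simulate_trajectory(interrupted_model, 1e5, seed=42)
        est = self._const_estimate(traj, 0.5, dt=10.0)
        assert mse(traj, est) == pytest.approx(0.25, abs=1e-6)

    def test_window_mismatch_raises(self, interrupted_model):
        traj = simulate_trajectory(interrupted_model, 100.0, seed=43)
        est = self._const_estimate(traj, 0.5)
        with pytest.raises(ValueError):
            mse(traj, est, t_start=200.0)


class TestMMSEOptimality:
    def test_snyder_beats_constant_estimator(self, interrupted_model):
        traj = simulate_trajectory(interrupted_model, 2e4, seed=51)
        photons = sample_photons(interrupted_model, traj, seed=52)
        grid = np.union1d(np.arange(0.0, traj.T + 1, 1.0), traj.change_times)
        out = general_filter(interrupted_model, photons, grid)
        assert mse(traj, out) < 0.25

    def test_mse_decreases_with_beta(self):
        # average over a few matched reps: higher beta -> lower mse_ph
        k = 0.01
        means = []
        for beta in (2.0, 20.0, 100.0):
            m = build_interrupted(alpha=beta * k, k=k)
            vals = []
            for rep in range(3):
                traj = simulate_trajectory(m, 4e4, seed=100 + rep)
                photons = sample_photons(m, traj, seed=200 + rep)
                grid = np.union1d(np.arange(0.0, traj.T + 1, 2.0),
                                  traj.change_times)
                out = general_filter(m, photons, grid)
                vals.append(mse(traj, out))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestMultiStateFilter:
    def test_bimodal_filter_matches_ode_oracle(self):
        # 8-state bimodal chain: spectral propagation vs direct ODE
        from qbnoise import build_bimodal
        m = build_bimodal(8, (2, 5), k=0.01, epsilon=0.01, alpha=0.5)
        traj = simulate_trajectory(m, 1500.0, seed=91)
        photons = sample_photons(m, traj, seed=92)
        grid = np.arange(0.0, traj.T + 2, 2.0)
        gf = general_filter(m, photons, grid)
        ode = general_filter_ode(m, photons, grid)
        np.testing.assert_allclose(gf.x_hat, ode.x_hat, atol=1e-6)
        np.testing.assert_allclose(gf.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert gf.x_hat.min() >= 0.0 and gf.x_hat.max() <= 1.0
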