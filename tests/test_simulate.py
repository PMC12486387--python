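"""Tests for bolus feeding and the chained fed-batch integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mckm import (
    CultureState,
    FeedEvent,
    FeedSchedule,
    ModelConstants,
    SolverOptions,
    apply_bolus_feed,
    batch_rhs,
    simulate_fedbatch,
)
from mckm.model import VARIABLE_NAMES

from test_model import make_state, make_theta


class TestApplyBolusFeed:
    def test_empty_bolus_changes_nothing(self):
        state = make_state()
        event = FeedEvent(time=72.0, V_feed=0.0, glc_conc=100.0, glu_conc=70.0)
        new_state, V = apply_bolus_feed(state, 0.015, event)
        assert new_state == state
        assert V == 0.015

    def test_equal_volume_mixing(self):
        state = make_state(glc=1.0)
        event = FeedEvent(time=72.0, V_feed=0.010, glc_conc=3.0, glu_conc=0.0)
        new_state, V = apply_bolus_feed(state, 0.010, event)
        assert new_state.glc == pytest.approx(2.0)
        assert V == pytest.approx(0.020)

    def test_mass_conservation_for_every_species(self):
        state = make_state()
        V = 0.0153
        event = FeedEvent(time=72.0, V_feed=0.0007, glc_conc=123.0, glu_conc=45.0)
        new_state, V_new = apply_bolus_feed(state, V, event)
        fed = {"glc": event.glc_conc, "glu": event.glu_conc}
        for name in VARIABLE_NAMES[:-1]:
            before = getattr(state, name) * V + fed.get(name, 0.0) * event.V_feed
            after = getattr(new_state, name) * V_new
            assert after == pytest.approx(before, rel=1e-12)

    def test_mu_est_passes_through_undiluted(self):
        state = make_state(mu_est=0.0123)
        event = FeedEvent(time=72.0, V_feed=0.005, glc_conc=100.0, glu_conc=70.0)
        new_state, _ = apply_bolus_feed(state, 0.015, event)
        assert new_state.mu_est == state.mu_est

    def test_negative_feed_volume_rejected(self):
        with pytest.raises(ValueError):
            FeedEvent(time=72.0, V_feed=-1e-4, glc_conc=0.0, glu_conc=0.0)


class TestFeedSchedule:
    def test_default_has_five_events_after_second_sample(self):
        times = [0, 72, 144, 192, 240, 312, 360]
        schedule = FeedSchedule.default(times)
        assert len(schedule) == 5
        assert list(schedule.times) == [72, 144, 192, 240, 312]

    def test_rejects_non_increasing_times(self):
        events = [
            FeedEvent(72.0, 1e-4, 0, 0),
            FeedEvent(72.0, 1e-4, 0, 0),
        ]
        with pytest.raises(ValueError):
            FeedSchedule(tuple(events))

    def test_csv_and_json_round_trip(self, tmp_path):
        schedule = FeedSchedule.default([0, 72, 144, 192, 240, 312, 360])
        for name in ("feeds.csv", "feeds.json"):
            path = tmp_path / name
            if path.suffix == ".csv":
                schedule.to_csv(path)
                loaded = FeedSchedule.from_csv(path)
            else:
                schedule.to_json(path)
                loaded = FeedSchedule.from_json(path)
            assert loaded == schedule


class TestSimulateFedbatch:
    def test_seven_sample_times_give_six_iterations(self, theta_ref, initial_state, constants):
        times = [0, 72, 144, 192, 240, 312, 360]
        result = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule.default(times), times
        )
        assert len(result.diagnostics) == 6
        assert result.states.shape == (7, 8)

    def test_empty_schedule_matches_single_continuous_integration(
        self, theta_ref, initial_state, constants
    ):
        # span chosen so glucose stays above the switch threshold: the
        # plain reference integration then sees no branch discontinuity
        times = [0.0, 50.0, 110.0, 150.0]
        options = SolverOptions(rtol=1e-9, atol=1e-11)
        result = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule(), times, options
        )
        sol = solve_ivp(
            lambda t, y: batch_rhs(t, y, theta_ref, constants),
            (times[0], times[-1]),
            initial_state.as_array(),
            rtol=1e-9,
            atol=1e-11,
            t_eval=times,
        )
        scale = np.maximum(np.abs(sol.y.T), 1e-3)
        assert np.all(np.abs(result.states - sol.y.T) / scale < 1e-6)

    def test_zero_dynamics_leaves_only_dilution(self, constants):
        theta = make_theta(mu_max=0.0, m_glc=0.0, k_d=0.0)
        times = [0.0, 72.0, 144.0, 192.0, 240.0, 312.0, 360.0]
        schedule = FeedSchedule.default(times)
        initial = make_state(mu_est=0.0)
        result = simulate_fedbatch(theta, initial, constants, schedule, times)
        # between feeds nothing moves: pre-feed state i+1 equals post-feed state i
        for i in range(6):
            assert np.allclose(
                result.states_prefeed[i + 1], result.states[i], rtol=1e-8, atol=1e-10
            )
        # volume increases by exactly the fed volumes
        assert result.volumes[-1] == pytest.approx(constants.V0 + 5 * 0.0005)

    def test_volume_non_decreasing(self, theta_ref, initial_state, constants):
        times = [0, 72, 144, 192, 240, 312, 360]
        result = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule.default(times), times
        )
        assert np.all(np.diff(result.volumes) >= 0)

    def test_chaining_property(self, theta_ref, initial_state, constants):
        # splitting a feed-free span at an interior point reproduces the
        # endpoint of the unsplit integration
        options = SolverOptions(rtol=1e-8, atol=1e-10)
        whole = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule(), [0.0, 200.0], options
        )
        split = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule(), [0.0, 87.0, 200.0], options
        )
        scale = np.maximum(np.abs(whole.states[-1]), 1e-3)
        assert np.all(np.abs(split.states[-1] - whole.states[-1]) / scale < 1e-6)

    def test_glucose_mass_balance_closes(self, theta_ref, initial_state, constants):
        # final mass - initial mass = fed mass - integrated consumption;
        # the consumption integral is computed with an augmented ODE state
        times = [0.0, 72.0, 144.0, 192.0, 240.0, 312.0, 360.0]
        schedule = FeedSchedule.default(times)
        options = SolverOptions(rtol=1e-10, atol=1e-12)
        result = simulate_fedbatch(
            theta_ref, initial_state, constants, schedule, times, options
        )

        consumed = 0.0
        y = initial_state.as_array()
        V = constants.V0
        event0 = schedule.event_at(times[0])
        assert event0 is None
        for i in range(len(times) - 1):
            aug0 = np.concatenate([y, [0.0]])

            def rhs_aug(t, z):
                dy = batch_rhs(t, np.maximum(z[:8], 0.0), theta_ref, constants)
                if z[2] <= 0:
                    dy[2] = 0.0  # exhausted glucose cannot be consumed further
                return np.concatenate([dy, [-dy[2] * V]])

            sol = solve_ivp(
                rhs_aug, (times[i], times[i + 1]), aug0, rtol=1e-10, atol=1e-12
            )
            consumed += sol.y[8, -1]
            y = np.maximum(sol.y[:8, -1], 0.0)
            event = schedule.event_at(times[i + 1])
            if event is not None:
                state, V = apply_bolus_feed(CultureState.from_array(y), V, event)
                y = state.as_array()

        fed = sum(e.V_feed * e.glc_conc for e in schedule)
        initial_mass = initial_state.glc * constants.V0
        final_mass = result.states[-1][2] * result.volumes[-1]
        assert final_mass - initial_mass == pytest.approx(fed - consumed, rel=1e-6, abs=1e-9)

    def test_lactate_monotone_when_production_always_active(self, theta_ref, initial_state):
        constants = ModelConstants(alpha_glc=1e-9)  # production branch everywhere
        times = [0.0, 72.0, 144.0, 192.0, 240.0, 312.0, 360.0]
        result = simulate_fedbatch(
            theta_ref, initial_state, constants, FeedSchedule(), times
        )
        lac = result.dense_states[6]
        assert np.all(np.diff(lac) >= -1e-9)

    def test_biomass_monotone_without_death(self, theta_ref, initial_state, constants):
        # no death and no feed dilution: cell concentration cannot decrease
        theta = theta_ref.replace(k_d=0.0)
        times = [0.0, 72.0, 144.0, 192.0, 240.0]
        result = simulate_fedbatch(theta, initial_state, constants, FeedSchedule(), times)
        xv = result.dense_states[0]
        assert np.all(np.diff(xv) >= -1e-9)

    def test_feed_times_must_coincide_with_samples(self, theta_ref, initial_state, constants):
        schedule = FeedSchedule((FeedEvent(100.0, 1e-4, 50.0, 10.0),))
        with pytest.raises(ValueError):
            simulate_fedbatch(
                theta_ref, initial_state, constants, schedule, [0.0, 72.0, 144.0, 192.0]
            )
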