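"""Simulation tests: media-exchange events, closed-form limits, refinement
stability and trajectory invariants."""

import numpy as np
import pytest

from hsckinetics.model import CultureEnvironment, FiveStateParams, ModelKind, ThreeStateParams
from hsckinetics.simulate import (
    ExchangeSchedule,
    apply_media_exchange,
    default_init_pop,
    simulate,
)


class TestExchange:
    def test_reset_values(self):
        env = CultureEnvironment(scf_conc=3.0, gc_conc=1.0, pool_DiffS=2.0, pool_ProI=0.4)
        fresh = apply_media_exchange(env, ExchangeSchedule())
        assert fresh.scf_conc == 100.0 and fresh.gc_conc == 10.0
        assert all(fresh.pool_amount(p) == 0.0 for p in ("DiffS", "DiffI", "ProS", "ProI"))
        assert fresh.media_volume == env.media_volume

    def test_idempotent_and_fixed_point(self):
        sched = ExchangeSchedule()
        env = CultureEnvironment(scf_conc=3.0, gc_conc=1.0, pool_DiffI=1.0)
        once = apply_media_exchange(env, sched)
        assert apply_media_exchange(once, sched) == once

    def test_event_times(self):
        assert list(ExchangeSchedule(frequency=2, horizon=9).exchange_times()) == [2, 4, 6, 8]
        assert list(ExchangeSchedule(frequency=10, horizon=9).exchange_times()) == []
        assert list(ExchangeSchedule(frequency=3, horizon=9).exchange_times()) == [3, 6, 9]

    def test_pools_kept_when_partial_reset_disabled(self):
        sched = ExchangeSchedule(reset_pools=False)
        env = CultureEnvironment(scf_conc=3.0, pool_DiffS=2.0)
        fresh = apply_media_exchange(env, sched)
        assert fresh.pool_DiffS == 2.0 and fresh.scf_conc == 100.0


class TestSimulate:
    def test_zero_rates_constant_populations(self):
        traj = simulate(ModelKind.three_state, ThreeStateParams(), ExchangeSchedule())
        for s, v0 in zip(traj.states, default_init_pop(ModelKind.three_state)):
            np.testing.assert_allclose(traj.state(s), v0, rtol=0, atol=1e-9)

    def test_pure_exponential_terminal_growth(self):
        """Proliferation-only Terminal compartment follows N0*exp(PR*t)."""
        k = 0.4
        params = FiveStateParams(PR_Term=k)
        init = np.array([0.0, 0.0, 0.0, 0.0, 1000.0])
        traj = simulate(ModelKind.five_state, params, ExchangeSchedule(), init_pop=init,
                        rtol=1e-10, atol=1e-10)
        expected = 1000.0 * np.exp(k * traj.times)
        np.testing.assert_allclose(traj.state("Terminal"), expected, rtol=1e-6)

    def test_post_event_environment_reset(self, traj3_default):
        env = traj3_default.environment
        for t_ev in (2.0, 4.0, 6.0, 8.0):
            row = env.loc[t_ev]
            assert row["scf_conc"] == pytest.approx(100.0)
            assert row["gc_conc"] == pytest.approx(10.0)
            assert row[["pool_DiffS", "pool_DiffI", "pool_ProS", "pool_ProI"]].max() == 0.0

    def test_trajectory_invariants(self, traj3_default):
        t = traj3_default.times
        assert np.all(np.diff(t) > 0)
        assert (traj3_default.populations.to_numpy() >= 0).all()
        assert (traj3_default.environment.to_numpy() >= 0).all()
        # dense 0.05-day grid over 9 days -> at least 181 rows
        assert len(t) >= 181

    def test_refinement_stability(self, three_params, sched_2d):
        """Halving integrator tolerances moves day-9 counts by <0.1%."""
        coarse = simulate(ModelKind.three_state, three_params, sched_2d,
                          rtol=1e-6, atol=1e-6)
        fine = simulate(ModelKind.three_state, three_params, sched_2d,
                        rtol=5e-7, atol=5e-7)
        np.testing.assert_allclose(
            coarse.final().to_numpy(), fine.final().to_numpy(), rtol=1e-3
        )

    def test_invalid_init_pop(self, three_params):
        with pytest.raises(ValueError, match="entries"):
            simulate(ModelKind.three_state, three_params, init_pop=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match=">= 0"):
            simulate(ModelKind.three_state, three_params, init_pop=np.array([-1.0, 0.0, 0.0]))


class TestSample:
    def test_grid_times_exact(self, traj3_default):
        t_grid = traj3_default.times[37]
        got = traj3_default.sample([t_grid])
        for s in traj3_default.states:
            assert got[s].iloc[0] == pytest.approx(traj3_default.populations[s].iloc[37])

    def test_t0_returns_init(self, traj3_default):
        got = traj3_default.sample([0.0])
        np.testing.assert_allclose(
            got.iloc[0].to_numpy(), default_init_pop(ModelKind.three_state)
        )

    def test_midpoint_matches_refined_grid(self, three_params, sched_2d):
        """Interpolated off-grid sample agrees with a rerun whose grid
        contains that time, to 0.1% relative."""
        t_star = 3.537
        base = simulate(ModelKind.three_state, three_params, sched_2d)
        refined = simulate(ModelKind.three_state, three_params, sched_2d,
                           sample_times=[t_star])
        a = base.sample([t_star]).iloc[0].to_numpy()
        b = refined.sample([t_star]).iloc[0].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-3)

    def test_out_of_range_rejected(self, traj3_default):
        with pytest.raises(ValueError, match="within"):
            traj3_default.sample([12.0])


def test_schedule_monotonicity(three_params):
    """More frequent media exchange yields more Terminal cells at day 9."""
    day9 = {}
    for f in (2.0, 5.0, 10.0):
        traj = simulate(ModelKind.three_state, three_params, ExchangeSchedule(frequency=f))
        day9[f] = traj.final()["Terminal"]
    assert day9[2.0] > day9[5.0] > day9[10.0]
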