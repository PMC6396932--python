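"""Calibration tests: the log-residual objective, bounded fitting,
reproducibility and the jump ablation helper."""

import math

import numpy as np
import pandas as pd
import pytest

from hsckinetics.calibrate import (
    LOG_DELTA,
    FitResult,
    ObservedTimeSeries,
    ablate_jump,
    fit,
    loss,
)
from hsckinetics.model import ModelKind
from hsckinetics.simulate import ExchangeSchedule, simulate
from hsckinetics.synthetic import NoiseModel, default_params, generate_observations


@pytest.fixture(scope="module")
def noise_free_obs(three_params, sched_2d):
    return generate_observations(
        ModelKind.three_state, three_params, sched_2d, noise=NoiseModel(kind="none")
    )


class TestLoss:
    def test_self_fit_is_zero(self, three_params, sched_2d, noise_free_obs):
        assert loss(three_params, noise_free_obs, ModelKind.three_state, sched_2d) < 1e-10

    def test_doubling_counts_increases_loss(self, three_params, sched_2d, noise_free_obs):
        doubled = ObservedTimeSeries(mean=noise_free_obs.mean * 2.0)
        assert loss(three_params, doubled, ModelKind.three_state, sched_2d) > loss(
            three_params, noise_free_obs, ModelKind.three_state, sched_2d
        )

    def test_hand_computed_example(self, three_params, sched_2d):
        """Two time points, log residuals summed by hand against the model's
        own sampled counts."""
        times = [1.0, 4.0]
        traj = simulate(ModelKind.three_state, three_params, sched_2d, sample_times=times)
        model = traj.sample(times)
        obs_counts = {"LSK": [1500.0, 700.0], "CMP": [60.0, 30.0],
                      "Terminal": [5000.0, 40000.0]}
        mean = pd.DataFrame(obs_counts, index=pd.Index(times, name="time_day"))
        expected = 0.0
        for s in ("LSK", "CMP", "Terminal"):
            for t in times:
                expected += (
                    math.log(model.loc[t, s] + LOG_DELTA) - math.log(mean.loc[t, s] + LOG_DELTA)
                ) ** 2
        got = loss(three_params, ObservedTimeSeries(mean=mean), ModelKind.three_state,
                   sched_2d, rtol=1e-8)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_state_mismatch_rejected(self, three_params, sched_2d):
        mean = pd.DataFrame({"LSK": [1.0]}, index=pd.Index([1.0], name="time_day"))
        with pytest.raises(ValueError, match="match"):
            loss(three_params, ObservedTimeSeries(mean=mean), ModelKind.three_state, sched_2d)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ObservedTimeSeries(mean=pd.DataFrame({"LSK": []}, index=pd.Index([], name="t")))


class TestFit:
    def test_frozen_fit_returns_init(self, three_params, sched_2d, noise_free_obs):
        res = fit(noise_free_obs, ModelKind.three_state, sched_2d, three_params, free=[])
        assert res.params == three_params
        assert res.loss == pytest.approx(
            loss(three_params, noise_free_obs, ModelKind.three_state, sched_2d)
        )
        assert res.n_iterations == 0 and res.converged

    def test_two_parameter_recovery(self, three_params, sched_2d, noise_free_obs):
        """Perturbed rates are pulled back to the generating values on
        noise-free data."""
        free = ["PR_max_Term", "DR_LSKtoTerm"]
        init = three_params.with_updates(PR_max_Term=0.58 * 1.3, DR_LSKtoTerm=2.6 * 0.7)
        res = fit(noise_free_obs, ModelKind.three_state, sched_2d, init, free, rtol=1e-6)
        for name in free:
            assert res.params.get(name) == pytest.approx(three_params.get(name), rel=0.02)
        assert res.loss < loss(init, noise_free_obs, ModelKind.three_state, sched_2d)

    def test_reproducible_for_fixed_seed(self, three_params, sched_2d, noise_free_obs):
        init = three_params.with_updates(PR_max_Term=0.7)
        kw = dict(free=["PR_max_Term"], n_restarts=2, seed=7, rtol=1e-6)
        a = fit(noise_free_obs, ModelKind.three_state, sched_2d, init, **kw)
        b = fit(noise_free_obs, ModelKind.three_state, sched_2d, init, **kw)
        assert a.params == b.params and a.loss == b.loss
        assert a.start_losses == b.start_losses

    def test_identifiability_guard(self, three_params, sched_2d, noise_free_obs):
        many = three_params.perturbable_names()[:15]
        with pytest.raises(ValueError, match="force"):
            fit(noise_free_obs, ModelKind.three_state, sched_2d, three_params, free=many)

    def test_unknown_parameter_rejected(self, three_params, sched_2d, noise_free_obs):
        with pytest.raises(ValueError, match="unknown"):
            fit(noise_free_obs, ModelKind.three_state, sched_2d, three_params,
                free=["not_a_param"])

    def test_bounds_must_enclose_init(self, three_params, sched_2d, noise_free_obs):
        with pytest.raises(ValueError, match="enclose"):
            fit(noise_free_obs, ModelKind.three_state, sched_2d, three_params,
                free=["PR_max_Term"], bounds={"PR_max_Term": (1.0, 2.0)})


class TestAblation:
    def test_three_state_copy(self, three_params):
        ab = ablate_jump(three_params)
        assert ab.j_max == 0.0
        assert ab.with_updates(j_max=three_params.j_max) == three_params

    def test_five_state_copy(self, five_params):
        ab = ablate_jump(five_params)
        assert ab.j_max_STtoTerm == 0.0 and ab.j_max_MPPtoTerm == 0.0
        assert ab.with_updates(
            j_max_STtoTerm=five_params.j_max_STtoTerm,
            j_max_MPPtoTerm=five_params.j_max_MPPtoTerm,
        ) == five_params

    def test_ablation_shifts_day9_composition(self, three_params, sched_2d, traj3_default):
        """Without the jump, CMPs over-accumulate and Terminal cells are
        under-populated at day 9."""
        ab = simulate(ModelKind.three_state, ablate_jump(three_params), sched_2d)
        assert ab.final()["CMP"] > traj3_default.final()["CMP"]
        assert ab.final()["Terminal"] < traj3_default.final()["Terminal"]
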