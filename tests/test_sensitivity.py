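"""Sensitivity tests: closed-form oracle on an exponential toy model,
matrix/temporal consistency, determinism and export round-trips."""

import numpy as np
import pytest

from hsckinetics.model import FiveStateParams, ModelKind
from hsckinetics.sensitivity import (
    load_matrix_csv,
    local_sensitivity,
    sensitivity_matrix,
)
from hsckinetics.simulate import ExchangeSchedule, simulate


@pytest.fixture(scope="module")
def matrix5(five_params, sched_2d):
    return sensitivity_matrix(ModelKind.five_state, five_params, sched_2d)


def test_exponential_toy_matches_closed_form():
    """For O(t) = N0*exp(k*t), perturbing k by delta gives the analytic
    S_t = (exp(k*t*delta) - 1)/delta ~ k*t; the numerical result agrees
    within 1% for k*t <= 3."""
    k, delta = 0.4, 0.01
    params = FiveStateParams(PR_Term=k)
    init = np.array([0.0, 0.0, 0.0, 0.0, 1000.0])
    eval_times = np.array([1.0, 2.0, 4.0, 7.0])  # k*t up to 2.8
    s, s_t = local_sensitivity(
        ModelKind.five_state, params, ExchangeSchedule(), "PR_Term", "Terminal",
        delta_frac=delta, eval_times=eval_times, init_pop=init, rtol=1e-10,
    )
    analytic = (np.exp(k * eval_times * delta) - 1) / delta
    np.testing.assert_allclose(s_t.to_numpy(), analytic, rtol=0.01)
    assert s == pytest.approx(analytic.mean(), rel=0.01)


def test_initial_count_linearity():
    """A transfer-free exponential compartment scales linearly with its
    seed: +1% initial cells gives +1% output at every time (S = 1)."""
    params = FiveStateParams(PR_Term=0.4)
    sched = ExchangeSchedule()
    base = simulate(ModelKind.five_state, params, sched,
                    init_pop=np.array([0.0, 0, 0, 0, 1000.0]))
    up = simulate(ModelKind.five_state, params, sched,
                  init_pop=np.array([0.0, 0, 0, 0, 1010.0]))
    times = [1.0, 4.0, 9.0]
    s_t = (up.sample(times)["Terminal"] / base.sample(times)["Terminal"] - 1) / 0.01
    np.testing.assert_allclose(s_t.to_numpy(), 1.0, rtol=1e-5)


def test_no_influence_parameter_is_zero(five_params, sched_2d):
    """Proliferation pools feed nothing in the five-state variant (constant
    PR), so their secretion rates carry zero sensitivity."""
    s, s_t = local_sensitivity(
        ModelKind.five_state, five_params, sched_2d, "c_prog_ProS", "Terminal"
    )
    assert s == pytest.approx(0.0, abs=1e-9)


def test_matrix_shape_and_determinism(matrix5, five_params, sched_2d):
    assert matrix5.S.shape[0] == 5
    assert set(matrix5.parameters) == set(five_params.perturbable_names())
    again = sensitivity_matrix(ModelKind.five_state, five_params, sched_2d)
    assert matrix5.S.equals(again.S) and matrix5.mask.equals(again.mask)


def test_matrix_entries_match_paired_recomputation(matrix5, five_params, sched_2d, rng):
    """Three randomly chosen entries recomputed via direct paired
    simulations equal the matrix values exactly."""
    names = list(matrix5.parameters)
    for _ in range(3):
        name = names[rng.integers(len(names))]
        state = ModelKind.five_state.states[rng.integers(5)]
        s, _ = local_sensitivity(ModelKind.five_state, five_params, sched_2d, name, state)
        assert s == matrix5.S.loc[state, name]


def test_temporal_mean_equals_matrix(matrix5):
    for name, table in matrix5.temporal.items():
        np.testing.assert_allclose(
            table.mean(axis=0, skipna=True).reindex(matrix5.S.index).to_numpy(),
            matrix5.S[name].to_numpy(),
            rtol=0, atol=1e-9,
        )


def test_delta_robustness(five_params, sched_2d):
    """Halving the perturbation changes smooth sensitivities by <10%."""
    for name, state in [("PR_Term", "Terminal"), ("f_max_ST", "ST_HSC"),
                        ("DR_LTtoST", "LT_HSC")]:
        s1, _ = local_sensitivity(ModelKind.five_state, five_params, sched_2d, name, state,
                                  delta_frac=0.01)
        s2, _ = local_sensitivity(ModelKind.five_state, five_params, sched_2d, name, state,
                                  delta_frac=0.005)
        assert s2 == pytest.approx(s1, rel=0.10)


def test_zero_baseline_excluded_with_warning(five_params, sched_2d):
    """CMP starts at zero cells; a day-0 evaluation point is dropped from
    the average instead of producing an infinite sensitivity."""
    with pytest.warns(UserWarning, match="excluded"):
        s, s_t = local_sensitivity(
            ModelKind.five_state, five_params, sched_2d, "PR_Term", "CMP",
            eval_times=[0.0, 1.0, 4.0],
        )
    assert np.isnan(s_t.iloc[0]) and np.isfinite(s)


def test_nonperturbable_parameter_rejected(five_params, sched_2d):
    frozen = five_params.with_updates(q_max_MPP=0.0)
    with pytest.raises(ValueError, match="perturbable"):
        local_sensitivity(ModelKind.five_state, frozen, sched_2d, "q_max_MPP", "MPP")


def test_export_roundtrip(matrix5, tmp_path):
    csv = tmp_path / "sense.csv"
    fig = tmp_path / "sense.png"
    from hsckinetics.sensitivity import export_heatmap

    export_heatmap(matrix5, csv, fig)
    assert fig.exists() and fig.stat().st_size > 0
    S, mask = load_matrix_csv(csv)
    order = list(matrix5.S.index)
    np.testing.assert_allclose(
        S.reindex(order)[list(matrix5.S.columns)].to_numpy(), matrix5.S.to_numpy(), rtol=1e-12
    )
    assert int(mask.to_numpy().sum()) == int(matrix5.mask.to_numpy().sum())
    assert (
        mask.reindex(order)[list(matrix5.mask.columns)].to_numpy() == matrix5.mask.to_numpy()
    ).all()
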