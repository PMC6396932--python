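"""Local parameter sensitivity analysis.

For each parameter P and cell state, the model is re-simulated with P
increased by a small fraction (1% by default) and the sensitivity at each
evaluation time is the relative output change divided by the relative
parameter change,

    S_t = [(O'(t) - O(t)) / O(t)] / (dP / P),

with O the state's cell count.  The summary statistic S is the mean of S_t
over the evaluation times (signed by default).  Entries with |S| > 1 — the
output moves by more than 1% for a 1% parameter change — are flagged as
high-impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import KineticParams, ModelKind
from .simulate import DEFAULT_SAMPLE_TIMES, ExchangeSchedule, simulate

__all__ = [
    "SensitivityMatrix",
    "local_sensitivity",
    "sensitivity_matrix",
    "export_heatmap",
    "load_matrix_csv",
]

FLAG_THRESHOLD = 1.0


@dataclass
class SensitivityMatrix:
    """States x parameters matrix of local sensitivities S with its
    high-impact mask (|S| > 1) and the per-time decomposition behind it."""

    S: pd.DataFrame  # index: states, columns: parameter names
    mask: pd.DataFrame  # same shape, boolean
    delta_frac: float
    temporal: dict[str, pd.DataFrame]  # parameter -> (times x states) S_t table

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.S.index)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.S.columns)

    def n_flagged(self) -> pd.Series:
        """Number of high-impact parameters per cell state."""
        return self.mask.sum(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for state in self.states:
            for parameter in self.parameters:
                rows.append(
                    {
                        "state": state,
                        "parameter": parameter,
                        "S": self.S.loc[state, parameter],
                        "flagged": bool(self.mask.loc[state, parameter]),
                    }
                )
        return pd.DataFrame(rows)


def _baseline_counts(kind, params, sched, eval_times, init_pop, rtol) -> pd.DataFrame:
    traj = simulate(kind, params, sched, init_pop=init_pop, sample_times=eval_times, rtol=rtol,
                    atol=rtol)
    return traj.sample(eval_times)


def _sens_table(
    kind: ModelKind,
    params: KineticParams,
    sched: ExchangeSchedule,
    param_name: str,
    delta_frac: float,
    eval_times: np.ndarray,
    init_pop,
    central: bool,
    rtol: float,
    baseline: pd.DataFrame,
    warn_states=None,
) -> pd.DataFrame:
    """S_t for one parameter, all states: (times x states) table.

    Times at which the baseline count is zero are excluded (NaN) with a
    warning rather than treated as infinite sensitivities.
    """
    base_val = params.get(param_name)
    if base_val <= 0:
        raise ValueError(f"parameter {param_name!r} is not perturbable (value {base_val})")
    up = _baseline_counts(
        kind, params.with_updates(**{param_name: base_val * (1 + delta_frac)}),
        sched, eval_times, init_pop, rtol,
    )
    if central:
        down = _baseline_counts(
            kind, params.with_updates(**{param_name: base_val * (1 - delta_frac)}),
            sched, eval_times, init_pop, rtol,
        )
        diff = (up.to_numpy() - down.to_numpy()) / 2.0
    else:
        diff = up.to_numpy() - baseline.to_numpy()
    base = baseline.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        s_t = (diff / base) / delta_frac
    zero = base == 0
    if zero.any():
        watch = list(baseline.columns) if warn_states is None else list(warn_states)
        idx = [baseline.columns.get_loc(s) for s in watch]
        if zero[:, idx].any():
            warnings.warn(
                f"baseline count is zero at {int(zero[:, idx].sum())} evaluation point(s) "
                f"for {param_name!r}; those times are excluded from the sensitivity average",
                stacklevel=3,
            )
        s_t = np.where(zero, np.nan, s_t)
    return pd.DataFrame(s_t, index=baseline.index, columns=baseline.columns)


def local_sensitivity(
    kind: ModelKind,
    params: KineticParams,
    sched: ExchangeSchedule,
    param_name: str,
    state: str,
    delta_frac: float = 0.01,
    eval_times=DEFAULT_SAMPLE_TIMES,
    *,
    init_pop=None,
    central: bool = False,
    absolute_mean: bool = False,
    rtol: float = 1e-8,
) -> tuple[float, pd.Series]:
    """Sensitivity of one state's counts to one parameter.

    Returns ``(S, S_t)`` where ``S_t`` is the per-evaluation-time series and
    ``S`` its mean (signed unless ``absolute_mean``).
    """
    if state not in kind.states:
        raise ValueError(f"unknown state {state!r} for {kind.value}")
    eval_times = np.asarray(eval_times, dtype=float)
    baseline = _baseline_counts(kind, params, sched, eval_times, init_pop, rtol)
    table = _sens_table(
        kind, params, sched, param_name, delta_frac, eval_times, init_pop, central, rtol,
        baseline, warn_states=[state],
    )
    s_t = table[state]
    vals = s_t.dropna()
    s = float(np.abs(vals).mean()) if absolute_mean else float(vals.mean())
    return s, s_t


def sensitivity_matrix(
    kind: ModelKind,
    params: KineticParams,
    sched: ExchangeSchedule,
    delta_frac: float = 0.01,
    eval_times=DEFAULT_SAMPLE_TIMES,
    *,
    parameters=None,
    init_pop=None,
    central: bool = False,
    absolute_mean: bool = False,
    rtol: float = 1e-8,
) -> SensitivityMatrix:
    """One-at-a-time sensitivity of every state to every perturbable
    parameter (one extra simulation per parameter).  Deterministic."""
    eval_times = np.asarray(eval_times, dtype=float)
    if parameters is None:
        parameters = params.perturbable_names()
    baseline = _baseline_counts(kind, params, sched, eval_times, init_pop, rtol)
    temporal: dict[str, pd.DataFrame] = {}
    cols = {}
    for name in parameters:
        table = _sens_table(
            kind, params, sched, name, delta_frac, eval_times, init_pop, central, rtol, baseline
        )
        temporal[name] = table
        if absolute_mean:
            cols[name] = table.abs().mean(axis=0, skipna=True)
        else:
            cols[name] = table.mean(axis=0, skipna=True)
    S = pd.DataFrame(cols).reindex(list(kind.states))
    S.index.name = "state"
    mask = S.abs() > FLAG_THRESHOLD
    return SensitivityMatrix(S=S, mask=mask, delta_frac=delta_frac, temporal=temporal)


def export_heatmap(matrix: SensitivityMatrix, csv_path, fig_path=None):
    """Write the matrix as tidy CSV and, optionally, a heat-map figure with
    the high-impact cells outlined."""
    tidy = matrix.to_tidy()
    tidy.to_csv(csv_path, index=False)
    if fig_path is None:
        return None
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    states = list(matrix.states)
    pars = list(matrix.parameters)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(pars)), 1.0 + 0.5 * len(states)))
    vmax = max(1.0, float(np.nanmax(np.abs(matrix.S.to_numpy()))))
    im = ax.imshow(matrix.S.to_numpy(), cmap="coolwarm", vmin=-vmax, vmax=vmax, aspect="auto")
    for i, state in enumerate(states):
        for jj, parameter in enumerate(pars):
            if matrix.mask.loc[state, parameter]:
                ax.add_patch(
                    plt.Rectangle((jj - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="red", lw=1.5)
                )
    ax.set_xticks(range(len(pars)), pars, rotation=90, fontsize=6)
    ax.set_yticks(range(len(states)), states)
    ax.set_title(f"Local sensitivity S (|S|>{FLAG_THRESHOLD:g} outlined), delta={matrix.delta_frac:g}")
    fig.colorbar(im, ax=ax, label="S")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return fig_path


def load_matrix_csv(csv_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a tidy sensitivity CSV as (S, mask) wide tables."""
    tidy = pd.read_csv(csv_path)
    S = tidy.pivot(index="state", columns="parameter", values="S")
    mask = tidy.pivot(index="state", columns="parameter", values="flagged").astype(bool)
    return S, mask
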