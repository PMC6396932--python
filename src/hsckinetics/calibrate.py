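"""Parameter estimation against observed cell-count time series.

Counts span roughly 1e2 (LSK) to 6e5 (Terminal) cells, so the objective is
a sum of squared *log* residuals, log(model + delta) - log(observed + delta)
with delta = 1 cell: each cell state contributes comparably regardless of
its absolute scale.  Fitting is bounded nonlinear least squares over a
declared subset of parameters, optionally multi-started from seeded
Latin-hypercube draws within the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import KineticParams, ModelKind, ThreeStateParams
from .simulate import ExchangeSchedule, simulate

__all__ = ["ObservedTimeSeries", "FitResult", "loss", "fit", "ablate_jump"]

#: additive offset (cells) inside the log residual
LOG_DELTA = 1.0

#: refusing full-parameter fits: with six time points per state anything
#: beyond this many simultaneously free parameters is unidentifiable
MAX_FREE_DEFAULT = 12


@dataclass
class ObservedTimeSeries:
    """Replicate-summarised cell counts over time.

    ``mean`` holds the replicate-mean count per state (columns) and time
    (index, days); ``sem`` optionally the standard error of the mean with
    the same shape; ``n_rep`` the replicate count behind each summary.
    """

    mean: pd.DataFrame
    sem: pd.DataFrame | None = None
    n_rep: int | None = None

    def __post_init__(self) -> None:
        t = self.times
        if len(t) == 0:
            raise ValueError("observed series must contain at least one time point")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be non-negative and strictly increasing")
        if (self.mean.to_numpy() < 0).any():
            raise ValueError("observed counts must be >= 0")
        if self.sem is not None:
            if list(self.sem.columns) != list(self.mean.columns) or len(self.sem) != len(self.mean):
                raise ValueError("sem table must match the mean table shape")
            if (self.sem.to_numpy() < 0).any():
                raise ValueError("SEM values must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.mean.index, dtype=float)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.mean.columns)

    def check_kind(self, kind: ModelKind) -> None:
        if self.states != kind.states:
            raise ValueError(
                f"observed states {self.states} do not match {kind.value} states {kind.states}"
            )


def _log_residuals(
    params: KineticParams,
    observed: ObservedTimeSeries,
    kind: ModelKind,
    sched: ExchangeSchedule,
    *,
    use_sem: bool = False,
    init_pop=None,
    rtol: float = 1e-7,
) -> pd.DataFrame:
    """Per-(time, state) log residuals, model minus observation."""
    observed.check_kind(kind)
    # coarse dense grid: residuals only ever read the exact sample times
    traj = simulate(
        kind, params, sched, init_pop=init_pop, sample_times=observed.times,
        rtol=rtol, atol=rtol, grid_dt=0.5,
    )
    model = traj.sample(observed.times)
    res = np.log(model.to_numpy() + LOG_DELTA) - np.log(observed.mean.to_numpy() + LOG_DELTA)
    if use_sem and observed.sem is not None:
        # weight by the relative precision of each summary point
        rel = observed.sem.to_numpy() / np.maximum(observed.mean.to_numpy(), LOG_DELTA)
        res = res / np.maximum(rel, 1e-3)
    return pd.DataFrame(res, index=observed.mean.index, columns=observed.mean.columns)


def loss(
    params: KineticParams,
    observed: ObservedTimeSeries,
    kind: ModelKind,
    sched: ExchangeSchedule,
    *,
    use_sem: bool = False,
    init_pop=None,
    rtol: float = 1e-7,
) -> float:
    """Sum of squared log residuals over all states and times."""
    res = _log_residuals(
        params, observed, kind, sched, use_sem=use_sem, init_pop=init_pop, rtol=rtol
    )
    return float((res.to_numpy() ** 2).sum())


@dataclass
class FitResult:
    """Outcome of one bounded least-squares calibration."""

    params: KineticParams
    loss: float
    per_state_loss: dict[str, float]
    converged: bool
    n_iterations: int
    free: tuple[str, ...]
    active_bounds: tuple[str, ...] = ()
    start_losses: tuple[float, ...] = field(default_factory=tuple)


def _default_bounds(init: KineticParams, free) -> dict[str, tuple[float, float]]:
    """Decade-wide box around each free parameter, capped at 1 for the
    fraction maxima."""
    bounds = {}
    for name in free:
        v = init.get(name)
        if v <= 0:
            raise ValueError(f"cannot derive default bounds for zero-valued parameter {name!r}")
        hi = v * 10.0
        if name.startswith(("f_max", "q_max", "j_max")):
            hi = min(hi, 1.0)
        bounds[name] = (v / 10.0, hi)
    return bounds


def fit(
    observed: ObservedTimeSeries,
    kind: ModelKind,
    sched: ExchangeSchedule,
    init_params: KineticParams,
    free: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 1,
    seed: int = 0,
    *,
    use_sem: bool = False,
    init_pop=None,
    rtol: float = 1e-7,
    max_free: int = MAX_FREE_DEFAULT,
    force: bool = False,
) -> FitResult:
    """Fit the declared ``free`` parameter subset to an observed series.

    Runs bounded least squares on the log residuals, starting from
    ``init_params`` plus ``n_restarts - 1`` seeded Latin-hypercube starts
    within the bounds, and returns the best result.  The final loss never
    exceeds the loss at ``init_params``.  Deterministic for fixed seed.
    """
    observed.check_kind(kind)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if len(free) > max_free and not force:
        raise ValueError(
            f"{len(free)} free parameters exceeds the identifiability guard of {max_free} "
            f"for {len(observed.times)} time points; pass force=True to override"
        )
    unknown = [n for n in free if n not in type(init_params).model_fields]
    if unknown:
        raise ValueError(f"unknown parameter names: {unknown}")

    init_loss = loss(
        init_params, observed, kind, sched, use_sem=use_sem, init_pop=init_pop, rtol=rtol
    )
    if not np.isfinite(init_loss):
        raise ValueError("loss at init_params is not finite; validate the parameter set")

    def result_at(params: KineticParams, loss_value: float, converged: bool, nit: int,
                  active=(), starts=()) -> FitResult:
        res = _log_residuals(
            params, observed, kind, sched, use_sem=use_sem, init_pop=init_pop, rtol=rtol
        )
        per_state = {s: float((res[s] ** 2).sum()) for s in res.columns}
        return FitResult(
            params=params,
            loss=loss_value,
            per_state_loss=per_state,
            converged=converged,
            n_iterations=nit,
            free=tuple(free),
            active_bounds=tuple(active),
            start_losses=tuple(starts),
        )

    if not free:
        return result_at(init_params, init_loss, True, 0)

    if bounds is None:
        bounds = _default_bounds(init_params, free)
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    x_init = np.array([init_params.get(n) for n in free])
    if np.any(x_init < lo) or np.any(x_init > hi):
        raise ValueError("bounds must enclose the initial parameter values")

    def residual_vec(x: np.ndarray) -> np.ndarray:
        trial = init_params.with_updates(**dict(zip(free, np.maximum(x, 0.0))))
        try:
            res = _log_residuals(
                trial, observed, kind, sched, use_sem=use_sem, init_pop=init_pop, rtol=rtol
            )
        except Exception:
            return np.full(observed.mean.size, 1e3)
        return res.to_numpy().ravel()

    starts = [x_init]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        # sample in log space so decade-wide boxes are covered evenly
        unit = sampler.random(n_restarts - 1)
        starts.extend(np.exp(np.log(lo) + unit * (np.log(hi) - np.log(lo))))

    best = None
    start_losses = []
    total_nfev = 0
    for x0 in starts:
        sol = least_squares(
            residual_vec, x0, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-10,
        )
        total_nfev += sol.nfev
        start_losses.append(float(sol.cost * 2))
        if best is None or sol.cost < best.cost:
            best = sol

    best_loss = float(2 * best.cost)  # least_squares cost = 0.5 * sum(res^2)
    if best_loss <= init_loss:
        fitted = init_params.with_updates(**dict(zip(free, best.x)))
        active = [
            n for n, x, l, h in zip(free, best.x, lo, hi)
            if np.isclose(x, l, rtol=1e-6) or np.isclose(x, h, rtol=1e-6)
        ]
        return result_at(fitted, best_loss, best.status > 0, total_nfev, active, start_losses)
    # optimizer failed to improve: keep the initial point
    return result_at(init_params, init_loss, False, total_nfev, (), start_losses)


def ablate_jump(params: KineticParams, kind: ModelKind | None = None) -> KineticParams:
    """Copy of ``params`` with every jump-fraction maximum set to zero.

    Removes the direct progenitor-to-Terminal differentiation route while
    leaving all other kinetics untouched.
    """
    if kind is None:
        kind = params.kind
    if kind is ModelKind.three_state:
        assert isinstance(params, ThreeStateParams)
        return params.with_updates(j_max=0.0)
    return params.with_updates(j_max_STtoTerm=0.0, j_max_MPPtoTerm=0.0)
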