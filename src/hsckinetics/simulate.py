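"""Culture simulation: ODE integration with pulsed media-exchange events.

Media exchange is modelled as an instantaneous reset of the environment
between integration segments: SCF and glucose return to their input
concentrations and (by default) the secreted biomolecule pools are emptied,
while populations and media volume are untouched.  Between events the
coupled population/environment ODE system is integrated with an adaptive,
stiff-capable solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .model import (
    ENV_FIELDS,
    CultureEnvironment,
    KineticParams,
    ModelKind,
    ModelStateError,
    compute_kernels,
    rhs,
)

__all__ = ["ExchangeSchedule", "Trajectory", "apply_media_exchange", "simulate", "default_init_pop"]

#: default FACS sampling days (12 h and 2 d added around the day-1 point)
DEFAULT_SAMPLE_TIMES = (0.5, 1.0, 2.0, 4.0, 7.0, 9.0)

#: default seeding: 5000 LSK cells in 300 uL
SEED_CELLS = 5000.0

#: default split of the seed across LT-HSC / ST-HSC / MPP in the five-state
#: model (ST-HSC dominance within the LSK gate)
FIVE_STATE_SEED_SPLIT = (0.10, 0.60, 0.30)


@dataclass(frozen=True)
class ExchangeSchedule:
    """Media-exchange schedule and fresh-media composition.

    ``frequency`` is the exchange period in days (2, 5 and 10 are the
    conditions of interest); a frequency >= horizon means the media is never
    exchanged.  ``reset_pools`` controls whether an exchange also removes the
    cell-secreted biomolecule pools (full media replacement, the default).
    """

    frequency: float = 2.0  # days
    horizon: float = 9.0  # days
    scf_input: float = 100.0  # ng/mL
    gc_input: float = 10.0  # mM
    media_volume: float = 300.0  # uL
    reset_pools: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("exchange frequency must be > 0 days")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0 days")

    def exchange_times(self) -> np.ndarray:
        """Event times {f, 2f, ...} strictly inside (0, horizon]."""
        n = int(np.floor(self.horizon / self.frequency + 1e-12))
        times = self.frequency * np.arange(1, n + 1)
        return times[times <= self.horizon + 1e-12]

    def fresh_environment(self) -> CultureEnvironment:
        return CultureEnvironment(
            scf_conc=self.scf_input,
            gc_conc=self.gc_input,
            media_volume=self.media_volume,
        )


def apply_media_exchange(env: CultureEnvironment, sched: ExchangeSchedule) -> CultureEnvironment:
    """Environment immediately after a media exchange (idempotent)."""
    pools = {f"pool_{p}": (0.0 if sched.reset_pools else env.pool_amount(p)) for p in
             ("DiffS", "DiffI", "ProS", "ProI")}
    return CultureEnvironment(
        scf_conc=sched.scf_input,
        gc_conc=sched.gc_input,
        media_volume=env.media_volume,
        **pools,
    )


def default_init_pop(kind: ModelKind, seed_cells: float = SEED_CELLS) -> np.ndarray:
    """Seeding populations: all cells start in the LSK gate.

    For the five-state model the LSK seed is split across LT-HSC, ST-HSC and
    MPP using :data:`FIVE_STATE_SEED_SPLIT`.
    """
    if kind is ModelKind.three_state:
        return np.array([seed_cells, 0.0, 0.0])
    lt, st, mpp = (frac * seed_cells for frac in FIVE_STATE_SEED_SPLIT)
    return np.array([lt, st, mpp, 0.0, 0.0])


@dataclass
class Trajectory:
    """Sampled solution of one culture simulation.

    ``populations`` has one column per cell state (cells); ``environment``
    one column per environment component; ``kernels`` the derived feedback
    quantities (f, q, j, PR, death rates, ratios) along the same time grid.
    """

    kind: ModelKind
    times: np.ndarray  # days, strictly increasing
    populations: pd.DataFrame  # index times, columns states
    environment: pd.DataFrame  # index times, columns ENV_FIELDS
    kernels: pd.DataFrame  # index times, kernel columns
    schedule: ExchangeSchedule
    params: KineticParams = field(repr=False, default=None)

    @property
    def states(self) -> tuple[str, ...]:
        return self.kind.states

    def state(self, name: str) -> np.ndarray:
        return self.populations[name].to_numpy()

    def final(self) -> pd.Series:
        return self.populations.iloc[-1]

    def sample(self, times) -> pd.DataFrame:
        """Populations at arbitrary times via shape-preserving (monotone
        cubic) interpolation on the dense grid; exact at grid points."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        t0, t1 = self.times[0], self.times[-1]
        if np.any(times < t0 - 1e-9) or np.any(times > t1 + 1e-9):
            raise ValueError(f"sample times must lie within [{t0}, {t1}] days")
        times = np.clip(times, t0, t1)
        out = {}
        for s in self.states:
            interp = PchipInterpolator(self.times, self.populations[s].to_numpy())
            out[s] = np.maximum(interp(times), 0.0)
        return pd.DataFrame(out, index=pd.Index(times, name="time_day"))

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (time, state), with environment
        columns repeated."""
        rows = []
        env = self.environment.reset_index(drop=True)
        for i, t in enumerate(self.times):
            for s in self.states:
                row = {"time_day": t, "state": s, "count": self.populations[s].iloc[i]}
                row.update({k: env[k].iloc[i] for k in ENV_FIELDS})
                rows.append(row)
        return pd.DataFrame(rows)


def _segment_edges(sched: ExchangeSchedule) -> list[tuple[float, float]]:
    events = [t for t in sched.exchange_times() if t < sched.horizon - 1e-12]
    edges = [0.0, *events, sched.horizon]
    return list(zip(edges[:-1], edges[1:]))


def simulate(
    kind: ModelKind,
    params: KineticParams,
    sched: ExchangeSchedule | None = None,
    init_pop: np.ndarray | None = None,
    *,
    grid_dt: float = 0.05,
    sample_times=None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the culture model over the schedule horizon.

    The system is integrated piecewise between media-exchange events, with
    the exchange applied instantaneously at each event time.  The returned
    grid combines a uniform ``grid_dt`` spacing with all event times and any
    requested ``sample_times``.  Deterministic for fixed inputs.
    """
    if sched is None:
        sched = ExchangeSchedule()
    if init_pop is None:
        init_pop = default_init_pop(kind)
    init_pop = np.asarray(init_pop, dtype=float)
    if init_pop.shape != (kind.n_states,):
        raise ValueError(f"init_pop must have {kind.n_states} entries for {kind.value}")
    if np.any(init_pop < 0):
        raise ValueError("initial populations must be >= 0")

    n_pop = kind.n_states
    volume = sched.media_volume

    def flat_rhs(t: float, y: np.ndarray) -> np.ndarray:
        pop = y[:n_pop]
        env = CultureEnvironment.from_vector(y[n_pop:], media_volume=volume)
        d_pop, d_env = rhs(kind, t, pop, env, params)
        # halt decay of exhausted populations so the floor is invariant
        d_pop = np.where((y[:n_pop] <= 0.0) & (d_pop < 0.0), 0.0, d_pop)
        return np.concatenate([d_pop, d_env])

    base_grid = np.arange(0.0, sched.horizon + grid_dt / 2, grid_dt)
    extra = np.asarray(sample_times, dtype=float) if sample_times is not None else np.array([])
    full_grid = np.unique(
        np.round(np.concatenate([base_grid, sched.exchange_times(), extra, [sched.horizon]]), 9)
    )
    full_grid = full_grid[(full_grid >= 0) & (full_grid <= sched.horizon + 1e-12)]

    env = sched.fresh_environment()
    y = np.concatenate([init_pop, env.as_vector()])

    times_out: list[float] = []
    y_out: list[np.ndarray] = []

    for t_start, t_end in _segment_edges(sched):
        t_eval = full_grid[(full_grid >= t_start - 1e-12) & (full_grid <= t_end + 1e-12)]
        if len(t_eval) == 0 or abs(t_eval[0] - t_start) > 1e-12:
            t_eval = np.concatenate([[t_start], t_eval])
        if abs(t_eval[-1] - t_end) > 1e-12:
            t_eval = np.concatenate([t_eval, [t_end]])
        sol = solve_ivp(
            flat_rhs,
            (t_start, t_end),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ModelStateError(
                f"integration failed in segment [{t_start}, {t_end}] d: {sol.message}"
            )
        seg_y = np.maximum(sol.y, 0.0)
        start = 1 if times_out else 0  # avoid duplicating the segment edge
        times_out.extend(sol.t[start:])
        y_out.extend(seg_y.T[start:])
        # event at segment end (unless this is the horizon); the stored row
        # at the event time carries the post-exchange environment
        y = np.maximum(sol.y[:, -1], 0.0)
        if t_end < sched.horizon - 1e-12:
            env_now = CultureEnvironment.from_vector(y[n_pop:], media_volume=volume)
            env_new = apply_media_exchange(env_now, sched)
            y = np.concatenate([y[:n_pop], env_new.as_vector()])
            y_out[-1] = y.copy()

    times = np.asarray(times_out)
    ys = np.asarray(y_out)
    pops = pd.DataFrame(ys[:, :n_pop], columns=list(kind.states))
    envs = pd.DataFrame(ys[:, n_pop:], columns=list(ENV_FIELDS))
    kernel_rows = []
    for i, t in enumerate(times):
        env_i = CultureEnvironment.from_vector(ys[i, n_pop:], media_volume=volume)
        kernel_rows.append(compute_kernels(kind, ys[i, :n_pop], env_i, params).flat())
    kernels = pd.DataFrame(kernel_rows)
    for df in (pops, envs, kernels):
        df.index = pd.Index(times, name="time_day")
    return Trajectory(
        kind=kind,
        times=times,
        populations=pops,
        environment=envs,
        kernels=kernels,
        schedule=sched,
        params=params,
    )
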