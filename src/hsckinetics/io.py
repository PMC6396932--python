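"""Readers and writers: parameter/config YAML and tidy time-series CSV.

The on-disk observed-series format is a long ("tidy") CSV with columns
``time_day, state, count[, sem, n_rep]`` — one row per time x state.  The
parameter format is a YAML document with the model variant tag and all
kinetic parameter fields by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .calibrate import ObservedTimeSeries
from .model import KineticParams, ModelKind, params_class
from .simulate import DEFAULT_SAMPLE_TIMES, ExchangeSchedule

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_params",
    "write_params",
    "params_to_dict",
    "params_from_dict",
    "RunConfig",
    "read_config",
]


# ---------------------------------------------------------------------------
# Observed time series
# ---------------------------------------------------------------------------

_VALID_STATE_SETS = {
    ModelKind.three_state: set(ModelKind.three_state.states),
    ModelKind.five_state: set(ModelKind.five_state.states),
}


def write_timeseries(series: ObservedTimeSeries, path) -> None:
    """Write an observed series as tidy CSV (time_day, state, count[, sem, n_rep])."""
    rows = []
    for t in series.mean.index:
        for state in series.mean.columns:
            row = {"time_day": float(t), "state": state, "count": float(series.mean.loc[t, state])}
            if series.sem is not None:
                row["sem"] = float(series.sem.loc[t, state])
            if series.n_rep is not None:
                row["n_rep"] = int(series.n_rep)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timeseries(path, kind: ModelKind | None = None) -> ObservedTimeSeries:
    """Read a tidy time-series CSV, validating states and counts.

    If ``kind`` is given, the file's state set must match that variant
    exactly; otherwise it must match one of the two supported variants.
    """
    df = pd.read_csv(path)
    required = {"time_day", "state", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = df[~np.isfinite(df["count"]) | (df["count"] < 0)]
    if len(bad):
        line = int(bad.index[0]) + 2  # 1-based, plus header
        raise ValueError(f"{path}: invalid count {bad['count'].iloc[0]!r} at line {line}")

    states_in_file = set(df["state"].unique())
    if kind is not None:
        if states_in_file != _VALID_STATE_SETS[kind]:
            raise ValueError(
                f"{path}: state set {sorted(states_in_file)} does not match "
                f"{kind.value} states {sorted(_VALID_STATE_SETS[kind])}"
            )
        order = list(kind.states)
    else:
        for k, valid in _VALID_STATE_SETS.items():
            if states_in_file == valid:
                order = list(k.states)
                break
        else:
            raise ValueError(f"{path}: unrecognised state set {sorted(states_in_file)}")

    mean = df.pivot(index="time_day", columns="state", values="count")[order].sort_index()
    mean.columns.name = None
    sem = None
    if "sem" in df.columns and df["sem"].notna().all():
        sem = df.pivot(index="time_day", columns="state", values="sem")[order].sort_index()
        sem.columns.name = None
    n_rep = int(df["n_rep"].iloc[0]) if "n_rep" in df.columns and df["n_rep"].notna().all() else None
    return ObservedTimeSeries(mean=mean, sem=sem, n_rep=n_rep)


# ---------------------------------------------------------------------------
# Parameter YAML
# ---------------------------------------------------------------------------


def params_to_dict(params: KineticParams) -> dict:
    return {"kind": params.kind.value, "params": params.model_dump()}


def params_from_dict(doc: dict) -> KineticParams:
    if "kind" not in doc or "params" not in doc:
        raise ValueError("parameter document must contain 'kind' and 'params'")
    kind = ModelKind(doc["kind"])
    return params_class(kind)(**doc["params"])


def write_params(params: KineticParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def read_params(path) -> KineticParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Single configuration document driving the pipeline commands."""

    model_config = ConfigDict(extra="forbid")

    kind: ModelKind = ModelKind.three_state
    params_file: str | None = None  # path, relative to the config file
    params: dict | None = None  # or inline field values
    frequency: float = 2.0
    horizon: float = 9.0
    scf_input: float = 100.0
    gc_input: float = 10.0
    media_volume: float = 300.0
    init_pop: list[float] | None = None
    sample_times: list[float] = Field(default_factory=lambda: list(DEFAULT_SAMPLE_TIMES))
    seed: int = 0
    log_level: str = "INFO"

    def schedule(self) -> ExchangeSchedule:
        return ExchangeSchedule(
            frequency=self.frequency,
            horizon=self.horizon,
            scf_input=self.scf_input,
            gc_input=self.gc_input,
            media_volume=self.media_volume,
        )

    def kinetic_params(self, base_dir: Path | None = None) -> KineticParams:
        if self.params_file is not None:
            p = Path(self.params_file)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            params = read_params(p)
            if params.kind is not self.kind:
                raise ValueError(
                    f"params file is for {params.kind.value}, config requests {self.kind.value}"
                )
            return params
        if self.params is not None:
            return params_class(self.kind)(**self.params)
        from .synthetic import default_params

        return default_params(self.kind)

    def initial_populations(self) -> np.ndarray:
        from .simulate import default_init_pop

        if self.init_pop is None:
            return default_init_pop(self.kind)
        arr = np.asarray(self.init_pop, dtype=float)
        if arr.shape != (self.kind.n_states,):
            raise ValueError(
                f"init_pop must list {self.kind.n_states} values for {self.kind.value}"
            )
        return arr


def read_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return RunConfig(**doc)


def write_run_metadata(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON sidecar recording how an output file was produced."""
    from . import __version__

    doc = {"version": __version__, "config": json.loads(config.model_dump_json())}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def trajectory_to_csv(traj, path) -> None:
    traj.to_tidy().to_csv(path, index=False)
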