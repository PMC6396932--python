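"""Domain types and rate-law kernels for the hematopoietic differentiation models.

The package models an in-vitro liquid culture of murine hematopoietic
progenitors as a small hierarchy of well-mixed cell compartments coupled to a
shared culture environment.  Two hierarchy variants are supported:

* **three-state** — LSK (early progenitors), CMP (common myeloid
  progenitors), Terminal (all mature cells);
* **five-state** — the LSK compartment resolved into LT-HSC, ST-HSC and MPP,
  followed by CMP and Terminal.

Cell behaviour (proliferation, self-renewal, quiescence, apoptosis, direct
"jump" differentiation into the Terminal state) is driven by feedback from
the environment: the exogenous cytokine SCF, a nutrient stock (glucose, GC),
and four pooled groups of cell-secreted biomolecules — differentiation
stimulators/inhibitors (DiffS/DiffI) and proliferation stimulators/inhibitors
(ProS/ProI).  The ratios R_d = DiffS/DiffI and R_p = ProS/ProI enter the
kernels below.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "ModelKind",
    "CultureEnvironment",
    "KineticParams",
    "ThreeStateParams",
    "FiveStateParams",
    "KernelValues",
    "POOLS",
    "EPS_POOL",
    "compute_ratios",
    "secretion_rate",
    "death_rate",
    "self_renewal_fraction",
    "proliferation_rate",
    "quiescent_fraction",
    "jump_fraction",
    "compute_kernels",
    "rhs_3state",
    "rhs_5state",
    "rhs",
    "ModelStateError",
]

#: Secreted biomolecule pools, in the fixed storage order used everywhere.
POOLS = ("DiffS", "DiffI", "ProS", "ProI")

#: Floor (ng) applied to inhibitor pool amounts when forming the
#: stimulator/inhibitor ratios, so that the ratios are defined at the empty
#: start state.  A zero numerator always yields a zero ratio.
EPS_POOL = 1e-9


class ModelStateError(RuntimeError):
    """Raised when a population or environment component becomes invalid
    (NaN) during right-hand-side evaluation; names the offending component."""


class ModelKind(str, enum.Enum):
    """Which hierarchy variant is being simulated."""

    three_state = "three_state"
    five_state = "five_state"

    @property
    def states(self) -> tuple[str, ...]:
        if self is ModelKind.three_state:
            return ("LSK", "CMP", "Terminal")
        return ("LT_HSC", "ST_HSC", "MPP", "CMP", "Terminal")

    @property
    def n_states(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# Culture environment
# ---------------------------------------------------------------------------

#: order of environment components in the flat ODE state vector
ENV_FIELDS = ("scf_conc", "gc_conc", "pool_DiffS", "pool_DiffI", "pool_ProS", "pool_ProI")


@dataclass
class CultureEnvironment:
    """State of the culture medium in one well.

    SCF and glucose are tracked as concentrations (ng/mL and mM); secreted
    biomolecule pools are tracked as amounts (ng) in the well.  The media
    volume is constant over a simulation; pool concentrations used by the
    feedback kernels are amount / volume.
    """

    scf_conc: float = 100.0  # ng/mL
    gc_conc: float = 10.0  # mM
    media_volume: float = 300.0  # uL, constant
    pool_DiffS: float = 0.0  # ng
    pool_DiffI: float = 0.0  # ng
    pool_ProS: float = 0.0  # ng
    pool_ProI: float = 0.0  # ng

    def __post_init__(self) -> None:
        for name in ("scf_conc", "gc_conc", "media_volume", *(f"pool_{p}" for p in POOLS)):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"CultureEnvironment.{name} must be finite and >= 0, got {v}")

    @property
    def volume_mL(self) -> float:
        return self.media_volume / 1000.0

    def pool_amount(self, pool: str) -> float:
        return getattr(self, f"pool_{pool}")

    def pool_conc(self, pool: str) -> float:
        """Concentration (ng/mL) of a secreted pool."""
        return self.pool_amount(pool) / self.volume_mL

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in ENV_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, media_volume: float = 300.0) -> "CultureEnvironment":
        vec = np.maximum(np.asarray(vec, dtype=float), 0.0)
        kw = dict(zip(ENV_FIELDS, vec))
        return cls(media_volume=media_volume, **kw)


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------

_NonNeg = Field(default=0.0, ge=0)
_Frac = Field(default=0.0, ge=0, le=1)


class KineticParams(BaseModel):
    """Base class for the full parameter set of one model variant.

    All rates and constants are non-negative; fraction maxima (f_max, q_max,
    j_max) are bounded by 1.  Parameters are accessed by their flat field
    name in calibration and sensitivity analysis.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # environment consumption (shared by both variants)
    K_SCF_consumption: float = _NonNeg  # ng/cell/day
    K_GC_consumption: float = _NonNeg  # mM/cell/day (volume folded in)

    # reference scales that nondimensionalize the exponential feedback
    # arguments; fixed at 1 in the stated units and absorbed into the fitted
    # feedback constants, so they are not perturbable parameters.
    c_hat: float = Field(default=1.0, gt=0)  # ng/mL, pool concentration scale
    s_hat: float = Field(default=1.0, gt=0)  # ng/mL, SCF*R_p scale
    t_hat: float = Field(default=1.0, gt=0)  # scale of the T_d feedback signal

    # model switches (not perturbable)
    td_mode: Literal["terminal_product", "diffs_pool"] = "terminal_product"
    quiescence_gates_death: bool = False

    _NON_PERTURBABLE = frozenset({"c_hat", "s_hat", "t_hat", "td_mode", "quiescence_gates_death"})

    @property
    def kind(self) -> ModelKind:
        raise NotImplementedError

    def perturbable_names(self) -> list[str]:
        """Names of parameters eligible for perturbation/fitting: numeric
        fields with a strictly positive current value."""
        out = []
        for name in type(self).model_fields:
            if name in self._NON_PERTURBABLE:
                continue
            v = getattr(self, name)
            if isinstance(v, (int, float)) and v > 0:
                out.append(name)
        return out

    def with_updates(self, **updates: float) -> "KineticParams":
        """Validated copy with the given fields replaced."""
        return type(self)(**{**self.model_dump(), **updates})

    def get(self, name: str) -> float:
        return float(getattr(self, name))


class ThreeStateParams(KineticParams):
    """Parameters of the LSK / CMP / Terminal model.

    In this variant proliferation saturates with the SCF x R_p signal and
    secretion rates decay exponentially with the accumulated pool
    concentration (negative feedback on secretion).
    """

    # proliferation maxima (1/day)
    PR_max_LSK: float = _NonNeg
    PR_max_CMP: float = _NonNeg
    PR_max_Term: float = _NonNeg
    # apoptosis law: DR_max / (1 + d * [GC])
    DR_max_LSK: float = _NonNeg
    DR_max_CMP: float = _NonNeg
    DR_max_Term: float = _NonNeg
    d_LSK: float = _NonNeg  # 1/mM
    d_CMP: float = _NonNeg
    d_Term: float = _NonNeg
    # self-renewal: f_max / (1 + R_d + s * [SCF])
    f_max_LSK: float = _Frac
    f_max_CMP: float = _Frac
    s_LSK: float = _NonNeg  # mL/ng
    s_CMP: float = _NonNeg
    # quiescence (LSK only) and jump (LSK -> Terminal)
    q_max: float = _Frac
    j_max: float = _Frac
    # stepwise differentiation constants (1/day)
    DR_LSKtoCMP: float = _NonNeg
    DR_LSKtoTerm: float = _NonNeg
    DR_CMPtoTerm: float = _NonNeg
    # base secretion rates m (ng/cell/day): cell group x pool
    m_prog_DiffS: float = _NonNeg
    m_prog_DiffI: float = _NonNeg
    m_prog_ProS: float = _NonNeg
    m_prog_ProI: float = _NonNeg
    m_term_DiffS: float = _NonNeg  # == c3, drives the T_d jump feedback
    m_term_DiffI: float = _NonNeg
    m_term_ProS: float = _NonNeg
    m_term_ProI: float = _NonNeg

    @property
    def kind(self) -> ModelKind:
        return ModelKind.three_state


class FiveStateParams(KineticParams):
    """Parameters of the LT-HSC / ST-HSC / MPP / CMP / Terminal model.

    Differences from the three-state variant: proliferation rates and
    secretion rates are constants (no environmental feedback on them), two
    jump fractions (ST-HSC and MPP directly to Terminal), and three
    quiescent fractions (LT-HSC, ST-HSC, MPP).
    """

    # constant proliferation rates (1/day)
    PR_LT: float = _NonNeg
    PR_ST: float = _NonNeg
    PR_MPP: float = _NonNeg
    PR_CMP: float = _NonNeg
    PR_Term: float = _NonNeg
    # apoptosis law
    DR_max_LT: float = _NonNeg
    DR_max_ST: float = _NonNeg
    DR_max_MPP: float = _NonNeg
    DR_max_CMP: float = _NonNeg
    DR_max_Term: float = _NonNeg
    d_LT: float = _NonNeg
    d_ST: float = _NonNeg
    d_MPP: float = _NonNeg
    d_CMP: float = _NonNeg
    d_Term: float = _NonNeg
    # self-renewal on all progenitor states
    f_max_LT: float = _Frac
    f_max_ST: float = _Frac
    f_max_MPP: float = _Frac
    f_max_CMP: float = _Frac
    s_LT: float = _NonNeg
    s_ST: float = _NonNeg
    s_MPP: float = _NonNeg
    s_CMP: float = _NonNeg
    # quiescence on the three stem/multipotent states
    q_max_LT: float = _Frac
    q_max_ST: float = _Frac
    q_max_MPP: float = _Frac
    # jump fractions
    j_max_STtoTerm: float = _Frac
    j_max_MPPtoTerm: float = _Frac
    # stepwise + jump differentiation constants (1/day)
    DR_LTtoST: float = _NonNeg
    DR_STtoMPP: float = _NonNeg
    DR_MPPtoCMP: float = _NonNeg
    DR_CMPtoTerm: float = _NonNeg
    DR_STtoTerm: float = _NonNeg
    DR_MPPtoTerm: float = _NonNeg
    # constant secretion rates c (ng/cell/day): cell group x pool
    c_prog_DiffS: float = _NonNeg
    c_prog_DiffI: float = _NonNeg
    c_prog_ProS: float = _NonNeg
    c_prog_ProI: float = _NonNeg
    c_term_DiffS: float = _NonNeg
    c_term_DiffI: float = _NonNeg
    c_term_ProS: float = _NonNeg
    c_term_ProI: float = _NonNeg

    @property
    def kind(self) -> ModelKind:
        return ModelKind.five_state


def params_class(kind: ModelKind) -> type[KineticParams]:
    return ThreeStateParams if kind is ModelKind.three_state else FiveStateParams


# ---------------------------------------------------------------------------
# Rate-law kernels
# ---------------------------------------------------------------------------


def compute_ratios(env: CultureEnvironment, eps: float = EPS_POOL) -> tuple[float, float]:
    """Stimulator/inhibitor ratios R_d = DiffS/DiffI and R_p = ProS/ProI.

    A zero numerator yields a zero ratio; a zero inhibitor amount is floored
    at ``eps`` (ng), so the empty start state gives R_d = R_p = 0 while a
    stimulated, inhibitor-free state gives a large finite ratio.
    """
    for p in POOLS:
        if env.pool_amount(p) < 0:
            raise ValueError(f"negative pool amount for {p}")

    def ratio(num: float, den: float) -> float:
        if num == 0.0:
            return 0.0
        return num / max(den, eps)

    r_d = ratio(env.pool_amount("DiffS"), env.pool_amount("DiffI"))
    r_p = ratio(env.pool_amount("ProS"), env.pool_amount("ProI"))
    return r_d, r_p


def secretion_rate(m: float, pool_conc: float, c_hat: float = 1.0) -> float:
    """Feedback-damped secretion rate c = m * exp(-[pool]/c_hat), ng/cell/day.

    Used by the three-state variant only: the more of a biomolecule has
    accumulated, the less of it the cells secrete.
    """
    if m < 0 or pool_conc < 0:
        raise ValueError("secretion_rate arguments must be >= 0")
    return m * math.exp(-pool_conc / c_hat)


def death_rate(dr_max: float, d: float, gc_conc: float) -> float:
    """Apoptosis rate DR_max / (1 + d*[GC]) (1/day): nutrient-starved
    cultures die at the maximal rate; abundant glucose suppresses death."""
    if gc_conc < 0:
        raise ValueError("gc_conc must be >= 0")
    if dr_max < 0 or d < 0:
        raise ValueError("death_rate parameters must be >= 0")
    return dr_max / (1.0 + d * gc_conc)


def self_renewal_fraction(f_max: float, s: float, r_d: float, scf_conc: float) -> float:
    """Self-renewing fraction f = f_max / (1 + R_d + s*[SCF]) (modified
    Monod form); never exceeds f_max, declines with differentiation
    stimulation and with SCF."""
    if not 0 <= f_max <= 1:
        raise ValueError("f_max must lie in [0, 1]")
    if s < 0 or r_d < 0 or scf_conc < 0:
        raise ValueError("self_renewal_fraction arguments must be >= 0")
    return f_max / (1.0 + r_d + s * scf_conc)


def proliferation_rate(pr_max: float, scf_conc: float, r_p: float, s_hat: float = 1.0) -> float:
    """Saturating proliferation rate PR = PR_max * (1 - exp(-[SCF]*R_p/s_hat)).

    Zero without SCF or without net proliferative stimulation (R_p = 0);
    saturates at PR_max for a strong combined signal.
    """
    if pr_max < 0 or scf_conc < 0 or r_p < 0:
        raise ValueError("proliferation_rate arguments must be >= 0")
    return pr_max * (1.0 - math.exp(-scf_conc * r_p / s_hat))


def quiescent_fraction(q_max: float, r_d: float) -> float:
    """Quiescent fraction q = q_max * exp(-R_d): differentiation stimulation
    pulls stem cells out of quiescence."""
    if not 0 <= q_max <= 1:
        raise ValueError("q_max must lie in [0, 1]")
    if r_d < 0:
        raise ValueError("R_d must be >= 0")
    return q_max * math.exp(-r_d)


def jump_fraction(j_max: float, t_d: float) -> float:
    """Fraction of differentiation flux that bypasses intermediate states
    directly into Terminal: j = j_max * exp(-T_d).

    T_d is the Terminal-cell-derived differentiation-stimulator signal, so a
    growing mature population feeds back negatively on the jump."""
    if not 0 <= j_max <= 1:
        raise ValueError("j_max must lie in [0, 1]")
    if t_d < 0:
        raise ValueError("T_d must be >= 0")
    return j_max * math.exp(-t_d)


# ---------------------------------------------------------------------------
# Kernel bundles and right-hand sides
# ---------------------------------------------------------------------------


@dataclass
class KernelValues:
    """All derived kernel values at one instant, keyed by state name where
    state-specific."""

    R_d: float
    R_p: float
    T_d: float
    f: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)
    j: dict[str, float] = field(default_factory=dict)
    PR: dict[str, float] = field(default_factory=dict)
    death: dict[str, float] = field(default_factory=dict)

    def flat(self) -> dict[str, float]:
        out = {"R_d": self.R_d, "R_p": self.R_p, "T_d": self.T_d}
        for group in ("f", "q", "j", "PR", "death"):
            for state, v in getattr(self, group).items():
                out[f"{group}_{state}"] = v
        return out


def _check_state(pop: np.ndarray, env_vec: np.ndarray, kind: ModelKind, t: float) -> None:
    if np.any(np.isnan(pop)):
        bad = kind.states[int(np.flatnonzero(np.isnan(pop))[0])]
        raise ModelStateError(f"NaN population for state {bad!r} at t={t:.4g} d")
    if np.any(np.isnan(env_vec)):
        bad = ENV_FIELDS[int(np.flatnonzero(np.isnan(env_vec))[0])]
        raise ModelStateError(f"NaN environment component {bad!r} at t={t:.4g} d")


def compute_kernels(
    kind: ModelKind,
    pop: np.ndarray,
    env: CultureEnvironment,
    params: KineticParams,
) -> KernelValues:
    """Evaluate every feedback kernel for the current populations and
    environment."""
    pop = np.maximum(np.asarray(pop, dtype=float), 0.0)
    r_d, r_p = compute_ratios(env)
    scf = max(env.scf_conc, 0.0)
    gc = max(env.gc_conc, 0.0)
    terminal = pop[-1]

    if kind is ModelKind.three_state:
        p: ThreeStateParams = params  # type: ignore[assignment]
        c3 = p.m_term_DiffS
        if p.td_mode == "terminal_product":
            t_d = c3 * terminal / p.t_hat
        else:
            t_d = env.pool_conc("DiffS") / p.t_hat
        return KernelValues(
            R_d=r_d,
            R_p=r_p,
            T_d=t_d,
            f={
                "LSK": self_renewal_fraction(p.f_max_LSK, p.s_LSK, r_d, scf),
                "CMP": self_renewal_fraction(p.f_max_CMP, p.s_CMP, r_d, scf),
            },
            q={"LSK": quiescent_fraction(p.q_max, r_d)},
            j={"LSK": jump_fraction(p.j_max, t_d)},
            PR={
                "LSK": proliferation_rate(p.PR_max_LSK, scf, r_p, p.s_hat),
                "CMP": proliferation_rate(p.PR_max_CMP, scf, r_p, p.s_hat),
                "Terminal": proliferation_rate(p.PR_max_Term, scf, r_p, p.s_hat),
            },
            death={
                "LSK": death_rate(p.DR_max_LSK, p.d_LSK, gc),
                "CMP": death_rate(p.DR_max_CMP, p.d_CMP, gc),
                "Terminal": death_rate(p.DR_max_Term, p.d_Term, gc),
            },
        )

    p5: FiveStateParams = params  # type: ignore[assignment]
    if p5.td_mode == "terminal_product":
        t_d = p5.c_term_DiffS * terminal / p5.t_hat
    else:
        t_d = env.pool_conc("DiffS") / p5.t_hat
    return KernelValues(
        R_d=r_d,
        R_p=r_p,
        T_d=t_d,
        f={
            "LT_HSC": self_renewal_fraction(p5.f_max_LT, p5.s_LT, r_d, scf),
            "ST_HSC": self_renewal_fraction(p5.f_max_ST, p5.s_ST, r_d, scf),
            "MPP": self_renewal_fraction(p5.f_max_MPP, p5.s_MPP, r_d, scf),
            "CMP": self_renewal_fraction(p5.f_max_CMP, p5.s_CMP, r_d, scf),
        },
        q={
            "LT_HSC": quiescent_fraction(p5.q_max_LT, r_d),
            "ST_HSC": quiescent_fraction(p5.q_max_ST, r_d),
            "MPP": quiescent_fraction(p5.q_max_MPP, r_d),
        },
        j={
            "ST_HSC": jump_fraction(p5.j_max_STtoTerm, t_d),
            "MPP": jump_fraction(p5.j_max_MPPtoTerm, t_d),
        },
        PR={
            "LT_HSC": p5.PR_LT,
            "ST_HSC": p5.PR_ST,
            "MPP": p5.PR_MPP,
            "CMP": p5.PR_CMP,
            "Terminal": p5.PR_Term,
        },
        death={
            "LT_HSC": death_rate(p5.DR_max_LT, p5.d_LT, gc),
            "ST_HSC": death_rate(p5.DR_max_ST, p5.d_ST, gc),
            "MPP": death_rate(p5.DR_max_MPP, p5.d_MPP, gc),
            "CMP": death_rate(p5.DR_max_CMP, p5.d_CMP, gc),
            "Terminal": death_rate(p5.DR_max_Term, p5.d_Term, gc),
        },
    )


def _env_derivative(
    pop: np.ndarray,
    env: CultureEnvironment,
    params: KineticParams,
    secretion: dict[str, tuple[float, float]],
    n_progenitors: float,
) -> np.ndarray:
    """Environment derivative in ENV_FIELDS order.

    ``secretion`` maps pool name -> (progenitor rate, terminal rate) in
    ng/cell/day.  Consumption halts once a stock is exhausted.
    """
    n_total = float(np.sum(pop))
    terminal = pop[-1]
    d_scf = -params.K_SCF_consumption * n_total / env.volume_mL if env.scf_conc > 0 else 0.0
    d_gc = -params.K_GC_consumption * n_total if env.gc_conc > 0 else 0.0
    d_pools = [
        secretion[p][0] * n_progenitors + secretion[p][1] * terminal for p in POOLS
    ]
    return np.array([d_scf, d_gc, *d_pools], dtype=float)


def rhs_3state(
    t: float,
    pop: np.ndarray,
    env: CultureEnvironment,
    params: ThreeStateParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives of (LSK, CMP, Terminal) populations and environment.

    Flow wiring: the quiescent fraction q gates proliferation and
    differentiation of LSK (not death); the self-renewal fraction f splits
    active LSK/CMP flux between proliferative inflow (f) and differentiation
    outflow (1-f); the jump fraction j splits LSK differentiation between the
    direct LSK->Terminal path (j) and the stepwise LSK->CMP path (1-j).
    """
    pop = np.asarray(pop, dtype=float)
    env_vec = env.as_vector()
    _check_state(pop, env_vec, ModelKind.three_state, t)
    pop = np.maximum(pop, 0.0)
    lsk, cmp_, term = pop

    k = compute_kernels(ModelKind.three_state, pop, env, params)
    f_lsk, f_cmp = k.f["LSK"], k.f["CMP"]
    q = k.q["LSK"]
    j = k.j["LSK"]
    active = 1.0 - q

    lsk_prolif = active * f_lsk * k.PR["LSK"] * lsk
    lsk_diff_total = active * (1.0 - f_lsk) * lsk
    flux_lsk_cmp = lsk_diff_total * (1.0 - j) * params.DR_LSKtoCMP
    flux_lsk_term = lsk_diff_total * j * params.DR_LSKtoTerm
    death_gate = active if params.quiescence_gates_death else 1.0

    d_lsk = lsk_prolif - flux_lsk_cmp - flux_lsk_term - death_gate * k.death["LSK"] * lsk

    cmp_prolif = f_cmp * k.PR["CMP"] * cmp_
    flux_cmp_term = (1.0 - f_cmp) * params.DR_CMPtoTerm * cmp_
    d_cmp = flux_lsk_cmp + cmp_prolif - flux_cmp_term - k.death["CMP"] * cmp_

    d_term = flux_lsk_term + flux_cmp_term + k.PR["Terminal"] * term - k.death["Terminal"] * term

    secretion = {
        p: (
            secretion_rate(getattr(params, f"m_prog_{p}"), env.pool_conc(p), params.c_hat),
            secretion_rate(getattr(params, f"m_term_{p}"), env.pool_conc(p), params.c_hat),
        )
        for p in POOLS
    }
    d_env = _env_derivative(pop, env, params, secretion, n_progenitors=lsk + cmp_)
    return np.array([d_lsk, d_cmp, d_term]), d_env


def rhs_5state(
    t: float,
    pop: np.ndarray,
    env: CultureEnvironment,
    params: FiveStateParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives for the LT-HSC -> ST-HSC -> MPP -> CMP -> Terminal
    chain, with constant proliferation and secretion rates, quiescence on the
    three stem/multipotent states and jumps from ST-HSC and MPP to Terminal."""
    pop = np.asarray(pop, dtype=float)
    env_vec = env.as_vector()
    _check_state(pop, env_vec, ModelKind.five_state, t)
    pop = np.maximum(pop, 0.0)
    lt, st, mpp, cmp_, term = pop

    k = compute_kernels(ModelKind.five_state, pop, env, params)
    a_lt = 1.0 - k.q["LT_HSC"]
    a_st = 1.0 - k.q["ST_HSC"]
    a_mpp = 1.0 - k.q["MPP"]
    gate = params.quiescence_gates_death

    # LT-HSC: stepwise differentiation only
    lt_diff = a_lt * (1.0 - k.f["LT_HSC"]) * params.DR_LTtoST * lt
    d_lt = (
        a_lt * k.f["LT_HSC"] * k.PR["LT_HSC"] * lt
        - lt_diff
        - (a_lt if gate else 1.0) * k.death["LT_HSC"] * lt
    )

    # ST-HSC: stepwise to MPP plus jump to Terminal
    st_out = a_st * (1.0 - k.f["ST_HSC"]) * st
    flux_st_mpp = st_out * (1.0 - k.j["ST_HSC"]) * params.DR_STtoMPP
    flux_st_term = st_out * k.j["ST_HSC"] * params.DR_STtoTerm
    d_st = (
        lt_diff
        + a_st * k.f["ST_HSC"] * k.PR["ST_HSC"] * st
        - flux_st_mpp
        - flux_st_term
        - (a_st if gate else 1.0) * k.death["ST_HSC"] * st
    )

    # MPP: stepwise to CMP plus jump to Terminal
    mpp_out = a_mpp * (1.0 - k.f["MPP"]) * mpp
    flux_mpp_cmp = mpp_out * (1.0 - k.j["MPP"]) * params.DR_MPPtoCMP
    flux_mpp_term = mpp_out * k.j["MPP"] * params.DR_MPPtoTerm
    d_mpp = (
        flux_st_mpp
        + a_mpp * k.f["MPP"] * k.PR["MPP"] * mpp
        - flux_mpp_cmp
        - flux_mpp_term
        - (a_mpp if gate else 1.0) * k.death["MPP"] * mpp
    )

    # CMP: no quiescence, no jump
    flux_cmp_term = (1.0 - k.f["CMP"]) * params.DR_CMPtoTerm * cmp_
    d_cmp = (
        flux_mpp_cmp
        + k.f["CMP"] * k.PR["CMP"] * cmp_
        - flux_cmp_term
        - k.death["CMP"] * cmp_
    )

    d_term = (
        flux_st_term
        + flux_mpp_term
        + flux_cmp_term
        + k.PR["Terminal"] * term
        - k.death["Terminal"] * term
    )

    secretion = {
        p: (getattr(params, f"c_prog_{p}"), getattr(params, f"c_term_{p}"))
        for p in POOLS
    }
    d_env = _env_derivative(pop, env, params, secretion, n_progenitors=lt + st + mpp + cmp_)
    return np.array([d_lt, d_st, d_mpp, d_cmp, d_term]), d_env


def rhs(
    kind: ModelKind,
    t: float,
    pop: np.ndarray,
    env: CultureEnvironment,
    params: KineticParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the variant-specific right-hand side."""
    if kind is ModelKind.three_state:
        return rhs_3state(t, pop, env, params)
    return rhs_5state(t, pop, env, params)
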