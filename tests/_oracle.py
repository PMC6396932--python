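"""Independent, deliberately naive re-evaluation of the model right-hand
sides, written directly from the rate laws without sharing code with the
package.  Used to cross-check the packaged RHS implementations."""

import math

import numpy as np

EPS = 1e-9


def _ratio(num, den):
    if num == 0.0:
        return 0.0
    return num / max(den, EPS)


def oracle_rhs_3state(pop, env, p):
    """pop = (LSK, CMP, Terminal); env is a CultureEnvironment; p a
    ThreeStateParams.  Returns (d_pop list, d_env list)."""
    lsk, cmp_, term = [max(x, 0.0) for x in pop]
    vol = env.media_volume / 1000.0
    pools = {n: getattr(env, "pool_" + n) for n in ("DiffS", "DiffI", "ProS", "ProI")}
    conc = {n: pools[n] / vol for n in pools}
    scf = max(env.scf_conc, 0.0)
    gc = max(env.gc_conc, 0.0)

    r_d = _ratio(pools["DiffS"], pools["DiffI"])
    r_p = _ratio(pools["ProS"], pools["ProI"])
    if p.td_mode == "terminal_product":
        t_d = p.m_term_DiffS * term / p.t_hat
    else:
        t_d = conc["DiffS"] / p.t_hat

    f_lsk = p.f_max_LSK / (1 + r_d + p.s_LSK * scf)
    f_cmp = p.f_max_CMP / (1 + r_d + p.s_CMP * scf)
    q = p.q_max * math.exp(-r_d)
    j = p.j_max * math.exp(-t_d)
    pr = lambda prmax: prmax * (1 - math.exp(-scf * r_p / p.s_hat))
    death = {
        "LSK": p.DR_max_LSK / (1 + p.d_LSK * gc),
        "CMP": p.DR_max_CMP / (1 + p.d_CMP * gc),
        "Term": p.DR_max_Term / (1 + p.d_Term * gc),
    }
    a = 1 - q
    dg = a if p.quiescence_gates_death else 1.0
    to_cmp = a * (1 - f_lsk) * (1 - j) * p.DR_LSKtoCMP * lsk
    to_term_jump = a * (1 - f_lsk) * j * p.DR_LSKtoTerm * lsk
    cmp_to_term = (1 - f_cmp) * p.DR_CMPtoTerm * cmp_

    d_lsk = a * f_lsk * pr(p.PR_max_LSK) * lsk - to_cmp - to_term_jump - dg * death["LSK"] * lsk
    d_cmp = to_cmp + f_cmp * pr(p.PR_max_CMP) * cmp_ - cmp_to_term - death["CMP"] * cmp_
    d_term = to_term_jump + cmp_to_term + pr(p.PR_max_Term) * term - death["Term"] * term

    n = lsk + cmp_ + term
    d_scf = -p.K_SCF_consumption * n / vol if env.scf_conc > 0 else 0.0
    d_gc = -p.K_GC_consumption * n if env.gc_conc > 0 else 0.0
    d_pools = []
    for name in ("DiffS", "DiffI", "ProS", "ProI"):
        cp = getattr(p, "m_prog_" + name) * math.exp(-conc[name] / p.c_hat)
        ct = getattr(p, "m_term_" + name) * math.exp(-conc[name] / p.c_hat)
        d_pools.append(cp * (lsk + cmp_) + ct * term)
    return [d_lsk, d_cmp, d_term], [d_scf, d_gc, *d_pools]


def oracle_rhs_5state(pop, env, p):
    lt, st, mpp, cmp_, term = [max(x, 0.0) for x in pop]
    vol = env.media_volume / 1000.0
    pools = {n: getattr(env, "pool_" + n) for n in ("DiffS", "DiffI", "ProS", "ProI")}
    scf = max(env.scf_conc, 0.0)
    gc = max(env.gc_conc, 0.0)
    r_d = _ratio(pools["DiffS"], pools["DiffI"])
    if p.td_mode == "terminal_product":
        t_d = p.c_term_DiffS * term / p.t_hat
    else:
        t_d = (pools["DiffS"] / vol) / p.t_hat

    f = {
        "LT": p.f_max_LT / (1 + r_d + p.s_LT * scf),
        "ST": p.f_max_ST / (1 + r_d + p.s_ST * scf),
        "MPP": p.f_max_MPP / (1 + r_d + p.s_MPP * scf),
        "CMP": p.f_max_CMP / (1 + r_d + p.s_CMP * scf),
    }
    q = {
        "LT": p.q_max_LT * math.exp(-r_d),
        "ST": p.q_max_ST * math.exp(-r_d),
        "MPP": p.q_max_MPP * math.exp(-r_d),
    }
    j_st = p.j_max_STtoTerm * math.exp(-t_d)
    j_mpp = p.j_max_MPPtoTerm * math.exp(-t_d)
    death = {
        "LT": p.DR_max_LT / (1 + p.d_LT * gc),
        "ST": p.DR_max_ST / (1 + p.d_ST * gc),
        "MPP": p.DR_max_MPP / (1 + p.d_MPP * gc),
        "CMP": p.DR_max_CMP / (1 + p.d_CMP * gc),
        "Term": p.DR_max_Term / (1 + p.d_Term * gc),
    }
    g = p.quiescence_gates_death
    a_lt, a_st, a_mpp = 1 - q["LT"], 1 - q["ST"], 1 - q["MPP"]

    lt_to_st = a_lt * (1 - f["LT"]) * p.DR_LTtoST * lt
    st_to_mpp = a_st * (1 - f["ST"]) * (1 - j_st) * p.DR_STtoMPP * st
    st_to_term = a_st * (1 - f["ST"]) * j_st * p.DR_STtoTerm * st
    mpp_to_cmp = a_mpp * (1 - f["MPP"]) * (1 - j_mpp) * p.DR_MPPtoCMP * mpp
    mpp_to_term = a_mpp * (1 - f["MPP"]) * j_mpp * p.DR_MPPtoTerm * mpp
    cmp_to_term = (1 - f["CMP"]) * p.DR_CMPtoTerm * cmp_

    d_lt = a_lt * f["LT"] * p.PR_LT * lt - lt_to_st - (a_lt if g else 1) * death["LT"] * lt
    d_st = (
        lt_to_st + a_st * f["ST"] * p.PR_ST * st - st_to_mpp - st_to_term
        - (a_st if g else 1) * death["ST"] * st
    )
    d_mpp = (
        st_to_mpp + a_mpp * f["MPP"] * p.PR_MPP * mpp - mpp_to_cmp - mpp_to_term
        - (a_mpp if g else 1) * death["MPP"] * mpp
    )
    d_cmp = mpp_to_cmp + f["CMP"] * p.PR_CMP * cmp_ - cmp_to_term - death["CMP"] * cmp_
    d_term = st_to_term + mpp_to_term + cmp_to_term + p.PR_Term * term - death["Term"] * term

    n = lt + st + mpp + cmp_ + term
    d_scf = -p.K_SCF_consumption * n / vol if env.scf_conc > 0 else 0.0
    d_gc = -p.K_GC_consumption * n if env.gc_conc > 0 else 0.0
    prog = lt + st + mpp + cmp_
    d_pools = [
        getattr(p, "c_prog_" + name) * prog + getattr(p, "c_term_" + name) * term
        for name in ("DiffS", "DiffI", "ProS", "ProI")
    ]
    return [d_lt, d_st, d_mpp, d_cmp, d_term], [d_scf, d_gc, *d_pools]


def random_three_state_params(rng):
    from hsckinetics.model import ThreeStateParams

    u = lambda lo, hi: float(rng.uniform(lo, hi))
    return ThreeStateParams(
        PR_max_LSK=u(0, 2), PR_max_CMP=u(0, 2), PR_max_Term=u(0, 2),
        DR_max_LSK=u(0, 0.5), DR_max_CMP=u(0, 0.5), DR_max_Term=u(0, 0.5),
        d_LSK=u(0, 2), d_CMP=u(0, 2), d_Term=u(0, 2),
        f_max_LSK=u(0, 1), f_max_CMP=u(0, 1), s_LSK=u(0, 0.05), s_CMP=u(0, 0.05),
        q_max=u(0, 1), j_max=u(0, 1),
        DR_LSKtoCMP=u(0, 3), DR_LSKtoTerm=u(0, 3), DR_CMPtoTerm=u(0, 4),
        m_prog_DiffS=u(0, 1e-3), m_prog_DiffI=u(0, 1e-3),
        m_prog_ProS=u(0, 1e-3), m_prog_ProI=u(0, 1e-3),
        m_term_DiffS=u(0, 1e-4), m_term_DiffI=u(0, 1e-3),
        m_term_ProS=u(0, 1e-3), m_term_ProI=u(0, 1e-3),
        K_SCF_consumption=u(0, 1e-4), K_GC_consumption=u(0, 1e-5),
    )


def random_five_state_params(rng):
    from hsckinetics.model import FiveStateParams

    u = lambda lo, hi: float(rng.uniform(lo, hi))
    return FiveStateParams(
        PR_LT=u(0, 1), PR_ST=u(0, 2), PR_MPP=u(0, 2), PR_CMP=u(0, 2), PR_Term=u(0, 1),
        DR_max_LT=u(0, 0.5), DR_max_ST=u(0, 0.5), DR_max_MPP=u(0, 0.5),
        DR_max_CMP=u(0, 0.5), DR_max_Term=u(0, 0.5),
        d_LT=u(0, 2), d_ST=u(0, 2), d_MPP=u(0, 2), d_CMP=u(0, 2), d_Term=u(0, 2),
        f_max_LT=u(0, 1), f_max_ST=u(0, 1), f_max_MPP=u(0, 1), f_max_CMP=u(0, 1),
        s_LT=u(0, 0.05), s_ST=u(0, 0.05), s_MPP=u(0, 0.05), s_CMP=u(0, 0.05),
        q_max_LT=u(0, 1), q_max_ST=u(0, 1), q_max_MPP=u(0, 1),
        j_max_STtoTerm=u(0, 1), j_max_MPPtoTerm=u(0, 1),
        DR_LTtoST=u(0, 2), DR_STtoMPP=u(0, 2), DR_MPPtoCMP=u(0, 2),
        DR_CMPtoTerm=u(0, 4), DR_STtoTerm=u(0, 3), DR_MPPtoTerm=u(0, 3),
        c_prog_DiffS=u(0, 1e-3), c_prog_DiffI=u(0, 1e-3),
        c_prog_ProS=u(0, 1e-3), c_prog_ProI=u(0, 1e-3),
        c_term_DiffS=u(0, 1e-4), c_term_DiffI=u(0, 1e-3),
        c_term_ProS=u(0, 1e-3), c_term_ProI=u(0, 1e-3),
        K_SCF_consumption=u(0, 1e-4), K_GC_consumption=u(0, 1e-5),
    )


def random_state(rng, n_states):
    from hsckinetics.model import CultureEnvironment

    pop = rng.uniform(0, 1e5, size=n_states)
    env = CultureEnvironment(
        scf_conc=float(rng.uniform(0, 100)),
        gc_conc=float(rng.uniform(0, 10)),
        pool_DiffS=float(rng.uniform(0, 5)),
        pool_DiffI=float(rng.uniform(0, 5)),
        pool_ProS=float(rng.uniform(0, 5)),
        pool_ProI=float(rng.uniform(0, 5)),
    )
    return pop, env
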