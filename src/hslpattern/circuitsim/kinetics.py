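"""Elementary regulatory operators and the per-cell reaction kinetics.

The circuit model is deterministic per-cell ODE kinetics with logistic
population growth; measurement noise enters only at observation time (see
wells.py).  State layout, shared by every genotype (unused slots stay zero):

    0  N       population density (OD600 units)
    1  eA      T7RNAP (intact) or N-terminal fragment T7RNAP[1-179]
    2  eB      C-terminal fragment T7RNAP[180-880]
    3  cfp_i   immature mTurquoise2 (per cell)
    4  cfp_m   mature mTurquoise2
    5  yfp_i   immature mVenus
    6  yfp_m   mature mVenus
    7  rfp_i   immature mRFP1
    8  rfp_m   mature mRFP1
    9  eI      sender synthase (LuxI or LasI)
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CircuitParams, Condition, HillParams

__all__ = [
    "hill_response",
    "split_and_activity",
    "burden_penalty",
    "competition_factor",
    "Genotype",
    "GENOTYPES",
    "state_derivative",
    "initial_state",
    "qss_state",
    "NSTATE",
]

NSTATE = 10
IDX = {
    "N": 0, "eA": 1, "eB": 2, "cfp_i": 3, "cfp_m": 4,
    "yfp_i": 5, "yfp_m": 6, "rfp_i": 7, "rfp_m": 8, "eI": 9,
}


def hill_response(c, p: HillParams):
    """Promoter synthesis rate basal + vmax * c^n / (K^n + c^n).

    Monotone non-decreasing in c; c must be non-negative.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("inducer concentration must be non-negative")
    cn = np.power(c, p.n)
    out = p.basal + p.vmax * cn / (p.K ** p.n + cn)
    return out if out.shape else float(out)


def _hill_norm(c, p: HillParams):
    """Normalized activation c^n / (K^n + c^n) in [0, 1)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("inducer concentration must be non-negative")
    cn = np.power(c, p.n)
    return cn / (p.K ** p.n + cn)


def split_and_activity(n_frag, c_frag, split_K: float, vcat: float):
    """Active polymerase from split-fragment complementation.

    Saturable bilinear form vcat * nf/(K+nf) * cf/(K+cf): exactly zero when
    either fragment is absent, which makes the AND null exact.
    """
    n_frag = np.asarray(n_frag, dtype=float)
    c_frag = np.asarray(c_frag, dtype=float)
    if np.any(n_frag < 0) or np.any(c_frag < 0):
        raise ValueError("fragment levels must be non-negative")
    out = vcat * (n_frag / (split_K + n_frag)) * (c_frag / (split_K + c_frag))
    return out if out.shape else float(out)


def burden_penalty(t7_load, params: CircuitParams):
    """Toxicity multiplier in (0, 1]: 1 below the threshold, then a smooth
    hyperbolic decline 1/(1 + slope*(load - threshold))."""
    load = np.asarray(t7_load, dtype=float)
    if np.any(load < 0):
        raise ValueError("t7_load must be non-negative")
    excess = np.maximum(0.0, load - params.burden_threshold)
    out = 1.0 / (1.0 + params.burden_slope * excess)
    return out if out.shape else float(out)


def competition_factor(t7_transcription, phi: float):
    """Host-capacity multiplier 1/(1 + phi * t7_transcription) applied to
    host-polymerase-driven CFP and YFP synthesis only."""
    t = np.asarray(t7_transcription, dtype=float)
    if np.any(t < 0) or phi < 0:
        raise ValueError("inputs must be non-negative")
    out = 1.0 / (1.0 + phi * t)
    return out if out.shape else float(out)


# --------------------------------------------------------------------------
# Genotypes: which operons a strain carries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    name: str
    t7_drive: str        # "none" | "lac" | "bad" | "hsl"
    ratiometric: bool    # YFP from the T7 promoter + constitutive CFP reference
    lux_operon: bool     # P_Lux76* -> T7RNAP[180-880] + mTurquoise2
    las_operon: bool     # P_Las81* -> T7RNAP[1-179] + mVenus
    rfp_reporter: bool   # P_T7(-3G) -> mRFP1
    sender: str          # "" | "luxI" | "lasI"
    grows: bool = True


GENOTYPES = {
    g.name: g
    for g in [
        # ratiometric reporter in T7 Express (IPTG -> genomic intact T7RNAP)
        Genotype("ratiometric_reporter", "lac", True, False, False, False, ""),
        # controller plasmid (arabinose -> T7RNAP variant) + ratiometric reporter
        Genotype("controller", "bad", True, False, False, False, ""),
        # three-color AND gate and its half circuits (+ RFP reporter plasmid)
        Genotype("and_full", "hsl", False, True, True, True, ""),
        Genotype("and_half_cfp", "hsl", False, True, False, True, ""),
        Genotype("and_half_yfp", "hsl", False, False, True, True, ""),
        # triple-transformed sender populations
        Genotype("sender_luxI", "hsl", False, True, True, True, "luxI"),
        Genotype("sender_lasI", "hsl", False, True, True, True, "lasI"),
        # media only
        Genotype("empty", "none", False, False, False, False, "", grows=False),
    ]
}


def _synthesis(params: CircuitParams, gt: Genotype, cond: dict, eA, eB):
    """Instantaneous synthesis rates given current enzyme levels.

    cond holds arrays (or scalars) iptg, arabinose, c6, c12.  Returns a dict
    of synthesis rates plus the burden multiplier.
    """
    zeros = np.zeros_like(np.asarray(eA, dtype=float))

    aA = zeros
    aB = zeros
    aC = zeros
    aY = zeros
    aR = zeros
    aI = zeros

    if gt.t7_drive == "lac":
        drive = hill_response(cond["iptg"], params.promoters["P_lac"])
        aA = drive + zeros
        if params.variant == "split":
            aB = drive + zeros
    elif gt.t7_drive == "bad":
        drive = hill_response(cond["arabinose"], params.promoters["P_BAD"])
        aA = drive + zeros
        if params.variant == "split":
            aB = drive + zeros
    elif gt.t7_drive == "hsl":
        p_lux = params.promoters["P_Lux76*"]
        p_las = params.promoters["P_Las81*"]
        p6 = hill_response(cond["c6"], p_lux) if gt.lux_operon else zeros
        if gt.las_operon:
            h12 = _hill_norm(cond["c12"], p_las)
            hx = _hill_norm(cond["c6"], p_lux)  # 3OC6HSL acting on P_Las81*
            h_or = h12 + params.crosstalk_eps * hx * (1.0 - h12)
            p12 = p_las.basal + p_las.vmax * h_or
        else:
            p12 = zeros
        # bicistronic operons: fragment + visual indicator from one promoter
        aB = p6 + zeros                                    # T7RNAP[180-880]
        aA = params.rbs_factor(params.nfrag_rbs) * p12     # T7RNAP[1-179]

    # toxicity load: the (condition-wise constant) T7RNAP synthesis drive
    g_b = burden_penalty(aA + aB, params)

    # T7 catalytic activity from the accumulated enzyme/fragment levels
    if gt.t7_drive == "none":
        act_raw = zeros
    elif params.variant == "split" or gt.t7_drive == "hsl":
        act_raw = split_and_activity(eA, eB, params.split_K, params.vcat)
    else:
        act_raw = params.vcat * np.asarray(eA, dtype=float)
    act_eff = g_b * act_raw
    t7_flux = params.t7_gain * act_eff
    comp = competition_factor(t7_flux, params.competition_phi)

    if gt.t7_drive == "hsl":
        aC = params.fp_rate * p6 * comp
        aY = params.fp_rate * p12 * comp
    if gt.ratiometric:
        aY = params.t7_basal + t7_flux
        aC = params.const_cfp_rate * comp + zeros
    if gt.rfp_reporter:
        aR = params.t7_basal + t7_flux + zeros
    if gt.sender:
        aI = params.sender_expr * _hill_norm(cond["arabinose"],
                                             params.promoters["P_BAD"]) + zeros

    return {"aA": aA, "aB": aB, "aC": aC, "aY": aY, "aR": aR, "aI": aI,
            "g_b": g_b, "act_eff": act_eff}


def state_derivative(params: CircuitParams, gt: Genotype, cond: dict, state):
    """Time derivative of the (NSTATE, nwells) state array."""
    s = np.asarray(state, dtype=float)
    N = s[0]
    rates = _synthesis(params, gt, cond, s[1], s[2])
    # toxicity slows growth, but less than it throttles T7-driven synthesis
    g_growth = np.maximum(rates["g_b"], params.burden_growth_floor)
    r = params.growth_rate
    K = params.carrying_capacity
    mu = r * g_growth * np.maximum(0.0, 1.0 - N / K) if gt.grows else 0.0 * N

    d = np.empty_like(s)
    d[0] = mu * N
    dil = mu + params.deg
    d[1] = rates["aA"] - dil * s[1]
    d[2] = rates["aB"] - dil * s[2]
    for prot, (ai, am, rate_key) in {
        "CFP": ((3, 4), None, "aC"),
        "YFP": ((5, 6), None, "aY"),
        "RFP": ((7, 8), None, "aR"),
    }.items():
        i_idx, m_idx = ai
        km = params.maturation[prot]
        d[i_idx] = rates[rate_key] - (dil + km) * s[i_idx]
        d[m_idx] = km * s[i_idx] - dil * s[m_idx]
    d[9] = rates["aI"] - dil * s[9]
    return d


def qss_state(params: CircuitParams, genotype: str, cond: Condition,
              mu: float | None = None) -> dict:
    """Algebraic quasi-steady state of the per-cell species at fixed
    specific growth rate (default: the maximal rate r).

    The burden load is the condition-wise constant T7 synthesis drive, so the
    steady state is available in closed form: enzyme levels first, then the
    fluorophore cascade.  Returns per-cell levels, synthesis rates and the
    effective T7 activity.
    """
    gt = GENOTYPES[genotype]
    mu0 = params.growth_rate if mu is None else float(mu)
    cd = cond.as_dict()
    pre = _synthesis(params, gt, cd, 0.0, 0.0)
    g_growth = max(float(np.asarray(pre["g_b"])), params.burden_growth_floor)
    mu_eff = mu0 * g_growth if gt.grows else 0.0
    dil = mu_eff + params.deg
    eA = float(np.asarray(pre["aA"])) / dil
    eB = float(np.asarray(pre["aB"])) / dil
    rates = _synthesis(params, gt, cd, eA, eB)
    out = {"eA": eA, "eB": eB, "eI": rates["aI"] / dil, "mu_eff": mu_eff,
           "act_eff": float(np.asarray(rates["act_eff"]))}
    for prot, key in (("CFP", "aC"), ("YFP", "aY"), ("RFP", "aR")):
        a = float(np.asarray(rates[key]))
        km = params.maturation[prot]
        xi = a / (dil + km)
        out[prot.lower() + "_i"] = xi
        out[prot.lower() + "_m"] = km * xi / dil
        out["a" + prot[0]] = a
    return out


def initial_state(params: CircuitParams, genotype: str, nwells: int = 1):
    """Inoculum state: cells precultured to exponential phase without
    inducers, so every species starts at its zero-inducer steady state."""
    gt = GENOTYPES[genotype]
    s = np.zeros((NSTATE, nwells))
    if not gt.grows:
        return s
    q = qss_state(params, genotype, Condition())
    s[0] = params.inoculum_od
    s[1] = q["eA"]
    s[2] = q["eB"]
    s[3], s[4] = q["cfp_i"], q["cfp_m"]
    s[5], s[6] = q["yfp_i"], q["yfp_m"]
    s[7], s[8] = q["rfp_i"], q["rfp_m"]
    s[9] = q["eI"]
    return s
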