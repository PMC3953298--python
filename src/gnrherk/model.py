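"""Right-hand side of the reduced GnRH -> ERK -> transcription ODE model.

State vector (all concentrations in uM, per-compartment):

========  ==========================================================
index     species
========  ==========================================================
0  HR     hormone-bound receptor
1  GQ     free G protein
2  E      active effector (drives MEK)
3  E_c    unphosphorylated cytosolic ERK
4  pE_c   mono-phosphorylated cytosolic ERK
5  ppE_c  dual-phosphorylated (active) cytosolic ERK
6  E_n    unphosphorylated nuclear ERK
7  ppE_n  dual-phosphorylated nuclear ERK
8  TF1    active transcription factor
9  TF1DT  TF1-dependent transcript
========  ==========================================================

ERK phosphorylation is distributive and two-step (Markevich-type competitive
Michaelis-Menten fluxes v1-v5) and occurs only in the cytoplasm; nuclear
dephosphorylation (v5) removes both phosphates in one step.  MEK activation
by the effector is algebraic (quasi-steady-state Michaelis-Menten).  ERK
shuttles between cytoplasm and nucleus with separate rates for the active
and inactive forms; transport terms carry the cytoplasm:nucleus volume ratio
C_cn so that ERK *amount* is conserved:

    (E_c + pE_c + ppE_c) + (E_n + ppE_n) / C_cn = ERK_tot.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet
from .protocols import PulseProtocol

__all__ = [
    "STATE_NAMES",
    "gnrh_input",
    "mek_active",
    "phospho_fluxes",
    "rhs",
    "resting_state",
    "conservation_residuals",
    "receptor_equilibrium",
    "erk_conservation_total",
]

STATE_NAMES: tuple[str, ...] = (
    "HR",
    "GQ",
    "E",
    "E_c",
    "pE_c",
    "ppE_c",
    "E_n",
    "ppE_n",
    "TF1",
    "TF1DT",
)


def gnrh_input(t: float, protocol: PulseProtocol) -> float:
    """Square-wave GnRH concentration (uM) at time ``t`` (min).

    Returns the pulse amplitude when ``mod(t, period) < width`` (half-open
    pulse windows) and 0 otherwise; 0 from any washout event onward.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    tw = protocol.washout_time
    if tw is not None and t >= tw:
        return 0.0
    if math.fmod(t, protocol.period) < protocol.width:
        return protocol.p
    return 0.0


def mek_is_inhibited(t: float, protocol: PulseProtocol) -> bool:
    """True once a mek_inhibition event has taken effect at time ``t``."""
    tm = protocol.mek_inhibition_time
    return tm is not None and t >= tm


def mek_active(E: float, params: ParameterSet) -> float:
    """Active MEK (ppMEK, uM) as a quasi-steady-state function of effector.

    ppMEK = MEK_tot * (k_MEK_basal + k_mek*E) / (k_MEK_basal + k_mek*(K_MM_MEK + E))

    With the default k_MEK_basal = 0 this reduces to the hyperbola
    MEK_tot * E / (K_MM_MEK + E); the result is always in [0, MEK_tot].
    """
    if E < 0:
        raise ValueError(f"effector concentration must be >= 0, got {E}")
    num = params.k_MEK_basal + params.k_mek * E
    den = params.k_MEK_basal + params.k_mek * (params.K_MM_MEK + E)
    if den == 0.0:  # k_mek = k_MEK_basal = 0: no MEK activation pathway
        return 0.0
    return params.MEK_tot * num / den


def phospho_fluxes(
    state: np.ndarray,
    ppMEK: float,
    params: ParameterSet,
    mek_inhibited: bool = False,
) -> tuple[float, float, float, float, float]:
    """ERK (de)phosphorylation fluxes v1..v5 (uM/min).

    v1/v2: distributive dual phosphorylation of cytosolic ERK by ppMEK, with
    competitive inhibition between the two substrate forms.  v3/v4: cytosolic
    dephosphorylation by MKP_c, competitive among all three cytosolic forms.
    v5: one-step nuclear dephosphorylation of ppE_n by MKP_n.  MEK inhibition
    zeroes v1 and v2 only.
    """
    E_c, pE_c, ppE_c = state[3], state[4], state[5]
    ppE_n = state[7]
    p = params
    if mek_inhibited:
        v1 = 0.0
        v2 = 0.0
    else:
        v1 = p.kcat_1 * ppMEK * E_c / (p.km_1 * (1.0 + pE_c / p.km_2) + E_c)
        v2 = p.kcat_2 * ppMEK * pE_c / (p.km_2 * (1.0 + E_c / p.km_1) + pE_c)
    v3 = p.kcat_3 * p.MKP_c * ppE_c / (
        p.km_3 * (1.0 + pE_c / p.km_4 + E_c / p.km_5) + ppE_c
    )
    v4 = p.kcat_4 * p.MKP_c * pE_c / (
        p.km_4 * (1.0 + ppE_c / p.km_3 + E_c / p.km_5) + pE_c
    )
    v5 = p.kcat_5 * p.MKP_n * ppE_n / (p.kd_ppEn + ppE_n)
    return v1, v2, v3, v4, v5


def rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    protocol: PulseProtocol,
    *,
    G: float | None = None,
    mek_inhibited: bool | None = None,
) -> np.ndarray:
    """Time derivative of the 10-component state.

    ``G`` and ``mek_inhibited`` may be supplied explicitly (the piecewise
    integrator freezes them per segment); by default they are evaluated from
    the protocol at ``t``.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state component")
    if G is None:
        G = gnrh_input(t, protocol)
    if mek_inhibited is None:
        mek_inhibited = mek_is_inhibited(t, protocol)
    return _rhs_core(state, G, mek_inhibited, params)


def _rhs_core(
    state: np.ndarray, G: float, mek_inhibited: bool, p: ParameterSet
) -> np.ndarray:
    HR, GQ, E, E_c, pE_c, ppE_c, E_n, ppE_n, TF1, TF1DT = state
    ppMEK = mek_active(E, p)
    v1, v2, v3, v4, v5 = phospho_fluxes(state, ppMEK, p, mek_inhibited)
    feedback = ppE_c if p.feedback_target == "ppE_c" else ppE_n
    C = p.C_cn
    d = np.empty(10)
    d[0] = p.k1 * G * (p.R0 - HR) - p.k_minus1 * HR
    d[1] = -p.k2 * HR * GQ + p.k_minus2 * (p.GQ_tot - GQ)
    d[2] = p.k2 * HR * GQ - p.k_minus3 * E - p.k3 * feedback * E
    d[3] = -v1 + v4 - p.k_imp * E_c + (p.k_exp / C) * E_n
    d[4] = v1 - v2 + v3 - v4
    d[5] = v2 - v3 - p.k_imp_act * ppE_c + (p.k_exp_act / C) * ppE_n
    d[6] = C * p.k_imp * E_c - p.k_exp * E_n + v5
    d[7] = C * p.k_imp_act * ppE_c - p.k_exp_act * ppE_n - v5
    d[8] = p.k_TF1 * ppE_n / (p.K_MM_TF1 + ppE_n) - p.d_TF1 * TF1
    d[9] = p.k_TF1DT * TF1 / (p.K_MM_TF1DT + TF1) - p.d_TF1DT * TF1DT
    return d


def resting_state(params: ParameterSet) -> np.ndarray:
    """Unstimulated fixed point of the system.

    No receptor occupancy or effector activity, full free G-protein pool,
    all phospho-species and transcription-tier species at zero, and
    unphosphorylated ERK partitioned by the import/export balance
    ``E_n / E_c = C_cn * k_imp / k_exp`` subject to ERK amount conservation.
    """
    p = params
    if p.k_exp <= 0:
        raise ValueError("resting state requires k_exp > 0")
    E_c = p.ERK_tot / (1.0 + p.k_imp / p.k_exp)
    E_n = p.C_cn * p.k_imp / p.k_exp * E_c
    y = np.zeros(10)
    y[1] = p.GQ_tot
    y[3] = E_c
    y[6] = E_n
    return y


def erk_conservation_total(state: np.ndarray, params: ParameterSet) -> float:
    """Conserved ERK amount, expressed as a cytoplasm-referenced concentration."""
    return (
        state[3] + state[4] + state[5] + (state[6] + state[7]) / params.C_cn
    )


def conservation_residuals(
    state: np.ndarray, params: ParameterSet
) -> tuple[float, list[str]]:
    """ERK-conservation residual and any negativity/bound violations."""
    residual = erk_conservation_total(state, params) - params.ERK_tot
    violations: list[str] = []
    for name, value in zip(STATE_NAMES, state):
        if value < 0:
            violations.append(f"{name} = {value} < 0")
    if state[0] > params.R0 * (1 + 1e-12):
        violations.append(f"HR = {state[0]} > R0 = {params.R0}")
    if state[1] > params.GQ_tot * (1 + 1e-12):
        violations.append(f"GQ = {state[1]} > GQ_tot = {params.GQ_tot}")
    return residual, violations


def receptor_equilibrium(params: ParameterSet, G: float) -> float:
    """Closed-form receptor occupancy (uM) under constant GnRH ``G`` (uM).

    HR* = R0 * k1*G / (k1*G + k_minus1); half-occupancy at the receptor Kd
    (k_minus1 / k1 = 1 nM at defaults).
    """
    if G < 0:
        raise ValueError("G must be >= 0")
    denom = params.k1 * G + params.k_minus1
    if denom == 0:
        return 0.0
    return params.R0 * params.k1 * G / denom
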