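"""Compiled fixed-step integrator for the fitting inner loop.

Genetic-algorithm fitting evaluates the model tens of thousands of times, so
the fitness path uses a numba-compiled classical RK4 integrator over the same
segmented right-hand side as :mod:`gnrherk.simulate`.  The receptor equation
is linear given a segment-constant input and is advanced with its exact
exponential solution inside each RK4 substep, which removes the fastest
timescale (k1*G + k_minus1, ~500/min during a maximal pulse) from the
explicit step and lets the remaining nine states integrate stably at
dt ~ 0.02 min.  Agreement with the adaptive reference integrator is covered
by tests; this path is an implementation detail of :mod:`gnrherk.fitting`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import gnrh_input, mek_is_inhibited
from .parameters import PARAM_NAMES, ParameterSet
from .protocols import PulseProtocol
from .simulate import segment_breakpoints

__all__ = ["fast_states", "protocol_plan"]

# indices into the theta vector (PARAM_NAMES order); kept in sync by a test
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


@njit(cache=True)
def _deriv(y, th, G, inh, fb_nuclear):
    """Derivatives of states 1..9 (HR slot returned as 0; handled exactly)."""
    GQ, E = y[1], y[2]
    E_c, pE_c, ppE_c = y[3], y[4], y[5]
    E_n, ppE_n = y[6], y[7]
    TF1, TF1DT = y[8], y[9]
    HR = y[0]

    num = th[14] + th[12] * E
    den = th[14] + th[12] * (th[13] + E)
    ppMEK = th[16] * num / den if den != 0.0 else 0.0

    if inh:
        v1 = 0.0
        v2 = 0.0
    else:
        v1 = th[17] * ppMEK * E_c / (th[22] * (1.0 + pE_c / th[23]) + E_c)
        v2 = th[18] * ppMEK * pE_c / (th[23] * (1.0 + E_c / th[22]) + pE_c)
    v3 = th[19] * th[29] * ppE_c / (th[24] * (1.0 + pE_c / th[25] + E_c / th[26]) + ppE_c)
    v4 = th[20] * th[29] * pE_c / (th[25] * (1.0 + ppE_c / th[24] + E_c / th[26]) + pE_c)
    v5 = th[21] * th[28] * ppE_n / (th[27] + ppE_n)

    fb = ppE_n if fb_nuclear else ppE_c
    C = th[30]

    d = np.zeros(10)
    d[1] = -th[3] * HR * GQ + th[4] * (th[7] - GQ)
    d[2] = th[3] * HR * GQ - th[6] * E - th[5] * fb * E
    d[3] = -v1 + v4 - th[11] * E_c + (th[9] / C) * E_n
    d[4] = v1 - v2 + v3 - v4
    d[5] = v2 - v3 - th[10] * ppE_c + (th[8] / C) * ppE_n
    d[6] = C * th[11] * E_c - th[9] * E_n + v5
    d[7] = C * th[10] * ppE_c - th[8] * ppE_n - v5
    d[8] = th[32] * ppE_n / (th[33] + ppE_n) - th[31] * TF1
    d[9] = th[35] * TF1 / (th[36] + TF1) - th[34] * TF1DT
    return d


@njit(cache=True)
def _integrate(theta, fb_nuclear, y0, cp, seg_G, seg_inh, record, dt):
    """RK4 over checkpoint intervals; exact exponential update for HR.

    cp: checkpoint times (unions of RHS breakpoints and evaluation times);
    seg_G/seg_inh: input value and inhibitor flag on each interval;
    record[i]: whether to store the state at checkpoint i.
    """
    n_out = 0
    for i in range(record.size):
        if record[i]:
            n_out += 1
    out = np.empty((n_out, 10))
    y = y0.copy()
    j = 0
    if record[0]:
        out[0] = y
        j = 1
    for s in range(seg_G.size):
        t0 = cp[s]
        t1 = cp[s + 1]
        G = seg_G[s]
        inh = seg_inh[s] != 0
        b = theta[1] * G + theta[2]
        hr_star = theta[0] * theta[1] * G / b if b > 0.0 else y[0]
        span = t1 - t0
        n = int(np.ceil(span / dt))
        if n < 1:
            n = 1
        h = span / n
        hr0 = y[0]
        for k in range(n):
            tau0 = k * h
            hr_a = hr_star + (hr0 - hr_star) * np.exp(-b * tau0)
            hr_m = hr_star + (hr0 - hr_star) * np.exp(-b * (tau0 + 0.5 * h))
            hr_b = hr_star + (hr0 - hr_star) * np.exp(-b * (tau0 + h))
            y[0] = hr_a
            k1 = _deriv(y, theta, G, inh, fb_nuclear)
            y1 = y + 0.5 * h * k1
            y1[0] = hr_m
            k2 = _deriv(y1, theta, G, inh, fb_nuclear)
            y2 = y + 0.5 * h * k2
            y2[0] = hr_m
            k3 = _deriv(y2, theta, G, inh, fb_nuclear)
            y3 = y + h * k3
            y3[0] = hr_b
            k4 = _deriv(y3, theta, G, inh, fb_nuclear)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            y[0] = hr_b
        if record[s + 1]:
            out[j] = y
            j += 1
    return out


def protocol_plan(
    protocol: PulseProtocol, t_eval: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute checkpoint arrays for a protocol (parameter-independent).

    Returns (checkpoints, seg_G, seg_inh, record, sorted_eval_times).
    """
    t_eval = np.unique(np.asarray(t_eval, dtype=float))
    if t_eval.size == 0:
        raise ValueError("t_eval must be non-empty")
    if t_eval[0] < 0 or t_eval[-1] > protocol.horizon:
        raise ValueError("evaluation times outside [0, horizon]")
    breaks = segment_breakpoints(protocol)
    breaks = breaks[breaks <= t_eval[-1]]
    cp = np.unique(np.concatenate([breaks, t_eval, [0.0]]))
    seg_G = np.array([gnrh_input(t, protocol) for t in cp[:-1]])
    seg_inh = np.array(
        [1 if mek_is_inhibited(t, protocol) else 0 for t in cp[:-1]], dtype=np.uint8
    )
    record = np.isin(cp, t_eval)
    return cp, seg_G, seg_inh, record, t_eval


def fast_states(
    params: ParameterSet,
    protocol: PulseProtocol,
    t_eval: np.ndarray,
    dt: float = 0.02,
    y0: np.ndarray | None = None,
    plan: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """States at the requested times via the compiled fixed-step integrator.

    Returns (sorted unique evaluation times, states array).  ``plan`` may be
    a cached result of :func:`protocol_plan` for the same protocol/t_eval.
    """
    from .model import resting_state

    if plan is None:
        plan = protocol_plan(protocol, np.asarray(t_eval, dtype=float))
    cp, seg_G, seg_inh, record, times = plan
    if y0 is None:
        y0 = resting_state(params)
    theta = params.to_array()
    fb_nuclear = params.feedback_target == "ppE_n"
    states = _integrate(theta, fb_nuclear, np.asarray(y0, float), cp, seg_G, seg_inh, record, dt)
    return times, states
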