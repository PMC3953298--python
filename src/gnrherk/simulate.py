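"""Piecewise ODE integration over pulse protocols.

The square-wave input makes the right-hand side discontinuous in time, but
all discontinuity times (pulse edges, washout, inhibitor addition) are known
a priori, so the trajectory is integrated segment by segment with the input
frozen within each segment and the solver restarted at every edge.  The
default integrator is stiff-capable and adaptive (LSODA, rtol 1e-8 /
atol 1e-10); a fixed-step classical Runge-Kutta integrator over the same
segments (:func:`oracle_simulate`) serves as an independent cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from . import __version__ as _pkg_version
from .model import (
    STATE_NAMES,
    _rhs_core,
    gnrh_input,
    mek_active,
    mek_is_inhibited,
    resting_state,
    erk_conservation_total,
)
from .parameters import ParameterSet
from .protocols import PulseProtocol

__all__ = ["Trajectory", "simulate", "oracle_simulate", "observables", "segment_breakpoints"]

#: Solver undershoot beyond this is treated as an integration failure.
_UNDERSHOOT_TOL = 1e-8


def segment_breakpoints(protocol: PulseProtocol) -> np.ndarray:
    """Sorted times at which the RHS changes discontinuously, incl. 0 and horizon."""
    pts = {0.0, float(protocol.horizon)}
    tw = protocol.washout_time
    if protocol.width < protocol.period:
        k = 0
        while True:
            start = k * protocol.period
            if start >= protocol.horizon:
                break
            if tw is None or start < tw:
                if start > 0:
                    pts.add(start)
                end = start + protocol.width
                if end < protocol.horizon and (tw is None or end < tw):
                    pts.add(end)
            k += 1
    for e in protocol.events:
        if 0 < e.time < protocol.horizon:
            pts.add(float(e.time))
    return np.array(sorted(pts))


def _output_grid(protocol: PulseProtocol, output_step: float) -> np.ndarray:
    if output_step <= 0:
        raise ValueError("output_step must be > 0")
    regular = np.arange(0.0, protocol.horizon, output_step)
    grid = np.unique(np.concatenate([regular, segment_breakpoints(protocol)]))
    return grid


@dataclass(frozen=True)
class Trajectory:
    """Simulated time courses of all species plus derived observables."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 10)
    params: ParameterSet
    protocol: PulseProtocol

    def state(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    @property
    def gnrh(self) -> np.ndarray:
        return np.array([gnrh_input(t, self.protocol) for t in self.t])

    @property
    def ppmek(self) -> np.ndarray:
        E = np.clip(self.state("E"), 0.0, None)
        return np.array([mek_active(e, self.params) for e in E])

    @property
    def pperk_wholecell(self) -> np.ndarray:
        """Whole-cell ppERK: volume-weighted mean of ppE_c and ppE_n (uM)."""
        C = self.params.C_cn
        ppE_c = np.clip(self.state("ppE_c"), 0.0, None)
        ppE_n = np.clip(self.state("ppE_n"), 0.0, None)
        return (C * ppE_c + ppE_n) / (C + 1.0)

    @property
    def nc_erk(self) -> np.ndarray:
        """Nuclear:cytoplasmic ratio of total ERK (the live-cell readout)."""
        num = np.clip(self.state("E_n"), 0.0, None) + np.clip(self.state("ppE_n"), 0.0, None)
        den = (
            np.clip(self.state("E_c"), 0.0, None)
            + np.clip(self.state("pE_c"), 0.0, None)
            + np.clip(self.state("ppE_c"), 0.0, None)
        )
        if np.any(den == 0):
            raise ZeroDivisionError("cytosolic ERK total is zero; N:C undefined")
        return num / den

    def measure(self, name: str) -> np.ndarray:
        """Trajectory of a named response measure (GnRH .. TF1DT)."""
        if name == "GnRH":
            return self.gnrh
        if name == "ppERK":
            return self.pperk_wholecell
        if name == "NC_ERK":
            return self.nc_erk
        if name == "ppMEK":
            return self.ppmek
        return self.state(name)

    def max_conservation_residual(self) -> float:
        totals = (
            self.y[:, 3]
            + self.y[:, 4]
            + self.y[:, 5]
            + (self.y[:, 6] + self.y[:, 7]) / self.params.C_cn
        )
        return float(np.max(np.abs(totals - self.params.ERK_tot)))

    def to_dataframe(self):
        import pandas as pd

        data = {"time_min": self.t}
        for i, name in enumerate(STATE_NAMES):
            data[name] = self.y[:, i]
        data["gnrh"] = self.gnrh
        data["ppmek"] = self.ppmek
        data["pperk_wholecell"] = self.pperk_wholecell
        data["nc_erk"] = self.nc_erk
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "package": "gnrherk",
                "version": _pkg_version,
                "parameters": self.params.to_dict(),
                "feedback_target": self.params.feedback_target,
                "protocol": self.protocol.to_dict(),
            }
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def observables(
    state: np.ndarray, params: ParameterSet
) -> tuple[float, float, float]:
    """(whole-cell ppERK uM, N:C ERK ratio, ppMEK uM) for a single state.

    Whole-cell ppERK is the volume-weighted mean concentration
    (C_cn*ppE_c + ppE_n) / (C_cn + 1); N:C is total nuclear over total
    cytosolic ERK.  Solver undershoot is clipped to zero here (and only
    here, never in state propagation).
    """
    s = np.clip(np.asarray(state, dtype=float), 0.0, None)
    C = params.C_cn
    wholecell = (C * s[5] + s[7]) / (C + 1.0)
    den = s[3] + s[4] + s[5]
    if den == 0:
        raise ZeroDivisionError("cytosolic ERK total is zero; N:C undefined")
    nc = (s[6] + s[7]) / den
    return wholecell, nc, mek_active(s[2], params)


def simulate(
    params: ParameterSet,
    protocol: PulseProtocol,
    output_step: float = 0.5,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over a protocol (deterministic, adaptive, stiff-capable).

    The output grid is ``output_step``-spaced and always includes every pulse
    edge and intervention time.  The initial condition defaults to the
    unstimulated resting state.
    """
    if y0 is None:
        y0 = resting_state(params)
    y0 = np.asarray(y0, dtype=float)
    grid = _output_grid(protocol, output_step)
    breaks = segment_breakpoints(protocol)

    times = [grid[:1]]
    states = [y0[None, :]]
    y = y0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        G = gnrh_input(t0, protocol)
        inh = mek_is_inhibited(t0, protocol)
        t_eval = grid[(grid > t0) & (grid <= t1)]
        sol = solve_ivp(
            lambda t, s: _rhs_core(s, G, inh, params),
            (t0, t1),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if len(t_eval) else None,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed on segment [{t0}, {t1}] min: {sol.message}"
            )
        if len(t_eval):
            times.append(sol.t)
            states.append(sol.y.T)
            y = sol.y[:, -1]
        else:  # degenerate segment shorter than the grid spacing
            y = sol.y[:, -1] if sol.y.size else y

    t = np.concatenate(times)
    Y = np.vstack(states)
    if Y.min() < -_UNDERSHOOT_TOL:
        raise RuntimeError(
            f"state undershoot {Y.min():.3e} exceeds tolerance {-_UNDERSHOOT_TOL:.0e}"
        )
    traj = Trajectory(t=t, y=Y, params=params, protocol=protocol)
    residual = traj.max_conservation_residual()
    if residual > 1e-6:
        raise RuntimeError(
            f"ERK conservation violated: residual {residual:.3e} > 1e-6"
        )
    return traj


def _rk4_step(y: np.ndarray, h: float, G: float, inh: bool, params: ParameterSet) -> np.ndarray:
    k1 = _rhs_core(y, G, inh, params)
    k2 = _rhs_core(y + 0.5 * h * k1, G, inh, params)
    k3 = _rhs_core(y + 0.5 * h * k2, G, inh, params)
    k4 = _rhs_core(y + h * k3, G, inh, params)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def oracle_simulate(
    params: ParameterSet,
    protocol: PulseProtocol,
    step: float = 0.001,
    output_step: float = 0.5,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Fixed-step classical RK4 integration over the same segmented RHS.

    Intended as an independent verification of :func:`simulate` (use a small
    ``step``; the input is frozen per segment exactly as in the adaptive
    path, and output times coincide with :func:`simulate`'s grid so states
    are directly comparable).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if y0 is None:
        y0 = resting_state(params)
    y = np.asarray(y0, dtype=float)
    grid = _output_grid(protocol, output_step)
    out = np.empty((len(grid), 10))
    out[0] = y
    for i, (t0, t1) in enumerate(zip(grid[:-1], grid[1:]), start=1):
        G = gnrh_input(t0, protocol)
        inh = mek_is_inhibited(t0, protocol)
        span = t1 - t0
        n = max(1, int(np.ceil(span / step)))
        h = span / n
        for _ in range(n):
            y = _rk4_step(y, h, G, inh, params)
        out[i] = y
    return Trajectory(t=grid, y=out, params=params, protocol=protocol)
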