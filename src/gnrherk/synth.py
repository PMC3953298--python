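"""Synthetic pseudo-experimental data with the structure of the imaging assays.

Two generators emulate the measurement types the model was trained on:
per-cell nuclear:cytoplasmic ERK2-GFP ratio time courses under pulsatile
GnRH, each trace normalized to its value at time 0, and dose-response
endpoints (integrated N:C response, or the transcript endpoint as a
reporter-gene proxy) normalized to the maximal-dose response.  Noise is
additive i.i.d. Gaussian on the measured quantity; all cells share the
deterministic model signal (the model describes the single-cell average, so
no cell-to-cell parameter variability is simulated).  A fixed seed makes the
output tables byte-identical.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import auc, baselines
from .parameters import ParameterSet
from .protocols import PulseProtocol, build_pulse_train
from .fitting import ObjectiveSet
from .simulate import simulate

__all__ = [
    "generate_nc_traces",
    "generate_dose_response",
    "make_objectives",
    "standard_fit_objectives",
]


def generate_nc_traces(
    params: ParameterSet,
    protocol: PulseProtocol,
    sample_interval: float = 6.0,
    noise_sd: float = 0.05,
    n_cells: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell N:C ERK ratio traces, normalized to the t=0 value.

    Returns a tidy table (cell_id, time_min, value).  Gaussian noise of
    standard deviation ``noise_sd`` (in normalized units) is added per cell
    and time point before the per-trace normalization.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    rng = np.random.default_rng(seed)
    traj = simulate(params, protocol, output_step=min(sample_interval, 0.5))
    grid = np.arange(0.0, protocol.horizon + 1e-9, sample_interval)
    nc = np.interp(grid, traj.t, traj.nc_erk)
    rows = []
    for cell in range(n_cells):
        noisy = nc + noise_sd * rng.standard_normal(len(grid))
        normalized = noisy / noisy[0]
        rows.append(
            pd.DataFrame(
                {"cell_id": cell, "time_min": grid, "value": normalized}
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_dose_response(
    params: ParameterSet,
    doses_molar: Sequence[float],
    width: float = 5.0,
    interval: float = 60.0,
    horizon: float = 480.0,
    observable: str = "nc_erk",
    noise_sd: float = 0.0,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Dose-response endpoints over a set of GnRH concentrations (mol/L).

    ``observable="nc_erk"`` integrates the N:C ratio above its resting
    baseline over the protocol; ``"tf1dt"`` takes the transcript level at
    the end of the protocol (reporter-gene proxy).  With ``normalize`` the
    responses are scaled to the maximal-dose response after noise is added.
    Returns a tidy table (dose_M, value).
    """
    if any(d < 0 for d in doses_molar):
        raise ValueError("doses must be >= 0")
    if observable not in ("nc_erk", "tf1dt"):
        raise ValueError(f"unknown observable {observable!r}")
    rng = np.random.default_rng(seed)
    base = baselines(params)
    responses = []
    for dose in doses_molar:
        if dose == 0:
            responses.append(0.0)
            continue
        protocol = build_pulse_train(dose, width, interval, horizon)
        traj = simulate(params, protocol, output_step=0.25)
        if observable == "nc_erk":
            responses.append(auc(traj.t, traj.nc_erk, base["NC_ERK"]))
        else:
            responses.append(float(traj.state("TF1DT")[-1]))
    values = np.asarray(responses) + noise_sd * rng.standard_normal(len(responses))
    if normalize:
        ref = values[int(np.argmax(doses_molar))]
        if ref == 0:
            raise ZeroDivisionError("maximal-dose response is zero; cannot normalize")
        values = values / ref
    return pd.DataFrame({"dose_M": list(doses_molar), "value": values})


def make_objectives(
    trace_entries: Sequence[tuple[str, PulseProtocol, pd.DataFrame]] = (),
    dose_entries: Sequence[tuple[str, Mapping[float, PulseProtocol], pd.DataFrame]] = (),
    default_weight: float = 1.0,
) -> ObjectiveSet:
    """Adapt synthetic tables into a fitting :class:`ObjectiveSet`.

    ``trace_entries`` are (protocol_id, protocol, table) triples with tables
    from :func:`generate_nc_traces`; replicate cells are averaged per time
    point and, where replicates carry spread, weighted by the inverse squared
    standard error of the mean.  The normalized traces map to the
    ``nc_erk_norm`` observable.

    ``dose_entries`` are (id_prefix, {dose -> protocol}, table) triples with
    (unnormalized) tables from :func:`generate_dose_response` using the
    ``tf1dt`` endpoint observable; each dose becomes its own protocol record
    at the protocol horizon.
    """
    protocols: dict[str, PulseProtocol] = {}
    records = []
    for pid, protocol, table in trace_entries:
        if pid in protocols:
            raise ValueError(f"duplicate protocol id {pid!r}")
        protocols[pid] = protocol
        grouped = table.groupby("time_min")["value"]
        mean = grouped.mean()
        n = grouped.count()
        sd = grouped.std(ddof=1)
        for time, value in mean.items():
            se2 = (sd[time] ** 2 / n[time]) if n[time] > 1 else np.nan
            weight = 1.0 / se2 if np.isfinite(se2) and se2 > 0 else default_weight
            records.append(
                {
                    "protocol_id": pid,
                    "observable": "nc_erk_norm",
                    "time_min": float(time),
                    "value": float(value),
                    "weight": weight,
                }
            )
    for prefix, by_dose, table in dose_entries:
        dose_map = dict(by_dose)
        for _, row in table.iterrows():
            dose = float(row["dose_M"])
            if dose == 0:
                continue  # zero-dose control carries no kinetic information
            if dose not in dose_map:
                raise ValueError(f"no protocol supplied for dose {dose}")
            pid = f"{prefix}:dose={dose:g}"
            if pid in protocols:
                raise ValueError(f"duplicate protocol id {pid!r}")
            protocols[pid] = dose_map[dose]
            records.append(
                {
                    "protocol_id": pid,
                    "observable": "tf1dt",
                    "time_min": float(dose_map[dose].horizon),
                    "value": float(row["value"]),
                    "weight": default_weight,
                }
            )
    if not records:
        raise ValueError("no objective records produced")
    return ObjectiveSet(protocols, pd.DataFrame(records))


def standard_fit_objectives(
    params: ParameterSet,
    noise_sd: float = 0.0,
    n_cells: int = 1,
    seed: int = 0,
    trace_horizon: float = 60.0,
    sample_interval: float = 3.0,
    doses_molar: Sequence[float] = (1e-11, 1e-10, 1e-9, 1e-8, 1e-7),
) -> ObjectiveSet:
    """Objective set covering the three stimulation regimes plus a dose-response.

    Mirrors the data the model was trained on: N:C ERK traces for a 1-min
    pulse, a 10-min pulse, and constant stimulation with maximal (1e-7 M)
    GnRH, plus transcript endpoints for single 5-min pulses across a dose
    range.  Dose-response records are weighted by the inverse square of the
    maximal endpoint so both data types contribute on a comparable scale.
    """
    from .protocols import single_pulse

    amplitude = 1e-7
    trace_protocols = {
        "pulse_1min": single_pulse(amplitude, 1.0, trace_horizon, "washout"),
        "pulse_10min": single_pulse(amplitude, 10.0, trace_horizon, "washout"),
        "constant": build_pulse_train(amplitude, trace_horizon, trace_horizon, trace_horizon),
    }
    trace_entries = []
    for i, (pid, protocol) in enumerate(trace_protocols.items()):
        table = generate_nc_traces(
            params,
            protocol,
            sample_interval=sample_interval,
            noise_sd=noise_sd,
            n_cells=n_cells,
            seed=seed + i,
        )
        trace_entries.append((pid, protocol, table))

    dose_width, dose_interval, dose_horizon = 5.0, 60.0, 60.0
    dose_table = generate_dose_response(
        params,
        doses_molar,
        width=dose_width,
        interval=dose_interval,
        horizon=dose_horizon,
        observable="tf1dt",
        noise_sd=noise_sd,
        seed=seed + len(trace_entries),
        normalize=False,
    )
    dose_protocols = {
        float(d): build_pulse_train(d, dose_width, dose_interval, dose_horizon)
        for d in doses_molar
        if d > 0
    }
    objectives = make_objectives(
        trace_entries=trace_entries,
        dose_entries=[("dose_response", dose_protocols, dose_table)],
    )
    # rescale dose-record weights so endpoint residuals (uM-scale transcript
    # levels) weigh comparably to the order-one normalized N:C residuals
    rec = objectives.records
    dose_mask = rec["observable"] == "tf1dt"
    ref = rec.loc[dose_mask, "value"].abs().max()
    if ref > 0:
        rec.loc[dose_mask, "weight"] = 1.0 / ref**2
    return objectives
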