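"""Integrated-response (area-under-curve) analyses of pulse protocols.

The comparison currency across stimulation protocols is the time integral of
each response measure above its pre-stimulus resting baseline.  Measures run
down the cascade: GnRH input, receptor occupancy (HR), active effector (E),
whole-cell ppERK, the nuclear:cytoplasmic ERK ratio, active transcription
factor (TF1), and the TF1-dependent transcript (TF1DT).  Frequency-response
and width-response tables, the post-pulse ppERK fraction, the
frequency-vs-width sensitivity ratio, and the inhibitor/washout termination
ratio are the quantitative summaries used throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import resting_state
from .parameters import ParameterSet
from .protocols import PulseProtocol, build_pulse_train, single_pulse
from .simulate import Trajectory, observables, simulate

__all__ = [
    "MEASURES",
    "auc",
    "baselines",
    "frequency_response",
    "width_response",
    "integrated_hr",
    "post_pulse_fraction",
    "sensitivity_gradient_ratio",
    "termination_ratio",
]

#: Response measures, ordered from input to transcriptional output.
MEASURES: tuple[str, ...] = ("GnRH", "HR", "E", "ppERK", "NC_ERK", "TF1", "TF1DT")

_TABLE_COLUMNS = [
    "measure",
    "width_min",
    "interval_min",
    "amplitude_uM",
    "R0_uM",
    "frequency_per_h",
    "auc",
    "auc_normalized",
]


def auc(t: Sequence[float], values: Sequence[float], baseline: float = 0.0) -> float:
    """Trapezoidal integral of (value - baseline) over time.

    The deviation is integrated signed, without clipping: model trajectories
    do not undershoot their resting baseline, so a negative contribution
    indicates a bug rather than a feature to be masked.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or len(t) < 2 or len(t) != len(v):
        raise ValueError("need >= 2 (time, value) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v - baseline, t))


def baselines(params: ParameterSet) -> dict[str, float]:
    """Pre-stimulus resting value of every measure."""
    rest = resting_state(params)
    wholecell, nc, ppmek = observables(rest, params)
    return {
        "GnRH": 0.0,
        "HR": 0.0,
        "E": 0.0,
        "ppERK": wholecell,
        "NC_ERK": nc,
        "TF1": 0.0,
        "TF1DT": 0.0,
    }


def _integrated_responses(
    params: ParameterSet,
    width: float,
    interval: float,
    amplitude_uM: float,
    horizon: float,
    output_step: float,
) -> dict[str, float]:
    protocol = PulseProtocol(p=amplitude_uM, period=interval, width=width, horizon=horizon)
    traj = simulate(params, protocol, output_step=output_step)
    base = baselines(params)
    return {m: auc(traj.t, traj.measure(m), base[m]) for m in MEASURES}


def _response_table(
    params: ParameterSet,
    combos: Iterable[tuple[float, float]],
    amplitude_uM: float,
    horizon: float,
    output_step: float,
) -> pd.DataFrame:
    rows = []
    for width, interval in combos:
        integrals = _integrated_responses(
            params, width, interval, amplitude_uM, horizon, output_step
        )
        for m in MEASURES:
            rows.append(
                {
                    "measure": m,
                    "width_min": width,
                    "interval_min": interval,
                    "amplitude_uM": amplitude_uM,
                    "R0_uM": params.R0,
                    "frequency_per_h": 60.0 / interval,
                    "auc": integrals[m],
                }
            )
    table = pd.DataFrame(rows)
    # normalization reference: highest duty cycle (constant stimulation when
    # the interval == width combination is included)
    duty = table["width_min"] / table["interval_min"]
    ref_idx = duty.idxmax()
    ref_w, ref_i = table.loc[ref_idx, ["width_min", "interval_min"]]
    ref = table[(table["width_min"] == ref_w) & (table["interval_min"] == ref_i)]
    ref_by_measure = ref.set_index("measure")["auc"]
    table["auc_normalized"] = table.apply(
        lambda r: r["auc"] / ref_by_measure[r["measure"]]
        if ref_by_measure[r["measure"]] != 0
        else np.nan,
        axis=1,
    )
    return table[_TABLE_COLUMNS]


def frequency_response(
    params: ParameterSet,
    width: float = 1.0,
    intervals: Sequence[float] | None = None,
    amplitude_uM: float = 0.1,
    horizon: float = 480.0,
    output_step: float = 0.25,
) -> pd.DataFrame:
    """Integrated responses of all measures at fixed width, varied interval.

    The default interval grid includes the constant-stimulation limit
    (interval == width), which is the maximal-frequency normalization
    reference; frequency is reported in pulses/h.
    """
    if intervals is None:
        intervals = [width] + [x for x in (15, 30, 45, 60, 90, 120, 240) if x >= width]
    intervals = list(intervals)
    if any(i < width for i in intervals):
        raise ValueError("all intervals must be >= width")
    return _response_table(
        params, [(width, i) for i in intervals], amplitude_uM, horizon, output_step
    )


def width_response(
    params: ParameterSet,
    widths: Sequence[float],
    interval: float = 60.0,
    amplitude_uM: float = 0.1,
    horizon: float = 480.0,
    output_step: float = 0.25,
) -> pd.DataFrame:
    """Integrated responses at fixed interval, varied pulse width."""
    widths = list(widths)
    if any(w > interval for w in widths):
        raise ValueError("all widths must be <= interval")
    return _response_table(
        params, [(w, interval) for w in widths], amplitude_uM, horizon, output_step
    )


def integrated_hr(
    params: ParameterSet,
    protocol: PulseProtocol,
    output_step: float = 0.25,
) -> float:
    """Integrated receptor occupancy (uM*min) over the protocol."""
    traj = simulate(params, protocol, output_step=output_step)
    return auc(traj.t, traj.state("HR"), 0.0)


def post_pulse_fraction(
    params: ParameterSet,
    width: float = 1.0,
    amplitude_molar: float = 1e-7,
    horizon: float = 30.0,
    output_step: float = 0.05,
) -> float:
    """Fraction of the integrated whole-cell ppERK response occurring after
    a single washout-terminated pulse ends.

    The numerator integrates ppERK over [width, horizon], the denominator
    over [0, horizon]; slow MEK inactivation after the pulse makes this
    fraction large for short pulses.
    """
    if not width < horizon:
        raise ValueError("width must be < horizon")
    protocol = single_pulse(amplitude_molar, width, horizon, termination="washout")
    traj = simulate(params, protocol, output_step=output_step)
    pperk = traj.pperk_wholecell
    total = auc(traj.t, pperk, 0.0)
    if total <= 0:
        raise ZeroDivisionError("total integrated ppERK response is zero")
    mask = traj.t >= width
    post = auc(traj.t[mask], pperk[mask], 0.0)
    return post / total


def sensitivity_gradient_ratio(
    params: ParameterSet,
    measure: str = "ppERK",
    base_width: float = 5.0,
    base_interval: float = 60.0,
    amplitude_uM: float = 0.1,
    horizon: float = 480.0,
    output_step: float = 0.25,
    rel_step: float = 0.1,
) -> float:
    """Ratio of d(integrated measure)/d(integrated HR) along the
    varied-frequency axis to the same gradient along the varied-width axis.

    Both gradients are central differences with +/-``rel_step`` relative
    perturbation of the interval (frequency axis) or the width (width axis)
    around the base protocol.  A ratio near 1 means the measure responds to
    integrated receptor occupancy identically however occupancy is
    controlled; a ratio > 1 means greater sensitivity to pulse frequency
    than to pulse width.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")

    def point(width: float, interval: float) -> tuple[float, float]:
        integrals = _integrated_responses(
            params, width, interval, amplitude_uM, horizon, output_step
        )
        return integrals["HR"], integrals[measure]

    hr_f1, m_f1 = point(base_width, base_interval * (1 - rel_step))
    hr_f2, m_f2 = point(base_width, base_interval * (1 + rel_step))
    hr_w1, m_w1 = point(base_width * (1 - rel_step), base_interval)
    hr_w2, m_w2 = point(base_width * (1 + rel_step), base_interval)

    if hr_f1 == hr_f2 or hr_w1 == hr_w2:
        raise ZeroDivisionError("degenerate HR perturbation")
    grad_freq = (m_f1 - m_f2) / (hr_f1 - hr_f2)
    grad_width = (m_w2 - m_w1) / (hr_w2 - hr_w1)
    if grad_width == 0:
        raise ZeroDivisionError("zero width-axis gradient")
    return grad_freq / grad_width


def termination_ratio(
    params: ParameterSet,
    widths: Sequence[float] = (1, 5, 15, 30, 60),
    amplitude_molar: float = 1e-7,
    total_time: float = 360.0,
    output_step: float = 0.25,
) -> pd.DataFrame:
    """Transcript level after MEK-inhibitor termination relative to washout.

    For each pulse width, a single pulse is terminated either by washing out
    GnRH or by blocking MEK; the ratio of the transcript (TF1DT) levels at
    ``total_time`` quantifies how much of the transcriptional output depends
    on ERK activity continuing after the pulse (ratio < 1 for short pulses,
    approaching 1 as the pulse lengthens).
    """
    rows = []
    for width in widths:
        if width > total_time:
            raise ValueError(f"width {width} exceeds total time {total_time}")
        if width == total_time:
            # no post-pulse period: both terminations are the same protocol
            rows.append(
                {"width_min": width, "tf1dt_washout": np.nan, "tf1dt_mek_inhibition": np.nan, "ratio": 1.0}
            )
            continue
        endpoints = {}
        for term in ("washout", "mek_inhibition"):
            protocol = single_pulse(amplitude_molar, width, total_time, termination=term)
            traj = simulate(params, protocol, output_step=output_step)
            endpoints[term] = float(traj.state("TF1DT")[-1])
        if endpoints["washout"] == 0:
            raise ZeroDivisionError(f"zero washout TF1DT endpoint at width {width}")
        rows.append(
            {
                "width_min": width,
                "tf1dt_washout": endpoints["washout"],
                "tf1dt_mek_inhibition": endpoints["mek_inhibition"],
                "ratio": endpoints["mek_inhibition"] / endpoints["washout"],
            }
        )
    return pd.DataFrame(rows)
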