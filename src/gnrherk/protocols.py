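"""Square-wave GnRH stimulation protocols and intervention events.

The hormone input is a square-wave pulse train: amplitude ``p`` (uM), period
``period`` (min), pulse width ``width`` (min), applied over ``horizon`` min.
Pulses occupy the half-open windows [k*period, k*period + width).  Two
interventions can terminate signaling mid-protocol:

* ``washout`` — GnRH is removed instantaneously; the input is 0 from the
  event time onward.
* ``mek_inhibition`` — MEK catalysis is blocked completely and irreversibly
  (the ERK phosphorylation fluxes are forced to zero) while GnRH and the
  upstream species keep evolving; this is the model counterpart of adding a
  saturating dose of the MEK inhibitor PD184352.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "InterventionEvent",
    "PulseProtocol",
    "build_pulse_train",
    "single_pulse",
    "receptor_sites_to_R0",
    "MOLAR_TO_UM",
]

#: Conversion factor mol/L -> uM.
MOLAR_TO_UM = 1.0e6

_EVENT_KINDS = ("washout", "mek_inhibition")


@dataclass(frozen=True)
class InterventionEvent:
    """A discrete intervention applied from ``time`` (min) onward."""

    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"event kind must be one of {_EVENT_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class PulseProtocol:
    """Square-wave GnRH pulse train with optional interventions.

    Parameters
    ----------
    p : pulse amplitude, uM GnRH.
    period : pulse period (interval between pulse onsets), min.
    width : pulse duration, min; ``width == period`` encodes constant
        stimulation.
    horizon : total simulated time, min.
    events : intervention events, sorted by time, at most one of each kind.
    """

    p: float
    period: float
    width: float
    horizon: float
    events: tuple[InterventionEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"pulse amplitude must be >= 0, got {self.p}")
        if not 0 < self.width <= self.period:
            raise ValueError(
                f"need 0 < width <= period, got width={self.width}, period={self.period}"
            )
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        events = tuple(sorted(self.events, key=lambda e: e.time))
        kinds = [e.kind for e in events]
        if len(kinds) != len(set(kinds)):
            raise ValueError("at most one event of each kind is allowed")
        for e in events:
            if not 0 <= e.time <= self.horizon:
                raise ValueError(f"event at t={e.time} outside [0, {self.horizon}]")
        object.__setattr__(self, "events", events)

    @property
    def washout_time(self) -> float | None:
        for e in self.events:
            if e.kind == "washout":
                return e.time
        return None

    @property
    def mek_inhibition_time(self) -> float | None:
        for e in self.events:
            if e.kind == "mek_inhibition":
                return e.time
        return None

    def to_dict(self) -> dict:
        return {
            "p_uM": self.p,
            "period_min": self.period,
            "width_min": self.width,
            "horizon_min": self.horizon,
            "events": [{"time_min": e.time, "kind": e.kind} for e in self.events],
        }


def build_pulse_train(
    amplitude_molar: float,
    width: float,
    interval: float,
    horizon: float | None = None,
) -> PulseProtocol:
    """Pulse train of ``width``-min pulses every ``interval`` min.

    ``amplitude_molar`` is the GnRH concentration in mol/L (e.g. 1e-7 for the
    maximal dose used throughout); ``interval == width`` gives constant
    stimulation.  ``horizon`` defaults to one period.
    """
    if amplitude_molar < 0:
        raise ValueError("amplitude must be >= 0")
    if not 0 < width <= interval:
        raise ValueError(f"need 0 < width <= interval, got {width} > {interval}")
    if horizon is None:
        horizon = interval
    if horizon < interval:
        raise ValueError(f"horizon {horizon} shorter than one interval {interval}")
    return PulseProtocol(
        p=amplitude_molar * MOLAR_TO_UM, period=interval, width=width, horizon=horizon
    )


def single_pulse(
    amplitude_molar: float,
    width: float,
    horizon: float,
    termination: str = "washout",
) -> PulseProtocol:
    """One pulse starting at t=0, terminated by washout or MEK inhibition.

    With ``termination="washout"`` the input is a one-pulse square wave (GnRH
    removed at ``width``).  With ``"mek_inhibition"`` GnRH stays on for the
    full square-wave pulse but ERK phosphorylation is blocked from ``width``
    onward — the inhibitor does not remove the ligand.
    """
    if not width < horizon:
        raise ValueError(f"width {width} must be < horizon {horizon}")
    if termination not in ("washout", "mek_inhibition"):
        raise ValueError(f"unknown termination {termination!r}")
    event = InterventionEvent(time=width, kind=termination)
    # period = horizon so exactly one pulse occurs in [0, width)
    return PulseProtocol(
        p=amplitude_molar * MOLAR_TO_UM,
        period=horizon,
        width=width,
        horizon=horizon,
        events=(event,),
    )


def receptor_sites_to_R0(sites_per_cell: float) -> float:
    """Map cell-surface receptor number to total receptor concentration (uM).

    Linear map anchored at the default-expression condition: 80,000
    sites/cell corresponds to R0 = 0.1 uM.
    """
    if sites_per_cell <= 0:
        raise ValueError("sites_per_cell must be > 0")
    return 0.1 * sites_per_cell / 80_000.0
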