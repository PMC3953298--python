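"""Strict YAML/JSON configuration for parameters, protocols and run options."""

from __future__ import annotations

from pathlib import Path

import yaml

from .parameters import PARAM_NAMES, ParameterSet
from .protocols import InterventionEvent, PulseProtocol, build_pulse_train, single_pulse

__all__ = ["load_config", "save_config"]

_TOP_KEYS = {"parameters", "protocol", "options"}
_PROTOCOL_KEYS = {"amplitude_molar", "width_min", "interval_min", "horizon_min", "terminate"}
_OPTION_KEYS = {"output_step_min", "seed", "outdir"}
_TERMINATE = {"wash": "washout", "mek": "mek_inhibition"}


def load_config(path: str | Path) -> tuple[ParameterSet, PulseProtocol | None, dict]:
    """Parse a config file into (parameters, protocol, options).

    The parameter block is a flat key -> value mapping using the model's
    parameter symbols; unknown keys are rejected with the offending key
    named, and an empty or absent block yields the default parameter set.
    The protocol block, if present, describes a pulse train
    (amplitude_molar, width_min, interval_min, horizon_min) or a terminated
    single pulse (terminate: wash | mek, no interval).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    pblock = raw.get("parameters") or {}
    if not isinstance(pblock, dict):
        raise ValueError("'parameters' must be a mapping")
    bad = set(pblock) - set(PARAM_NAMES) - {"feedback_target"}
    if bad:
        raise ValueError(f"unknown parameter keys: {sorted(bad)}")
    for key, value in pblock.items():
        if key != "feedback_target" and not isinstance(value, (int, float)):
            raise ValueError(f"parameter {key!r} must be numeric, got {value!r}")
    params = ParameterSet(**pblock)

    protocol = None
    if "protocol" in raw and raw["protocol"] is not None:
        block = raw["protocol"]
        if not isinstance(block, dict):
            raise ValueError("'protocol' must be a mapping")
        bad = set(block) - _PROTOCOL_KEYS
        if bad:
            raise ValueError(f"unknown protocol keys: {sorted(bad)}")
        for key in ("amplitude_molar", "width_min", "horizon_min"):
            if key not in block:
                raise ValueError(f"protocol block missing required key {key!r}")
        terminate = block.get("terminate")
        if terminate is not None:
            if terminate not in _TERMINATE:
                raise ValueError(f"terminate must be one of {sorted(_TERMINATE)}")
            protocol = single_pulse(
                block["amplitude_molar"],
                block["width_min"],
                block["horizon_min"],
                termination=_TERMINATE[terminate],
            )
        else:
            if "interval_min" not in block:
                raise ValueError("pulse-train protocol requires 'interval_min'")
            protocol = build_pulse_train(
                block["amplitude_molar"],
                block["width_min"],
                block["interval_min"],
                block["horizon_min"],
            )

    options = raw.get("options") or {}
    if not isinstance(options, dict):
        raise ValueError("'options' must be a mapping")
    bad = set(options) - _OPTION_KEYS
    if bad:
        raise ValueError(f"unknown option keys: {sorted(bad)}")
    return params, protocol, dict(options)


def save_config(
    path: str | Path,
    params: ParameterSet,
    protocol: PulseProtocol | None = None,
    options: dict | None = None,
) -> None:
    """Write a config file that :func:`load_config` round-trips exactly."""
    doc: dict = {"parameters": params.to_dict()}
    doc["parameters"]["feedback_target"] = params.feedback_target
    if protocol is not None:
        block = {
            "amplitude_molar": protocol.p / 1e6,
            "width_min": protocol.width,
            "horizon_min": protocol.horizon,
        }
        tw, tm = protocol.washout_time, protocol.mek_inhibition_time
        if tm is not None:
            block["terminate"] = "mek"
        elif tw is not None and tw == protocol.width:
            block["terminate"] = "wash"
        else:
            block["interval_min"] = protocol.period
        doc["protocol"] = block
    if options:
        doc["options"] = options
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
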