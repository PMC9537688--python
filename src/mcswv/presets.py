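"""Packaged waveform presets and config-file loading.

The dopamine (M-CSWV) preset carries the published analysis constants:
square-wave half-amplitude 0.4 V, staircase increment 0.025 V, 1 ms pulse,
2 ms gap, 5 CSWs per scan, 10 s repetition period (0.1 Hz), 2 MHz
sampling.  Its staircase envelope (``e_initial``, ``e_peak``,
``e_holding``) is a PLACEHOLDER: the validated envelope values are
published elsewhere and electrode-dependent, so users must set them for
their own electrodes.  The serotonin (N-MCSWV) preset likewise ships with
a placeholder envelope.

Presets and user configs are plain YAML/JSON mappings whose keys are
exactly the :class:`~mcswv.waveform.WaveformSpec` field names in SI units.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .simulate import ElectrodeModel, SessionPlan
from .waveform import TriggerSpec, WaveformSpec

__all__ = [
    "PRESETS",
    "get_preset",
    "load_waveform_config",
    "load_trigger_config",
    "load_model_config",
    "load_plan_config",
]

# Published constants; envelope entries marked placeholder are
# user-settable and NOT validated values.
PRESETS: dict[str, dict[str, Any]] = {
    "dopamine-mcswv": {
        "e_holding": -0.2,  # placeholder — set for your electrode
        "e_initial": -0.2,  # placeholder — set for your electrode
        "e_peak": 0.6,  # placeholder — set for your electrode
        "e_sw": 0.4,
        "e_staircase": 0.025,
        "tau_pulse": 1e-3,
        "gap": 2e-3,
        "csw_n": 5,
        "repetition_period": 10.0,
        "sample_rate": 2e6,
    },
    "serotonin-nmcswv": {
        "e_holding": 0.2,  # placeholder — set for your electrode
        "e_initial": 0.2,  # placeholder — set for your electrode
        "e_peak": 1.0,  # placeholder — set for your electrode
        "e_sw": 0.4,
        "e_staircase": 0.025,
        "tau_pulse": 1e-3,
        "gap": 2e-3,
        "csw_n": 5,
        "repetition_period": 10.0,
        "sample_rate": 2e6,
    },
}

PLACEHOLDER_FIELDS = ("e_holding", "e_initial", "e_peak")


def demo_spec(sample_rate: float = 1e5) -> WaveformSpec:
    """Reduced-rate demonstration waveform used by examples and the
    simulation studies.

    Same published square-wave parameters as the dopamine preset (E_sw
    0.4 V, staircase 0.025 V, 1 ms pulse, 2 ms gap, 5 CSWs, 10 s period)
    over a 33-step staircase (-0.1 -> +0.3 V), sampled at 100 kHz so a
    full session simulates in seconds while every per-phase transient is
    still resolved by 50 samples.
    """
    return WaveformSpec(
        e_holding=-0.15,
        e_initial=-0.1,
        e_peak=0.3,
        e_sw=0.4,
        e_staircase=0.025,
        tau_pulse=1e-3,
        gap=2e-3,
        csw_n=5,
        repetition_period=10.0,
        sample_rate=sample_rate,
    )


def get_preset(name: str, **overrides: Any) -> WaveformSpec:
    """Build a WaveformSpec from a named preset, with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = {**PRESETS[name], **overrides}
    return WaveformSpec(**cfg)


def _load_mapping(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of field names")
    return data


def load_waveform_config(path: str | Path) -> WaveformSpec:
    return WaveformSpec(**_load_mapping(path))


def load_trigger_config(path: str | Path) -> TriggerSpec:
    return TriggerSpec(**_load_mapping(path))


def load_model_config(path: str | Path) -> ElectrodeModel:
    return ElectrodeModel(**_load_mapping(path))


def load_plan_config(path: str | Path) -> SessionPlan:
    data = _load_mapping(path)
    if "concentration_per_scan" in data:
        return SessionPlan(tuple(data["concentration_per_scan"]))
    if {"pre", "post", "n_pre", "n_post"} <= set(data):
        return SessionPlan.step(
            data["pre"], data["post"], data["n_pre"], data["n_post"]
        )
    if {"concentration", "n_scans"} <= set(data):
        return SessionPlan.constant(data["concentration"], data["n_scans"])
    raise ValueError(
        "plan config needs concentration_per_scan, or pre/post/n_pre/n_post, "
        "or concentration/n_scans"
    )
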