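"""Shared fixtures: small waveform specs and simulator configurations.

Unit tests run on a tiny 9-step staircase at 100 kHz so a scan is ~5k
samples; session-level studies use the packaged 33-step demo spec.
"""

from __future__ import annotations

import numpy as np
import pytest

from mcswv import ElectrodeModel, WaveformSpec, render_waveform
from mcswv.presets import demo_spec


@pytest.fixture(scope="session")
def tiny_spec() -> WaveformSpec:
    """9-step staircase, 5 CSWs, 100 kHz: 5,300 samples per scan."""
    return WaveformSpec(
        e_holding=-0.05,
        e_initial=0.0,
        e_peak=0.1,
        e_sw=0.4,
        e_staircase=0.025,
        tau_pulse=1e-3,
        gap=2e-3,
        csw_n=5,
        repetition_period=10.0,
        sample_rate=1e5,
    )


@pytest.fixture(scope="session")
def tiny_wf(tiny_spec):
    return render_waveform(tiny_spec)


@pytest.fixture(scope="session")
def study_spec() -> WaveformSpec:
    """The 33-step reduced-rate spec used for session-level studies."""
    return demo_spec()


@pytest.fixture(scope="session")
def study_wf(study_spec):
    return render_waveform(study_spec)


@pytest.fixture
def quiet_model() -> ElectrodeModel:
    """Noiseless, drift-free electrode for closed-form checks."""
    return ElectrodeModel(noise_sd=0.0, broadband_noise_sd=0.0, drift_rate=0.0)


@pytest.fixture
def noisy_model() -> ElectrodeModel:
    """The default study-condition electrode (quantization-floor noise,
    sub-nA broadband contamination, 0.1%/scan drift)."""
    return ElectrodeModel(seed=11)
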