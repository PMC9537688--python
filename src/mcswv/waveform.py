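"""Cyclic-square-wave (CSW) waveform and trigger synthesis.

A CSW scan applies ``csw_n`` cyclic square waves back to back.  Each CSW is
a staircase sweep from ``e_initial`` up to ``e_peak`` and back down, with a
square wave of half-amplitude ``e_sw`` superimposed on every staircase step:
the electrode is driven to ``step + e_sw`` for the anodic half of the pulse
and to ``step - e_sw`` for the cathodic half.  Between successive CSWs the
electrode rests at the holding potential ``e_holding`` for ``gap`` seconds.
Scans repeat every ``repetition_period`` seconds (0.1 Hz by default), which
is what makes tonic — as opposed to phasic — concentration tracking
possible: the late CSWs of each scan deplete the adsorbed analyte and serve
as a within-scan background for the early ones.

This module is purely geometric: it turns parameter sets into sampled
voltage traces with per-sample segment labels, and schedules/validates
external-device trigger pulses against them.  Nothing here touches current
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

import numpy as np

__all__ = [
    "WaveformSpec",
    "SampledWaveform",
    "TriggerSpec",
    "PHASE_ANODIC",
    "PHASE_CATHODIC",
    "PHASE_GAP",
    "build_staircase_schedule",
    "render_waveform",
    "render_trigger",
    "check_no_overlap",
]

# Integer phase codes used in SampledWaveform.phase.
PHASE_ANODIC = 0
PHASE_CATHODIC = 1
PHASE_GAP = 2

_STEP_TOL = 1e-9  # volts; tolerance for the staircase divisibility check


@dataclass(frozen=True)
class WaveformSpec:
    """Complete parameterization of a multi-CSW scan waveform.

    Parameters
    ----------
    e_holding : float
        Holding potential between CSWs and between scans, in volts.
    e_sw : float
        Square-wave half-amplitude in volts (the anodic phase sits at
        ``step + e_sw``, the cathodic at ``step - e_sw``).
    e_staircase : float
        Potential increment between successive staircase steps, volts.
    e_peak : float
        Turning-point (maximum) staircase potential, volts.
    e_initial : float
        First staircase potential of each CSW, volts.
    tau_pulse : float
        Duration of one full square wave (anodic + cathodic), seconds.
        With ``tau_convention="full-cycle"`` (default) each phase lasts
        ``tau_pulse / 2``; with ``"per-phase"`` each phase lasts
        ``tau_pulse``.
    gap : float
        Holding time between successive CSWs, seconds.
    csw_n : int
        Number of CSWs per scan.
    repetition_period : float
        Scan-to-scan period in seconds (10 s, i.e. 0.1 Hz, by default).
    sample_rate : float
        DAC/ADC sample rate in Hz.
    tau_convention : str
        ``"full-cycle"`` or ``"per-phase"``; see ``tau_pulse``.
    emit_peak_twice : bool
        If True the turning-point step appears twice in the staircase
        (up-sweep and down-sweep); default False emits it once, like the
        apex of a triangle wave.
    """

    e_holding: float = 0.0
    e_sw: float = 0.4
    e_staircase: float = 0.025
    e_peak: float = 0.1
    e_initial: float = 0.0
    tau_pulse: float = 1e-3
    gap: float = 2e-3
    csw_n: int = 5
    repetition_period: float = 10.0
    sample_rate: float = 2e6
    tau_convention: Literal["full-cycle", "per-phase"] = "full-cycle"
    emit_peak_twice: bool = False

    def __post_init__(self) -> None:
        if self.e_initial > self.e_peak:
            raise ValueError(
                f"e_initial ({self.e_initial} V) must not exceed "
                f"e_peak ({self.e_peak} V)"
            )
        if self.e_staircase <= 0:
            raise ValueError("e_staircase must be > 0")
        if self.tau_pulse <= 0:
            raise ValueError("tau_pulse must be > 0")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.csw_n < 1:
            raise ValueError("csw_n must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        span = self.e_peak - self.e_initial
        n = round(span / self.e_staircase)
        residual = abs(span - n * self.e_staircase)
        if residual > _STEP_TOL:
            raise ValueError(
                "(e_peak - e_initial) must be an integer multiple of "
                f"e_staircase; residual {residual:.3e} V exceeds "
                f"{_STEP_TOL:.0e} V"
            )
        if self.repetition_period < self.duration:
            raise ValueError(
                f"repetition_period ({self.repetition_period} s) is shorter "
                f"than the waveform duration ({self.duration:.6g} s)"
            )

    @property
    def phase_duration(self) -> float:
        """Duration of one square-wave phase (anodic or cathodic), s."""
        if self.tau_convention == "full-cycle":
            return self.tau_pulse / 2.0
        return self.tau_pulse

    @property
    def n_up(self) -> int:
        """Number of up-sweep increments between e_initial and e_peak."""
        return round((self.e_peak - self.e_initial) / self.e_staircase)

    @property
    def n_steps(self) -> int:
        """Steps per CSW (forward sweep + reverse sweep, peak once/twice)."""
        n = 2 * self.n_up + 1
        if self.emit_peak_twice and self.n_up > 0:
            n += 1
        return n

    @property
    def duration(self) -> float:
        """Total scan waveform duration in seconds (gaps between CSWs only)."""
        csw = self.n_steps * 2 * self.phase_duration
        return self.csw_n * csw + (self.csw_n - 1) * self.gap


@dataclass
class SampledWaveform:
    """A rendered waveform with per-sample segment labels.

    Attributes
    ----------
    voltages : ndarray of float
        Applied potential per sample, volts.
    sample_rate : float
        Samples per second.
    csw_index : ndarray of int
        1-based CSW number per sample; 0 during gaps.
    step_index : ndarray of int
        1-based staircase step number per sample; 0 during gaps.
    phase : ndarray of int
        ``PHASE_ANODIC``, ``PHASE_CATHODIC`` or ``PHASE_GAP`` per sample.
    spec : WaveformSpec
        The generating spec.
    """

    voltages: np.ndarray
    sample_rate: float
    csw_index: np.ndarray
    step_index: np.ndarray
    phase: np.ndarray
    spec: WaveformSpec

    def __len__(self) -> int:
        return self.voltages.size

    @property
    def duration(self) -> float:
        return self.voltages.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltages.size) / self.sample_rate


@dataclass(frozen=True)
class TriggerSpec:
    """Rectangular trigger-pulse train for gating external devices."""

    amplitude: float = 5.0
    pulse_duration: float = 1e-3
    start_time: float = 0.0
    interpulse_interval: float = 0.0
    n_pulses: int = 0

    def __post_init__(self) -> None:
        for name in ("pulse_duration", "start_time", "interpulse_interval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")

    @property
    def end_time(self) -> float:
        """Time at which the last pulse (including its tail interval) ends."""
        if self.n_pulses == 0:
            return self.start_time
        return self.start_time + self.n_pulses * (
            self.pulse_duration + self.interpulse_interval
        )


def build_staircase_schedule(spec: WaveformSpec) -> np.ndarray:
    """Ordered staircase step potentials for one CSW.

    Forward sweep ``e_initial -> e_peak`` in increments of ``e_staircase``,
    then reverse back to ``e_initial``.  By default the turning-point step
    is emitted once, so the schedule has ``2 * n_up + 1`` entries.
    """
    up = spec.e_initial + spec.e_staircase * np.arange(spec.n_up + 1)
    up[-1] = spec.e_peak  # exact, avoids float accumulation
    if spec.n_up == 0:
        return up
    down = up[::-1] if spec.emit_peak_twice else up[-2::-1]
    return np.concatenate([up, down])


def render_waveform(spec: WaveformSpec) -> SampledWaveform:
    """Render a spec to a sampled voltage trace with segment labels.

    Phase boundaries are accumulated in exact rational seconds and snapped
    to the nearest sample, so no rounding drift accrues over a scan.  The
    rendered trace spans the active scan only (CSWs and inter-CSW gaps);
    the idle remainder of the repetition period is not materialized.
    """
    phase_dur = Fraction(spec.phase_duration).limit_denominator(10**12)
    gap_dur = Fraction(spec.gap).limit_denominator(10**12)
    rate = Fraction(spec.sample_rate).limit_denominator(10**12)

    n_phase_samples = round(phase_dur * rate)
    if n_phase_samples < 2:
        raise ValueError(
            f"sample_rate {spec.sample_rate:g} Hz resolves only "
            f"{n_phase_samples} sample(s) per square-wave phase; >= 2 required"
        )

    steps = build_staircase_schedule(spec)
    # Build (duration, voltage, csw, step, phase) segment list in order.
    segments: list[tuple[Fraction, float, int, int, int]] = []
    for k in range(1, spec.csw_n + 1):
        if k > 1 and spec.gap > 0:
            segments.append((gap_dur, spec.e_holding, 0, 0, PHASE_GAP))
        for s, v in enumerate(steps, start=1):
            segments.append((phase_dur, v + spec.e_sw, k, s, PHASE_ANODIC))
            segments.append((phase_dur, v - spec.e_sw, k, s, PHASE_CATHODIC))

    total = sum(seg[0] for seg in segments)
    n_total = round(total * rate)
    voltages = np.empty(n_total, dtype=np.float64)
    csw_index = np.zeros(n_total, dtype=np.int32)
    step_index = np.zeros(n_total, dtype=np.int32)
    phase = np.full(n_total, PHASE_GAP, dtype=np.int8)

    t = Fraction(0)
    i0 = 0
    for dur, v, k, s, ph in segments:
        t += dur
        i1 = round(t * rate)
        voltages[i0:i1] = v
        csw_index[i0:i1] = k
        step_index[i0:i1] = s
        phase[i0:i1] = ph
        i0 = i1

    return SampledWaveform(
        voltages=voltages,
        sample_rate=spec.sample_rate,
        csw_index=csw_index,
        step_index=step_index,
        phase=phase,
        spec=spec,
    )


def render_trigger(
    trig: TriggerSpec, horizon: float, sample_rate: float
) -> np.ndarray:
    """Sample a trigger-pulse train on ``[0, horizon)`` at ``sample_rate``.

    Raises if any pulse extends past the horizon.
    """
    if trig.n_pulses > 0 and trig.start_time + (trig.n_pulses - 1) * (
        trig.pulse_duration + trig.interpulse_interval
    ) + trig.pulse_duration > horizon + 1e-12:
        raise ValueError(
            f"trigger train ends at "
            f"{trig.end_time - trig.interpulse_interval:.6g} s, past the "
            f"{horizon:.6g} s horizon"
        )
    n = round(horizon * sample_rate)
    trace = np.zeros(n, dtype=np.float64)
    period = trig.pulse_duration + trig.interpulse_interval
    for p in range(trig.n_pulses):
        t_on = trig.start_time + p * period
        i0 = round(t_on * sample_rate)
        i1 = round((t_on + trig.pulse_duration) * sample_rate)
        trace[i0:i1] = trig.amplitude
    return trace


def check_no_overlap(
    wf: SampledWaveform, trigger: np.ndarray, sample_rate: float | None = None
) -> list[tuple[float, float]]:
    """Report time intervals where a trigger fires during active scanning.

    The trigger trace may be longer than the rendered waveform (covering the
    idle remainder of the repetition period); samples beyond the waveform
    are treated as holding and never conflict.  Returns a list of
    ``(t_start, t_end)`` intervals in seconds; an empty list means the
    schedule is artifact-safe.
    """
    if sample_rate is None:
        sample_rate = wf.sample_rate
    trigger = np.asarray(trigger)
    n = trigger.size
    active = np.zeros(n, dtype=bool)
    m = min(n, len(wf))
    active[:m] = wf.phase[:m] != PHASE_GAP
    conflict = active & (trigger != 0)
    if not conflict.any():
        return []
    # Run-length extraction: starts where conflict turns on, ends where off.
    d = np.diff(np.concatenate([[0], conflict.astype(np.int8), [0]]))
    on = np.flatnonzero(d == 1)
    off = np.flatnonzero(d == -1)
    return [(s / sample_rate, e / sample_rate) for s, e in zip(on, off)]
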