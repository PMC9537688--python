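"""Carbon-fiber microelectrode signal simulator.

Generates synthetic raw current scans with the structure the analysis
pipeline assumes, so every downstream stage is testable without
instrumentation:

* **Capacitive (non-Faradaic) transients** — the electrode double layer
  behaves as a series RC circuit, so every square-wave voltage step of size
  ΔV launches a charging/discharging exponential ``(ΔV/R)·exp(-t'/RC)``.
  The full piecewise-constant drive is solved exactly with a per-segment
  recursion on the double-layer voltage, which is equivalent to
  superposing all step responses.  With the default R = 50 kΩ and an
  0.85 V transition the initial transient is ~1.7e4 nA, the order of
  magnitude seen at real electrodes.
* **Background drift** — the capacitance is scaled by
  ``(1 + drift_rate) ** scan_index``, emulating slow electrode-surface
  drift across a session.
* **Adsorption-limited Faradaic peaks** — oxidation current is a Gaussian
  in staircase potential centered at ``e_ox``, scaled by analyte
  concentration, shaped in time as a decaying exponential that is slower
  than the capacitive transient.  Successive CSWs within a scan deplete
  the adsorbed analyte by a factor ``depletion_factor`` per CSW, which is
  what lets a late CSW serve as the within-scan background.  A mirrored
  reduction peak of opposite sign appears on cathodic phases.
* **Noise** — per-sample white Gaussian noise plus "broadband" noise drawn
  as high-spatial-frequency structure across the (step × within-pulse)
  plane, independent per CSW, giving the 2-D FFT mask filter a realistic
  target.

The drift magnitudes and noise levels are order-of-magnitude laboratory
values, not fitted to any particular electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .waveform import (
    PHASE_ANODIC,
    PHASE_CATHODIC,
    PHASE_GAP,
    SampledWaveform,
    WaveformSpec,
    build_staircase_schedule,
    render_waveform,
)

__all__ = ["ElectrodeModel", "SessionPlan", "RawScan", "simulate_scan", "simulate_session"]


@dataclass(frozen=True)
class ElectrodeModel:
    """Physical parameters of the simulated electrode/analyte system.

    Units: ohms, farads, volts, nA.  ``faradaic_gain`` is the oxidation
    peak current per nM of analyte at full adsorption; ``depletion_factor``
    multiplies the adsorbed pool per applied CSW; ``adsorption_recovery``
    is the fraction of the depleted pool restored per repetition period.

    Defaults describe a generic carbon-fiber microelectrode: R = 50 kΩ and
    C = 0.5 nF give RC = 25 µs and ~1.7e4 nA step transients; gain
    0.2 nA/nM yields ~20-25 pC kernel charges at 150 nM tonic analyte,
    the scale a real electrode produces; white noise sits at the 16-bit
    quantization floor (0.5 nA at the stated gain and range) with sub-nA
    broadband contamination; drift is 0.1% capacitance per scan.  The
    within-pulse Faradaic time constant (0.5 ms, one phase) implies
    moderate per-pulse consumption of the adsorbed pool, consistent with
    the per-CSW depletion factor 0.3.
    """

    resistance: float = 50e3
    capacitance: float = 0.5e-9
    drift_rate: float = 1e-3
    faradaic_gain: float = 0.2
    e_ox: float = 0.1
    peak_width: float = 0.08
    depletion_factor: float = 0.3
    adsorption_recovery: float = 1.0
    tau_faradaic: float = 0.5e-3
    reduction_offset: float = 0.1
    reduction_fraction: float = 0.6
    noise_sd: float = 0.5
    broadband_noise_sd: float = 0.7
    preamp_gain: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resistance", "capacitance", "tau_faradaic", "preamp_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.depletion_factor < 1:
            raise ValueError("depletion_factor must be in [0, 1)")
        if not 0 <= self.adsorption_recovery <= 1:
            raise ValueError("adsorption_recovery must be in [0, 1]")
        for name in ("faradaic_gain", "peak_width", "noise_sd", "broadband_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rc(self) -> float:
        """Double-layer time constant R·C in seconds (at zero drift)."""
        return self.resistance * self.capacitance


@dataclass(frozen=True)
class SessionPlan:
    """Tonic analyte concentration (nM) at each scan of a session."""

    concentration_per_scan: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentration_per_scan):
            raise ValueError("concentrations must be >= 0")

    @property
    def n_scans(self) -> int:
        return len(self.concentration_per_scan)

    @classmethod
    def constant(cls, concentration: float, n_scans: int) -> "SessionPlan":
        return cls(tuple([concentration] * n_scans))

    @classmethod
    def step(
        cls, pre: float, post: float, n_pre: int, n_post: int
    ) -> "SessionPlan":
        return cls(tuple([pre] * n_pre + [post] * n_post))


@dataclass
class RawScan:
    """One scan's raw current trace (nA) plus index and timestamp."""

    current: np.ndarray
    scan_index: int
    timestamp: float

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=np.float64)
        if not np.all(np.isfinite(self.current)):
            raise ValueError("scan contains non-finite samples")


def _capacitive_current(
    wf: SampledWaveform,
    resistance: float,
    capacitance: float,
    drift_per_second: float = 0.0,
) -> np.ndarray:
    """Exact series-RC response to the piecewise-constant drive, in nA.

    Within each constant-voltage run the current decays as
    ``I(t') = I_start · exp(-t'/RC)`` where ``I_start = (V_seg - V_dl)/R``
    and the double-layer voltage relaxes toward the applied voltage.  The
    double layer starts equilibrated at the holding potential, where the
    electrode rests between scans, so the first square-wave edge also
    launches a transient.

    Drift is continuous: the capacitance grows by the factor
    ``(1 + drift_per_second)`` per second, evaluated piecewise-constant
    per voltage run, so late CSWs in a scan see a slightly different
    double layer than early ones — the mismatch the residual background
    subtraction exists to remove.
    """
    v = wf.voltages
    dt = 1.0 / wf.sample_rate
    # Boundaries of constant-voltage runs.
    change = np.flatnonzero(np.diff(v) != 0) + 1
    bounds = np.concatenate([[0], change, [v.size]])
    out = np.empty(v.size, dtype=np.float64)
    v_dl = wf.spec.e_holding  # pre-equilibrated at the inter-scan holding level
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        cap = capacitance * (1.0 + drift_per_second) ** (b0 * dt)
        rc = resistance * cap
        v_seg = v[b0]
        i_start = (v_seg - v_dl) / resistance  # amperes
        t = np.arange(b1 - b0) * dt
        out[b0:b1] = i_start * np.exp(-t / rc)
        # Double-layer voltage at the end of the run (start of next).
        v_dl = v_seg - (v_seg - v_dl) * np.exp(-(b1 - b0) * dt / rc)
    return out * 1e9  # A -> nA


def _faradaic_current(
    wf: SampledWaveform,
    model: ElectrodeModel,
    concentration: float,
    adsorption_state: float,
) -> np.ndarray:
    """Noiseless Faradaic current in nA for one scan.

    Oxidation: Gaussian in staircase potential centered at ``e_ox`` on
    anodic phases; reduction: mirrored negative Gaussian centered at
    ``e_ox - reduction_offset`` on cathodic phases, scaled by
    ``reduction_fraction``.  Amplitude for the k-th CSW carries the
    depletion factor ``d**(k-1)``.  Within each pulse the current decays
    with the slower Faradaic time constant, emulating adsorbed-analyte
    consumption during the pulse.
    """
    out = np.zeros(len(wf), dtype=np.float64)
    if concentration == 0 or model.faradaic_gain == 0 or adsorption_state == 0:
        return out
    steps = build_staircase_schedule(wf.spec)
    dt = 1.0 / wf.sample_rate
    d = model.depletion_factor
    amp0 = concentration * model.faradaic_gain * adsorption_state

    # Iterate over contiguous (csw, step, phase) pulse runs.
    keys = (
        wf.csw_index.astype(np.int64) * 10_000_000
        + wf.step_index.astype(np.int64) * 10
        + wf.phase.astype(np.int64)
    )
    change = np.flatnonzero(np.diff(keys) != 0) + 1
    bounds = np.concatenate([[0], change, [keys.size]])
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        ph = wf.phase[b0]
        if ph == PHASE_GAP:
            continue
        k = int(wf.csw_index[b0])
        s = int(wf.step_index[b0])
        v_step = steps[s - 1]
        if ph == PHASE_ANODIC:
            gauss = np.exp(-0.5 * ((v_step - model.e_ox) / model.peak_width) ** 2)
            sign = 1.0
        else:
            center = model.e_ox - model.reduction_offset
            gauss = model.reduction_fraction * np.exp(
                -0.5 * ((v_step - center) / model.peak_width) ** 2
            )
            sign = -1.0
        amp = sign * amp0 * gauss * d ** (k - 1)
        if amp == 0.0:
            continue
        t = np.arange(b1 - b0) * dt
        out[b0:b1] = amp * np.exp(-t / model.tau_faradaic)
    return out


def _broadband_noise(
    wf: SampledWaveform, model: ElectrodeModel, rng: np.random.Generator
) -> np.ndarray:
    """High-spatial-frequency contamination across the pulse plane, nA.

    For each CSW an independent white pattern over (step, within-phase
    sample) is high-pass filtered in 2-D frequency (DC and the lowest
    eighth of each axis removed) and written onto that CSW's pulses.  The
    pattern differs between CSWs, so it survives the CSW-pair subtraction
    and reaches the pseudocolor plot — the contamination the elliptical
    FFT mask is designed to remove.
    """
    out = np.zeros(len(wf), dtype=np.float64)
    if model.broadband_noise_sd == 0:
        return out
    spec = wf.spec
    n_steps = spec.n_steps
    # samples per phase from the rendered labels (first anodic run)
    first = np.flatnonzero(wf.phase == PHASE_ANODIC)
    if first.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(first) != 1)
    spp = int(breaks[0] + 1) if breaks.size else int(first.size)
    for k in range(1, spec.csw_n + 1):
        pattern = rng.standard_normal((2 * spp, n_steps))
        f = np.fft.fft2(pattern)
        ru, cu = pattern.shape[0] // 8, max(1, pattern.shape[1] // 8)
        f[:ru, :cu] = 0
        f[:ru, -cu:] = 0
        f[-ru:, :cu] = 0
        f[-ru:, -cu:] = 0
        pattern = np.fft.ifft2(f).real
        sd = pattern.std()
        if sd > 0:
            pattern *= model.broadband_noise_sd / sd
        in_csw = wf.csw_index == k
        for ph, row0 in ((PHASE_ANODIC, 0), (PHASE_CATHODIC, spp)):
            sel = in_csw & (wf.phase == ph)
            idx = np.flatnonzero(sel)
            # contiguous runs of length spp, one per step, in step order
            runs = idx.reshape(n_steps, spp)
            for col in range(n_steps):
                out[runs[col]] = pattern[row0 : row0 + spp, col]
    return out


def simulate_scan(
    model: ElectrodeModel,
    wf: SampledWaveform,
    concentration: float,
    scan_index: int = 0,
    rng: np.random.Generator | None = None,
    adsorption_state: float = 1.0,
    timestamp: float | None = None,
) -> RawScan:
    """Simulate one raw scan: capacitive + Faradaic + noise, in nA.

    The capacitance is scaled by ``(1 + drift_rate) ** scan_index``.
    Reproducible: with ``rng=None`` a generator seeded from ``model.seed``
    and ``scan_index`` is used.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=model.seed, spawn_key=(scan_index,))
        )
    cap = model.capacitance * (1.0 + model.drift_rate) ** scan_index
    period = wf.spec.repetition_period
    drift_per_second = (1.0 + model.drift_rate) ** (1.0 / period) - 1.0
    current = _capacitive_current(
        wf, model.resistance, cap, drift_per_second=drift_per_second
    )
    current += _faradaic_current(wf, model, concentration, adsorption_state)
    current += _broadband_noise(wf, model, rng)
    if model.noise_sd > 0:
        current += rng.normal(0.0, model.noise_sd, size=len(wf))
    if timestamp is None:
        timestamp = scan_index * wf.spec.repetition_period
    return RawScan(current=current, scan_index=scan_index, timestamp=timestamp)


def simulate_session(
    model: ElectrodeModel,
    plan: SessionPlan,
    spec: WaveformSpec,
    wf: SampledWaveform | None = None,
):
    """Yield one :class:`RawScan` per plan entry.

    Drift and the adsorbed-analyte pool are carried across scans: each scan
    depletes the pool by ``depletion_factor ** csw_n`` and it recovers
    toward equilibrium by ``adsorption_recovery`` per repetition period.
    Deterministic under a fixed ``model.seed``.
    """
    if wf is None:
        wf = render_waveform(spec)
    state = 1.0  # adsorbed fraction of equilibrium at scan start
    for i, conc in enumerate(plan.concentration_per_scan):
        yield simulate_scan(
            model, wf, conc, scan_index=i, adsorption_state=state
        )
        depleted = state * model.depletion_factor**spec.csw_n
        state = depleted + model.adsorption_recovery * (1.0 - depleted)
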