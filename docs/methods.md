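# Methods

`mcswv` implements the analysis chain used to track *tonic* (basal)
neurotransmitter concentrations with multi-cyclic square wave voltammetry
(M-CSWV) at carbon-fiber microelectrodes, together with a physics-based
signal simulator that makes the whole chain testable without
instrumentation.  This note records the models, the defaults and why they
were chosen, and the places where the design was genuinely open.

## The measurement model

A scan applies `csw_n` cyclic square waves (CSWs) back to back, each a
staircase sweep with a square wave of half-amplitude `E_sw` on every step,
then rests at the holding potential until the next scan
(`repetition_period`, 10 s).  The recorded current is a sum of:

* **Non-Faradaic (capacitive) current.**  The electrode double layer is a
  series RC element; every voltage edge of size ΔV launches a transient
  `(ΔV/R)·exp(−t/RC)` that can reach the 10⁴ nA range — orders of
  magnitude above the signal.
* **Faradaic current** from analyte oxidation/reduction: localized in
  staircase potential around the oxidation peak, adsorption-limited, and
  *depleting* across the CSWs of a scan because the scan consumes adsorbed
  analyte faster than it re-adsorbs.

Tonic extraction uses that depletion: by a late CSW (the 5th, for
dopamine) the Faradaic component has essentially vanished, so
`CSW2 − CSW5` removes the (nearly identical) capacitive background while
retaining the tonic Faradaic signal of CSW 2.  Slow electrode drift makes
the two backgrounds differ slightly; the remaining mismatch is removed by
fitting each phase's discharge with `I = I₀·exp(−t/τ) + c` and
subtracting the *difference of the fitted models*.  The result is
arranged as a pseudocolor plot (within-pulse sample × staircase step),
optionally denoised with a hard elliptical low-pass mask in the 2-D
Fourier plane, thresholded at `mean + k·SD` (k = 1 by default) of the
pixel distribution accumulated over scans to form the analyte kernel, and
integrated to a per-scan charge (1 nA·ms = 1 pC).  Charge maps to
concentration through a straight-line calibration against in-vitro
standards (100/300/500 nM).

## Background-fit design

Three choices here are load-bearing and deliberate:

1. **The offset is a nuisance parameter and is never subtracted.**  A
   capacitive discharge decays to zero; any DC level in a phase's tail is
   slowly varying Faradaic signal.  The fitted `c` therefore stabilizes
   the fit but is excluded from the subtracted model
   `model₂ − model₅`.  Subtracting the offsets removes the tonic signal
   itself (we measured ~95% signal destruction when the offsets are
   included).
2. **`τ` is bounded to `[dt, phase/4]`.**  The technique requires
   RC ≪ phase (otherwise the transient never settles and no fit window
   exists); a fitted "capacitive" decay slower than the phase is
   indistinguishable from Faradaic signal, and an unbounded fit locks
   onto the analyte decay and subtracts it.
3. **The charging spike is excluded.**  The first 5% of each phase
   (`skip_fraction`, a logged parameter) precedes analyte oxidation and
   is excluded from the fit, from the residual subtraction, and from the
   threshold statistics and charge integration (flagged invalid, not
   zeroed — zeroing would bias the pixel distribution).

Initialization is deterministic (`i0` = first − last sample,
`τ` = window/5 clipped to the bound, `c` = last sample), so identical
segments always produce identical fits and per-segment fitting can be
parallelized without changing results.  A non-converged fit falls back to
the converged fit of the same (step, phase) from the previous scan, and
otherwise to the raw difference, always flagged.

## Threshold statistics

The kernel threshold is `mean + k·SD` of the *pooled* valid-pixel current
distribution across scans (`statistic="scalar"`, the default).  A
per-pixel variant exists but is not the default: a pixel's own running
`mean + 1·SD` is exceeded only transiently in steady state, so a
per-pixel kernel tracks *changes* rather than the tonic oxidation zone.
The pooled statistic makes the threshold scale with the signal amplitude,
which in turn makes the kernel charge proportional to concentration —
the property the step-response check verifies.

Cumulative statistics ("over all scans") are the default; an
exponential-forgetting variant (`forgetting=W`, effective window `W`
scans) is available and is what the step-response study uses, because a
cumulative threshold drags the pre-step epoch behind it indefinitely.
The fix/reset workflow mirrors live operation: `fix()` freezes the
threshold, `reset()` recomputes it from the last 20 scans
(`reset_window`).

Charge aggregation defaults to the **sum** of `I·dt` over the kernel (a
physical charge, pC); a mean-per-pixel variant is selectable.  The kernel
is oxidation-only (anodic half) by default, with reduction-zone inclusion
as a flag.

## The simulator

`ElectrodeModel` emulates what the analysis assumes: an exact
piecewise-exponential RC response to the rendered waveform (solved by
per-run recursion on the double-layer voltage, equivalent to superposing
all step responses), continuous capacitive drift, adsorption-limited
Gaussian Faradaic peaks with per-CSW depletion `d^(k−1)` and a mirrored
reduction peak, white noise, and broadband contamination drawn as
high-spatial-frequency structure over the pulse plane (independent per
CSW, so it survives the pair subtraction and reaches the pseudocolor
plot — the mask filter's target).

Defaults (order-of-magnitude laboratory values, fixed once):

| parameter | default | rationale |
| --- | --- | --- |
| R | 50 kΩ | CFM solution + access resistance; with C gives ~1.7·10⁴ nA step transients |
| C | 0.5 nF | double layer of a 7–10 µm CFM tip; RC = 25 µs ≪ 0.5 ms phase |
| faradaic_gain | 0.2 nA/nM | yields ~26 pC kernel charge at 150 nM — the pC scale real electrodes produce |
| depletion d | 0.3 | d⁴ ≈ 0.8%: Faradaic current has effectively vanished by CSW 5 |
| τ_faradaic | 0.5 ms | one phase; moderate per-pulse consumption, coherent with d = 0.3 (a much faster decay would exhaust the local pool every pulse) |
| drift_rate | 10⁻³ /scan | slow surface drift, applied continuously in time so CSW 2 and CSW 5 genuinely differ |
| noise_sd | 0.5 nA | the 16-bit quantization floor at 2000 nA/V over ±10 V (0.61 nA/count) |
| broadband_noise_sd | 0.7 nA | visible plane contamination at a few % of the signal peak |
| adsorption_recovery | 1.0 | full re-equilibration over the 10 s rest |

What the simulator does **not** model: electrode kinetics
(Butler–Volmer), pH and ionic-strength effects, fouling, tissue
diffusion, multi-analyte interference, and correlated (line-frequency)
interference.  Passing tests therefore demonstrate that the *pipeline*
recovers what this signal model injects — not that any particular
electrode in tissue behaves like the model.

## Study problem sizes

Session-level studies run on a reduced waveform, `presets.demo_spec()`:
the published square-wave constants (E_sw 0.4 V, staircase 0.025 V, τ
1 ms, gap 2 ms, 5 CSWs, 0.1 Hz) over a 33-step staircase (−0.1 → +0.3 V)
sampled at 100 kHz — 17,300 samples and 50 samples per phase, so a
50-scan session simulates and analyzes in well under a minute while every
transient is still resolved.  A 9-step staircase proved spectrally too
cramped for a meaningful elliptical-mask study (the signal blob fills the
whole column band).  The packaged 2 MHz dopamine/serotonin presets carry
the published constants; their staircase envelopes (E_initial, E_peak,
E_holding) are placeholders the user must set for their electrode, since
the validated envelopes are electrode-dependent and published elsewhere.

The filter study uses mask radii (30, 10) — chosen, per the operating
rule that the radius is adjusted until no signal component is clipped, at
the point where the noiseless filtered charge plateaus at the raw value.
The packaged default radii remain a quarter of each axis's extent.

## Numerical conventions

Currents are nA and times seconds internally; displayed charge is pC
(1 nA·ms).  Phase boundaries are accumulated in exact rational seconds
before snapping to samples, so no rounding drift accrues across a scan.
The staircase turning point is emitted once (configurable).  τ in the
waveform sense is the *full* square-wave cycle (τ/2 per phase); the
per-phase reading is selectable via `tau_convention` and recorded in the
parameter log.  The stored pseudocolor layout is rows = within-pulse
sample (anodic block then cathodic), columns = staircase sweep; display
orientation is a view concern.  Int16 storage scale defaults to
preamp gain × ADC range over the int16 range and lives in the session
header, never in code.  Filtered data are always derived copies — raw
records are immutable and replay with a parameter log is bit-identical.

## Known limitations

* Single-exponential background per phase; no bi-exponential option.
* The charge/concentration relation is linear only while the kernel
  captures the whole blob; near the threshold it is soft, which is why
  real deployments calibrate with standards rather than assuming
  proportionality.
* The per-pixel threshold variant is exploratory (see above).
* No real DAQ backend: the acquisition interface has exactly one bundled
  implementation, the simulator.
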