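"""Scan segmentation and capacitive-background modeling.

After every square-wave voltage step the electrode double layer charges or
discharges exponentially; the Faradaic signal of interest rides on the
discharging tail of each phase.  This module splits a raw scan into
per-(CSW, step, phase) pulse segments using the rendered waveform's sample
labels, fits the single-exponential background model

    I(t) = i0 · exp(-t / tau_decay) + offset

to the discharge portion of each segment by bounded least squares (RMSE
objective), and evaluates the fitted model as a per-segment background
trace.  The first ``skip_fraction`` of each phase — the charging spike,
which precedes analyte oxidation — is excluded from the fit and flagged so
downstream charge computation can ignore it.

Fitting is deterministic (fixed initialization, no randomness) and each
segment is independent, so fits may run in any order with bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import RawScan
from .waveform import PHASE_ANODIC, PHASE_CATHODIC, PHASE_GAP, SampledWaveform

__all__ = [
    "PulseSegment",
    "CapacitiveFit",
    "segment_scan",
    "fit_capacitive_decay",
    "fit_all_segments",
    "model_background",
    "DEFAULT_SKIP_FRACTION",
]

DEFAULT_SKIP_FRACTION = 0.05


@dataclass
class PulseSegment:
    """Current samples of one square-wave phase.

    ``csw_index`` and ``step_index`` are 1-based; ``phase`` is
    ``PHASE_ANODIC`` or ``PHASE_CATHODIC``.  ``t0`` is the segment's start
    time within the scan and ``dt`` the sample interval, both in seconds.
    """

    csw_index: int
    step_index: int
    phase: int
    samples: np.ndarray
    t0: float
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("segment has no samples")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.csw_index, self.step_index, self.phase)

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to the segment start, seconds."""
        return np.arange(self.samples.size) * self.dt


@dataclass
class CapacitiveFit:
    """Fitted exponential background for one segment.

    ``tau_decay`` is the background decay constant in seconds — distinct
    from the waveform's pulse duration, though both are conventionally
    written τ.  ``converged`` is False when the optimizer failed; callers
    fall back rather than raising.  ``skip`` is the number of leading
    charging-spike samples excluded from the fit window.
    """

    i0: float
    tau_decay: float
    offset: float
    rmse: float
    converged: bool
    skip: int = 0

    def evaluate(self, times: np.ndarray, include_offset: bool = True) -> np.ndarray:
        """Evaluate the model at ``times`` (seconds from the fit origin).

        With ``include_offset=False`` only the decaying exponential — the
        physically capacitive part — is returned.  The offset is a fit
        nuisance parameter: a true double-layer discharge decays to zero,
        while any DC level in the tail belongs to slowly varying Faradaic
        signal, so background *subtraction* must exclude it.
        """
        exp_part = self.i0 * np.exp(-np.asarray(times) / self.tau_decay)
        return exp_part + self.offset if include_offset else exp_part


def segment_scan(raw: RawScan, wf: SampledWaveform) -> list[PulseSegment]:
    """Split a raw scan into pulse segments using the waveform's labels.

    Returns one segment per (CSW, step, phase) in time order; together
    with the gap samples they partition the scan exactly.
    """
    if len(raw.current) != len(wf):
        raise ValueError(
            f"scan length {len(raw.current)} != waveform length {len(wf)}"
        )
    dt = 1.0 / wf.sample_rate
    keys = (
        wf.csw_index.astype(np.int64) * 10_000_000
        + wf.step_index.astype(np.int64) * 10
        + wf.phase.astype(np.int64)
    )
    change = np.flatnonzero(np.diff(keys) != 0) + 1
    bounds = np.concatenate([[0], change, [keys.size]])
    segments: list[PulseSegment] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if wf.phase[b0] == PHASE_GAP:
            continue
        segments.append(
            PulseSegment(
                csw_index=int(wf.csw_index[b0]),
                step_index=int(wf.step_index[b0]),
                phase=int(wf.phase[b0]),
                samples=raw.current[b0:b1].copy(),
                t0=b0 * dt,
                dt=dt,
            )
        )
    return segments


def _exp_model(t, i0, tau, offset):
    return i0 * np.exp(-t / tau) + offset


def fit_capacitive_decay(
    seg: PulseSegment, skip: int | None = None
) -> CapacitiveFit:
    """Fit ``i0·exp(-t/tau_decay) + offset`` to a segment's discharge tail.

    Parameters
    ----------
    seg : PulseSegment
    skip : int, optional
        Leading samples to exclude (the charging spike).  Default: 5% of
        the segment length.

    The fit minimizes RMSE over the retained samples, with time measured
    from the first retained sample.  Initialization: ``i0`` = first - last
    retained sample, ``tau_decay`` = fitted-window duration / 5,
    ``offset`` = last sample.  ``tau_decay`` is bounded to
    ``[dt, phase duration / 4]``: a capacitive discharge must die off
    well within its phase (the technique requires RC ≪ phase), and an
    unbounded fit would lock onto slow Faradaic decays and subtract the
    signal itself.  On optimizer failure a fit with ``converged=False``
    is returned — never an exception.
    """
    if skip is None:
        skip = int(round(DEFAULT_SKIP_FRACTION * seg.samples.size))
    y = seg.samples[skip:]
    if y.size < 4:
        raise ValueError(
            f"segment has {y.size} usable samples after skip={skip}; >= 4 required"
        )
    t = np.arange(y.size) * seg.dt
    span = seg.samples.size * seg.dt
    tau_max = max(span / 4.0, 2.0 * seg.dt)
    i0_init = float(y[0] - y[-1])
    tau_init = min(max(y.size * seg.dt / 5.0, seg.dt), tau_max)
    p0 = (i0_init, tau_init, float(y[-1]))
    lo = (-np.inf, seg.dt, -np.inf)
    hi = (np.inf, tau_max, np.inf)
    try:
        popt, _ = curve_fit(
            _exp_model, t, y, p0=p0, bounds=(lo, hi), maxfev=2000
        )
        resid = y - _exp_model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        return CapacitiveFit(
            i0=float(popt[0]),
            tau_decay=float(popt[1]),
            offset=float(popt[2]),
            rmse=rmse,
            converged=True,
            skip=skip,
        )
    except (RuntimeError, ValueError):
        return CapacitiveFit(
            i0=i0_init,
            tau_decay=tau_init,
            offset=float(y[-1]),
            rmse=float("nan"),
            converged=False,
            skip=skip,
        )


def fit_all_segments(
    segments: list[PulseSegment],
    skip_fraction: float = DEFAULT_SKIP_FRACTION,
    previous: dict[tuple[int, int, int], CapacitiveFit] | None = None,
) -> list[CapacitiveFit]:
    """Fit every segment; segment order and parallel scheduling are
    immaterial because each fit depends only on its own samples.

    ``previous`` maps segment keys from the prior scan; a non-converged
    fit falls back to the prior scan's converged fit for the same
    (step, phase) when available (fallback fits keep ``converged=False``
    so the substitution is visible in diagnostics).
    """
    fits = []
    for seg in segments:
        skip = int(round(skip_fraction * seg.samples.size))
        fit = fit_capacitive_decay(seg, skip=skip)
        if not fit.converged and previous is not None:
            prior = previous.get(seg.key)
            if prior is not None and prior.converged:
                fit = CapacitiveFit(
                    i0=prior.i0,
                    tau_decay=prior.tau_decay,
                    offset=prior.offset,
                    rmse=float("nan"),
                    converged=False,
                    skip=skip,
                )
        fits.append(fit)
    return fits


def fit_diagnostics_frame(
    segments: list[PulseSegment],
    fits: list[CapacitiveFit],
    scan_index: int = 0,
):
    """Fit diagnostics as a table, one row per segment (for delimited
    text export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "scan": scan_index,
            "csw": [s.csw_index for s in segments],
            "step": [s.step_index for s in segments],
            "phase": ["anodic" if s.phase == PHASE_ANODIC else "cathodic"
                      for s in segments],
            "i0_nA": [f.i0 for f in fits],
            "tau_decay_s": [f.tau_decay for f in fits],
            "offset_nA": [f.offset for f in fits],
            "rmse_nA": [f.rmse for f in fits],
            "converged": [f.converged for f in fits],
            "skip": [f.skip for f in fits],
        }
    )


def model_background(
    segments: list[PulseSegment], fits: list[CapacitiveFit]
) -> list[np.ndarray]:
    """Evaluate each fit on its segment's time base.

    Returns one background trace per segment, same length as the segment;
    samples inside the charging-spike skip window are NaN (excluded from
    modeling and from downstream subtraction), matching the convention
    that the background model is defined on the discharge portion only.
    """
    if len(segments) == 0:
        raise ValueError("no segments provided")
    if len(segments) != len(fits):
        raise ValueError(
            f"{len(segments)} segments but {len(fits)} fits; need one fit per segment"
        )
    traces = []
    for seg, fit in zip(segments, fits):
        trace = np.full(seg.samples.size, np.nan)
        t = np.arange(seg.samples.size - fit.skip) * seg.dt
        trace[fit.skip :] = fit.evaluate(t)
        traces.append(trace)
    return traces
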