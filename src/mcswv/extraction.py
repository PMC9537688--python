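"""Tonic Faradaic signal extraction and pseudocolor-plot assembly.

Within one scan, successive CSWs deplete the adsorbed analyte, so by a
late CSW (the 5th for dopamine) the Faradaic current has essentially
vanished and that CSW carries only non-Faradaic background.  Subtracting
the late CSW from an early one (the 2nd) therefore removes most of the
capacitive background while retaining the tonic Faradaic signal.  Slow
electrode drift leaves a residual, which is removed by subtracting the
*difference of the fitted background models* of the two CSWs from the raw
pair difference.

The result — one Faradaic trace per (staircase step, phase) — is arranged
into a 2-D pseudocolor plot: rows are the within-pulse sample index
(anodic block on top of the cathodic block), columns are the staircase
steps in sweep order (forward then reverse).  Oxidation currents appear as
a positive zone in the anodic half, reduction as a negative zone in the
cathodic half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CapacitiveFit, PulseSegment
from .waveform import PHASE_ANODIC, PHASE_CATHODIC, WaveformSpec, build_staircase_schedule

__all__ = [
    "ColorPlot",
    "csw_pair_difference",
    "residual_background_subtract",
    "assemble_colorplot",
    "DEFAULT_SIGNAL_CSW",
    "DEFAULT_BACKGROUND_CSW",
]

DEFAULT_SIGNAL_CSW = 2
DEFAULT_BACKGROUND_CSW = 5


@dataclass
class ColorPlot:
    """2-D Faradaic current array with axis metadata.

    ``current[row, col]``: row = within-pulse sample index, rows
    ``0 .. spp-1`` anodic, ``spp .. 2·spp-1`` cathodic; col = staircase
    step in sweep order.  ``valid`` marks samples inside the background
    fit window (charging-spike rows are invalid and excluded from charge
    computation).  ``dt`` is seconds per row sample.
    """

    current: np.ndarray
    dt: float
    step_potentials: np.ndarray
    scan_index: int = 0
    filtered: bool = False
    mask_radii: tuple[float, float] | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=np.float64)
        self.step_potentials = np.asarray(self.step_potentials, dtype=np.float64)
        if self.current.ndim != 2:
            raise ValueError("current must be 2-D")
        if self.current.shape[1] != self.step_potentials.size:
            raise ValueError("step_potentials length must match column count")
        if self.current.shape[0] % 2 != 0:
            raise ValueError("row count must be even (anodic + cathodic halves)")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current contains non-finite values")
        if self.valid is None:
            self.valid = np.ones(self.current.shape, dtype=bool)

    @property
    def samples_per_phase(self) -> int:
        return self.current.shape[0] // 2

    @property
    def anodic(self) -> np.ndarray:
        return self.current[: self.samples_per_phase]

    @property
    def cathodic(self) -> np.ndarray:
        return self.current[self.samples_per_phase :]


def save_colorplot_text(plot: ColorPlot, path) -> None:
    """Write a ColorPlot as a delimited text matrix with a header line of
    axis metadata (dt, scan index, filtered flag, step potentials)."""
    header = (
        f"dt_s={plot.dt!r} scan={plot.scan_index} filtered={plot.filtered} "
        f"step_potentials_V={','.join(repr(v) for v in plot.step_potentials)}"
    )
    np.savetxt(path, plot.current, delimiter="\t", header=header)


def save_colorplot_binary(plot: ColorPlot, path) -> None:
    """Write a ColorPlot as a .npz bundle: current array, validity mask,
    step potentials, and scalar metadata."""
    np.savez(
        path,
        current=plot.current,
        valid=plot.valid,
        step_potentials=plot.step_potentials,
        dt=plot.dt,
        scan_index=plot.scan_index,
        filtered=plot.filtered,
    )


def load_colorplot_binary(path) -> ColorPlot:
    with np.load(path) as data:
        return ColorPlot(
            current=data["current"],
            dt=float(data["dt"]),
            step_potentials=data["step_potentials"],
            scan_index=int(data["scan_index"]),
            filtered=bool(data["filtered"]),
            valid=data["valid"],
        )


def _group_by_csw(
    segments: list[PulseSegment],
) -> dict[int, dict[tuple[int, int], PulseSegment]]:
    out: dict[int, dict[tuple[int, int], PulseSegment]] = {}
    for seg in segments:
        out.setdefault(seg.csw_index, {})[(seg.step_index, seg.phase)] = seg
    return out


def csw_pair_difference(
    segments: list[PulseSegment],
    signal_csw: int = DEFAULT_SIGNAL_CSW,
    background_csw: int = DEFAULT_BACKGROUND_CSW,
) -> dict[tuple[int, int], np.ndarray]:
    """Per-(step, phase) difference signal_csw − background_csw.

    Traces are aligned by within-phase sample index.  Defaults subtract
    the 5th CSW from the 2nd, the pairing validated for dopamine.
    """
    by_csw = _group_by_csw(segments)
    for idx in (signal_csw, background_csw):
        if idx not in by_csw:
            present = sorted(by_csw)
            raise ValueError(f"CSW index {idx} not present (have {present})")
    sig, bg = by_csw[signal_csw], by_csw[background_csw]
    if set(sig) != set(bg):
        raise ValueError("signal and background CSWs cover different (step, phase) sets")
    return {key: sig[key].samples - bg[key].samples for key in sig}


def residual_background_subtract(
    diff: dict[tuple[int, int], np.ndarray],
    fits_signal: dict[tuple[int, int], CapacitiveFit],
    fits_background: dict[tuple[int, int], CapacitiveFit],
    dt: float,
) -> tuple[dict[tuple[int, int], np.ndarray], dict[tuple[int, int], np.ndarray]]:
    """Remove the drift residual: diff − (model_signal − model_background).

    Only the decaying exponential parts of the fitted models are
    subtracted: capacitive discharges decay to zero by construction, so
    the fits' offset terms — which absorb any slowly varying Faradaic
    level in the discharge tail — must not be removed from the signal.
    The model difference is evaluated samplewise on the background-fit
    window only; charging-spike samples (outside the window) pass through
    unchanged and are flagged invalid in the returned mask.  A missing fit
    for a (step, phase) falls back to the raw difference for that trace,
    also flagged.  ``dt`` is the sample interval of the traces, seconds.

    Returns ``(faradaic, valid)`` dicts keyed by (step, phase); ``valid``
    marks samples where the residual model was actually subtracted.
    """
    out: dict[tuple[int, int], np.ndarray] = {}
    valid: dict[tuple[int, int], np.ndarray] = {}
    for key, trace in diff.items():
        f_sig = fits_signal.get(key)
        f_bg = fits_background.get(key)
        result = trace.copy()
        mask = np.zeros(trace.size, dtype=bool)
        if f_sig is not None and f_bg is not None:
            skip = max(f_sig.skip, f_bg.skip)
            n = trace.size - skip
            if n > 0:
                # Each fit's time origin is its own first retained sample;
                # evaluate both from the common (larger) skip onward.
                rel = np.arange(n)
                t_sig = (rel + (skip - f_sig.skip)) * dt
                t_bg = (rel + (skip - f_bg.skip)) * dt
                result[skip:] = trace[skip:] - (
                    f_sig.evaluate(t_sig, include_offset=False)
                    - f_bg.evaluate(t_bg, include_offset=False)
                )
                mask[skip:] = True
        out[key] = result
        valid[key] = mask
    return out, valid


def assemble_colorplot(
    faradaic: dict[tuple[int, int], np.ndarray],
    spec: WaveformSpec,
    dt: float,
    scan_index: int = 0,
    valid: dict[tuple[int, int], np.ndarray] | None = None,
) -> ColorPlot:
    """Arrange per-(step, phase) Faradaic traces into a ColorPlot.

    Layout: rows carry the within-pulse sample index with the anodic block
    first, columns carry the staircase sweep (forward then reverse).
    """
    steps = build_staircase_schedule(spec)
    n_steps = steps.size
    lengths = {v.size for v in faradaic.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged trace lengths: {sorted(lengths)}")
    spp = lengths.pop()
    expected = {(s, ph) for s in range(1, n_steps + 1) for ph in (PHASE_ANODIC, PHASE_CATHODIC)}
    if set(faradaic) != expected:
        missing = expected - set(faradaic)
        raise ValueError(f"incomplete trace set; missing {sorted(missing)[:5]} ...")
    current = np.empty((2 * spp, n_steps), dtype=np.float64)
    vmask = np.zeros((2 * spp, n_steps), dtype=bool)
    for s in range(1, n_steps + 1):
        current[:spp, s - 1] = faradaic[(s, PHASE_ANODIC)]
        current[spp:, s - 1] = faradaic[(s, PHASE_CATHODIC)]
        if valid is not None:
            vmask[:spp, s - 1] = valid[(s, PHASE_ANODIC)]
            vmask[spp:, s - 1] = valid[(s, PHASE_CATHODIC)]
    return ColorPlot(
        current=current,
        dt=dt,
        step_potentials=steps,
        scan_index=scan_index,
        valid=vmask if valid is not None else None,
    )
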