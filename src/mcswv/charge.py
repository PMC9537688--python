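"""Adaptive-threshold kernel charge extraction and calibration.

Each scan's Faradaic pseudocolor plot is reduced to a scalar charge by

1. **thresholding** — pixels below ``mean + k·SD`` of the per-pixel
   current response accumulated over the scan history are zeroed out
   (``k`` = 1 SD by default, adjustable).  The threshold can be *fixed* at
   its present level ("Fix"), and *reset* from the statistics of the last
   ``reset_window`` scans (20 by default);
2. **kernel formation** — the retained, oxidation-zone pixels form the
   analyte kernel;
3. **charge integration** — per-pixel charge ``q = I·dt`` (1 nA·ms =
   1 pC) aggregated over the kernel.  The default aggregation is the SUM
   over the kernel (a physical charge, matching the pC magnitudes a real
   electrode produces); a MEAN-over-kernel variant is selectable.

Charges map to concentrations through a straight-line calibration curve
fitted to in-vitro standards of known concentration (100/300/500 nM for
dopamine).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import ColorPlot

__all__ = [
    "ThresholdState",
    "KernelMask",
    "ChargeTrace",
    "CalibrationCurve",
    "update_threshold",
    "compute_kernel",
    "compute_charge",
    "fit_calibration",
    "charge_to_concentration",
    "DEFAULT_K",
    "DEFAULT_RESET_WINDOW",
    "PC_PER_NA_S",
]

DEFAULT_K = 1.0
DEFAULT_RESET_WINDOW = 20
#: 1 nA·ms = 1 pC, i.e. 1000 pC per nA·s.
PC_PER_NA_S = 1e3


class ThresholdState:
    """Running per-pixel threshold statistics across a session.

    In *dynamic* mode the threshold is ``mean + k·SD`` of the pixel
    current distribution accumulated over all scans seen so far (Welford
    running statistics, so memory is independent of session length).  The
    default ``statistic="scalar"`` pools all pixels and scans into one
    mean/SD: analyte-zone pixels sit far above the mostly-near-zero pixel
    population, so the kernel selects the oxidation blob.  A *per-pixel*
    variant (each pixel thresholded against its own scan history) is
    selectable; note that in steady state a pixel only exceeds its own
    mean + 1 SD transiently, so the per-pixel kernel tracks *changes*
    rather than the tonic zone.

    Statistics are tracked as running first and second moments.  By
    default every scan weighs equally (cumulative, "over all scans");
    with ``forgetting`` set to an effective window length ``W`` the
    moments are exponentially weighted with factor ``1/W``, so the
    threshold re-equilibrates within a few ``W`` scans after a tonic
    change instead of dragging the full session history behind it.

    A bounded buffer of the most recent ``reset_window`` plots supports
    the fix/reset workflow: :meth:`fix` freezes the present threshold,
    :meth:`reset` recomputes it from the recent window, :meth:`unfix`
    returns to dynamic updating.
    """

    def __init__(
        self,
        k: float = DEFAULT_K,
        reset_window: int = DEFAULT_RESET_WINDOW,
        statistic: Literal["per-pixel", "scalar"] = "scalar",
        forgetting: float | None = None,
    ) -> None:
        if reset_window < 1:
            raise ValueError("reset_window must be >= 1")
        if forgetting is not None and forgetting < 1:
            raise ValueError("forgetting window must be >= 1 scan")
        self.k = float(k)
        self.reset_window = int(reset_window)
        self.statistic = statistic
        self.forgetting = forgetting
        self.mode: Literal["dynamic", "fixed"] = "dynamic"
        self.fixed_value: np.ndarray | float | None = None
        self.n = 0
        self._m1: np.ndarray | float | None = None  # running E[x]
        self._m2: np.ndarray | float | None = None  # running E[x^2]
        self.history: deque[np.ndarray] = deque(maxlen=self.reset_window)

    def _scan_moments(self, current: np.ndarray, valid: np.ndarray):
        if self.statistic == "scalar":
            vals = current[valid]
            return float(vals.mean()), float(np.mean(vals**2))
        # per-pixel: invalid pixels contribute their value but are never
        # admitted to kernels, so they cannot bias the charge
        return current.astype(np.float64), current.astype(np.float64) ** 2

    def _accumulate(self, current: np.ndarray, valid: np.ndarray) -> None:
        self.history.append((current.copy(), valid.copy()))
        self.n += 1
        m1, m2 = self._scan_moments(current, valid)
        if self._m1 is None:
            self._m1, self._m2 = m1, m2
            return
        # weight 1/n reproduces the exact cumulative mean; a constant
        # 1/forgetting gives exponential forgetting
        w = 1.0 / self.n if self.forgetting is None else max(
            1.0 / self.n, 1.0 / self.forgetting
        )
        self._m1 = (1 - w) * self._m1 + w * m1
        self._m2 = (1 - w) * self._m2 + w * m2

    def _threshold_from(self, plots) -> np.ndarray | float:
        stack = np.stack([c for c, _ in plots])
        if self.statistic == "scalar":
            vmask = np.stack([v for _, v in plots])
            vals = stack[vmask]
            return float(vals.mean() + self.k * vals.std(ddof=0))
        return stack.mean(axis=0) + self.k * stack.std(axis=0, ddof=0)

    def current_threshold(self) -> np.ndarray | float:
        if self.mode == "fixed":
            return self.fixed_value
        if self.n == 0:
            raise RuntimeError("no scans accumulated yet")
        var = np.maximum(self._m2 - np.asarray(self._m1) ** 2, 0.0)
        thr = self._m1 + self.k * np.sqrt(var)
        return float(thr) if self.statistic == "scalar" else thr

    def fix(self) -> None:
        """Hold the present threshold instead of updating dynamically."""
        self.fixed_value = self.current_threshold()
        self.mode = "fixed"

    def unfix(self) -> None:
        self.mode = "dynamic"
        self.fixed_value = None

    def reset(self) -> None:
        """Recompute the fixed threshold from the last ``reset_window`` scans."""
        if not self.history:
            raise RuntimeError("no scan history to reset from")
        self.fixed_value = self._threshold_from(list(self.history))
        self.mode = "fixed"


@dataclass
class KernelMask:
    """Binary pixel mask over a ColorPlot used for charge aggregation."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def size(self) -> int:
        """Number of retained pixels."""
        return int(self.mask.sum())


@dataclass
class ChargeTraceEntry:
    """Per-scan provenance record of the charge computation."""

    scan_index: int
    charge_pc: float
    threshold_na: float
    kernel_px: int
    filtered: bool
    concentration_nm: float | None = None
    flagged: bool = False


class ChargeTrace:
    """Append-only per-scan charge record with full threshold provenance."""

    def __init__(self) -> None:
        self.entries: list[ChargeTraceEntry] = []

    def append(self, entry: ChargeTraceEntry) -> None:
        if self.entries and entry.scan_index <= self.entries[-1].scan_index:
            raise ValueError("scan_index must be strictly increasing")
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def charges(self) -> np.ndarray:
        return np.array([e.charge_pc for e in self.entries])

    def to_frame(self, repetition_period: float = 10.0) -> pd.DataFrame:
        """Tabular export (one row per scan) for delimited-text output."""
        return pd.DataFrame(
            {
                "scan": [e.scan_index for e in self.entries],
                "time_s": [e.scan_index * repetition_period for e in self.entries],
                "charge_pC": [e.charge_pc for e in self.entries],
                "conc_nM": [e.concentration_nm for e in self.entries],
                "threshold_nA": [e.threshold_na for e in self.entries],
                "kernel_px": [e.kernel_px for e in self.entries],
                "filtered": [e.filtered for e in self.entries],
            }
        )


def update_threshold(
    state: ThresholdState, plot: ColorPlot
) -> np.ndarray | float:
    """Accumulate a scan into the threshold statistics and return the
    threshold to use for it.

    Dynamic mode: ``mean + k·SD`` of the valid-pixel current distribution
    over all scans including this one (charging-spike pixels are excluded
    so their large unsubtracted transients cannot bias the statistics).
    Fixed mode: the stored value (the scan still enters the history
    buffer so a later reset sees it).  With an empty history the first
    scan's own values act as the threshold — flagged by the caller.
    """
    state._accumulate(plot.current, plot.valid)
    return state.current_threshold()


def compute_kernel(
    plot: ColorPlot,
    threshold: np.ndarray | float,
    oxidation_only: bool = True,
) -> KernelMask:
    """Threshold the plot into the charge-computation kernel.

    A pixel is retained when its current is >= the (per-pixel or scalar)
    threshold, it lies inside the background-fit validity window, and —
    by default — it sits in the oxidation (anodic) half of the plot.  Set
    ``oxidation_only=False`` to also admit reduction-zone pixels whose
    *negated* current clears the threshold.
    """
    thr = np.broadcast_to(np.asarray(threshold, dtype=np.float64), plot.current.shape)
    if not np.all(np.isfinite(thr)):
        raise ValueError("threshold must be finite")
    spp = plot.samples_per_phase
    mask = plot.current >= thr
    if oxidation_only:
        mask[spp:] = False
    else:
        mask[spp:] = (-plot.current[spp:]) >= thr[spp:]
    mask &= plot.valid
    return KernelMask(mask=mask)


def compute_charge(
    plot: ColorPlot,
    kernel: KernelMask,
    aggregation: Literal["sum", "mean"] = "sum",
) -> float:
    """Aggregate per-pixel charge ``|I|·dt`` over the kernel, in pC.

    ``sum`` (default) returns the total Faradaic charge; ``mean`` returns
    the average per-pixel charge.  An empty kernel yields 0 pC.
    """
    if kernel.mask.shape != plot.current.shape:
        raise ValueError("kernel shape does not match plot shape")
    if kernel.size == 0:
        return 0.0
    q = np.abs(plot.current[kernel.mask]) * plot.dt * PC_PER_NA_S
    return float(q.sum() if aggregation == "sum" else q.mean())


@dataclass
class CalibrationCurve:
    """Straight-line charge-vs-concentration calibration.

    ``charge_pC = slope · concentration_nM + intercept``; fitted by
    ordinary least squares to in-vitro standards.
    """

    concentrations: np.ndarray
    charges: np.ndarray
    slope: float
    intercept: float
    residuals: np.ndarray
    r_value: float

    def predict_charge(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    standards: np.ndarray, charges: np.ndarray
) -> CalibrationCurve:
    """Least-squares line through (concentration, charge) standards."""
    standards = np.asarray(standards, dtype=np.float64)
    charges = np.asarray(charges, dtype=np.float64)
    if standards.size < 2 or standards.size != charges.size:
        raise ValueError("need >= 2 (concentration, charge) standards")
    if np.unique(standards).size < 2:
        raise ValueError("standards are degenerate: all concentrations equal")
    res = stats.linregress(standards, charges)
    fitted = res.slope * standards + res.intercept
    return CalibrationCurve(
        concentrations=standards,
        charges=charges,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residuals=charges - fitted,
        r_value=float(res.rvalue),
    )


def charge_to_concentration(
    curve: CalibrationCurve, charge: float
) -> tuple[float, bool]:
    """Invert the calibration line: charge (pC) -> concentration (nM).

    Returns ``(concentration, floored)``; negative estimates are floored
    at 0 with ``floored=True``.
    """
    if curve.slope <= 0:
        raise ValueError(f"calibration slope {curve.slope:g} is not positive")
    conc = (charge - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return float(conc), False
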