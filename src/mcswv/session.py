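"""Streaming session storage, parameter logging, and the analysis pipeline.

Raw scans are quantized from float64 nA to int16 counts and appended to a
binary container so that hours-long sessions never saturate memory: the
writer releases each scan after appending and the reader yields scans
lazily.  The container is a single JSON text header line followed by
fixed-size records::

    header line (UTF-8 JSON + b"\\n")
    record := uint32 scan_index | float64 timestamp | int16 * n_samples

all little-endian.  ``scale`` (nA per count) is stored in the header and
defaults to full-scale = preamp gain × ADC voltage range, never
hard-coded.  A plain-text export mode (TSV, one scan per row) is provided
for parity with text-based workflows; its layout is documented here, not
claimed compatible with any other tool.

``run_pipeline`` executes the full per-scan analysis chain —
segment → fit background → CSW-pair subtract → residual subtract →
pseudocolor plot → optional FFT mask filter → threshold/kernel → charge —
streaming one scan at a time, and can replay a session under a per-scan
parameter log to reproduce a live run bit-identically.  Raw data are
never mutated by any stage.
"""

from __future__ import annotations

import hashlib
import json
import struct
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

from .charge import (
    DEFAULT_K,
    DEFAULT_RESET_WINDOW,
    CalibrationCurve,
    ChargeTrace,
    ChargeTraceEntry,
    ThresholdState,
    charge_to_concentration,
    compute_charge,
    compute_kernel,
    update_threshold,
)
from .extraction import (
    DEFAULT_BACKGROUND_CSW,
    DEFAULT_SIGNAL_CSW,
    assemble_colorplot,
    csw_pair_difference,
    residual_background_subtract,
)
from .segmentation import DEFAULT_SKIP_FRACTION, fit_all_segments, segment_scan
from .simulate import RawScan
from .spectral import apply_mask_filter, build_elliptical_mask, default_radii
from .waveform import SampledWaveform, WaveformSpec, render_waveform

__all__ = [
    "SessionHeader",
    "AnalysisParams",
    "SessionWriter",
    "read_session",
    "write_session",
    "run_pipeline",
    "write_parameter_log",
    "read_parameter_log",
]

_MAGIC = "mcswv-session"
_FORMAT_VERSION = 1
_ADC_RANGE_V = 10.0  # ± volts at the digitizer input


@dataclass
class SessionHeader:
    """Metadata stored at the head of a session file."""

    sample_rate: float
    n_samples: int
    preamp_gain: float = 2000.0
    scale: float | None = None  # nA per int16 count
    waveform_preset: str = ""
    waveform_hash: str = ""
    start_timestamp: float = 0.0
    version: int = _FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.scale is None:
            # full scale = preamp gain (nA/V) × ADC range (V) over int16 range
            self.scale = self.preamp_gain * _ADC_RANGE_V / 32767.0
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def record_size(self) -> int:
        return 4 + 8 + 2 * self.n_samples

    def to_json(self) -> str:
        d = asdict(self)
        d["magic"] = _MAGIC
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SessionHeader":
        d = json.loads(text)
        if d.pop("magic", None) != _MAGIC:
            raise ValueError("not a session file (bad magic)")
        return cls(**d)


def waveform_hash(spec: WaveformSpec) -> str:
    """Stable short hash identifying a waveform parameterization."""
    payload = json.dumps(
        {k: getattr(spec, k) for k in spec.__dataclass_fields__}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class SessionWriter:
    """Appends quantized scans to a binary sink with bounded memory.

    Per-scan clipping (samples beyond int16 full scale) is counted and
    reported in :attr:`clip_counts`; a failed append is retried once
    before the error surfaces — a scan is never silently dropped.
    """

    def __init__(self, sink: IO[bytes], header: SessionHeader) -> None:
        self.sink = sink
        self.header = header
        self.clip_counts: list[int] = []
        sink.write(header.to_json().encode() + b"\n")

    def write_scan(self, raw: RawScan) -> int:
        """Quantize and append one scan; returns clipped-sample count."""
        if raw.current.size != self.header.n_samples:
            raise ValueError(
                f"scan has {raw.current.size} samples, header says "
                f"{self.header.n_samples}"
            )
        counts = np.round(raw.current / self.header.scale)
        n_clip = int(np.count_nonzero((counts < -32768) | (counts > 32767)))
        counts = np.clip(counts, -32768, 32767).astype("<i2")
        record = (
            struct.pack("<I", raw.scan_index)
            + struct.pack("<d", raw.timestamp)
            + counts.tobytes()
        )
        try:
            self.sink.write(record)
        except OSError:
            self.sink.write(record)  # one retry, then surface
        self.clip_counts.append(n_clip)
        return n_clip


def write_session(
    scans: Iterable[RawScan], header: SessionHeader, path: str | Path
) -> list[int]:
    """Stream scans to a new session file; returns per-scan clip counts."""
    with open(path, "wb") as fh:
        writer = SessionWriter(fh, header)
        for raw in scans:
            writer.write_scan(raw)
    return writer.clip_counts


def read_session(
    source: str | Path | IO[bytes],
) -> tuple[SessionHeader, Iterator[RawScan]]:
    """Open a session file; returns the header and a lazy scan iterator.

    Scans are dequantized back to nA.  A truncated final record is not
    yielded; a warning reports the truncation instead.
    """
    fh = open(source, "rb") if isinstance(source, (str, Path)) else source
    header_line = fh.readline()
    header = SessionHeader.from_json(header_line.decode())

    def _iter() -> Iterator[RawScan]:
        rec = header.record_size
        try:
            while True:
                buf = fh.read(rec)
                if not buf:
                    break
                if len(buf) < rec:
                    warnings.warn(
                        f"truncated final record ({len(buf)} of {rec} bytes) "
                        "ignored",
                        stacklevel=2,
                    )
                    break
                scan_index = struct.unpack_from("<I", buf, 0)[0]
                timestamp = struct.unpack_from("<d", buf, 4)[0]
                counts = np.frombuffer(buf, dtype="<i2", offset=12)
                yield RawScan(
                    current=counts.astype(np.float64) * header.scale,
                    scan_index=int(scan_index),
                    timestamp=float(timestamp),
                )
        finally:
            if isinstance(source, (str, Path)):
                fh.close()

    return header, _iter()


def export_session_text(source: str | Path, out: str | Path) -> None:
    """Text export: header JSON line, then one tab-separated int16 row per
    scan prefixed by ``scan_index`` and ``timestamp``.  Documented layout
    of this package; larger and slower than the binary container."""
    header, scans = read_session(source)
    with open(out, "w") as fh:
        fh.write(header.to_json() + "\n")
        for raw in scans:
            counts = np.round(raw.current / header.scale).astype(int)
            fh.write(
                f"{raw.scan_index}\t{raw.timestamp!r}\t"
                + "\t".join(map(str, counts.tolist()))
                + "\n"
            )


@dataclass
class AnalysisParams:
    """Per-scan (or global) analysis parameters; one row of the log."""

    skip_fraction: float = DEFAULT_SKIP_FRACTION
    filter_on: bool = False
    radius_rows: float | None = None
    radius_cols: float | None = None
    threshold_mode: str = "dynamic"  # dynamic | fixed
    k: float = DEFAULT_K
    fixed_value: float | None = None
    threshold_statistic: str = "scalar"  # scalar | per-pixel
    threshold_forgetting: float | None = None  # effective window, scans
    kernel_aggregation: str = "sum"  # sum | mean
    oxidation_only: bool = True
    signal_csw: int = DEFAULT_SIGNAL_CSW
    background_csw: int = DEFAULT_BACKGROUND_CSW


_LOG_COLUMNS = [
    "scan_index",
    "skip_fraction",
    "filter_on",
    "radius_rows",
    "radius_cols",
    "threshold_mode",
    "k",
    "fixed_value",
    "threshold_statistic",
    "threshold_forgetting",
    "kernel_aggregation",
    "oxidation_only",
    "signal_csw",
    "background_csw",
]


def write_parameter_log(
    rows: dict[int, AnalysisParams], path: str | Path
) -> None:
    """Write a per-scan parameter log (CSV, one row per scan)."""
    records = []
    for scan_index in sorted(rows):
        d = asdict(rows[scan_index])
        d["scan_index"] = scan_index
        records.append(d)
    pd.DataFrame.from_records(records, columns=_LOG_COLUMNS).to_csv(
        path, index=False
    )


def read_parameter_log(path: str | Path) -> dict[int, AnalysisParams]:
    df = pd.read_csv(path)
    out: dict[int, AnalysisParams] = {}
    for _, row in df.iterrows():
        d = row.to_dict()
        idx = int(d.pop("scan_index"))
        for key in ("radius_rows", "radius_cols", "fixed_value", "threshold_forgetting"):
            if pd.isna(d.get(key)):
                d[key] = None
        d["filter_on"] = bool(d["filter_on"])
        d["oxidation_only"] = bool(d["oxidation_only"])
        d["signal_csw"] = int(d["signal_csw"])
        d["background_csw"] = int(d["background_csw"])
        out[idx] = AnalysisParams(**d)
    return out


def run_pipeline(
    scans: Iterable[RawScan],
    spec: WaveformSpec,
    params: AnalysisParams | None = None,
    parameter_log: dict[int, AnalysisParams] | None = None,
    calibration: CalibrationCurve | None = None,
    wf: SampledWaveform | None = None,
    reset_window: int = DEFAULT_RESET_WINDOW,
    collect_plots: bool = False,
):
    """Run the full analysis chain over a scan stream.

    Parameters are either a single global :class:`AnalysisParams` or a
    per-scan ``parameter_log`` (scan_index -> params); the log reproduces
    a live run's per-scan parameter changes exactly, so replaying a
    session with its log yields a bit-identical charge trace.  Memory is
    bounded: only the threshold statistics and (optionally) collected
    plots outlive a scan.

    Returns ``(trace, plots)`` where ``plots`` is a list of per-scan
    ColorPlots when ``collect_plots`` else an empty list.
    """
    if params is None:
        params = AnalysisParams()
    if wf is None:
        wf = render_waveform(spec)
    state = ThresholdState(
        k=params.k,
        reset_window=reset_window,
        statistic=params.threshold_statistic,
        forgetting=params.threshold_forgetting,
    )
    trace = ChargeTrace()
    plots = []
    prev_fits: dict[tuple[int, int, int], object] | None = None
    dt = 1.0 / spec.sample_rate

    for raw in scans:
        p = (
            parameter_log.get(raw.scan_index, params)
            if parameter_log is not None
            else params
        )
        flagged = False
        try:
            segments = segment_scan(raw, wf)
            # only the pair-subtraction CSWs need background fits
            fit_targets = [
                s for s in segments
                if s.csw_index in (p.signal_csw, p.background_csw)
            ]
            fits = fit_all_segments(
                fit_targets, skip_fraction=p.skip_fraction, previous=prev_fits
            )
            fit_map = {s.key: f for s, f in zip(fit_targets, fits)}
            prev_fits = fit_map
            diff = csw_pair_difference(
                segments, signal_csw=p.signal_csw, background_csw=p.background_csw
            )
            fits_sig = {
                (s, ph): fit_map[(p.signal_csw, s, ph)]
                for (s, ph) in diff
                if (p.signal_csw, s, ph) in fit_map
            }
            fits_bg = {
                (s, ph): fit_map[(p.background_csw, s, ph)]
                for (s, ph) in diff
                if (p.background_csw, s, ph) in fit_map
            }
            faradaic, valid = residual_background_subtract(
                diff, fits_sig, fits_bg, dt
            )
            plot = assemble_colorplot(
                faradaic, spec, dt, scan_index=raw.scan_index, valid=valid
            )
        except ValueError as err:
            warnings.warn(f"scan {raw.scan_index} failed: {err}", stacklevel=2)
            trace.append(
                ChargeTraceEntry(
                    scan_index=raw.scan_index,
                    charge_pc=float("nan"),
                    threshold_na=float("nan"),
                    kernel_px=0,
                    filtered=False,
                    flagged=True,
                )
            )
            continue

        analysis_plot = plot
        if p.filter_on:
            radii = (
                (p.radius_rows, p.radius_cols)
                if p.radius_rows is not None and p.radius_cols is not None
                else default_radii(plot.current.shape)
            )
            mask = build_elliptical_mask(plot.current.shape, *radii)
            analysis_plot = apply_mask_filter(plot, mask, radii=radii)

        if p.threshold_mode == "fixed" and p.fixed_value is not None:
            state.mode = "fixed"
            state.fixed_value = p.fixed_value
        first_scan = state.n == 0
        threshold = update_threshold(state, analysis_plot)
        kernel = compute_kernel(
            analysis_plot, threshold, oxidation_only=p.oxidation_only
        )
        charge = compute_charge(
            analysis_plot, kernel, aggregation=p.kernel_aggregation
        )
        conc = None
        if calibration is not None:
            conc, _ = charge_to_concentration(calibration, charge)
        thr_scalar = float(np.mean(threshold))
        trace.append(
            ChargeTraceEntry(
                scan_index=raw.scan_index,
                charge_pc=charge,
                threshold_na=thr_scalar,
                kernel_px=kernel.size,
                filtered=analysis_plot.filtered,
                concentration_nm=conc,
                flagged=flagged or first_scan,
            )
        )
        if collect_plots:
            plots.append(analysis_plot)
    return trace, plots
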