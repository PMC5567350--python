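"""Breath segmentation, artifact masking, epoch selection and ventilation.

The segmentation strategy: band-pass the pressure channel around plausible
breathing frequencies, find inspiratory peaks by prominence with a
refractory minimum spacing, and take the trough between successive peaks as
the breath onset.  Amplitude is peak minus preceding trough on the filtered
signal.  This mirrors how plethysmography waveforms are scored by hand:
each breath is a trough-to-peak excursion, and the interbreath interval
(IBI) is the onset-to-onset time.

Epoch selection implements the analysis-window rule used for conscious,
unrestrained recordings: artifact-free segments of at least ``min_segment``
seconds (default 10 s) drawn from the last ``window_s`` seconds (default
600 s) of a condition block, accumulated latest-first until at least
``cumulative_target`` seconds (default 60 s) have been collected; if the
target cannot be reached the selection is flagged insufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .trace_io import ConditionSchedule, ScheduleBlock, Trace

__all__ = [
    "DetectionParams",
    "ArtifactParams",
    "SelectionCriteria",
    "EpochSelection",
    "VentilationMetrics",
    "detect_breaths",
    "detect_artifacts",
    "select_epochs",
    "select_epochs_in_block",
    "compute_ventilation",
    "breaths_in_selection",
]

BREATH_COLUMNS = ["onset", "peak_time", "amplitude", "ibi"]


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the peak-prominence breath detector.

    ``band`` brackets plausible mouse breathing content (fundamental plus
    the harmonics that carry the pulse shape); ``prominence_factor`` sets
    the minimum peak prominence as a fraction of the robust amplitude scale
    (95th percentile of |filtered signal|); ``refractory_s`` is the minimum
    peak spacing, bounding the maximum detectable rate.
    """

    band: tuple[float, float] = (0.5, 30.0)
    prominence_factor: float = 0.3
    refractory_s: float = 0.05
    filter_order: int = 2


@dataclass(frozen=True)
class ArtifactParams:
    """Movement-artifact detector: short-window signal power against a
    robust whole-trace reference (a low quantile of window power, so the
    reference stays on clean breathing even when bursts cover half the
    record), with a small dilation so burst edges are covered."""

    window_s: float = 0.25
    threshold_factor: float = 12.0
    reference_quantile: float = 20.0
    dilate_s: float = 0.2


@dataclass(frozen=True)
class SelectionCriteria:
    min_segment: float = 10.0  # s, shortest usable artifact-free segment
    cumulative_target: float = 60.0  # s, analysis time to accumulate
    window_s: float = 600.0  # s, look-back window at the end of a block

    def __post_init__(self) -> None:
        if self.min_segment <= 0 or self.cumulative_target <= 0 or self.window_s <= 0:
            raise ValueError("selection criteria must be positive")


@dataclass
class EpochSelection:
    """Artifact-free analysis intervals chosen from one condition block."""

    intervals: list[tuple[float, float]]
    source_condition: str
    cno_status: str | None = None
    insufficient: bool = False
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    def __post_init__(self) -> None:
        self.intervals = sorted((float(s), float(e)) for s, e in self.intervals)
        prev = -math.inf
        for s, e in self.intervals:
            if e <= s:
                raise ValueError("selection interval with non-positive length")
            if s < prev:
                raise ValueError("selection intervals must be disjoint")
            prev = e

    @property
    def total_duration(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean: which times fall inside a selected interval."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for s, e in self.intervals:
            out |= (t >= s) & (t < e)
        return out


@dataclass(frozen=True)
class VentilationMetrics:
    vf: float  # breaths/min
    vt: float  # mL/breath/g
    ve: float  # mL/min/g

    def __post_init__(self) -> None:
        if min(self.vf, self.vt, self.ve) < 0:
            raise ValueError("ventilation metrics must be non-negative")


def _bandpass(x: np.ndarray, fs: float, params: DetectionParams) -> np.ndarray:
    lo, hi = params.band
    if fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz is below Nyquist for the {hi} Hz detection band"
        )
    sos = signal.butter(params.filter_order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_breaths(trace: Trace, params: DetectionParams | None = None) -> pd.DataFrame:
    """Segment the pressure channel into breaths.

    Returns a breath table with one row per breath: ``onset`` (preceding
    trough time, s), ``peak_time`` (s), ``amplitude`` (peak minus preceding
    trough, filtered signal units) and ``ibi`` (onset-to-next-onset, s; NaN
    for the final breath).  A flat signal yields an empty table.

    The first detected peak usually has no recorded trough before it; its
    onset is extrapolated as ``peak_time`` minus the median trough-to-peak
    delay of the remaining breaths, and may precede the trace start (the
    breath began before the recording).
    """
    params = params or DetectionParams()
    if "pressure" not in trace.channels:
        raise ValueError("trace has no pressure channel")
    fs = trace.sampling_rate
    if fs <= 2 * params.band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz is below Nyquist for the {params.band[1]} Hz detection band"
        )
    x = trace.channels["pressure"]
    empty = pd.DataFrame(columns=BREATH_COLUMNS, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return empty
    xf = _bandpass(x, fs, params)
    scale = float(np.percentile(np.abs(xf), 95))
    if scale <= 0:
        return empty
    peaks, _ = signal.find_peaks(
        xf,
        prominence=params.prominence_factor * scale,
        distance=max(1, int(round(params.refractory_s * fs))),
    )
    if peaks.size == 0:
        return empty

    onset_idx = np.empty(peaks.size, dtype=float)
    amplitude = np.empty(peaks.size)
    for k in range(1, peaks.size):
        seg = xf[peaks[k - 1] : peaks[k]]
        j = int(np.argmin(seg)) + peaks[k - 1]
        onset_idx[k] = j
        amplitude[k] = xf[peaks[k]] - xf[j]
    trough_val = float(np.min(xf[: peaks[0]])) if peaks[0] > 0 else float(xf[0])
    if peaks.size > 1:
        delay = float(np.median(peaks[1:] - onset_idx[1:]))
        onset_idx[0] = peaks[0] - delay
    else:
        onset_idx[0] = int(np.argmin(xf[: peaks[0]])) if peaks[0] > 0 else 0
    amplitude[0] = xf[peaks[0]] - trough_val

    onsets = trace.start_time + onset_idx / fs
    ibi = np.append(np.diff(onsets), np.nan)
    return pd.DataFrame(
        {
            "onset": onsets,
            "peak_time": trace.start_time + peaks / fs,
            "amplitude": amplitude,
            "ibi": ibi,
        }
    )


def detect_artifacts(trace: Trace, params: ArtifactParams | None = None) -> np.ndarray:
    """Flag movement-artifact samples on the pressure channel.

    Short-window mean power is compared against ``threshold_factor`` times
    the ``reference_quantile``-th percentile of window power (a robust
    breathing-power reference); flagged regions are dilated by ``dilate_s``
    to cover burst edges.  Returns a boolean mask aligned with the trace
    samples.  The relative reference fails only when artifacts occupy
    nearly the whole record, in which case selection downstream reports
    insufficient data anyway.
    """
    params = params or ArtifactParams()
    if "pressure" not in trace.channels:
        raise ValueError("trace has no pressure channel")
    x = trace.channels["pressure"]
    fs = trace.sampling_rate
    if x.size == 0:
        return np.zeros(0, dtype=bool)
    centred = x - np.median(x)
    w = max(1, int(round(params.window_s * fs)))
    power = ndimage.uniform_filter1d(centred**2, size=w, mode="nearest")
    ref = float(np.percentile(power, params.reference_quantile))
    if ref <= 0:
        return np.zeros(x.size, dtype=bool)
    mask = power > params.threshold_factor * ref
    if params.dilate_s > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=max(1, int(round(params.dilate_s * fs))))
    return mask


def _clean_runs(mask: np.ndarray, fs: float, t0: float) -> list[tuple[float, float]]:
    """Maximal unmasked runs as (start, end) times."""
    clean = ~mask
    if not clean.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], clean.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    return [(t0 + s / fs, t0 + e / fs) for s, e in zip(starts, ends)]


def select_epochs_in_block(
    trace: Trace,
    block: ScheduleBlock,
    criteria: SelectionCriteria | None = None,
    artifact_mask: np.ndarray | None = None,
    artifact_params: ArtifactParams | None = None,
) -> EpochSelection:
    """Apply the epoch-selection rule within one schedule block."""
    criteria = criteria or SelectionCriteria()
    if artifact_mask is None:
        artifact_mask = (
            trace.artifact_mask
            if trace.artifact_mask is not None
            else detect_artifacts(trace, artifact_params)
        )
    window_start = max(block.start, block.end - criteria.window_s)
    sub = trace.slice(window_start, min(block.end, trace.start_time + trace.duration))
    i0 = int(round((sub.start_time - trace.start_time) * trace.sampling_rate))
    sub_mask = artifact_mask[i0 : i0 + sub.n_samples]
    runs = [
        (s, e)
        for s, e in _clean_runs(sub_mask, trace.sampling_rate, sub.start_time)
        if e - s >= criteria.min_segment
    ]
    chosen: list[tuple[float, float]] = []
    total = 0.0
    for s, e in reversed(runs):  # latest-first accumulation
        chosen.append((s, e))
        total += e - s
        if total >= criteria.cumulative_target:
            break
    return EpochSelection(
        intervals=chosen,
        source_condition=block.label,
        cno_status=block.cno_status,
        insufficient=total < criteria.cumulative_target,
        criteria=criteria,
    )


def select_epochs(
    trace: Trace,
    schedule: ConditionSchedule,
    condition_label: str,
    cno_status: str,
    criteria: SelectionCriteria | None = None,
    artifact_mask: np.ndarray | None = None,
) -> EpochSelection:
    """Select analysis epochs for a (condition, CNO status) cell.

    When the schedule contains several matching blocks the last one is
    used (the steady-state instance of the condition); analyse blocks
    individually with :func:`select_epochs_in_block` if finer control is
    needed.
    """
    blocks = schedule.matching(condition_label, cno_status)
    if not blocks:
        raise ValueError(f"no {condition_label!r}/{cno_status!r} block in schedule")
    return select_epochs_in_block(trace, blocks[-1], criteria, artifact_mask)


def breaths_in_selection(breaths: pd.DataFrame, selection: EpochSelection) -> pd.DataFrame:
    """Breaths whose onset falls inside a selected interval (half-open)."""
    if breaths.empty:
        return breaths
    return breaths[selection.contains(breaths["onset"].to_numpy())]


def compute_ventilation(
    breaths: pd.DataFrame,
    selection: EpochSelection,
    calibration_factor: float,
    mass: float,
) -> VentilationMetrics:
    """Ventilatory metrics over the selected epochs.

    ``vf`` is the breath count inside the selection divided by the selected
    minutes; ``vt`` is the mean breath amplitude scaled by the
    known-volume calibration factor (mL per signal unit) and normalised to
    body mass; ``ve = vf * vt``.
    """
    if calibration_factor <= 0 or mass <= 0:
        raise ValueError("calibration_factor and mass must be positive")
    minutes = selection.total_duration / 60.0
    if minutes <= 0:
        raise ValueError("selection has zero duration")
    inside = breaths_in_selection(breaths, selection)
    vf = len(inside) / minutes
    amp = float(inside["amplitude"].mean()) if len(inside) else 0.0
    vt = amp * calibration_factor / mass
    return VentilationMetrics(vf=vf, vt=vt, ve=vf * vt)
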