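"""Apnea/sigh calling and breathing-variability metrics.

Event definitions, applied over the same ~1-minute epoch compilation used
for the ventilatory metrics:

* **Apnea** -- an interbreath interval (IBI) at least ``factor`` (default 2)
  times the mean IBI of the compilation.
* **Sigh** -- a breath whose amplitude is at least ``factor`` (default 2)
  times the mean amplitude of the compilation.

The compilation mean includes the apneic IBIs and sigh amplitudes
themselves; there is no iterative re-estimation, and "at least" is
inclusive (>=).  Rates are events per minute of selected time.

Two coefficients of variation are reported for both IBI and amplitude:
``cv`` = (SD/sqrt(n))/mean -- a standard-error-over-mean form used as the
instability index -- and the conventional ``cv_sd`` = SD/mean, which equals
``cv * sqrt(n)``.  Sample SDs use n-1.

Poincare (first-return map) descriptors of the IBI series follow the
standard short/long-term decomposition: SD1^2 = SDSD^2 / 2 and
SD2^2 = 2 SDNN^2 - SDSD^2 / 2, where SDNN is the SD of the IBIs and SDSD
the SD of successive differences; by construction SD1^2 + SD2^2 = 2 SDNN^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breath_analysis import EpochSelection, breaths_in_selection

__all__ = [
    "EventCalls",
    "PatternMetrics",
    "call_apneas",
    "call_sighs",
    "variability",
    "compilation_ibis",
]


@dataclass(frozen=True)
class EventCalls:
    """Called events of one type within an epoch compilation."""

    kind: str  # apnea | sigh
    times: np.ndarray  # onset time (s) of each called event
    rate: float  # events/min of selected time (NaN when undefined)
    threshold: float  # the factor x mean cutoff actually applied
    n_breaths: int
    flagged: bool = False  # too few breaths to define the call


@dataclass(frozen=True)
class PatternMetrics:
    apnea_rate: float  # events/min
    sigh_rate: float  # events/min
    cv_ibi: float  # (SD/sqrt(n))/mean, the reported instability index
    cv_amp: float
    cv_ibi_sd: float  # conventional SD/mean
    cv_amp_sd: float
    poincare_sd1: float  # s
    poincare_sd2: float  # s

    def __post_init__(self) -> None:
        for name in ("cv_ibi", "cv_amp", "cv_ibi_sd", "cv_amp_sd",
                     "poincare_sd1", "poincare_sd2"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")


def compilation_ibis(breaths: pd.DataFrame, selection: EpochSelection) -> np.ndarray:
    """IBIs of the compilation: onset-to-next-onset gaps whose *both*
    endpoints lie inside the same selected interval, so gaps spanning
    discarded (artifact) time are never counted as breathing pauses."""
    if breaths.empty:
        return np.empty(0)
    onsets = breaths["onset"].to_numpy()
    ibis = []
    for s, e in selection.intervals:
        inside = onsets[(onsets >= s) & (onsets < e)]
        if inside.size >= 2:
            ibis.append(np.diff(inside))
    return np.concatenate(ibis) if ibis else np.empty(0)


def _ibi_times(breaths: pd.DataFrame, selection: EpochSelection) -> tuple[np.ndarray, np.ndarray]:
    onsets = breaths["onset"].to_numpy() if not breaths.empty else np.empty(0)
    times, ibis = [], []
    for s, e in selection.intervals:
        inside = onsets[(onsets >= s) & (onsets < e)]
        if inside.size >= 2:
            times.append(inside[:-1])
            ibis.append(np.diff(inside))
    if not ibis:
        return np.empty(0), np.empty(0)
    return np.concatenate(times), np.concatenate(ibis)


def call_apneas(
    breaths: pd.DataFrame, selection: EpochSelection, factor: float = 2.0
) -> EventCalls:
    """Call apneas: IBIs >= ``factor`` x the compilation mean IBI."""
    times, ibis = _ibi_times(breaths, selection)
    minutes = selection.total_duration / 60.0
    if ibis.size < 1 or len(breaths) < 2:
        return EventCalls("apnea", np.empty(0), np.nan, np.nan, len(breaths), flagged=True)
    threshold = factor * float(ibis.mean())
    hit = ibis >= threshold
    return EventCalls(
        kind="apnea",
        times=times[hit],
        rate=int(hit.sum()) / minutes,
        threshold=threshold,
        n_breaths=len(breaths),
    )


def call_sighs(
    breaths: pd.DataFrame, selection: EpochSelection, factor: float = 2.0
) -> EventCalls:
    """Call sighs: breath amplitudes >= ``factor`` x the compilation mean."""
    inside = breaths_in_selection(breaths, selection)
    minutes = selection.total_duration / 60.0
    if inside.empty:
        return EventCalls("sigh", np.empty(0), np.nan, np.nan, 0, flagged=True)
    amps = inside["amplitude"].to_numpy()
    threshold = factor * float(amps.mean())
    hit = amps >= threshold
    return EventCalls(
        kind="sigh",
        times=inside["onset"].to_numpy()[hit],
        rate=int(hit.sum()) / minutes,
        threshold=threshold,
        n_breaths=len(inside),
    )


def _cv_pair(x: np.ndarray) -> tuple[float, float]:
    mean = float(x.mean())
    if mean == 0:
        return np.nan, np.nan
    sd = float(x.std(ddof=1))
    return (sd / np.sqrt(x.size)) / mean, sd / mean


def _poincare(ibis: np.ndarray) -> tuple[float, float]:
    if ibis.size < 3:
        return np.nan, np.nan
    sdnn = float(ibis.std(ddof=1))
    sdsd = float(np.diff(ibis).std(ddof=1))
    sd1_sq = 0.5 * sdsd**2
    sd2_sq = max(2.0 * sdnn**2 - 0.5 * sdsd**2, 0.0)
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


def variability(
    breaths: pd.DataFrame,
    selection: EpochSelection,
    apnea_factor: float = 2.0,
    sigh_factor: float = 2.0,
) -> PatternMetrics:
    """All pattern metrics over one epoch compilation.

    Requires at least 3 breaths inside the selection; otherwise every
    field is NaN (callers should treat the record as undefined).
    """
    inside = breaths_in_selection(breaths, selection)
    ibis = compilation_ibis(breaths, selection)
    if len(inside) < 3 or ibis.size < 2:
        nan = float("nan")
        return PatternMetrics(nan, nan, nan, nan, nan, nan, nan, nan)
    cv_ibi, cv_ibi_sd = _cv_pair(ibis)
    cv_amp, cv_amp_sd = _cv_pair(inside["amplitude"].to_numpy())
    sd1, sd2 = _poincare(ibis)
    return PatternMetrics(
        apnea_rate=call_apneas(breaths, selection, apnea_factor).rate,
        sigh_rate=call_sighs(breaths, selection, sigh_factor).rate,
        cv_ibi=cv_ibi,
        cv_amp=cv_amp,
        cv_ibi_sd=cv_ibi_sd,
        cv_amp_sd=cv_amp_sd,
        poincare_sd1=sd1,
        poincare_sd2=sd2,
    )
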