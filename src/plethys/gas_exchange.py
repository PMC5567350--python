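"""Oxygen consumption from chamber O2 traces, with first-order lag correction.

A flow-through plethysmography chamber dilutes the animal's oxygen uptake
into the carrier flow: at steady state

    F_out = F_in - VO2_total / flow,

so comparing the mean outflow O2 fraction during live breathing against an
empty-chamber calibration segment recovers VO2.  The gas path (chamber
washout plus inline sensor) behaves as a first-order low-pass with time
constant tau (~1.5 s as calibrated by acute carboxygen injections);
:func:`correct_lag` inverts one first-order stage so transients line up
with the pressure record before the steady-state means are taken.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .breath_analysis import EpochSelection, VentilationMetrics

__all__ = [
    "OxygenConsumption",
    "DEFAULT_TAU",
    "correct_lag",
    "apply_lag",
    "estimate_vo2",
    "ventilatory_equivalent",
]

#: Calibrated gas-path time constant, seconds.
DEFAULT_TAU = 1.5


@dataclass(frozen=True)
class OxygenConsumption:
    vo2: float  # mL O2/min/g
    lag_tau: float  # s
    flow: float  # mL/min
    fraction_difference: float  # calibration minus animal mean O2 fraction

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise ValueError("flow must be positive")


def apply_lag(x: np.ndarray, tau: float, sampling_rate: float) -> np.ndarray:
    """Forward first-order low-pass (exact exponential stepping); the
    model of the chamber/sensor lag that :func:`correct_lag` inverts."""
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        return x.copy()
    a = math.exp(-1.0 / (tau * sampling_rate))
    out = np.empty_like(x)
    y = x[0]
    b = 1.0 - a
    for i, v in enumerate(x):
        y = a * y + b * v
        out[i] = y
    return out


def correct_lag(
    x: np.ndarray,
    tau: float,
    sampling_rate: float,
    smooth_s: float = 0.2,
    noise_warning_level: float = 1e-3,
) -> np.ndarray:
    """Invert a first-order sensor/chamber lag.

    For measured y with dynamics ``tau dy/dt = u - y``, the underlying
    signal is ``u(t) = y(t) + tau * dy/dt``; the derivative is taken by
    central differences on a lightly smoothed copy (boxcar of ``smooth_s``)
    since differentiation amplifies sensor noise.  A warning is emitted
    when the added high-frequency content exceeds ``noise_warning_level``
    (in signal units -- for O2 fractions, 1e-3 is on the order of the
    consumption depressions of interest); steady-state means are unaffected
    either way.
    """
    x = np.asarray(x, dtype=float)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0 or x.size < 3:
        return x.copy()
    w = max(1, int(round(smooth_s * sampling_rate)))
    smoothed = ndimage.uniform_filter1d(x, size=w, mode="nearest")
    deriv = np.gradient(smoothed, 1.0 / sampling_rate)
    corrected = x + tau * deriv
    # warn only on high-frequency added content: smooth corrections (real
    # transients, slow drifts) are the point of the inversion, not noise
    d = corrected - x
    hf = d - ndimage.uniform_filter1d(d, size=w, mode="nearest")
    added_noise = 1.4826 * float(np.median(np.abs(hf - np.median(hf))))
    if added_noise > noise_warning_level:
        warnings.warn(
            "lag correction amplified noise substantially; consider a larger "
            "smoothing window or check tau",
            RuntimeWarning,
            stacklevel=2,
        )
    return corrected


def estimate_vo2(
    cal_segment: np.ndarray,
    animal_segment: np.ndarray,
    flow: float,
    mass: float,
    tau: float = DEFAULT_TAU,
    sampling_rate: float | None = None,
    lag_corrected: bool = False,
    noise_tolerance: float = 1e-4,
) -> OxygenConsumption:
    """Oxygen consumption from empty-chamber vs. live-breathing O2 means.

    ``vo2 = flow * (mean(cal) - mean(animal)) / mass`` over steady-state
    windows.  If ``lag_corrected`` is false and ``sampling_rate`` is given,
    both segments are lag-corrected first (a no-op on steady segments).

    Raises if the animal fraction exceeds the calibration fraction by more
    than ``noise_tolerance`` (nonphysical: the animal would be producing
    oxygen); smaller negative differences are clipped to zero.
    """
    if flow <= 0 or mass <= 0:
        raise ValueError("flow and mass must be positive")
    cal = np.asarray(cal_segment, dtype=float)
    ani = np.asarray(animal_segment, dtype=float)
    if not lag_corrected and sampling_rate is not None and tau > 0:
        cal = correct_lag(cal, tau, sampling_rate)
        ani = correct_lag(ani, tau, sampling_rate)
    diff = float(cal.mean() - ani.mean())
    if diff < -noise_tolerance:
        raise ValueError(
            f"animal O2 fraction exceeds calibration by {-diff:.2e} "
            "(nonphysical; check segment assignment)"
        )
    diff = max(diff, 0.0)
    return OxygenConsumption(
        vo2=flow * diff / mass, lag_tau=tau, flow=flow, fraction_difference=diff
    )


def ventilatory_equivalent(
    vent: VentilationMetrics, oc: OxygenConsumption
) -> float:
    """V_E / V_O2, the ventilatory equivalent for oxygen.

    Both quantities are mass-normalised (mL/min/g), so the ratio is
    dimensionless; it separates primary respiratory changes from
    metabolically matched ones.  NaN when VO2 is zero.
    """
    if oc.vo2 <= 0:
        return float("nan")
    return vent.ve / oc.vo2


def mean_fraction_in_selection(
    o2: np.ndarray,
    sampling_rate: float,
    start_time: float,
    selection: EpochSelection,
) -> float:
    """Mean O2 fraction over the samples inside the selected epochs."""
    t = start_time + np.arange(o2.size) / sampling_rate
    inside = selection.contains(t)
    if not inside.any():
        raise ValueError("selection covers no O2 samples")
    return float(np.asarray(o2)[inside].mean())
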