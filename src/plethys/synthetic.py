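"""Synthetic plethysmography traces and cohorts with known ground truth.

The generator emulates the structure of a whole-body plethysmography assay
on a mouse: quasi-periodic breathing with breath-to-breath variability in
interbreath interval (IBI) and amplitude, sporadic apneas (abnormally long
IBIs) and sighs (augmented breaths), movement-artifact bursts, and a chamber
O2 channel whose depression below the inflow fraction reflects the animal's
oxygen consumption, smoothed by first-order chamber washout and sensor lag.

Every inserted breath and event is recorded in a :class:`GroundTruth`
object, so downstream detection, selection and estimation stages can be
scored against truth.

Breath pulse model
------------------
Each breath contributes a smooth biphasic pulse: a pre-inspiratory trough
(raised-cosine dip of depth ``dip_fraction`` x amplitude) followed by an
inspiration/expiration hump (raised-cosine of height = amplitude).  The
ground-truth *onset* of a breath is the time of the trough minimum -- the
same landmark the detector uses -- and the ground-truth *amplitude* is the
peak-minus-trough excursion, ``(1 + dip_fraction) x`` the drawn amplitude.

IBIs are gamma distributed (positive and right-skewed, like real breathing)
with block-specific means set by ``effect_map``; an apnea replaces one IBI
with ``apnea_scale x`` the current block mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace_io import (
    AnimalRecord,
    ConditionSchedule,
    TEMPERATURE_TIMEPOINTS,
    Trace,
    hypercapnic_schedule,
    hypoxic_schedule,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortConfig",
    "SimulatedAnimal",
    "SimulatedCohort",
    "generate_trace",
    "generate_o2_channel",
    "generate_cohort",
    "simulate_metric_cohort",
]

#: effect_map keys are (condition_label, cno_status); values are
#: multiplicative modifiers applied within matching schedule blocks.
EffectMap = dict[tuple[str, str], dict[str, float]]

_MODIFIER_KEYS = ("ibi", "amplitude", "vo2")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic animal recording.

    Defaults describe a resting adult mouse in a flow-through chamber:
    ~150 breaths/min (0.4 s mean IBI), moderate breath-to-breath
    variability, sparse apneas/sighs/artifacts, VO2 ~= 0.03 mL/min/g, and a
    ~1.5 s first-order lag between chamber gas and the O2 sensor reading.
    """

    sampling_rate: float = 1000.0  # Hz
    baseline_ibi_mean: float = 0.4  # s
    ibi_dispersion: float = 0.15  # CV of the gamma IBI distribution
    amplitude_mean: float = 1.0  # signal units (pre-dip drawn amplitude)
    amplitude_dispersion: float = 0.12  # CV of the gamma amplitude distribution
    apnea_rate: float = 0.5  # events/min
    apnea_scale: float = 3.0  # multiple of current mean IBI (> 1; > 2 callable)
    sigh_rate: float = 0.5  # events/min
    sigh_scale: float = 3.0  # multiple of current mean amplitude (> 1)
    artifact_rate: float = 0.5  # bursts/min
    artifact_amplitude: float = 5.0  # sd of broadband burst, signal units
    artifact_duration: tuple[float, float] = (0.5, 2.0)  # s, uniform range
    noise_sd: float = 0.05  # baseline Gaussian noise, signal units
    effect_map: EffectMap = field(default_factory=dict)
    vo2_true: float = 0.03  # mL O2/min/g
    mass: float = 25.0  # g
    chamber_flow: float = 500.0  # mL/min
    tau: float = 1.5  # s, chamber washout & sensor lag time constant
    inflow_fraction: float = 0.21  # O2 fraction of the inflow gas
    o2_noise_sd: float = 5e-5  # sensor noise on the O2 fraction
    dip_fraction: float = 0.5  # pre-inspiratory trough depth / amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_ibi_mean <= 0 or self.amplitude_mean <= 0:
            raise ValueError("baseline_ibi_mean and amplitude_mean must be positive")
        for name in ("apnea_rate", "sigh_rate", "artifact_rate", "noise_sd",
                     "ibi_dispersion", "amplitude_dispersion", "o2_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.apnea_scale <= 1:
            raise ValueError("apnea_scale must exceed 1 (event would be uncallable)")
        if self.sigh_scale <= 1:
            raise ValueError("sigh_scale must exceed 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.chamber_flow <= 0 or self.mass <= 0:
            raise ValueError("chamber_flow and mass must be positive")
        if not 0 < self.inflow_fraction < 1:
            raise ValueError("inflow_fraction must lie in (0, 1)")
        for key, mods in self.effect_map.items():
            for mk, v in mods.items():
                if mk not in _MODIFIER_KEYS:
                    raise ValueError(f"unknown effect modifier {mk!r} for {key}")
                if v <= 0:
                    raise ValueError(f"effect modifier {mk}={v} for {key} must be > 0")

    def modifiers(self, label: str, cno_status: str) -> dict[str, float]:
        mods = dict.fromkeys(_MODIFIER_KEYS, 1.0)
        mods.update(self.effect_map.get((label, cno_status), {}))
        return mods


@dataclass
class GroundTruth:
    """Everything the generator inserted, for scoring downstream stages."""

    breath_onsets: np.ndarray  # s, trough-minimum time of each breath
    breath_peaks: np.ndarray  # s, hump-maximum time of each breath
    breath_amplitudes: np.ndarray  # peak-minus-trough excursion, signal units
    sigh_times: np.ndarray  # s, onset times of sigh breaths
    apnea_intervals: list[tuple[float, float]]  # (onset, next onset) of long IBIs
    artifact_intervals: list[tuple[float, float]]
    block_truth: pd.DataFrame  # label, cno_status, start, end, vf_true, amp_true, vo2_true
    duration: float

    def __post_init__(self) -> None:
        for name in ("breath_onsets", "breath_peaks", "sigh_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"{name} must be strictly increasing")
            if arr.size and arr[-1] > self.duration + 1e-9:
                raise ValueError(f"{name} extends beyond trace duration")
        self.breath_amplitudes = np.asarray(self.breath_amplitudes, dtype=float)
        for ivs, name in ((self.apnea_intervals, "apnea"), (self.artifact_intervals, "artifact")):
            prev_end = -math.inf
            for s, e in ivs:
                if s < prev_end - 1e-9:
                    raise ValueError(f"{name} intervals must be disjoint and sorted")
                prev_end = e

    def onsets_in(self, start: float, end: float) -> np.ndarray:
        o = self.breath_onsets
        return o[(o >= start) & (o < end)]

    def vf_in(self, start: float, end: float) -> float:
        """True breathing rate (breaths/min) over ``[start, end)``."""
        return len(self.onsets_in(start, end)) / ((end - start) / 60.0)


def _first_order(target: np.ndarray, tau: float, dt: float, init: float | None = None) -> np.ndarray:
    """Exact exponential stepping of dy/dt = (target - y)/tau."""
    if tau <= 0:
        return target.copy()
    a = math.exp(-dt / tau)
    out = np.empty_like(target)
    y = target[0] if init is None else init
    b = 1.0 - a
    for i, x in enumerate(target):
        y = a * y + b * x
        out[i] = y
    return out


def generate_o2_channel(
    vo2_true: float,
    mass: float,
    chamber_flow: float,
    tau: float,
    duration: float,
    inflow_fraction: float = 0.21,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    start_at_steady_state: bool = True,
) -> np.ndarray:
    """Chamber-outflow O2 fraction for a constant consumption rate.

    Mass balance of a flow-through chamber: the steady-state outflow
    fraction is ``inflow_fraction - vo2_true * mass / chamber_flow``,
    approached with first-order washout dynamics of time constant ``tau``;
    the measured signal is additionally low-pass filtered by the sensor lag
    (same ``tau``).
    """
    if chamber_flow <= 0:
        raise ValueError("chamber_flow must be positive")
    if not 0 < inflow_fraction < 1:
        raise ValueError("inflow_fraction must lie in (0, 1)")
    vo2_series = np.full(int(round(duration * sampling_rate)), float(vo2_true))
    return _o2_from_series(
        vo2_series, mass, chamber_flow, tau, inflow_fraction, sampling_rate,
        noise_sd, rng, start_at_steady_state,
    )


def _o2_from_series(
    vo2_series: np.ndarray,
    mass: float,
    chamber_flow: float,
    tau: float,
    inflow_fraction: float,
    sampling_rate: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    start_at_steady_state: bool = True,
) -> np.ndarray:
    target = inflow_fraction - vo2_series * mass / chamber_flow
    if np.any(target < 0):
        raise ValueError("oxygen consumption exceeds delivered O2 (outflow fraction < 0)")
    dt = 1.0 / sampling_rate
    init = target[0] if start_at_steady_state else inflow_fraction
    chamber = _first_order(target, tau, dt, init=init)
    measured = _first_order(chamber, tau, dt, init=init)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        measured = measured + rng.normal(0.0, noise_sd, size=measured.size)
    return np.clip(measured, 0.0, 1.0)


def _pulse_widths(ibi: float, dip_fraction: float) -> tuple[float, float]:
    """Widths (s) of the pre-inspiratory dip and the inspiratory hump."""
    w = min(0.7 * ibi, 0.35)
    w = max(w, 0.08)
    dip_w = min(0.3 * w, 0.10)
    return dip_w, w - dip_w


def _add_pulse(pressure: np.ndarray, fs: float, t0: float, ibi: float,
               amp: float, dip_fraction: float) -> tuple[float, float]:
    """Add one biphasic breath pulse starting at ``t0``; return the
    (trough_time, peak_time) landmarks."""
    dip_w, hump_w = _pulse_widths(ibi, dip_fraction)
    n = pressure.size
    i0 = int(round(t0 * fs))
    i1 = min(n, int(round((t0 + dip_w) * fs)))
    if i1 > i0 >= 0:
        tt = np.arange(i0, i1) / fs - t0
        pressure[i0:i1] -= dip_fraction * amp * np.sin(np.pi * tt / dip_w) ** 2
    j0 = int(round((t0 + dip_w) * fs))
    j1 = min(n, int(round((t0 + dip_w + hump_w) * fs)))
    if j1 > j0 >= 0:
        tt = np.arange(j0, j1) / fs - (t0 + dip_w)
        pressure[j0:j1] += amp * np.sin(np.pi * tt / hump_w) ** 2
    return t0 + dip_w / 2.0, t0 + dip_w + hump_w / 2.0


def generate_trace(
    config: SimulationConfig, schedule: ConditionSchedule
) -> tuple[Trace, GroundTruth]:
    """Synthesize a pressure + chamber-O2 trace over an assay schedule.

    Returns the trace together with the ground truth of every breath,
    apnea, sigh and artifact burst inserted, and per-block true rate,
    amplitude and VO2.
    """
    if schedule.duration <= 0:
        raise ValueError("schedule has zero duration")
    fs = config.sampling_rate
    duration = schedule.duration
    t_offset = schedule.start
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed)
    pressure = np.zeros(n)

    ibi_shape = None
    if config.ibi_dispersion > 1e-9:
        ibi_shape = 1.0 / config.ibi_dispersion**2
    amp_shape = None
    if config.amplitude_dispersion > 1e-9:
        amp_shape = 1.0 / config.amplitude_dispersion**2

    onsets, peaks, amps, sigh_times = [], [], [], []
    apnea_ivs: list[tuple[float, float]] = []
    t = 0.0  # pulse-start clock, relative to schedule start
    pending_apnea_start: float | None = None
    while t < duration:
        block = schedule.block_at(t + t_offset)
        mods = config.modifiers(block.label, block.cno_status)
        ibi_mean = config.baseline_ibi_mean * mods["ibi"]
        amp_mean = config.amplitude_mean * mods["amplitude"]

        amp = amp_mean if amp_shape is None else rng.gamma(amp_shape, amp_mean / amp_shape)
        is_sigh = rng.random() < config.sigh_rate * ibi_mean / 60.0
        if is_sigh:
            amp *= config.sigh_scale
        is_apnea = rng.random() < config.apnea_rate * ibi_mean / 60.0
        if is_apnea:
            ibi = config.apnea_scale * ibi_mean
        elif ibi_shape is None:
            ibi = ibi_mean
        else:
            ibi = rng.gamma(ibi_shape, ibi_mean / ibi_shape)

        trough_t, peak_t = _add_pulse(pressure, fs, t, ibi, amp, config.dip_fraction)
        if peak_t < duration:  # keep only breaths whose landmarks fit the record
            onsets.append(trough_t)
            peaks.append(peak_t)
            amps.append(amp * (1.0 + config.dip_fraction))
            if is_sigh:
                sigh_times.append(trough_t)
            if pending_apnea_start is not None:
                apnea_ivs.append((pending_apnea_start, trough_t))
                pending_apnea_start = None
            if is_apnea:
                pending_apnea_start = trough_t
        t += ibi

    # artifacts: broadband bursts at Poisson times
    artifact_ivs: list[tuple[float, float]] = []
    n_bursts = rng.poisson(config.artifact_rate * duration / 60.0)
    starts = np.sort(rng.uniform(0.0, duration, size=n_bursts))
    for s in starts:
        d = rng.uniform(*config.artifact_duration)
        e = min(s + d, duration)
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        if i1 > i0:
            pressure[i0:i1] += rng.normal(0.0, config.artifact_amplitude, size=i1 - i0)
            if artifact_ivs and s <= artifact_ivs[-1][1]:
                artifact_ivs[-1] = (artifact_ivs[-1][0], max(e, artifact_ivs[-1][1]))
            else:
                artifact_ivs.append((s, e))
    if config.noise_sd > 0:
        pressure += rng.normal(0.0, config.noise_sd, size=n)

    # chamber O2: per-sample true consumption from block modifiers
    sample_blocks = np.searchsorted(
        [b.end for b in schedule.blocks], t_offset + np.arange(n) / fs, side="right"
    ).clip(max=len(schedule.blocks) - 1)
    vo2_mods = np.array(
        [config.modifiers(b.label, b.cno_status)["vo2"] for b in schedule.blocks]
    )
    vo2_series = config.vo2_true * vo2_mods[sample_blocks]
    o2 = _o2_from_series(
        vo2_series, config.mass, config.chamber_flow, config.tau,
        config.inflow_fraction, fs, config.o2_noise_sd, rng,
    )

    onsets_arr = np.asarray(onsets)
    block_rows = []
    for b in schedule.blocks:
        s, e = b.start - t_offset, b.end - t_offset
        in_block = (onsets_arr >= s) & (onsets_arr < e)
        block_rows.append(
            {
                "label": b.label,
                "cno_status": b.cno_status,
                "start": s,
                "end": e,
                "vf_true": in_block.sum() / ((e - s) / 60.0),
                "amp_true": float(np.mean(np.asarray(amps)[in_block])) if in_block.any() else np.nan,
                "vo2_true": config.vo2_true * config.modifiers(b.label, b.cno_status)["vo2"],
            }
        )

    trace = Trace(
        sampling_rate=fs,
        channels={"pressure": pressure, "o2_fraction": o2},
        start_time=t_offset,
    )
    truth = GroundTruth(
        breath_onsets=onsets_arr,
        breath_peaks=np.asarray(peaks),
        breath_amplitudes=np.asarray(amps),
        sigh_times=np.asarray(sigh_times),
        apnea_intervals=apnea_ivs,
        artifact_intervals=artifact_ivs,
        block_truth=pd.DataFrame(block_rows),
        duration=duration,
    )
    return trace, truth


@dataclass
class CohortConfig:
    """A simulated cohort: experimental animals carry ``effect_map`` in their
    post-CNO (or condition-specific) blocks, sibling controls do not."""

    n_experimental: int = 6
    n_control: int = 6
    cross: str = "crossA"
    assay: str = "hypercapnic"  # hypercapnic | hypoxic
    block_s: float = 1200.0
    sex_assignment: list[str] | None = None  # per animal, exp then control
    mass_mean: float = 25.0  # g
    mass_sd: float = 3.0
    effect_map: EffectMap = field(default_factory=dict)
    temperature_baseline: float = 37.5  # degC
    temperature_offsets: dict[str, float] = field(default_factory=dict)
    # per-timepoint additive offset applied to experimental animals
    temperature_sd: float = 0.3
    base: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experimental < 1 or self.n_control < 1:
            raise ValueError("both groups must contain at least one animal")
        if self.assay not in ("hypercapnic", "hypoxic"):
            raise ValueError("assay must be 'hypercapnic' or 'hypoxic'")
        if self.mass_mean <= 0:
            raise ValueError("mass_mean must be positive")
        n = self.n_experimental + self.n_control
        if self.sex_assignment is not None and len(self.sex_assignment) != n:
            raise ValueError("sex_assignment length must equal cohort size")


@dataclass
class SimulatedAnimal:
    record: AnimalRecord
    trace: Trace
    truth: GroundTruth
    calibration: Trace  # empty-chamber O2 segment for this session
    config: SimulationConfig


@dataclass
class SimulatedCohort:
    config: CohortConfig
    schedule: ConditionSchedule
    animals: list[SimulatedAnimal]

    @property
    def records(self) -> list[AnimalRecord]:
        return [a.record for a in self.animals]


def simulate_metric_cohort(
    rng: np.random.Generator,
    n_experimental: int = 6,
    n_control: int = 6,
    baseline: float = 150.0,
    between_sd: float = 10.0,
    within_sd: float = 5.0,
    effect: float = 0.0,
    metric: str = "vf",
    condition: str = "room_air",
    sex_effect: float = 0.0,
) -> pd.DataFrame:
    """Draw one cohort's metric table directly at the metrics level.

    Each animal gets a random intercept (SD ``between_sd``); each pre/post
    cell adds residual noise (SD ``within_sd``); experimental animals get
    ``effect`` added post-CNO (males additionally ``sex_effect``).  This is
    the fast generator for statistical calibration studies, where the
    waveform stage is irrelevant.
    """
    rows = []
    n = n_experimental + n_control
    for i in range(n):
        group = "experimental" if i < n_experimental else "control"
        sex = "M" if i % 2 == 0 else "F"
        intercept = baseline + rng.normal(0.0, between_sd)
        for cno in ("pre", "post"):
            value = intercept + rng.normal(0.0, within_sd)
            if group == "experimental" and cno == "post":
                value += effect + (sex_effect if sex == "M" else 0.0)
            rows.append(
                {
                    "animal_id": f"a{i:02d}",
                    "cross": "sim",
                    "group": group,
                    "sex": sex,
                    "cno_status": cno,
                    "condition": condition,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Simulate a full cohort: per-animal traces with ground truth, a shared
    assay schedule, masses, sexes and four-timepoint rectal temperatures."""
    schedule = (
        hypercapnic_schedule(config.block_s)
        if config.assay == "hypercapnic"
        else hypoxic_schedule(config.block_s)
    )
    n = config.n_experimental + config.n_control
    sexes = config.sex_assignment or [("M" if i % 2 == 0 else "F") for i in range(n)]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n + 1)
    meta_rng = np.random.default_rng(children[-1])

    animals = []
    for i in range(n):
        group = "experimental" if i < config.n_experimental else "control"
        mass = float(
            np.clip(meta_rng.normal(config.mass_mean, config.mass_sd),
                    0.3 * config.mass_mean, None)
        )
        temps = {}
        for tp in TEMPERATURE_TIMEPOINTS:
            val = config.temperature_baseline + meta_rng.normal(0.0, config.temperature_sd)
            if group == "experimental":
                val += config.temperature_offsets.get(tp, 0.0)
            temps[tp] = float(np.clip(val, 20.0, 42.0))
        sim = replace(
            config.base,
            mass=mass,
            effect_map=dict(config.effect_map) if group == "experimental" else {},
            seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        trace, truth = generate_trace(sim, schedule)
        cal_rng = np.random.default_rng(sim.seed + 1)
        cal = Trace(
            sampling_rate=sim.sampling_rate,
            channels={
                "o2_fraction": generate_o2_channel(
                    0.0, mass, sim.chamber_flow, sim.tau, duration=60.0,
                    inflow_fraction=sim.inflow_fraction,
                    sampling_rate=sim.sampling_rate,
                    noise_sd=sim.o2_noise_sd, rng=cal_rng,
                )
            },
        )
        record = AnimalRecord(
            animal_id=f"{config.cross}_{group[:3]}{i:02d}",
            cross=config.cross,
            group=group,
            sex=sexes[i],
            mass=mass,
            temperatures=temps,
        )
        animals.append(SimulatedAnimal(record, trace, truth, cal, sim))
    return SimulatedCohort(config=config, schedule=schedule, animals=animals)
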