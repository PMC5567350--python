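"""Readers and writers for plethysmography traces, assay schedules and cohorts.

All on-disk formats are plain text so that runs are diffable and
language-neutral:

* **Trace** -- delimited columns (time plus one column per channel) preceded
  by a ``#``-prefixed key/value header carrying the sampling rate, channel
  units and the pressure-to-volume calibration factor.
* **ConditionSchedule** -- a YAML document listing the ordered gas blocks of
  an assay and the CNO injection time.
* **Cohort** -- a tab-separated table with one row per animal.

Times are seconds from assay start; block intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trace",
    "ScheduleBlock",
    "ConditionSchedule",
    "AnimalRecord",
    "GAS_MIXTURES",
    "TEMPERATURE_TIMEPOINTS",
    "read_trace",
    "write_trace",
    "read_schedule",
    "write_schedule",
    "read_cohort",
    "write_cohort",
    "hypercapnic_schedule",
    "hypoxic_schedule",
]

#: Named gas mixtures used by the two assay protocols (volume fractions).
GAS_MIXTURES: dict[str, dict[str, float]] = {
    "room_air": {"O2": 0.21, "N2": 0.79},
    "hypercapnia": {"CO2": 0.05, "O2": 0.21, "N2": 0.74},
    "hypoxia": {"O2": 0.10, "N2": 0.90},
}

#: Rectal-temperature timepoints of the assay protocol, in order.
TEMPERATURE_TIMEPOINTS = ("pre_begin", "pre_mid", "post_end", "post_30min")

_TEMP_RANGE = (20.0, 42.0)


class TraceFormatError(ValueError):
    """Raised when a trace file violates the columnar text format."""


@dataclass
class Trace:
    """A multichannel, uniformly sampled recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), shared by all channels.
    channels : dict[str, numpy.ndarray]
        Named signals.  Conventional names are ``pressure`` (plethysmograph
        differential pressure, arbitrary signal units) and ``o2_fraction``
        (chamber outflow O2 volume fraction, 0-1).
    start_time : float
        Time of the first sample, seconds from assay start.
    calibration_factor : float or None
        mL of tidal volume per pressure signal unit, from the known-volume
        injection calibration; carried in the file header.
    artifact_mask : numpy.ndarray or None
        Optional boolean series marking movement-artifact samples.
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    start_time: float = 0.0
    calibration_factor: float | None = None
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("Trace requires at least one channel")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }
        o2 = self.channels.get("o2_fraction")
        if o2 is not None and o2.size and (np.nanmin(o2) < 0 or np.nanmax(o2) > 1):
            raise ValueError("o2_fraction must lie within [0, 1]")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if len(self.artifact_mask) != self.n_samples:
                raise ValueError("artifact_mask length must match channels")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from assay start."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def slice(self, start: float, end: float) -> "Trace":
        """Return the sub-trace covering ``[start, end)`` in assay time."""
        i0 = max(0, int(math.ceil((start - self.start_time) * self.sampling_rate - 1e-9)))
        i1 = min(self.n_samples, int(round((end - self.start_time) * self.sampling_rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end})")
        return Trace(
            sampling_rate=self.sampling_rate,
            channels={k: v[i0:i1] for k, v in self.channels.items()},
            start_time=self.start_time + i0 / self.sampling_rate,
            calibration_factor=self.calibration_factor,
            artifact_mask=None if self.artifact_mask is None else self.artifact_mask[i0:i1],
        )


def write_trace(trace: Trace, path, precision: int = 10) -> None:
    """Write a Trace to the columnar text format (see module docstring)."""
    names = list(trace.channels)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        fh.write(f"# start_time_s: {trace.start_time!r}\n")
        if trace.calibration_factor is not None:
            fh.write(f"# calibration_factor_ml_per_unit: {trace.calibration_factor!r}\n")
        fh.write(f"# channels: {','.join(names)}\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        cols = [trace.time] + [trace.channels[n] for n in names]
        fmt = f"%.{precision}g"
        np.savetxt(fh, np.column_stack(cols), fmt=fmt, delimiter="\t")


def read_trace(path) -> Trace:
    """Read a Trace written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        If header fields are missing, channel columns are absent or ragged,
        or the time column is not strictly increasing.
    """
    header: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            header[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    if "sampling_rate_hz" not in header or "channels" not in header:
        raise TraceFormatError("header must declare sampling_rate_hz and channels")
    names = [n for n in header["channels"].split(",") if n]
    try:
        table = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"cannot parse trace body: {exc}") from exc
    missing = [n for n in names if n not in table.columns]
    if missing or "time" not in table.columns:
        raise TraceFormatError(f"missing columns: {missing or ['time']}")
    if table[names + ["time"]].isna().any().any():
        raise TraceFormatError("ragged or non-numeric rows in trace body")
    t = table["time"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise TraceFormatError("time column must be strictly increasing")
    cal = header.get("calibration_factor_ml_per_unit")
    return Trace(
        sampling_rate=float(header["sampling_rate_hz"]),
        channels={n: table[n].to_numpy(dtype=float) for n in names},
        start_time=float(header.get("start_time_s", 0.0)),
        calibration_factor=None if cal is None else float(cal),
    )


@dataclass(frozen=True)
class ScheduleBlock:
    """One gas block of an assay: half-open interval ``[start, end)``."""

    label: str  # room_air | hypercapnia | hypoxia
    cno_status: str  # pre | post
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in GAS_MIXTURES:
            raise ValueError(f"unknown gas label {self.label!r}")
        if self.cno_status not in ("pre", "post"):
            raise ValueError(f"cno_status must be 'pre' or 'post', got {self.cno_status!r}")
        if not self.end > self.start:
            raise ValueError("block end must exceed start")

    @property
    def gas(self) -> dict[str, float]:
        return GAS_MIXTURES[self.label]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ConditionSchedule:
    """The ordered, contiguous gas blocks of one assay plus injection time."""

    blocks: list[ScheduleBlock]
    injection_time: float | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not math.isclose(a.end, b.start, abs_tol=1e-9):
                verb = "overlap" if b.start < a.end else "leave a gap"
                raise ValueError(f"blocks {a.label} and {b.label} {verb}")
        if self.injection_time is not None:
            for b in self.blocks:
                midpoint_pre = b.start < self.injection_time
                if (b.cno_status == "pre") != midpoint_pre and not math.isclose(
                    b.start, self.injection_time, abs_tol=1e-9
                ):
                    raise ValueError(
                        f"block at {b.start}s labelled {b.cno_status} is on the wrong "
                        f"side of injection_time={self.injection_time}"
                    )

    @property
    def start(self) -> float:
        return self.blocks[0].start

    @property
    def end(self) -> float:
        return self.blocks[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    def matching(self, label: str, cno_status: str | None = None) -> list[ScheduleBlock]:
        """Blocks with the given gas label (and CNO status, if specified)."""
        return [
            b
            for b in self.blocks
            if b.label == label and (cno_status is None or b.cno_status == cno_status)
        ]

    def block_at(self, t: float) -> ScheduleBlock:
        for b in self.blocks:
            if b.start <= t < b.end:
                return b
        return self.blocks[-1] if t >= self.end else self.blocks[0]


def hypercapnic_schedule(block_s: float = 1200.0) -> ConditionSchedule:
    """The six-block hypercapnic protocol.

    Room air, 5% CO2, room air (all pre-CNO), then after the injection
    room air, 5% CO2, room air (post-CNO); each block ``block_s`` long
    (20 min in the original protocol).
    """
    labels = ["room_air", "hypercapnia", "room_air", "room_air", "hypercapnia", "room_air"]
    status = ["pre"] * 3 + ["post"] * 3
    blocks = [
        ScheduleBlock(lab, st, i * block_s, (i + 1) * block_s)
        for i, (lab, st) in enumerate(zip(labels, status))
    ]
    return ConditionSchedule(blocks, injection_time=3 * block_s)


def hypoxic_schedule(block_s: float = 1200.0) -> ConditionSchedule:
    """The hypoxic protocol: room-air baseline, then post-CNO room air and
    10% O2.  No pre-CNO hypoxia block is scheduled, to avoid hypoxic
    plasticity confounding the post-CNO response."""
    blocks = [
        ScheduleBlock("room_air", "pre", 0.0, block_s),
        ScheduleBlock("room_air", "post", block_s, 2 * block_s),
        ScheduleBlock("hypoxia", "post", 2 * block_s, 3 * block_s),
    ]
    return ConditionSchedule(blocks, injection_time=block_s)


def write_schedule(schedule: ConditionSchedule, path) -> None:
    doc = {
        "injection_time": schedule.injection_time,
        "blocks": [
            {"label": b.label, "cno_status": b.cno_status, "start": b.start, "end": b.end}
            for b in schedule.blocks
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_schedule(path, template: str | None = None) -> ConditionSchedule:
    """Read a schedule YAML file, optionally checking it against a protocol
    template (``"hypercapnic"`` or ``"hypoxic"``: same labels, order and
    CNO statuses, equal-duration blocks)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "blocks" not in doc or not doc["blocks"]:
        raise ValueError(f"{path}: empty or blockless schedule")
    schedule = ConditionSchedule(
        blocks=[
            ScheduleBlock(d["label"], d["cno_status"], float(d["start"]), float(d["end"]))
            for d in doc["blocks"]
        ],
        injection_time=doc.get("injection_time"),
    )
    if template is not None:
        block_s = schedule.blocks[0].duration
        ref = {"hypercapnic": hypercapnic_schedule, "hypoxic": hypoxic_schedule}[template](
            block_s
        )
        got = [(b.label, b.cno_status, b.duration) for b in schedule.blocks]
        want = [(b.label, b.cno_status, b.duration) for b in ref.blocks]
        if got != want:
            raise ValueError(f"schedule does not match the {template} protocol template")
    return schedule


@dataclass
class AnimalRecord:
    """Metadata for one assayed animal."""

    animal_id: str
    cross: str
    group: str  # experimental | control
    sex: str  # M | F
    mass: float  # grams
    temperatures: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("experimental", "control"):
            raise ValueError(f"group must be experimental/control, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        for tp, val in self.temperatures.items():
            if tp not in TEMPERATURE_TIMEPOINTS:
                raise ValueError(f"unknown temperature timepoint {tp!r}")
            if val is not None and not (_TEMP_RANGE[0] <= val <= _TEMP_RANGE[1]):
                raise ValueError(f"temperature {val} degC at {tp} outside {_TEMP_RANGE}")


def write_cohort(records: list[AnimalRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id,
            "cross": r.cross,
            "group": r.group,
            "sex": r.sex,
            "mass_g": r.mass,
        }
        for tp in TEMPERATURE_TIMEPOINTS:
            row[f"temp_{tp}"] = r.temperatures.get(tp, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> list[AnimalRecord]:
    table = pd.read_csv(path, sep="\t")
    required = {"animal_id", "cross", "group", "sex", "mass_g"}
    if missing := required - set(table.columns):
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        temps = {
            tp: float(row[f"temp_{tp}"])
            for tp in TEMPERATURE_TIMEPOINTS
            if f"temp_{tp}" in table.columns and pd.notna(row[f"temp_{tp}"])
        }
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                cross=str(row["cross"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                mass=float(row["mass_g"]),
                temperatures=temps,
            )
        )
    return records


def _replace_block(block: ScheduleBlock, **kw) -> ScheduleBlock:
    return replace(block, **kw)
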