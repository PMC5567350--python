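"""End-to-end orchestration: simulate -> detect -> select -> metrics ->
gas exchange -> statistics -> report.

The analysis consumes a cohort (simulated in memory or loaded from a
simulation directory), produces one metrics row per
animal x condition x CNO-status x metric (long format), fits the
comparison design appropriate to the assay, and writes delimited result
tables plus a run log.  Animals or cells with insufficient artifact-free
data are excluded with a logged reason; the run continues.

Per (condition, CNO status) cell the schedule may contain several blocks
(the hypercapnic protocol has two pre and two post room-air blocks); each
block is analysed separately and the cell value is the mean across blocks
with sufficient data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breath_analysis import (
    ArtifactParams,
    DetectionParams,
    SelectionCriteria,
    compute_ventilation,
    detect_artifacts,
    detect_breaths,
    select_epochs_in_block,
)
from .gas_exchange import (
    correct_lag,
    estimate_vo2,
    mean_fraction_in_selection,
    ventilatory_equivalent,
)
from .pattern_metrics import variability
from .stats_models import (
    EffectEstimate,
    effects_table,
    fit_group_model,
    fit_pre_post_model,
)
from .synthetic import CohortConfig, SimulatedCohort, generate_cohort
from .trace_io import (
    TEMPERATURE_TIMEPOINTS,
    read_cohort,
    read_schedule,
    read_trace,
    write_cohort,
    write_schedule,
    write_trace,
)

logger = logging.getLogger("plethys")

__all__ = [
    "AnalysisParams",
    "AnalysisResult",
    "run_simulation",
    "load_simulation",
    "run_analysis",
    "temperature_analysis",
    "METRICS",
]

#: Metrics modelled statistically, in reporting order.
METRICS = ["vf", "vt", "ve", "vo2", "ve_vo2", "apnea_rate", "sigh_rate", "cv_ibi", "cv_amp"]


@dataclass
class AnalysisParams:
    """Everything the analysis stage needs beyond the data itself."""

    calibration_factor: float = 0.005  # mL tidal volume per signal unit
    chamber_flow: float = 500.0  # mL/min
    tau: float = 1.5  # s
    detection: DetectionParams = field(default_factory=DetectionParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    fit_sex_models: bool = False


@dataclass
class AnalysisResult:
    metrics_long: pd.DataFrame  # animal_id, cross, group, sex, cno_status, condition, metric, value
    effects: pd.DataFrame
    exclusions: list[dict]
    selection_summary: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_long.to_csv(out / "metrics_long.tsv", sep="\t", index=False)
        self.effects.to_csv(out / "effects.tsv", sep="\t", index=False)
        self.selection_summary.to_csv(out / "selection_summary.tsv", sep="\t", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=2)


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(_stringify_keys(dataclasses.asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_simulation(cohort_config: CohortConfig, out_dir, force: bool = False) -> SimulatedCohort:
    """Simulate a cohort and write it to ``out_dir``.

    Writes per-animal trace files, ground-truth event sidecars, the shared
    schedule, the cohort table and a manifest recording seed, config hash
    and package version.  Refuses to write into a non-empty directory
    unless ``force`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    cohort = generate_cohort(cohort_config)
    write_schedule(cohort.schedule, out / "schedule.yaml")
    write_cohort(cohort.records, out / "cohort.tsv")
    for animal in cohort.animals:
        stem = animal.record.animal_id
        write_trace(animal.trace, out / f"{stem}.trace.txt", precision=6)
        write_trace(animal.calibration, out / f"{stem}.calibration.txt", precision=8)
        _write_ground_truth(animal.truth, out / f"{stem}.truth.tsv")
    manifest = {
        "seed": cohort_config.seed,
        "config_hash": _config_hash(cohort_config),
        "n_animals": len(cohort.animals),
        "assay": cohort_config.assay,
        "package_version": __version__,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return cohort


def _write_ground_truth(truth, path) -> None:
    rows = [
        {"event": "breath", "start": o, "end": p, "value": a}
        for o, p, a in zip(truth.breath_onsets, truth.breath_peaks, truth.breath_amplitudes)
    ]
    rows += [{"event": "sigh", "start": t, "end": t, "value": np.nan} for t in truth.sigh_times]
    rows += [{"event": "apnea", "start": s, "end": e, "value": e - s} for s, e in truth.apnea_intervals]
    rows += [{"event": "artifact", "start": s, "end": e, "value": e - s} for s, e in truth.artifact_intervals]
    pd.DataFrame(rows, columns=["event", "start", "end", "value"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class _LoadedAnimal:
    record: object
    trace: object
    calibration: object


def load_simulation(sim_dir):
    """Load a simulation directory back into analysable objects."""
    sim = Path(sim_dir)
    schedule = read_schedule(sim / "schedule.yaml")
    records = read_cohort(sim / "cohort.tsv")
    animals = [
        _LoadedAnimal(
            record=r,
            trace=read_trace(sim / f"{r.animal_id}.trace.txt"),
            calibration=read_trace(sim / f"{r.animal_id}.calibration.txt"),
        )
        for r in records
    ]
    return schedule, animals


def _analyze_animal(record, trace, calibration, schedule, params: AnalysisParams):
    """Per-animal metrics rows for every (condition, CNO) cell."""
    rows, exclusions, summaries = [], [], []
    mask = detect_artifacts(trace, params.artifacts)
    breaths = detect_breaths(trace, params.detection)
    cal_o2 = correct_lag(
        calibration.channels["o2_fraction"], params.tau, calibration.sampling_rate
    )
    animal_o2 = correct_lag(
        trace.channels["o2_fraction"], params.tau, trace.sampling_rate
    )

    cells: dict[tuple[str, str], list[dict]] = {}
    for block in schedule.blocks:
        selection = select_epochs_in_block(
            trace, block, params.selection, artifact_mask=mask
        )
        summaries.append(
            {
                "animal_id": record.animal_id,
                "condition": block.label,
                "cno_status": block.cno_status,
                "block_start": block.start,
                "selected_s": selection.total_duration,
                "n_intervals": len(selection.intervals),
                "insufficient": selection.insufficient,
            }
        )
        if selection.insufficient or selection.total_duration <= 0:
            exclusions.append(
                {
                    "animal_id": record.animal_id,
                    "condition": block.label,
                    "cno_status": block.cno_status,
                    "block_start": block.start,
                    "reason": "insufficient artifact-free data "
                    f"({selection.total_duration:.1f}s selected)",
                }
            )
            continue
        vent = compute_ventilation(
            breaths, selection, params.calibration_factor, record.mass
        )
        pattern = variability(breaths, selection)
        animal_mean = mean_fraction_in_selection(
            animal_o2, trace.sampling_rate, trace.start_time, selection
        )
        oc = estimate_vo2(
            cal_o2, np.array([animal_mean]), params.chamber_flow, record.mass,
            tau=params.tau, lag_corrected=True,
        )
        block_metrics = {
            "vf": vent.vf,
            "vt": vent.vt,
            "ve": vent.ve,
            "vo2": oc.vo2,
            "ve_vo2": ventilatory_equivalent(vent, oc),
            "apnea_rate": pattern.apnea_rate,
            "sigh_rate": pattern.sigh_rate,
            "cv_ibi": pattern.cv_ibi,
            "cv_amp": pattern.cv_amp,
            "cv_ibi_sd": pattern.cv_ibi_sd,
            "cv_amp_sd": pattern.cv_amp_sd,
            "poincare_sd1": pattern.poincare_sd1,
            "poincare_sd2": pattern.poincare_sd2,
        }
        cells.setdefault((block.label, block.cno_status), []).append(block_metrics)

    for (label, cno), block_list in cells.items():
        merged = pd.DataFrame(block_list).mean()
        for metric, value in merged.items():
            rows.append(
                {
                    "animal_id": record.animal_id,
                    "cross": record.cross,
                    "group": record.group,
                    "sex": record.sex,
                    "cno_status": cno,
                    "condition": label,
                    "metric": metric,
                    "value": value,
                }
            )
    return rows, exclusions, summaries


def run_analysis(
    cohort: SimulatedCohort | None = None,
    sim_dir=None,
    params: AnalysisParams | None = None,
    out_dir=None,
) -> AnalysisResult:
    """Analyse a cohort end-to-end and fit the assay's comparison design.

    Accepts either an in-memory :class:`SimulatedCohort` or a simulation
    directory written by :func:`run_simulation`.
    """
    params = params or AnalysisParams()
    if cohort is not None:
        schedule = cohort.schedule
        animals = [(a.record, a.trace, a.calibration) for a in cohort.animals]
    elif sim_dir is not None:
        schedule, loaded = load_simulation(sim_dir)
        animals = [(a.record, a.trace, a.calibration) for a in loaded]
    else:
        raise ValueError("provide a cohort or a sim_dir")

    all_rows, all_exclusions, all_summaries = [], [], []
    for record, trace, calibration in animals:
        rows, exclusions, summaries = _analyze_animal(
            record, trace, calibration, schedule, params
        )
        for exc in exclusions:
            logger.info("excluded %(animal_id)s %(condition)s/%(cno_status)s: %(reason)s", exc)
        all_rows += rows
        all_exclusions += exclusions
        all_summaries += summaries

    metrics_long = pd.DataFrame(all_rows)
    effects = _fit_assay_models(metrics_long, schedule, params)
    result = AnalysisResult(
        metrics_long=metrics_long,
        effects=effects_table(effects),
        exclusions=all_exclusions,
        selection_summary=pd.DataFrame(all_summaries),
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def _fit_assay_models(
    metrics_long: pd.DataFrame, schedule, params: AnalysisParams
) -> list[EffectEstimate]:
    """Pre/post models where both CNO states exist for a condition,
    group-only models where only post-CNO data exists (hypoxia)."""
    effects: list[EffectEstimate] = []
    if metrics_long.empty:
        return effects
    for condition in metrics_long["condition"].unique():
        sub = metrics_long[metrics_long["condition"] == condition]
        has_pre = (sub["cno_status"] == "pre").any()
        for metric in METRICS:
            if metric not in set(sub["metric"]):
                continue
            try:
                if has_pre:
                    effects.append(fit_pre_post_model(sub, metric))
                else:
                    est = fit_group_model(sub, metric)
                    effects.append(dataclasses.replace(est, condition=condition))
            except ValueError as exc:
                logger.warning("model for %s/%s not fit: %s", condition, metric, exc)
    return effects


def temperature_analysis(records) -> pd.DataFrame:
    """Group-only comparison of rectal temperature at each of the four
    protocol timepoints.  Missing timepoints are skipped with a log entry.
    Accepts a list of AnimalRecord (possibly pooled across assays)."""
    effects = []
    for tp in TEMPERATURE_TIMEPOINTS:
        rows = [
            {
                "animal_id": r.animal_id,
                "cross": r.cross,
                "group": r.group,
                "sex": r.sex,
                "cno_status": "post",
                "condition": "temperature",
                "metric": f"temp_{tp}",
                "value": r.temperatures.get(tp, np.nan),
            }
            for r in records
        ]
        frame = pd.DataFrame(rows).dropna(subset=["value"])
        if frame.empty or frame["group"].nunique() < 2:
            logger.info("temperature timepoint %s skipped: insufficient data", tp)
            continue
        effects.append(fit_group_model(frame, f"temp_{tp}"))
    return effects_table(effects)
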