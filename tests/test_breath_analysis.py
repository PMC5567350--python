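import numpy as np
import pandas as pd
import pytest
from scipy.signal import argrelmax

from plethys import (
    SimulationConfig,
    Trace,
    compute_ventilation,
    detect_artifacts,
    detect_breaths,
    generate_trace,
    select_epochs,
    select_epochs_in_block,
)
from plethys.breath_analysis import (
    DetectionParams,
    EpochSelection,
    SelectionCriteria,
    breaths_in_selection,
)
from plethys.trace_io import ConditionSchedule, ScheduleBlock

from conftest import SCALED_CRITERIA, SCALED_FS, match_onsets, single_block_schedule


def sinusoid_trace(freq=3.0, duration=60.0, fs=1000.0, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return Trace(sampling_rate=fs, channels={"pressure": amp * np.sin(2 * np.pi * freq * t)})


class TestDetector:
    def test_noise_free_sinusoid_exact(self):
        """A 3 Hz noise-free sinusoid over 60 s yields 180 breaths with
        every IBI equal to 1/3 s (to sample resolution)."""
        breaths = detect_breaths(sinusoid_trace())
        assert len(breaths) == 180
        ibis = breaths["ibi"].to_numpy()[:-1]
        np.testing.assert_allclose(ibis, 1.0 / 3.0, atol=2e-3)

    def test_matches_brute_force_extrema_on_clean_signal(self):
        """On a noise-free synthetic trace the detector finds exactly the
        local-maxima breaths an exhaustive extrema scan finds."""
        config = SimulationConfig(
            sampling_rate=SCALED_FS, noise_sd=0.0, artifact_rate=0.0,
            apnea_rate=0.0, sigh_rate=0.0, seed=2,
        )
        trace, truth = generate_trace(config, single_block_schedule(60.0))
        breaths = detect_breaths(trace)
        x = trace.channels["pressure"]
        brute_peaks = [
            i for i in argrelmax(x)[0] if x[i] > 0.5 * np.median(x[argrelmax(x)[0]])
        ]
        assert len(breaths) == len(brute_peaks) == len(truth.breath_onsets)

    def test_onset_recall_on_default_noise_trace(self, clean_sim):
        """>= 99% of ground-truth onsets recovered within +/- 10 ms at the
        generator's default noise level, with no spurious breaths called
        during inserted apneas."""
        _, _, trace, truth = clean_sim
        breaths = detect_breaths(trace)
        recall = match_onsets(breaths["onset"].to_numpy(), truth.breath_onsets)
        assert recall >= 0.99
        onsets = breaths["onset"].to_numpy()
        for s, e in truth.apnea_intervals:
            inside = (onsets > s + 0.05) & (onsets < e - 0.05)
            assert not inside.any()

    def test_flat_trace_yields_empty_table(self):
        trace = Trace(sampling_rate=SCALED_FS, channels={"pressure": np.zeros(2500)})
        breaths = detect_breaths(trace)
        assert breaths.empty
        assert list(breaths.columns) == ["onset", "peak_time", "amplitude", "ibi"]

    def test_sub_nyquist_sampling_rejected(self):
        trace = Trace(sampling_rate=40.0, channels={"pressure": np.ones(100)})
        with pytest.raises(ValueError, match="Nyquist"):
            detect_breaths(trace, DetectionParams(band=(0.5, 30.0)))

    def test_time_shift_invariance(self, clean_sim):
        """Shifting the trace start time shifts onsets but leaves IBIs and
        amplitudes unchanged."""
        _, _, trace, _ = clean_sim
        shifted = Trace(
            sampling_rate=trace.sampling_rate,
            channels=trace.channels,
            start_time=trace.start_time + 500.0,
        )
        b0, b1 = detect_breaths(trace), detect_breaths(shifted)
        np.testing.assert_allclose(b1["onset"], b0["onset"] + 500.0, atol=1e-9)
        np.testing.assert_allclose(b1["amplitude"], b0["amplitude"], atol=1e-12)


class TestArtifacts:
    def test_burst_detection_rates(self):
        """>= 95% of artifact-burst time flagged, <= 5% of clean time
        falsely flagged at default thresholds."""
        config = SimulationConfig(sampling_rate=SCALED_FS, artifact_rate=2.0, seed=7)
        trace, truth = generate_trace(config, single_block_schedule(300.0))
        mask = detect_artifacts(trace)
        t = trace.time
        in_burst = np.zeros(trace.n_samples, dtype=bool)
        for s, e in truth.artifact_intervals:
            in_burst |= (t >= s) & (t < e)
        assert in_burst.any()
        assert mask[in_burst].mean() >= 0.95
        assert mask[~in_burst].mean() <= 0.05

    def test_clean_trace_unflagged(self, clean_sim):
        _, _, trace, _ = clean_sim
        assert detect_artifacts(trace).mean() <= 0.02

    def test_all_artifact_trace_fully_flagged_and_selection_insufficient(self):
        rng = np.random.default_rng(0)
        n = int(120 * SCALED_FS)
        trace = Trace(
            sampling_rate=SCALED_FS,
            channels={"pressure": rng.normal(0, 5, n) + np.sin(np.arange(n) / 10)},
        )
        mask = np.ones(n, dtype=bool)  # caller-supplied all-artifact mask
        sel = select_epochs_in_block(
            trace, ScheduleBlock("room_air", "pre", 0, 120), SCALED_CRITERIA,
            artifact_mask=mask,
        )
        assert sel.insufficient
        assert sel.intervals == []


def mask_from_intervals(intervals, duration, fs=SCALED_FS):
    mask = np.zeros(int(duration * fs), dtype=bool)
    for s, e in intervals:
        mask[int(s * fs) : int(e * fs)] = True
    return mask


class TestEpochSelection:
    def make_trace(self, duration):
        n = int(duration * SCALED_FS)
        return Trace(sampling_rate=SCALED_FS, channels={"pressure": np.zeros(n)})

    def test_clean_block_selects_within_last_window(self):
        """A fully clean 20-min block yields a selection inside the last
        600 s totalling at least 60 s."""
        trace = self.make_trace(1200.0)
        block = ScheduleBlock("room_air", "pre", 0, 1200)
        sel = select_epochs_in_block(
            trace, block, SelectionCriteria(), artifact_mask=np.zeros(trace.n_samples, bool)
        )
        assert not sel.insufficient
        assert sel.total_duration >= 60.0
        assert all(s >= 600.0 and e <= 1200.0 for s, e in sel.intervals)

    def test_short_gaps_flagged_insufficient(self):
        """Clean gaps of only 8 s never qualify (min segment 10 s)."""
        duration = 120.0
        artifact = []
        t = 0.0
        while t < duration:  # 8 s clean / 2 s artifact comb
            artifact.append((t + 8.0, min(t + 10.0, duration)))
            t += 10.0
        mask = mask_from_intervals(artifact, duration)
        sel = select_epochs_in_block(
            self.make_trace(duration), ScheduleBlock("room_air", "pre", 0, duration),
            SCALED_CRITERIA, artifact_mask=mask,
        )
        assert sel.insufficient
        assert sel.intervals == []

    def test_qualifying_gaps_enumerated(self):
        """Clean gaps of 15 s and 50 s inside the window are both selected,
        totalling 65 s."""
        duration = 120.0
        # clean: [10, 25) -> 15 s, [40, 90) -> 50 s; rest artifact
        artifact = [(0, 10), (25, 40), (90, 120)]
        mask = mask_from_intervals(artifact, duration)
        sel = select_epochs_in_block(
            self.make_trace(duration), ScheduleBlock("room_air", "pre", 0, duration),
            SCALED_CRITERIA, artifact_mask=mask,
        )
        assert not sel.insufficient
        assert sel.total_duration == pytest.approx(65.0, abs=0.05)
        assert len(sel.intervals) == 2

    def test_latest_first_accumulation_stops_at_target(self):
        """With ample clean segments, accumulation is latest-first and
        stops once the cumulative target is reached."""
        duration = 600.0
        artifact = [(i * 50.0 + 40.0, i * 50.0 + 50.0) for i in range(12)]
        mask = mask_from_intervals(artifact, duration)
        sel = select_epochs_in_block(
            self.make_trace(duration), ScheduleBlock("room_air", "pre", 0, duration),
            SelectionCriteria(min_segment=10, cumulative_target=60, window_s=600),
            artifact_mask=mask,
        )
        assert not sel.insufficient
        assert 60.0 <= sel.total_duration <= 80.01
        assert min(s for s, _ in sel.intervals) >= 400.0  # latest segments only

    def test_selection_never_crosses_artifact_samples(self, default_sim):
        _, schedule, trace, _ = default_sim
        mask = detect_artifacts(trace)
        sel = select_epochs(
            trace, schedule, "room_air", "pre", SCALED_CRITERIA, artifact_mask=mask
        )
        t = trace.time
        for s, e in sel.intervals:
            assert not mask[(t >= s) & (t < e)].any()

    def test_absent_condition_is_error(self, default_sim):
        _, schedule, trace, _ = default_sim
        with pytest.raises(ValueError, match="hypoxia"):
            select_epochs(trace, schedule, "hypoxia", "post")


class TestVentilation:
    def breaths_table(self, n, ibi, amp):
        onsets = np.arange(n) * ibi
        return pd.DataFrame(
            {
                "onset": onsets,
                "peak_time": onsets + 0.1,
                "amplitude": np.full(n, amp),
                "ibi": np.append(np.diff(onsets), np.nan),
            }
        )

    def selection(self, start, end):
        return EpochSelection([(start, end)], "room_air")

    def test_definition_arithmetic(self):
        """120 breaths in 60 s with amplitude*cal/mass = 0.01 mL/breath/g
        gives vf 120, vt 0.01, ve 1.2."""
        breaths = self.breaths_table(120, 0.5, amp=50.0)
        vent = compute_ventilation(breaths, self.selection(0, 60), 0.005, 25.0)
        assert vent.vf == pytest.approx(120.0)
        assert vent.vt == pytest.approx(0.01)
        assert vent.ve == pytest.approx(1.2)

    def test_calibration_linearity(self):
        breaths = self.breaths_table(100, 0.5, amp=50.0)
        sel = self.selection(0, 50)
        v1 = compute_ventilation(breaths, sel, 0.005, 25.0)
        v2 = compute_ventilation(breaths, sel, 0.010, 25.0)
        assert v2.vt == pytest.approx(2 * v1.vt)
        assert v2.ve == pytest.approx(2 * v1.ve)
        assert v2.vf == pytest.approx(v1.vf)

    def test_ve_identity(self, clean_sim):
        """V_E == V_f * V_T to 1e-9 relative on real detections."""
        _, schedule, trace, _ = clean_sim
        breaths = detect_breaths(trace)
        sel = select_epochs(trace, schedule, "room_air", "pre", SCALED_CRITERIA)
        vent = compute_ventilation(breaths, sel, 0.005, 25.0)
        assert vent.ve == pytest.approx(vent.vf * vent.vt, rel=1e-9)

    def test_recovery_against_ground_truth(self, clean_sim):
        """Measured vf within 2% and vt within 5% of the ground truth over
        the same selected intervals."""
        config, schedule, trace, truth = clean_sim
        breaths = detect_breaths(trace)
        sel = select_epochs(trace, schedule, "room_air", "pre", SCALED_CRITERIA)
        vent = compute_ventilation(breaths, sel, 0.005, config.mass)
        true_n = sum(
            ((truth.breath_onsets >= s) & (truth.breath_onsets < e)).sum()
            for s, e in sel.intervals
        )
        true_vf = true_n / (sel.total_duration / 60.0)
        true_amps = np.concatenate(
            [
                truth.breath_amplitudes[(truth.breath_onsets >= s) & (truth.breath_onsets < e)]
                for s, e in sel.intervals
            ]
        )
        true_vt = true_amps.mean() * 0.005 / config.mass
        assert vent.vf == pytest.approx(true_vf, rel=0.02)
        assert vent.vt == pytest.approx(true_vt, rel=0.05)

    def test_zero_selection_duration_is_error(self):
        breaths = self.breaths_table(10, 0.5, 1.0)
        empty = EpochSelection([], "room_air")
        with pytest.raises(ValueError, match="zero duration"):
            compute_ventilation(breaths, empty, 0.005, 25.0)

    def test_breaths_assigned_by_onset_half_open(self):
        breaths = self.breaths_table(10, 1.0, 1.0)  # onsets 0..9
        sel = EpochSelection([(0.0, 5.0)], "room_air")
        assert len(breaths_in_selection(breaths, sel)) == 5  # onsets 0-4
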