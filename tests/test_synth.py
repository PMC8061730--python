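"""Synthetic generator: percept statistics, event processes, schedules,
rendering, and determinism."""
import numpy as np
import pytest

import ocumotor as om
from ocumotor.synth import (
    ConfigError,
    Kernel,
    SimConfig,
    _raised_cosine_displacement,
    sample_modulated_events,
    schedule_blanks,
    schedule_microshifts,
)


class TestPerceptSequence:
    def test_zero_latency_lift_equals_switch(self):
        cfg = SimConfig(seed=0, report_latency_s=(0.0, 0.0), trial_duration_s=300.0)
        switches, tl = om.sample_percept_sequence(cfg, np.random.default_rng(0))
        lifts = [r.time_s for r in tl.records if r.action == "lift"]
        for (t_switch, _), t_lift in zip(switches, lifts):
            assert t_lift == pytest.approx(t_switch)

    def test_coherent_duration_mean_matches_target(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(42)
        draws = np.array(
            [om.synth.sample_percept_duration(cfg, "coherent", rng) for _ in range(10_000)]
        )
        se = 6.65 / np.sqrt(draws.size)
        assert abs(draws.mean() - 14.77) < 2 * se + 0.02  # small truncation allowance

    def test_short_trial_reports_no_switches(self):
        cfg = SimConfig(seed=0, trial_duration_s=1.0)
        switches, tl = om.sample_percept_sequence(cfg, np.random.default_rng(3))
        assert switches == []

    def test_reported_lift_latency_within_range(self):
        cfg = SimConfig(seed=5, trial_duration_s=600.0)
        switches, tl = om.sample_percept_sequence(cfg, np.random.default_rng(5))
        lifts = [r.time_s for r in tl.records if r.action == "lift"]
        lo, hi = cfg.report_latency_s
        for (t_switch, _), t_lift in zip(switches, lifts):
            assert lo - 1e-9 <= t_lift - t_switch <= hi + 1e-9

    def test_invalid_mean_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(percept_duration={"coherent": (-1.0, 1.0), "component": (7.57, 4.41)})


class TestModulatedEvents:
    def test_zero_rate_empty(self):
        assert sample_modulated_events(0.0, [], [], 100.0, np.random.default_rng(0)).size == 0

    def test_homogeneous_count_matches_poisson(self):
        rng = np.random.default_rng(7)
        events = sample_modulated_events(0.2, [], [], 10_000.0, rng)
        assert abs(events.size - 2000) < 3 * np.sqrt(2000)

    def test_total_blackout_kernel_forces_empty_window(self):
        kern = [Kernel(-1.0, 0.0, 0.0)]
        for seed in range(20):
            ev = sample_modulated_events(2.0, kern, [5.0], 10.0, np.random.default_rng(seed))
            assert not np.any((ev >= 4.0) & (ev < 5.0))

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            Kernel(-1.0, 0.0, -0.5)

    def test_counts_scale_linearly_with_rate(self):
        counts = []
        for rate in (0.5, 1.0, 2.0):
            n = [
                sample_modulated_events(rate, [], [], 500.0, np.random.default_rng(s)).size
                for s in range(30)
            ]
            counts.append(np.mean(n))
        # slope of mean count vs rate ~ duration
        slope = np.polyfit([0.5, 1.0, 2.0], counts, 1)[0]
        se = 3 * np.sqrt(2.0 * 500.0) / np.sqrt(30)
        assert abs(slope - 500.0) < se

    def test_dip_kernel_reduces_rate_in_window(self):
        kern = {"coherent": [Kernel(-0.8, -0.2, 0.4)]}
        anchors = {"coherent": np.arange(10.0, 1000.0, 20.0)}
        ev = sample_modulated_events(1.0, kern, anchors, 1000.0, np.random.default_rng(0))
        rel = (ev[None, :] - np.asarray(anchors["coherent"])[:, None]).ravel()
        in_dip = np.sum((rel >= -0.8) & (rel < -0.2))
        outside = np.sum((rel >= 0.2) & (rel < 0.8))
        assert in_dip < 0.75 * outside


class TestSchedules:
    def test_too_short_trial_empty(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(0)
        assert schedule_blanks(cfg, 2.0, rng) == []
        assert schedule_microshifts(cfg, 2.0, rng) == []

    def test_blank_gaps_and_durations(self):
        cfg = SimConfig(seed=0)
        blanks = schedule_blanks(cfg, 5000.0, np.random.default_rng(1))
        onsets = np.array([b.onset_s for b in blanks])
        durations = np.array([b.duration_s for b in blanks])
        gaps = np.diff(np.concatenate(([0.0], onsets)))
        allowed = np.array(cfg.blank_gap_choices_s)
        assert np.all(np.isclose(gaps[:, None], allowed[None, :]).any(axis=1))
        assert durations.min() >= 0.116 and durations.max() <= 0.167
        assert blanks[-1].offset_s <= 5000.0

    def test_microshift_cap_and_forced_reversal(self):
        cfg = SimConfig(seed=0)
        shifts = schedule_microshifts(cfg, 50_000.0, np.random.default_rng(2))
        offsets = np.array([s.attributes["offset_deg"] for s in shifts])
        assert offsets.max() <= 0.8 + 1e-9 and offsets.min() >= -0.8 - 1e-9
        assert offsets.max() == pytest.approx(0.8)  # the cap is attainable
        # immediately after hitting +cap the next shift goes left
        at_cap = np.flatnonzero(np.isclose(offsets[:-1], 0.8))
        assert all(shifts[i + 1].attributes["shift_direction"] == "left" for i in at_cap)

    def test_cap_must_be_four_steps(self):
        with pytest.raises(ConfigError):
            SimConfig(microshift_cap_deg=0.6)


class TestRendering:
    def test_quiet_render_is_constant(self):
        from ocumotor.core import ReportTimeline
        from ocumotor.synth import TrialGroundTruth, render_recording

        cfg = SimConfig(seed=0, drift_sd_deg=0.0, pupil_noise_sd=0.0, pursuit_speed_dps=0.0)
        gt = TrialGroundTruth(
            0, "quiet", "test", 0.0, 2.0, 500.0, ReportTimeline([]), [], [], [], [], []
        )
        rec = render_recording(gt, cfg, np.random.default_rng(0))
        assert np.ptp(rec.left.gaze_x) == 0.0
        assert np.ptp(rec.left.pupil) == 0.0

    def test_raised_cosine_integrates_to_amplitude(self):
        t = np.linspace(0.0, 0.02, 2001)
        disp = _raised_cosine_displacement(t, 0.5, 0.02)
        assert disp[-1] == pytest.approx(0.5, rel=1e-6)
        assert disp[0] == pytest.approx(0.0, abs=1e-12)

    def test_rendered_blink_leaves_missing_core(self, rendered_trial, short_cfg):
        gt, rec = rendered_trial
        ramp = short_cfg.blink_ramp_ms / 1000.0
        fs = rec.sample_rate
        for blink in gt.blinks[:5]:
            core = (rec.sample_times >= blink.onset_s + ramp) & (
                rec.sample_times < blink.offset_s - ramp
            )
            assert np.all(np.isnan(rec.left.pupil[core]))
            assert np.all(np.isnan(rec.right.pupil[core]))

    def test_event_outside_span_rejected(self):
        from ocumotor.core import IntervalEvent, ReportTimeline
        from ocumotor.synth import TrialGroundTruth, render_recording

        cfg = SimConfig(seed=0)
        gt = TrialGroundTruth(
            0,
            "bad",
            "test",
            0.0,
            1.0,
            500.0,
            ReportTimeline([]),
            [],
            [IntervalEvent(0.5, 1.5, "blink")],
            [],
            [],
            [],
        )
        gt.blinks = [IntervalEvent(0.5, 1.5, "blink")]
        with pytest.raises(om.core.ValidationError):
            render_recording(gt, cfg, np.random.default_rng(0))


class TestDeterminism:
    def test_same_seed_identical_trials(self):
        cfg = SimConfig(seed=123, trial_duration_s=30.0)
        a = om.simulate_trial(cfg, 2, 3)
        b = om.simulate_trial(cfg, 2, 3)
        assert [r.time_s for r in a.timeline.records] == [r.time_s for r in b.timeline.records]
        assert [x.onset_s for x in a.blinks] == [x.onset_s for x in b.blinks]
        assert [m.time_s for m in a.microsaccades] == [m.time_s for m in b.microsaccades]

    def test_same_seed_byte_identical_recording_files(self, tmp_path):
        cfg = SimConfig(seed=9, trial_duration_s=5.0)
        paths = []
        for name in ("a", "b"):
            gt = om.simulate_trial(cfg, 0, 0)
            rec = om.render_recording(gt, cfg)
            p = tmp_path / f"{name}.tsv"
            om.write_recording(rec, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_trials_use_independent_streams(self):
        cfg = SimConfig(seed=123, trial_duration_s=30.0)
        a = om.simulate_trial(cfg, 2, 3)
        c = om.simulate_trial(cfg, 2, 4)
        assert [x.onset_s for x in a.blinks] != [x.onset_s for x in c.blinks]


class TestDetectorRoundTrip:
    def test_blink_detector_recovers_rendered_blinks(self, rendered_trial):
        gt, rec = rendered_trial
        detected = om.detect_blinks(rec)
        hits = 0
        for b in gt.blinks:
            if any(d.onset_s < b.offset_s and b.onset_s < d.offset_s for d in detected):
                hits += 1
        assert hits >= 0.95 * len(gt.blinks)

    def test_microsaccade_detector_recovers_large_events(self, rendered_trial):
        gt, rec = rendered_trial
        blinks = om.detect_blinks(rec)
        detected = om.detect_microsaccades(rec, blinks=blinks)
        truth = [
            m
            for m in gt.microsaccades
            if m.attributes["amplitude_deg"] >= 0.2
            and not any(
                m.time_s > b.onset_s - 0.1 and m.time_s < b.offset_s + 0.1 for b in gt.blinks
            )
        ]
        hits = sum(
            any(
                d.onset_s < m.time_s + m.attributes["duration_s"] and m.time_s < d.offset_s
                for d in detected
            )
            for m in truth
        )
        assert hits >= 0.9 * len(truth)
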