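"""Peri-event binning, weighting, normalization, no-switch baselines, and
event-locked time courses."""
import warnings

import numpy as np
import pytest

import ocumotor as om
from ocumotor.core import IntervalEvent, ReportRecord, ReportTimeline
from ocumotor.peri import (
    PeriEventConfig,
    TrialEvents,
    bin_counts,
    condition_timecourses,
    event_locked_timecourse,
    no_switch_anchors,
    switch_anchor_times,
    trial_series_for_anchors,
    trial_timecourse,
)

CFG = PeriEventConfig()  # +/-2 s, 100-ms bins -> 40 bins


class TestBinCounts:
    def test_event_at_anchor_lands_in_center_bin(self):
        mat = bin_counts(np.array([10.0]), np.array([10.0]), CFG)
        assert mat.shape == (1, 40)
        assert mat[0, 20] == 1.0 and mat.sum() == 1.0

    def test_event_at_right_edge_excluded(self):
        mat = bin_counts(np.array([10.0]), np.array([12.0]), CFG)
        assert mat.sum() == 0.0

    def test_event_at_left_edge_included(self):
        mat = bin_counts(np.array([10.0]), np.array([8.0]), CFG)
        assert mat[0, 0] == 1.0

    def test_shared_event_split_between_anchors(self):
        mat = bin_counts(np.array([10.0, 11.0]), np.array([10.5]), CFG)
        assert mat[0].sum() == pytest.approx(0.5)
        assert mat[1].sum() == pytest.approx(0.5)
        assert mat.sum() == pytest.approx(1.0)

    def test_conservation_across_many_anchors(self):
        rng = np.random.default_rng(0)
        anchors = np.sort(rng.uniform(2, 98, 30))
        events = np.sort(rng.uniform(0, 100, 200))
        mat = bin_counts(anchors, events, CFG)
        in_any = np.array(
            [np.any(np.abs(e - anchors + 1e-12) < CFG.half_window_s) for e in events]
        )
        # every event inside >=1 window contributes exactly 1 in total
        assert mat.sum() == pytest.approx(np.count_nonzero(in_any))


class TestTrialTimecourse:
    def test_single_event_series_zscored(self):
        mat = np.zeros((1, 40))
        mat[0, 7] = 1.0
        ts = trial_timecourse(mat, 1.0, CFG)
        assert ts.usable
        assert ts.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert ts.values.std() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(ts.values) == 7

    def test_uniform_counts_degenerate(self):
        ts = trial_timecourse(np.ones((3, 40)), 10.0, CFG)
        assert ts.degenerate and not ts.usable

    def test_scale_invariance_after_normalization(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(2.0, (5, 40)).astype(float)
        t1 = trial_timecourse(mat, 100.0, CFG)
        t2 = trial_timecourse(2 * mat, 200.0, CFG)
        assert t1.values == pytest.approx(t2.values)

    def test_zero_anchors_marked_empty(self):
        ts = trial_timecourse(np.zeros((0, 40)), 5.0, CFG)
        assert ts.values is None and ts.n_anchors == 0


class TestNoSwitchAnchors:
    def test_short_percept_yields_no_periods(self):
        pv = [IntervalEvent(0.0, 5.9, "percept_coherent")]
        a, b = no_switch_anchors(pv, 100.0, CFG)
        assert a.size == 0 and b.size == 0

    def test_ten_second_percept_tiles_two_periods(self):
        pv = [IntervalEvent(0.0, 10.1, "percept_coherent")]
        a, b = no_switch_anchors(pv, 100.0, CFG)
        # periods [2,6) and [6,10): centers 4 and 8, alternately assigned
        assert a.tolist() == [4.0]
        assert b.tolist() == [8.0]

    def test_empty_timeline(self):
        a, b = no_switch_anchors([], 100.0, CFG)
        assert a.size == 0 and b.size == 0

    def test_periods_never_contain_reports(self, short_cfg):
        switches, tl = om.sample_percept_sequence(short_cfg, np.random.default_rng(3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pv = om.percept_intervals(tl)
        a, b = no_switch_anchors(pv, short_cfg.trial_duration_s, CFG)
        centers = np.concatenate([a, b])
        W = CFG.half_window_s
        report_times = np.array([r.time_s for r in tl.records])
        for c in centers:
            assert not np.any((report_times > c - W) & (report_times < c + W))
        # periods are non-overlapping
        centers.sort()
        assert np.all(np.diff(centers) >= 2 * W - 1e-9)


def _timeline(*recs):
    return ReportTimeline([ReportRecord(*r) for r in recs])


def _trial(events, timeline, duration=100.0, condition="test", participant=0):
    return TrialEvents(
        participant=participant,
        trial_id="t",
        condition=condition,
        duration_s=duration,
        timeline=timeline,
        events={"blink": np.asarray(events, dtype=float)},
    )


class TestConditionTimecourses:
    def test_switch_anchor_times_classification(self):
        tl = _timeline(
            (10.0, "press", "coherent"),
            (20.0, "lift", "coherent"),
            (20.5, "press", "component"),
            (30.0, "lift", "component"),
            (30.5, "press", "coherent"),
            (40.0, "lift", "coherent"),
        )
        assert switch_anchor_times(tl, "switch_to_component").tolist() == [20.0]
        assert switch_anchor_times(tl, "switch_to_coherent").tolist() == [30.0]

    def test_blank_trials_excluded_for_blink_rates(self):
        tl = _timeline((10.0, "press", "coherent"), (90.0, "lift", "coherent"))
        cohort = {0: [_trial([20.0, 30.0], tl, condition="blank")]}
        with pytest.warns(UserWarning, match="dropped"):
            a, b, kept = condition_timecourses(cohort, "blink", "switch_to_coherent", CFG)
        assert kept == [] and a.shape[0] == 0

    def test_flat_cohort_mean_under_homogeneous_events(self):
        # homogeneous Poisson events around random anchors: after
        # normalization no bin of the seed-mean (of trial-averaged series)
        # departs from 0
        rng = np.random.default_rng(5)
        series = []
        for _ in range(100):
            trials = []
            for _ in range(4):
                anchors = np.sort(rng.uniform(2.0, 178.0, 10))
                events = np.sort(rng.uniform(0.0, 180.0, 40))
                ts = trial_timecourse(bin_counts(anchors, events, CFG), 40.0, CFG)
                if ts.usable:
                    trials.append(ts.values)
            if trials:
                series.append(np.mean(trials, axis=0))
        mat = np.array(series)
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        assert np.all(np.abs(mean) < 4 * se)

    def test_identical_conditions_zero_difference(self):
        tl = _timeline(
            (5.0, "press", "coherent"),
            (50.0, "lift", "coherent"),
            (50.5, "press", "component"),
            (90.0, "lift", "component"),
        )
        trial = _trial(np.arange(3.0, 97.0, 1.7), tl)
        s1 = trial_series_for_anchors(trial, np.array([50.0]), "blink", CFG)
        s2 = trial_series_for_anchors(trial, np.array([50.0]), "blink", CFG)
        assert s1.values == pytest.approx(s2.values)


class TestEventLocked:
    def _cohort(self):
        cohort = {}
        rng = np.random.default_rng(2)
        for p in range(3):
            tl = _timeline((1.0, "press", "coherent"), (99.0, "lift", "coherent"))
            trials = []
            for k in range(2):
                trials.append(
                    TrialEvents(
                        participant=p,
                        trial_id=f"p{p}t{k}",
                        condition="microshift",
                        duration_s=100.0,
                        timeline=tl,
                        events={
                            "microsaccade": np.sort(rng.uniform(0, 100, 120)),
                            "microshift": np.arange(5.0, 95.0, 9.0),
                        },
                        offsets={"microshift": np.arange(5.0, 95.0, 9.0)},
                    )
                )
            cohort[p] = trials
        return cohort

    def test_microshift_onset_equals_offset(self):
        cohort = self._cohort()
        cfg = PeriEventConfig(bin_ms=50.0)
        on, kept_on = event_locked_timecourse(cohort, "microshift", "onset", cfg)
        off, kept_off = event_locked_timecourse(cohort, "microshift", "offset", cfg)
        assert kept_on == kept_off
        assert on == pytest.approx(off)

    def test_no_anchors_empty(self):
        cohort = self._cohort()
        for trials in cohort.values():
            for t in trials:
                t.events["microshift"] = np.empty(0)
                t.offsets["microshift"] = np.empty(0)
        mat, kept = event_locked_timecourse(cohort, "microshift", "onset")
        assert kept == [] and mat.shape[0] == 0

    def test_suppression_after_blank_visible(self):
        # generator's blank kernels suppress microsaccades right after onset
        cfg = om.SimConfig(
            seed=31,
            trials_per_participant=0,
            n_blank_trials=6,
            n_microshift_trials=0,
            trial_duration_s=180.0,
        )
        cohort = {
            p: [TrialEvents.from_ground_truth(gt) for gt in om.simulate_session(cfg, p)]
            for p in range(4)
        }
        pcfg = PeriEventConfig(bin_ms=50.0, half_window_s=1.0)
        mat, kept = event_locked_timecourse(cohort, "blank", "onset", pcfg)
        assert len(kept) == 4
        mean = mat.mean(axis=0)
        centers = pcfg.bin_centers_s
        post = mean[(centers > 0.0) & (centers < 0.25)].mean()
        pre = mean[(centers > -0.5) & (centers < 0.0)].mean()
        assert post < pre
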