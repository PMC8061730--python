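"""Peri-event rate time courses around perceptual switches and around
oculomotor/stimulus events.

The switch-locked analysis counts event onsets in 100-ms bins within a
+/-2-s window around each button lift, shares events falling into several
windows by weighting them 1/m, averages over anchors, divides by the
trial's total event count, and z-transforms the per-trial series before
averaging over trials.  The baseline condition uses matched "no-switch"
anchors: all non-overlapping 4-s periods free of perceptual change that
start 2 s after the last switch, alternately assigned to the
coherent-switch and component-switch comparisons.  The event-locked mode
applies the same machinery with 50-ms bins around blink/blank/microshift
onsets or offsets.

Anchors whose window would extend beyond the trial span are excluded in
both conditions; otherwise switch anchors near trial edges would place
structural zeros in the outer bins that the interior-only no-switch
periods can never match.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    IntervalEvent,
    ReportTimeline,
    ValidationError,
    percept_intervals,
    switch_anchors,
)

SWITCH_ANCHOR_TYPES = ("switch_to_coherent", "switch_to_component")
EVENT_ANCHOR_TYPES = ("blink", "blank", "microshift")


@dataclass
class PeriEventConfig:
    half_window_s: float = 2.0
    bin_ms: float = 100.0  # 50 ms for the event-locked mode
    share_across_anchors: bool = True
    normalize_by_trial_total: bool = True
    z_transform: bool = True
    no_switch_lead_s: float = 2.0  # quiet time required after a switch

    def __post_init__(self):
        if self.half_window_s <= 0:
            raise ValueError("half_window_s must be > 0")
        nb = 2.0 * self.half_window_s / (self.bin_ms / 1000.0)
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError("bin width must divide the window evenly")

    @property
    def n_bins(self) -> int:
        return int(round(2.0 * self.half_window_s / (self.bin_ms / 1000.0)))

    @property
    def bin_centers_s(self) -> np.ndarray:
        w = self.bin_ms / 1000.0
        return -self.half_window_s + w * (np.arange(self.n_bins) + 0.5)


@dataclass
class TrialEvents:
    """Lightweight per-trial bundle the peri-event machinery consumes."""

    participant: int
    trial_id: str
    condition: str
    duration_s: float
    timeline: ReportTimeline
    events: dict = field(default_factory=dict)  # label -> onset times
    offsets: dict = field(default_factory=dict)  # label -> offset times

    @classmethod
    def from_ground_truth(cls, gt) -> "TrialEvents":
        """Build from a synthetic TrialGroundTruth (duck-typed)."""
        return cls(
            participant=gt.participant,
            trial_id=gt.trial_id,
            condition=gt.condition,
            duration_s=gt.duration_s,
            timeline=gt.timeline,
            events={
                "blink": gt.event_onsets("blink"),
                "microsaccade": gt.event_onsets("microsaccade"),
                "blank": gt.event_onsets("blank"),
                "microshift": gt.event_onsets("microshift"),
            },
            offsets={
                "blink": np.array([b.offset_s for b in gt.blinks]),
                "blank": np.array([b.offset_s for b in gt.blanks]),
                "microshift": gt.event_onsets("microshift"),
            },
        )


@dataclass
class TrialSeries:
    """One trial's binned, normalized (and possibly z-scored) series.

    ``degenerate`` marks a zero-variance series whose z-transform was
    skipped; such trials are excluded from participant averages.
    """

    values: np.ndarray | None
    n_anchors: int
    degenerate: bool = False

    @property
    def usable(self) -> bool:
        return self.values is not None and not self.degenerate


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_counts(
    anchors: np.ndarray, event_onsets: np.ndarray, cfg: PeriEventConfig
) -> np.ndarray:
    """Weighted per-anchor binned counts, shape (n_anchors, n_bins).

    An event at time t relative to anchor a lands in bin
    ``floor((t - a + W) / bin)`` when inside the half-open window
    ``[-W, +W)``.  With sharing on, an event inside the windows of m
    anchors contributes 1/m to each, so its total contribution is 1.
    """
    anchors = np.asarray(anchors, dtype=float)
    events = np.asarray(event_onsets, dtype=float)
    W = cfg.half_window_s
    width = cfg.bin_ms / 1000.0
    nb = cfg.n_bins
    mat = np.zeros((anchors.size, nb))
    if anchors.size == 0 or events.size == 0:
        return mat
    rel = events[None, :] - anchors[:, None]  # (n_anchors, n_events)
    inside = (rel >= -W) & (rel < W)
    if cfg.share_across_anchors:
        m = inside.sum(axis=0)
        with np.errstate(divide="ignore"):
            weight = np.where(m > 0, 1.0 / np.maximum(m, 1), 0.0)
    else:
        weight = np.ones(events.size)
    idx = np.floor((rel + W) / width).astype(int)
    for i in range(anchors.size):
        cols = idx[i, inside[i]]
        np.add.at(mat[i], np.clip(cols, 0, nb - 1), weight[inside[i]])
    return mat


def trial_timecourse(
    count_matrix: np.ndarray, trial_event_total: float, cfg: PeriEventConfig
) -> TrialSeries:
    """Average over anchors, normalize by the trial's event total, and
    z-transform across bins (population sd; mean 0, sd 1)."""
    count_matrix = np.asarray(count_matrix, dtype=float)
    n_anchors = count_matrix.shape[0]
    if n_anchors == 0:
        return TrialSeries(values=None, n_anchors=0)
    series = count_matrix.mean(axis=0)
    if cfg.normalize_by_trial_total:
        if trial_event_total <= 0:
            return TrialSeries(values=None, n_anchors=n_anchors)
        series = series / trial_event_total
    if cfg.z_transform:
        sd = series.std()
        if sd == 0:
            return TrialSeries(values=series, n_anchors=n_anchors, degenerate=True)
        series = (series - series.mean()) / sd
    return TrialSeries(values=series, n_anchors=n_anchors)


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


def _in_span(anchors, duration_s: float, cfg: PeriEventConfig) -> np.ndarray:
    a = np.asarray(anchors, dtype=float)
    W = cfg.half_window_s
    return a[(a - W >= 0.0) & (a + W <= duration_s)]


def switch_anchor_times(timeline: ReportTimeline, anchor_type: str) -> np.ndarray:
    """Lift times for switches to the requested percept."""
    if anchor_type not in SWITCH_ANCHOR_TYPES:
        raise ValidationError(f"unknown switch anchor type {anchor_type!r}")
    want = anchor_type.removeprefix("switch_to_")
    return np.array(
        [
            a.time_s
            for a in switch_anchors(timeline)
            if a.attributes["to_percept"] == want
        ]
    )


def no_switch_anchors(
    percepts: list[IntervalEvent], trial_span: float, cfg: PeriEventConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Centers of all non-overlapping no-switch periods, split into the
    coherent-comparison and component-comparison lists.

    Within each percept interval, periods of length ``2*half_window_s``
    are tiled forward from 2 s after the switch into the percept; each
    period is fully free of perceptual change, and its center anchors a
    window equal to the period.  Periods are assigned alternately (in time
    order across the trial): 1st, 3rd, ... to the coherent-comparison
    list, 2nd, 4th, ... to the component-comparison list.
    """
    period = 2.0 * cfg.half_window_s
    centers: list[float] = []
    for iv in sorted(percepts, key=lambda e: e.onset_s):
        start = iv.onset_s + cfg.no_switch_lead_s
        while start + period <= min(iv.offset_s, trial_span):
            centers.append(start + period / 2.0)
            start += period
    centers_arr = np.asarray(centers)
    return centers_arr[0::2], centers_arr[1::2]


def trial_series_for_anchors(
    trial: TrialEvents, anchors, event_type: str, cfg: PeriEventConfig
) -> TrialSeries:
    """Binned/normalized/z-scored series for one trial and anchor list,
    with out-of-span anchors excluded."""
    anchors = _in_span(anchors, trial.duration_s, cfg)
    events = np.asarray(trial.events.get(event_type, np.empty(0)), dtype=float)
    mat = bin_counts(anchors, events, cfg)
    return trial_timecourse(mat, float(events.size), cfg)


# ---------------------------------------------------------------------------
# Cohort-level time courses
# ---------------------------------------------------------------------------


def condition_timecourses(
    cohort: dict[int, list[TrialEvents]],
    event_type: str,
    anchor_type: str,
    cfg: PeriEventConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-participant paired series: (switch condition, matched no-switch).

    Blink/microsaccade rates are taken from test-condition trials only
    (trials with blanks or microshifts are excluded); blank/microshift
    rates come from their own condition trials, pooled across rotations.
    Per participant, usable trial series are averaged within condition; a
    participant lacking a usable trial in either condition is dropped with
    a warning.  Returns (A, B, participants) with one row per kept
    participant.
    """
    cfg = cfg or PeriEventConfig()
    trial_condition = {"blink": "test", "microsaccade": "test"}.get(event_type, event_type)
    comparison = 0 if anchor_type == "switch_to_coherent" else 1
    rows_a, rows_b, kept = [], [], []
    for participant, trials in cohort.items():
        sw, ns = [], []
        for trial in trials:
            if trial.condition != trial_condition:
                continue
            anchors = switch_anchor_times(trial.timeline, anchor_type)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pv = percept_intervals(trial.timeline)
            ns_lists = no_switch_anchors(pv, trial.duration_s, cfg)
            s1 = trial_series_for_anchors(trial, anchors, event_type, cfg)
            s2 = trial_series_for_anchors(trial, ns_lists[comparison], event_type, cfg)
            if s1.usable:
                sw.append(s1.values)
            if s2.usable:
                ns.append(s2.values)
        if sw and ns:
            rows_a.append(np.mean(sw, axis=0))
            rows_b.append(np.mean(ns, axis=0))
            kept.append(participant)
        else:
            warnings.warn(
                f"participant {participant} lacks a usable series in one "
                "condition; dropped",
                stacklevel=2,
            )
    if not rows_a:
        return (
            np.empty((0, cfg.n_bins)),
            np.empty((0, cfg.n_bins)),
            [],
        )
    return np.vstack(rows_a), np.vstack(rows_b), kept


def event_locked_timecourse(
    cohort: dict[int, list[TrialEvents]],
    anchor_event: str,
    align: str = "onset",
    cfg: PeriEventConfig | None = None,
    event_type: str = "microsaccade",
) -> tuple[np.ndarray, list[int]]:
    """Per-participant series of ``event_type`` onsets around the onsets or
    offsets of blinks, blanks, or microshifts (50-ms bins by default).

    For a microshift (an instantaneous two-frame change) onset and offset
    coincide.  Blink-locked series come from test trials, blank- and
    microshift-locked series from their own condition trials.
    """
    if anchor_event not in EVENT_ANCHOR_TYPES:
        raise ValidationError(f"unknown anchor event {anchor_event!r}")
    if align not in ("onset", "offset"):
        raise ValidationError("align must be 'onset' or 'offset'")
    cfg = cfg or PeriEventConfig(bin_ms=50.0)
    trial_condition = "test" if anchor_event == "blink" else anchor_event
    rows, kept = [], []
    for participant, trials in cohort.items():
        series = []
        for trial in trials:
            if trial.condition != trial_condition:
                continue
            if align == "offset" and anchor_event != "microshift":
                anchors = trial.offsets.get(anchor_event, np.empty(0))
            else:
                anchors = trial.events.get(anchor_event, np.empty(0))
            s = trial_series_for_anchors(trial, anchors, event_type, cfg)
            if s.usable:
                series.append(s.values)
        if series:
            rows.append(np.mean(series, axis=0))
            kept.append(participant)
    if not rows:
        return np.empty((0, cfg.n_bins)), []
    return np.vstack(rows), kept
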