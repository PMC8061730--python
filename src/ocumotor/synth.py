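"""Synthetic binocular eye-tracking sessions for the bistable-plaid task.

The generator produces, per trial, everything the analysis consumes plus the
ground truth it can be scored against:

* a percept-report timeline: alternating coherent/component dominance with
  gamma-distributed durations, each internal switch reported by a button
  lift after a uniform 500-700 ms latency and a re-press on the other
  button shortly after;
* blink and microsaccade point processes: inhomogeneous Poisson streams
  whose hazard is the base rate multiplied by piecewise-constant kernels
  locked to reported switches (and, for microsaccades, to blink/blank/
  microshift events), sampled by thinning;
* stimulus schedules: screen blanks (116-167 ms every 3-6 s in 0.5-s
  steps) and horizontal microshifts (0.2 deg steps, running offset capped
  at +/-0.8 deg);
* optionally, rendered gaze/pupil traces: random-walk drift plus slow
  pursuit toward the perceived motion direction, raised-cosine
  microsaccade profiles, and blinks rendered as pupil ramp-down, missing
  samples, ramp-up.

One random stream is derived per (seed, participant, trial) so any trial
can be regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    IntervalEvent,
    PointEvent,
    Recording,
    EyeTrace,
    ReportRecord,
    ReportTimeline,
    ValidationError,
    coherent_direction_deg,
    component_directions_deg,
    switch_anchors,
)


class ConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class Kernel:
    """Piecewise-constant multiplicative hazard over ``[start_s, end_s)``
    relative to an anchor event; ``mult`` scales the base rate there."""

    start_s: float
    end_s: float
    mult: float

    def __post_init__(self):
        if self.mult < 0:
            raise ConfigError(f"kernel multiplier must be >= 0, got {self.mult}")
        if not self.start_s < self.end_s:
            raise ConfigError("kernel window must have start < end")


def default_switch_kernels() -> dict:
    """Switch-locked rate modulation, keyed by event type then switch type.

    Shapes follow the qualitative findings the analysis is meant to expose:
    blink rate dips before any reported switch and rebounds only after a
    switch to coherent; microsaccade rate dips just before a switch to
    component.
    """
    return {
        "blink": {
            "coherent": [Kernel(-0.8, -0.2, 0.4), Kernel(0.1, 0.6, 2.0)],
            "component": [Kernel(-0.3, 0.0, 0.4)],
        },
        "microsaccade": {
            "component": [Kernel(-0.3, 0.0, 0.5)],
        },
    }


def default_ms_event_kernels() -> dict:
    """Microsaccade-rate modulation around blinks, blanks and microshifts:
    suppression around every event, an anticipatory component only for the
    (internally generated) blink, and a rebound only after blanks."""
    return {
        "blink_onset": [Kernel(-0.2, 0.0, 0.3)],
        "blink_offset": [Kernel(0.0, 0.25, 0.4)],
        "blank_onset": [Kernel(0.0, 0.25, 0.3), Kernel(0.35, 0.6, 1.6)],
        "microshift": [Kernel(0.0, 0.25, 0.5)],
    }


def default_direction_mixture() -> dict:
    """Per-percept mixture over microsaccade directions (stimulus-aligned).

    Components: a narrow lobe opposite the coherent motion, two narrow lobes
    opposite the component motions, and a uniform floor.  Weights chosen so
    sector shares land near the rates real observers show (roughly 22% vs
    16% opposite-coherent and 10% vs 14% opposite-components).
    """
    return {
        "coherent": {"opp_coherent": 0.22, "opp_component": 0.02, "uniform": 0.76},
        "component": {"opp_coherent": 0.14, "opp_component": 0.06, "uniform": 0.80},
    }


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort (defaults emulate the 500-Hz
    experiment: 3-min trials, gamma percept durations with coherent mean
    14.77 s / sd 6.65 s and component mean 7.57 s / sd 4.41 s, 12.09
    blinks/min, 1.39 microsaccades/s, 0.5-0.7 s report latency)."""

    seed: int = 0
    n_participants: int = 19
    trials_per_participant: int = 8  # test-condition trials
    n_blank_trials: int = 4
    n_microshift_trials: int = 4
    trial_duration_s: float = 180.0
    sample_rate_hz: float = 500.0
    # percept alternation
    percept_duration: dict = field(
        default_factory=lambda: {
            "coherent": (14.77, 6.65),
            "component": (7.57, 4.41),
        }
    )
    min_percept_duration_s: float = 0.3
    report_latency_s: tuple[float, float] = (0.5, 0.7)
    press_gap_s: tuple[float, float] = (0.1, 0.3)
    # event rates
    blink_rate_per_min: float = 12.09
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    min_blink_gap_s: float = 0.2
    microsaccade_rate_hz: float = 1.39
    # modulation kernels
    switch_kernels: dict = field(default_factory=default_switch_kernels)
    ms_event_kernels: dict = field(default_factory=default_ms_event_kernels)
    # stimulus schedules
    blank_gap_choices_s: tuple = (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)
    blank_duration_s: tuple[float, float] = (0.116, 0.167)
    microshift_step_deg: float = 0.2
    microshift_cap_deg: float = 0.8
    # microsaccade properties
    ms_amplitude_mean_deg: float = 0.32
    ms_amplitude_sd_deg: float = 0.16
    ms_max_amplitude_deg: float = 1.2
    direction_bias: float = 0.22  # opposite-coherent weight during coherent percept
    direction_mixture: dict = field(default_factory=default_direction_mixture)
    direction_lobe_sd_deg: float = 7.0
    # rendering
    drift_sd_deg: float = 0.001  # random-walk step sd per sample
    pursuit_speed_dps: float = 0.1
    pupil_baseline: float = 1000.0
    pupil_noise_sd: float = 10.0
    blink_ramp_ms: float = 20.0
    blink_depth: float = 150.0  # pupil drop at the end of the closing ramp

    def __post_init__(self):
        if self.blink_rate_per_min < 0 or self.microsaccade_rate_hz < 0:
            raise ConfigError("event rates must be >= 0")
        for label, (mean, sd) in self.percept_duration.items():
            if mean <= 0:
                raise ConfigError(f"{label} percept mean duration must be > 0")
            if sd <= 0:
                raise ConfigError(f"{label} percept duration sd must be > 0")
        if abs(self.microshift_cap_deg - 4 * self.microshift_step_deg) > 1e-9:
            raise ConfigError("microshift cap must equal 4 x step")
        mix = self.direction_mixture
        # direction_bias is the headline knob; keep the mixture consistent with it
        if "coherent" in mix:
            w = mix["coherent"]
            w["opp_coherent"] = self.direction_bias
            w["uniform"] = max(0.0, 1.0 - w["opp_coherent"] - w.get("opp_component", 0.0))


def null_config(**overrides) -> SimConfig:
    """A SimConfig with all rate modulation removed (homogeneous events)."""
    cfg = SimConfig(switch_kernels={}, ms_event_kernels={}, **overrides)
    return cfg


def trial_rng(cfg: SimConfig, participant: int, trial: int, stream: int = 0):
    """Independent random stream for one (participant, trial) pair."""
    return np.random.default_rng([cfg.seed, participant, trial, stream])


# ---------------------------------------------------------------------------
# Percept sequence
# ---------------------------------------------------------------------------


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def _duration_floor(cfg: SimConfig) -> float:
    # a percept must outlast the worst-case report skew (latency jitter plus
    # the lift-to-press gap) or the next lift could precede the current press
    lat_lo, lat_hi = cfg.report_latency_s
    return max(cfg.min_percept_duration_s, lat_hi - lat_lo + cfg.press_gap_s[1] + 0.01)


def sample_percept_duration(cfg: SimConfig, percept: str, rng) -> float:
    """One gamma-distributed dominance duration, resampled above a small
    floor so reports stay well ordered."""
    mean, sd = cfg.percept_duration[percept]
    shape, scale = _gamma_params(mean, sd)
    floor = _duration_floor(cfg)
    for _ in range(1000):
        d = rng.gamma(shape, scale)
        if d >= floor:
            return float(d)
    return floor


def sample_percept_sequence(
    cfg: SimConfig, rng
) -> tuple[list[tuple[float, str]], ReportTimeline]:
    """Internal percept alternation plus the behavioural report of it.

    Returns ``(internal_switches, timeline)`` where ``internal_switches``
    is a list of ``(time_s, to_percept)`` for every switch that was
    actually reported (lift + press) inside the trial.  The observer
    presses the button for the starting percept after one report latency,
    lifts it one latency after each internal switch, and presses the other
    button after a short lift-to-press gap.  Reports beyond the trial end
    are truncated.
    """
    T = cfg.trial_duration_s
    lo, hi = cfg.report_latency_s

    def latency() -> float:
        return float(rng.uniform(lo, hi)) if hi > lo else lo

    def press_gap() -> float:
        glo, ghi = cfg.press_gap_s
        return float(rng.uniform(glo, ghi)) if ghi > glo else glo

    percept = str(rng.choice(["coherent", "component"]))
    records: list[ReportRecord] = []
    switches: list[tuple[float, str]] = []

    t_press = latency()  # initial press, one latency after stimulus onset
    if t_press >= T:
        return [], ReportTimeline([])
    records.append(ReportRecord(t_press, "press", percept))

    t_switch = sample_percept_duration(cfg, percept, rng)
    while True:
        t_lift = t_switch + latency()
        if t_lift >= T:
            break  # trailing percept truncated at trial end; press stays open
        new_percept = "component" if percept == "coherent" else "coherent"
        t_next_press = t_lift + press_gap()
        records.append(ReportRecord(t_lift, "lift", percept))
        if t_next_press >= T:
            break
        records.append(ReportRecord(t_next_press, "press", new_percept))
        switches.append((t_switch, new_percept))
        percept = new_percept
        t_switch = t_switch + sample_percept_duration(cfg, percept, rng)

    # drop a trailing open press so the stored timeline is fully paired
    if records and records[-1].action == "press" and len(records) > 1:
        timeline = ReportTimeline(records)
    else:
        timeline = ReportTimeline(records)
    return switches, timeline


# ---------------------------------------------------------------------------
# Inhomogeneous Poisson events (thinning)
# ---------------------------------------------------------------------------


def _as_groups(kernels, anchors) -> list[tuple[np.ndarray, list[Kernel]]]:
    if isinstance(kernels, dict):
        if not isinstance(anchors, dict):
            raise ConfigError("dict kernels require dict anchors with same keys")
        return [
            (np.asarray(anchors.get(k, []), dtype=float), list(v))
            for k, v in kernels.items()
        ]
    return [(np.asarray(anchors, dtype=float), list(kernels))]


def modulated_rate(
    t: np.ndarray,
    base_rate: float,
    groups: Sequence[tuple[np.ndarray, Sequence[Kernel]]],
) -> np.ndarray:
    """lambda(t) = base_rate * prod over anchors/kernels of the active
    multipliers; kernel windows are half-open in anchor-relative time."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam = np.full(t.shape, float(base_rate))
    for anchor_times, kernels in groups:
        for a in anchor_times:
            rel = t - a
            for k in kernels:
                inside = (rel >= k.start_s) & (rel < k.end_s)
                lam[inside] *= k.mult
    return lam


def _rate_upper_bound(base_rate, groups, duration_s) -> float:
    """Exact max of the piecewise-constant lambda(t) on [0, duration)."""
    edges = {0.0, float(duration_s)}
    for anchor_times, kernels in groups:
        for a in anchor_times:
            for k in kernels:
                for e in (a + k.start_s, a + k.end_s):
                    if 0.0 < e < duration_s:
                        edges.add(float(e))
    pts = np.sort(np.fromiter(edges, dtype=float))
    if pts.size < 2:
        return float(base_rate)
    mid = (pts[:-1] + pts[1:]) / 2.0
    return float(np.max(modulated_rate(mid, base_rate, groups))) if mid.size else float(base_rate)


def sample_modulated_events(
    base_rate: float,
    kernels,
    switches,
    duration_s: float,
    rng,
) -> np.ndarray:
    """Sample an inhomogeneous Poisson stream on ``[0, duration_s)`` by
    thinning against ``lambda(t) = base_rate * prod g_k(t - t_k)``.

    ``kernels`` may be a flat list (with ``switches`` a flat list of anchor
    times) or a dict keyed like ``switches`` for per-anchor-type kernels.
    With no kernels this reduces to an exact homogeneous Poisson sample.
    Returns sorted event times.
    """
    if base_rate < 0:
        raise ConfigError("base_rate must be >= 0")
    if base_rate == 0 or duration_s <= 0:
        return np.empty(0)
    groups = _as_groups(kernels, switches)
    lam_max = _rate_upper_bound(base_rate, groups, duration_s)
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n))
    if cand.size == 0:
        return cand
    accept = rng.uniform(0.0, 1.0, size=cand.size) * lam_max < modulated_rate(
        cand, base_rate, groups
    )
    return cand[accept]


# ---------------------------------------------------------------------------
# Stimulus schedules
# ---------------------------------------------------------------------------


def schedule_blanks(cfg: SimConfig, trial_duration_s: float, rng) -> list[IntervalEvent]:
    """Blank schedule: successive gaps drawn uniformly from {3.0,...,6.0} s
    (0.5-s steps), each blank 116-167 ms, none crossing the trial end."""
    out: list[IntervalEvent] = []
    t = 0.0
    lo, hi = cfg.blank_duration_s
    while True:
        t += float(rng.choice(cfg.blank_gap_choices_s))
        dur = float(rng.uniform(lo, hi))
        if t + dur > trial_duration_s:
            break
        out.append(IntervalEvent(t, t + dur, "blank"))
    return out


def schedule_microshifts(cfg: SimConfig, trial_duration_s: float, rng) -> list[PointEvent]:
    """Microshift schedule: gaps as for blanks; each shift moves the
    stimulus 0.2 deg left or right (uniform), except that at a running
    offset of +/-0.8 deg the next shift is forced back toward center."""
    out: list[PointEvent] = []
    t = 0.0
    offset = 0.0
    cap = cfg.microshift_cap_deg
    step = cfg.microshift_step_deg
    while True:
        t += float(rng.choice(cfg.blank_gap_choices_s))
        if t >= trial_duration_s:
            break
        if offset >= cap - 1e-12:
            direction = "left"
        elif offset <= -cap + 1e-12:
            direction = "right"
        else:
            direction = "right" if rng.uniform() < 0.5 else "left"
        offset += step if direction == "right" else -step
        out.append(
            PointEvent(
                t,
                "microshift",
                {"shift_direction": direction, "offset_deg": round(offset, 10)},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full trial
# ---------------------------------------------------------------------------


@dataclass
class TrialGroundTruth:
    """Everything generated for one trial, including what detectors should find."""

    participant: int
    trial_id: str
    condition: str  # test | blank | microshift
    rotation_deg: float
    duration_s: float
    sample_rate_hz: float
    timeline: ReportTimeline
    internal_switches: list  # (time_s, to_percept)
    blinks: list  # IntervalEvent
    blanks: list  # IntervalEvent
    microshifts: list  # PointEvent
    microsaccades: list  # PointEvent with amplitude/direction/duration attrs

    @property
    def blink_onsets(self) -> np.ndarray:
        return np.array([b.onset_s for b in self.blinks])

    @property
    def microsaccade_onsets(self) -> np.ndarray:
        return np.array([m.time_s for m in self.microsaccades])

    def event_onsets(self, label: str) -> np.ndarray:
        if label == "blink":
            return self.blink_onsets
        if label == "microsaccade":
            return self.microsaccade_onsets
        if label == "blank":
            return np.array([b.onset_s for b in self.blanks])
        if label == "microshift":
            return np.array([m.time_s for m in self.microshifts])
        raise KeyError(label)


def _percept_at(t: float, timeline: ReportTimeline) -> str | None:
    """Reported percept at time t (None between lift and next press)."""
    current = None
    for r in timeline.records:
        if r.time_s > t:
            break
        current = r.percept if r.action == "press" else None
    return current


def _sample_direction(cfg: SimConfig, percept: str | None, rotation_deg: float, rng) -> float:
    """Microsaccade direction (deg, screen frame) from the per-percept mixture."""
    coh = coherent_direction_deg(rotation_deg)
    comp = component_directions_deg(rotation_deg)
    weights = cfg.direction_mixture.get(
        percept if percept in ("coherent", "component") else "coherent"
    )
    u = rng.uniform()
    sd = cfg.direction_lobe_sd_deg
    if u < weights["opp_coherent"]:
        center = coh + 180.0
    elif u < weights["opp_coherent"] + weights["opp_component"]:
        center = comp[int(rng.uniform() < 0.5)] + 180.0
    else:
        return float(rng.uniform(0.0, 360.0))
    return float((center + rng.normal(0.0, sd)) % 360.0)


def _ms_duration_s(amplitude_deg: float) -> float:
    # duration grows with amplitude (12 ms + 24 ms/deg), keeping peak
    # velocity 2A/d on a realistic main sequence
    return 0.012 + 0.024 * amplitude_deg


def _sample_microsaccade_amplitude(cfg: SimConfig, rng) -> float:
    mean, sd = cfg.ms_amplitude_mean_deg, cfg.ms_amplitude_sd_deg
    shape, scale = _gamma_params(mean, sd)
    for _ in range(100):
        a = rng.gamma(shape, scale)
        if 0.05 <= a <= cfg.ms_max_amplitude_deg:
            return float(a)
    return mean


def simulate_trial(
    cfg: SimConfig,
    participant: int,
    trial_index: int,
    condition: str = "test",
    rotation_deg: float = 0.0,
) -> TrialGroundTruth:
    """Generate the complete ground truth for one trial."""
    if condition not in ("test", "blank", "microshift"):
        raise ConfigError(f"unknown condition {condition!r}")
    T = cfg.trial_duration_s

    rng_rep = trial_rng(cfg, participant, trial_index, stream=0)
    switches, timeline = sample_percept_sequence(cfg, rng_rep)

    # anchors for switch-locked kernels: the reported lifts, by switch type
    lifts = {"coherent": [], "component": []}
    for a in switch_anchors(timeline):
        to = a.attributes["to_percept"]
        if to in lifts:
            lifts[to].append(a.time_s)

    rng_sched = trial_rng(cfg, participant, trial_index, stream=1)
    blanks = schedule_blanks(cfg, T, rng_sched) if condition == "blank" else []
    microshifts = (
        schedule_microshifts(cfg, T, rng_sched) if condition == "microshift" else []
    )

    # blinks: switch-locked modulation only
    rng_blink = trial_rng(cfg, participant, trial_index, stream=2)
    blink_kernels = cfg.switch_kernels.get("blink", {})
    onsets = sample_modulated_events(
        cfg.blink_rate_per_min / 60.0, blink_kernels, lifts, T, rng_blink
    )
    lo_ms, hi_ms = cfg.blink_duration_ms
    blinks: list[IntervalEvent] = []
    t_free = 0.0
    for t0 in onsets:
        dur = float(rng_blink.uniform(lo_ms, hi_ms)) / 1000.0
        if t0 < t_free or t0 + dur > T:
            continue  # keep blinks separated so each is individually detectable
        blinks.append(IntervalEvent(float(t0), float(t0 + dur), "blink"))
        t_free = t0 + dur + cfg.min_blink_gap_s

    # microsaccades: switch-locked + event-locked modulation
    rng_ms = trial_rng(cfg, participant, trial_index, stream=3)
    ms_kernels: dict = dict(cfg.switch_kernels.get("microsaccade", {}))
    ms_anchors: dict = {k: lifts.get(k, []) for k in ms_kernels}
    for key, kernels in cfg.ms_event_kernels.items():
        if key == "blink_onset":
            times = [b.onset_s for b in blinks]
        elif key == "blink_offset":
            times = [b.offset_s for b in blinks]
        elif key == "blank_onset":
            times = [b.onset_s for b in blanks]
        elif key == "blank_offset":
            times = [b.offset_s for b in blanks]
        elif key == "microshift":
            times = [m.time_s for m in microshifts]
        else:
            raise ConfigError(f"unknown event-kernel anchor {key!r}")
        if times:
            ms_kernels[key] = kernels
            ms_anchors[key] = times
    ms_onsets = sample_modulated_events(
        cfg.microsaccade_rate_hz, ms_kernels, ms_anchors, T, rng_ms
    )
    # the eye is closed during a blink: no microsaccade can occur near one
    for b in blinks:
        ms_onsets = ms_onsets[
            (ms_onsets < b.onset_s - 0.05) | (ms_onsets > b.offset_s + 0.05)
        ]
    microsaccades: list[PointEvent] = []
    t_prev_end = -1.0
    for t0 in ms_onsets:
        amp = _sample_microsaccade_amplitude(cfg, rng_ms)
        dur = _ms_duration_s(amp)
        if t0 <= t_prev_end or t0 + dur > T:
            continue
        direction = _sample_direction(cfg, _percept_at(float(t0), timeline), rotation_deg, rng_ms)
        microsaccades.append(
            PointEvent(
                float(t0),
                "microsaccade",
                {
                    "amplitude_deg": amp,
                    "direction_deg": direction,
                    "duration_s": dur,
                    "peak_velocity_dps": 2.0 * amp / dur,
                },
            )
        )
        t_prev_end = t0 + dur + 0.02
    return TrialGroundTruth(
        participant=participant,
        trial_id=f"p{participant:02d}_t{trial_index:02d}_{condition}",
        condition=condition,
        rotation_deg=rotation_deg,
        duration_s=T,
        sample_rate_hz=cfg.sample_rate_hz,
        timeline=timeline,
        internal_switches=switches,
        blinks=blinks,
        blanks=blanks,
        microshifts=microshifts,
        microsaccades=microsaccades,
    )


def simulate_session(cfg: SimConfig, participant: int) -> list[TrialGroundTruth]:
    """All trials for one participant: test trials cycling through the four
    stimulus rotations, then blank trials, then microshift trials."""
    rotations = (0.0, 22.5, 67.5, 90.0)
    trials: list[TrialGroundTruth] = []
    idx = 0
    for _ in range(cfg.trials_per_participant):
        trials.append(
            simulate_trial(cfg, participant, idx, "test", rotations[idx % 4])
        )
        idx += 1
    for _ in range(cfg.n_blank_trials):
        trials.append(
            simulate_trial(cfg, participant, idx, "blank", rotations[idx % 4])
        )
        idx += 1
    for _ in range(cfg.n_microshift_trials):
        trials.append(
            simulate_trial(cfg, participant, idx, "microshift", rotations[idx % 4])
        )
        idx += 1
    return trials


def simulate_cohort(cfg: SimConfig) -> dict[int, list[TrialGroundTruth]]:
    return {p: simulate_session(cfg, p) for p in range(cfg.n_participants)}


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _raised_cosine_displacement(t_rel: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Displacement along the saccade axis at times t_rel in [0, duration].

    Velocity profile v(t) = (A/d)(1 - cos(2 pi t/d)): starts and ends at
    zero, peaks at 2A/d mid-flight, integrates exactly to A.
    """
    x = np.clip(t_rel / duration, 0.0, 1.0)
    return amplitude * (x - np.sin(2.0 * np.pi * x) / (2.0 * np.pi))


def render_recording(gt: TrialGroundTruth, cfg: SimConfig, rng=None) -> Recording:
    """Render gaze and pupil traces for a trial's ground truth.

    Gaze (conjugate in both eyes) = random-walk drift + slow pursuit toward
    the currently perceived motion direction + raised-cosine microsaccade
    displacements.  Pupil (independent noise per eye) = baseline + Gaussian
    noise, with each blink rendered as a 20-ms linear ramp down, a missing
    core, and a ramp up.  Gaze is missing wherever the pupil is.
    """
    if rng is None:
        rng = np.random.default_rng(
            [cfg.seed, gt.participant, hash(gt.trial_id) % (2**31), 4]
        )
    fs = gt.sample_rate_hz
    n = int(round(gt.duration_s * fs))
    t = np.arange(n) / fs
    for ev in gt.blinks + gt.microsaccades:
        end = ev.offset_s if isinstance(ev, IntervalEvent) else ev.time_s
        if end > gt.duration_s + 1e-9:
            raise ValidationError(f"event ending at {end} s outside trial span")

    # --- gaze: shared (conjugate) signal ---
    x = np.cumsum(rng.normal(0.0, cfg.drift_sd_deg, size=n))
    y = np.cumsum(rng.normal(0.0, cfg.drift_sd_deg, size=n))
    if cfg.pursuit_speed_dps > 0:
        from .core import percept_intervals  # local import to avoid clutter

        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for iv in percept_intervals(gt.timeline):
                percept = iv.label.removeprefix("percept_")
                if percept == "coherent":
                    ang = np.deg2rad(coherent_direction_deg(gt.rotation_deg))
                else:
                    ang = np.deg2rad(component_directions_deg(gt.rotation_deg)[0])
                sel = (t >= iv.onset_s) & (t < iv.offset_s)
                ramp = np.cumsum(sel) / fs * cfg.pursuit_speed_dps
                x += np.cos(ang) * ramp * sel
                y += np.sin(ang) * ramp * sel

    for ms in gt.microsaccades:
        amp = ms.attributes["amplitude_deg"]
        dur = ms.attributes["duration_s"]
        ang = np.deg2rad(ms.attributes["direction_deg"])
        i0 = int(np.ceil(ms.time_s * fs))
        i1 = min(n, int(np.floor((ms.time_s + dur) * fs)) + 1)
        if i0 >= n:
            continue
        disp = _raised_cosine_displacement(t[i0:i1] - ms.time_s, amp, dur)
        x[i0:i1] += np.cos(ang) * disp
        y[i0:i1] += np.sin(ang) * disp
        x[i1:] += np.cos(ang) * amp
        y[i1:] += np.sin(ang) * amp

    # --- pupil per eye, with blinks ---
    ramp_s = cfg.blink_ramp_ms / 1000.0
    missing = np.zeros(n, dtype=bool)

    def pupil_trace() -> np.ndarray:
        p = cfg.pupil_baseline + rng.normal(0.0, cfg.pupil_noise_sd, size=n)
        for b in gt.blinks:
            on, off = b.onset_s, b.offset_s
            core0 = int(np.ceil((on + ramp_s) * fs))
            core1 = int(np.floor((off - ramp_s) * fs)) + 1
            i_on = int(np.ceil(on * fs))
            i_off = min(n, int(np.floor(off * fs)) + 1)
            core0, core1 = max(0, core0), min(n, core1)
            down = np.arange(i_on, core0)
            if down.size:
                frac = (t[down] - on) / ramp_s
                p[down] -= cfg.blink_depth * np.clip(frac, 0.0, 1.0)
            up = np.arange(core1, i_off)
            if up.size:
                frac = (off - t[up]) / ramp_s
                p[up] -= cfg.blink_depth * np.clip(frac, 0.0, 1.0)
            missing[core0:core1] = True
        return p

    pl = pupil_trace()
    pr = pupil_trace()
    pl[missing] = np.nan
    pr[missing] = np.nan
    xl, yl = x.copy(), y.copy()
    xr, yr = x.copy(), y.copy()
    for arr in (xl, yl, xr, yr):
        arr[missing] = np.nan
    valid = ~missing
    return Recording(
        sample_times=t,
        left=EyeTrace(xl, yl, pl, valid.copy()),
        right=EyeTrace(xr, yr, pr, valid.copy()),
        sample_rate=fs,
        trial_id=gt.trial_id,
        rotation_deg=gt.rotation_deg,
        condition=gt.condition,
        trial_duration_s=gt.duration_s,
    )
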