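"""Binocular microsaccade detection in two-dimensional velocity space.

Gaze positions are converted to velocities with a 5-point moving-window
derivative; per-component thresholds are a multiple ``lambda_sd`` of a
median-based velocity spread estimate, so the threshold adapts to each
trial's noise while ignoring the saccades themselves.  Samples whose
velocity lies outside the threshold ellipse form monocular candidates;
only binocularly coincident candidates are kept, then filtered by the
1-deg amplitude ceiling, a peak-velocity ceiling, and a 20-ms exclusion
zone around blinks.  The amplitude/peak-velocity main sequence is the
standard detector diagnostic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import InsufficientDataError, IntervalEvent, Recording, ValidationError

SampleRun = tuple[int, int]

_SIGMA_FLOOR = 1e-9


@dataclass
class MsConfig:
    lambda_sd: float = 6.0
    min_samples: int = 4
    max_amplitude_deg: float = 1.0
    peak_velocity_ceiling_dps: float = 300.0
    blink_exclusion_ms: float = 20.0
    require_binocular: bool = True

    def __post_init__(self):
        if self.lambda_sd <= 0:
            raise ValueError("lambda_sd must be > 0")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        if self.max_amplitude_deg <= 0:
            raise ValueError("max_amplitude_deg must be > 0")


@dataclass
class Microsaccade:
    """A detected (binocular) microsaccade.

    ``direction_deg`` is in [0, 360) with 0 = rightward, counter-clockwise
    positive; ``amplitude_deg`` is the start-to-end Euclidean displacement.
    """

    onset_s: float
    offset_s: float
    amplitude_deg: float
    direction_deg: float
    peak_velocity_dps: float
    eye: str = "binocular"

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def velocity_trace(x: np.ndarray, y: np.ndarray, sample_rate: float) -> np.ndarray:
    """5-point moving-window velocity, shape (n, 2), in deg/s.

    v_n = (p_{n+2} + p_{n+1} - p_{n-1} - p_{n-2}) / (6 dt) per component;
    exact for linear position signals.  The first/last two samples are NaN,
    as is any sample whose window touches missing gaze.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5 or y.size != n:
        raise InsufficientDataError("need >= 5 samples in both components")
    dt = 1.0 / sample_rate
    v = np.full((n, 2), np.nan)
    for j, p in enumerate((x, y)):
        v[2:-2, j] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt)
    return v


def velocity_thresholds(v: np.ndarray, lambda_sd: float) -> tuple[float, float]:
    """Per-component detection thresholds eta = lambda_sd * sigma, where
    sigma^2 = median(v^2) - median(v)^2 over non-missing samples.

    The median estimator is insensitive to the (rare, fast) saccades it is
    meant to detect.  If it degenerates (constant velocity), sigma is
    floored at a small epsilon with a warning.
    """
    v = np.asarray(v, dtype=float)
    etas = []
    for j in range(2):
        comp = v[:, j]
        comp = comp[~np.isnan(comp)]
        if comp.size < 2:
            raise InsufficientDataError("need >= 2 non-missing velocity samples")
        var = np.median(comp**2) - np.median(comp) ** 2
        if var <= _SIGMA_FLOOR**2:
            warnings.warn(
                "degenerate velocity spread; flooring sigma at epsilon", stacklevel=2
            )
            sigma = _SIGMA_FLOOR
        else:
            sigma = float(np.sqrt(var))
        etas.append(lambda_sd * sigma)
    return (etas[0], etas[1])


def detect_monocular(
    v: np.ndarray, thresholds: tuple[float, float], min_samples: int = 4
) -> list[SampleRun]:
    """Maximal runs with (v_x/eta_x)^2 + (v_y/eta_y)^2 > 1 lasting at least
    ``min_samples`` samples; NaN velocity is sub-threshold."""
    ex, ey = thresholds
    if ex <= 0 or ey <= 0:
        raise ValueError("thresholds must be > 0")
    with np.errstate(invalid="ignore"):
        crit = (v[:, 0] / ex) ** 2 + (v[:, 1] / ey) ** 2 > 1.0
    crit = np.where(np.isnan(v).any(axis=1), False, crit)
    padded = np.concatenate(([False], crit, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = list(zip(edges[::2].tolist(), edges[1::2].tolist()))
    return [(s, e) for s, e in runs if e - s >= min_samples]


def binocular_match(
    left_candidates: list[SampleRun], right_candidates: list[SampleRun]
) -> list[SampleRun]:
    """Pair monocular candidates that overlap by at least one sample.

    Greedy by onset; each candidate is used at most once; the binocular
    event spans the union of the pair.
    """
    used = np.zeros(len(right_candidates), dtype=bool)
    out: list[SampleRun] = []
    for ls, le in sorted(left_candidates):
        for i, (rs, re) in enumerate(right_candidates):
            if used[i]:
                continue
            if ls < re and rs < le:  # >= 1 sample overlap (half-open runs)
                out.append((min(ls, rs), max(le, re)))
                used[i] = True
                break
    return sorted(out)


class PropertyUndefinedError(ValueError):
    """Event touches missing gaze samples; its properties are undefined."""


def event_properties(
    event: SampleRun,
    x: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    sample_times: np.ndarray,
) -> Microsaccade:
    """Amplitude (start-to-end displacement), direction (atan2, deg in
    [0,360)), and peak velocity over the event."""
    s, e = event
    last = min(e, x.size - 1)
    dx = x[last] - x[s]
    dy = y[last] - y[s]
    if np.isnan(dx) or np.isnan(dy):
        raise PropertyUndefinedError("event touches missing gaze samples")
    seg = v[s:e]
    speed = np.sqrt(seg[:, 0] ** 2 + seg[:, 1] ** 2)
    if np.all(np.isnan(speed)):
        raise PropertyUndefinedError("no velocity samples inside event")
    onset_s = float(sample_times[s])
    offset_s = float(
        sample_times[e] if e < sample_times.size else sample_times[-1]
    )
    return Microsaccade(
        onset_s=onset_s,
        offset_s=offset_s,
        amplitude_deg=float(np.hypot(dx, dy)),
        direction_deg=float(np.degrees(np.arctan2(dy, dx)) % 360.0),
        peak_velocity_dps=float(np.nanmax(speed)),
    )


def filter_events(
    events: list[Microsaccade],
    cfg: MsConfig,
    blinks: list[IntervalEvent] | None = None,
) -> list[Microsaccade]:
    """Keep events with amplitude <= 1 deg, peak velocity below the ceiling,
    and no blink within 20 ms of the event."""
    blinks = blinks or []
    margin = cfg.blink_exclusion_ms / 1000.0
    out = []
    for ev in events:
        if ev.amplitude_deg - cfg.max_amplitude_deg > 1e-9:  # epsilon for float round-off
            continue
        if ev.peak_velocity_dps > cfg.peak_velocity_ceiling_dps:
            continue
        lo, hi = ev.onset_s - margin, ev.offset_s + margin
        if any(b.onset_s < hi and lo < b.offset_s for b in blinks):
            continue
        out.append(ev)
    return out


def main_sequence(events: list[Microsaccade]) -> tuple[float, float, float]:
    """Least-squares fit of log10(peak velocity) on log10(amplitude).

    Returns (slope, intercept, r).  The near-linear log-log relation is the
    classic sanity check that detections are genuine saccades.
    """
    amps = np.array([e.amplitude_deg for e in events])
    pv = np.array([e.peak_velocity_dps for e in events])
    ok = (amps > 0) & (pv > 0)
    if ok.sum() < 3:
        raise InsufficientDataError("need >= 3 events with positive amplitude")
    res = stats.linregress(np.log10(amps[ok]), np.log10(pv[ok]))
    return float(res.slope), float(res.intercept), float(res.rvalue)


def detect_microsaccades(
    rec: Recording,
    cfg: MsConfig | None = None,
    blinks: list[IntervalEvent] | None = None,
) -> list[Microsaccade]:
    """Full binocular detection pipeline on a recording."""
    cfg = cfg or MsConfig()
    events: list[Microsaccade] = []
    runs_per_eye = []
    vels = []
    for eye in (rec.left, rec.right):
        v = velocity_trace(eye.gaze_x, eye.gaze_y, rec.sample_rate)
        thr = velocity_thresholds(v, cfg.lambda_sd)
        runs_per_eye.append(detect_monocular(v, thr, cfg.min_samples))
        vels.append(v)
    matched = (
        binocular_match(runs_per_eye[0], runs_per_eye[1])
        if cfg.require_binocular
        else sorted(set(runs_per_eye[0]) | set(runs_per_eye[1]))
    )
    for run in matched:
        try:
            ev = event_properties(
                run, rec.left.gaze_x, rec.left.gaze_y, vels[0], rec.sample_times
            )
        except PropertyUndefinedError:
            continue
        events.append(ev)
    return filter_events(events, cfg, blinks)
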