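"""Blink detection from binocular pupil-diameter traces.

A video-based tracker loses the pupil while the eyelid is closed and sees a
rapidly shrinking pupil while it is closing.  The detector therefore:

1. z-transforms each eye's pupil trace (over non-missing samples),
2. marks candidate blinks as maximal runs where BOTH eyes are either below
   ``-k_sd`` standard deviations or missing,
3. extends each candidate outward until both eyes are back above half the
   threshold (``-k_sd/2``),
4. concatenates blinks less than 100 ms apart and discards blinks shorter
   than 50 ms or longer than 1000 ms.

Candidate/extension/merge stages work on half-open 0-based sample-index
runs ``(start, end)``; :func:`detect_blinks` composes them and returns
events in seconds on the recording clock.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateTraceError,
    InsufficientDataError,
    IntervalEvent,
    Recording,
    ValidationError,
)

SampleRun = tuple[int, int]


@dataclass
class BlinkConfig:
    """Detector settings.  ``k_sd`` is the z-threshold (the field sets it by
    visual inspection, typically between 1.9 and 4); boundary extension uses
    half of it.  Merging happens before duration filtering."""

    k_sd: float = 2.5
    merge_gap_ms: float = 100.0
    min_duration_ms: float = 50.0
    max_duration_ms: float = 1000.0
    missing_counts_as_subthreshold: bool = True

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if not 0 < self.min_duration_ms < self.max_duration_ms:
            raise ValueError("need 0 < min_duration < max_duration")
        if self.merge_gap_ms <= 0:
            raise ValueError("merge_gap_ms must be > 0")


def zscore_pupil(pupil: np.ndarray) -> np.ndarray:
    """z-transform a pupil trace over its non-missing samples.

    Uses the population standard deviation (divide by n); missing (NaN)
    samples stay missing.  Raises if fewer than two samples are usable or
    the usable samples have zero variance.
    """
    p = np.asarray(pupil, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 non-missing pupil samples")
    mu = p[ok].mean()
    sd = p[ok].std()  # ddof=0
    if sd == 0:
        raise DegenerateTraceError("pupil trace has zero variance")
    return (p - mu) / sd


def _runs(mask: np.ndarray) -> list[SampleRun]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def candidate_blinks(
    z_left: np.ndarray, z_right: np.ndarray, cfg: BlinkConfig
) -> list[SampleRun]:
    """Maximal runs where both eyes are in blink-state.

    An eye is in blink-state at a sample iff its z-scored pupil is below
    ``-k_sd`` or the sample is missing (fully covered pupil).
    """
    zl = np.asarray(z_left, dtype=float)
    zr = np.asarray(z_right, dtype=float)
    if zl.shape != zr.shape:
        raise ValidationError("left/right traces differ in length")

    def state(z):
        miss = np.isnan(z)
        below = np.where(miss, cfg.missing_counts_as_subthreshold, z < -cfg.k_sd)
        return below

    return _runs(state(zl) & state(zr))


def extend_bounds(
    candidates: list[SampleRun],
    z_left: np.ndarray,
    z_right: np.ndarray,
    cfg: BlinkConfig,
) -> list[SampleRun]:
    """Grow each candidate outward sample-by-sample until both eyes are
    above half the threshold (missing counts as not-above); extension
    clamps at the trace boundaries."""
    zl = np.asarray(z_left, dtype=float)
    zr = np.asarray(z_right, dtype=float)
    half = -cfg.k_sd / 2.0
    # above-half means strictly greater; NaN compares False (not above)
    above = (zl > half) & (zr > half)
    n = zl.size
    out: list[SampleRun] = []
    for start, end in candidates:
        s = start
        while s > 0 and not above[s - 1]:
            s -= 1
        e = end
        while e < n and not above[e]:
            e += 1
        out.append((s, e))
    return out


def merge_and_filter(
    blinks: list[SampleRun], cfg: BlinkConfig, sample_rate: float
) -> list[SampleRun]:
    """Concatenate blinks less than ``merge_gap_ms`` apart (merging first),
    then discard durations outside ``[min_duration_ms, max_duration_ms]``."""
    for a, b in zip(blinks, blinks[1:]):
        if b[0] < a[0]:
            raise ValidationError("blinks must be sorted by onset")
    gap_samples = cfg.merge_gap_ms / 1000.0 * sample_rate
    merged: list[list[int]] = []
    for s, e in blinks:
        if merged and (s - merged[-1][1]) < gap_samples:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    lo = cfg.min_duration_ms / 1000.0 * sample_rate
    hi = cfg.max_duration_ms / 1000.0 * sample_rate
    return [(s, e) for s, e in merged if lo <= (e - s) <= hi]


def detect_blinks(rec: Recording, cfg: BlinkConfig | None = None) -> list[IntervalEvent]:
    """Run the full blink pipeline on a recording.

    Returns blink intervals in seconds on the recording clock, each
    carrying its duration in ms.
    """
    cfg = cfg or BlinkConfig()
    zl = zscore_pupil(rec.left.pupil)
    zr = zscore_pupil(rec.right.pupil)
    cands = candidate_blinks(zl, zr, cfg)
    extended = extend_bounds(cands, zl, zr, cfg)
    kept = merge_and_filter(extended, cfg, rec.sample_rate)
    t = rec.sample_times
    fs = rec.sample_rate
    out = []
    for s, e in kept:
        onset = float(t[s])
        offset = float(t[e]) if e < t.size else float(t[-1] + 1.0 / fs)
        out.append(
            IntervalEvent(
                onset, offset, "blink", {"duration_ms": (offset - onset) * 1000.0}
            )
        )
    return out
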