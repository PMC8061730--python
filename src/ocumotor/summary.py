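"""Per-percept event rates, paired effect sizes, microsaccade direction
analyses in stimulus-aligned coordinates, and participant QC screens.

Directions are pooled across stimulus rotations by first rotating each
trial's microsaccade directions so the coherent-motion direction sits at
0 deg; "opposite to coherent" is then always the 180 +/- 10 deg sector and
"opposite to the components" the union of the 112.5 +/- 10 and
247.5 +/- 10 deg sectors.  Sectors are closed on the lower edge and open
on the upper so the boundary cases are deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    COMPONENT_OFFSET_DEG,
    DegenerateTraceError,
    InsufficientDataError,
    IntervalEvent,
    coherent_direction_deg,
)


@dataclass
class DirectionConfig:
    bin_deg: float = 10.0
    opposition_halfwidth_deg: float = 10.0
    component_offsets_deg: float = COMPONENT_OFFSET_DEG

    def __post_init__(self):
        if abs(360.0 / self.bin_deg - round(360.0 / self.bin_deg)) > 1e-9:
            raise ValueError("360 must be divisible by bin_deg")


# ---------------------------------------------------------------------------
# Rates and paired tests
# ---------------------------------------------------------------------------


def rate_by_percept(
    event_times: np.ndarray,
    percepts: list[IntervalEvent],
    per: str = "s",
) -> dict[str, float | None]:
    """Event rate during each percept, honouring the percept durations.

    rate(label) = (# event onsets inside intervals of that label) /
    (total duration of those intervals).  A percept never reported in the
    input gets ``None`` (missing), not zero.  ``per`` selects the unit:
    's' for events/s, 'min' for events/min.
    """
    if per not in ("s", "min"):
        raise ValueError("per must be 's' or 'min'")
    events = np.asarray(event_times, dtype=float)
    totals: dict[str, float] = {}
    counts: dict[str, float] = {}
    for iv in percepts:
        label = iv.label.removeprefix("percept_")
        totals[label] = totals.get(label, 0.0) + iv.duration_s
        counts[label] = counts.get(label, 0.0) + float(
            np.count_nonzero((events >= iv.onset_s) & (events < iv.offset_s))
        )
    scale = 1.0 if per == "s" else 60.0
    out: dict[str, float | None] = {"coherent": None, "component": None}
    for label, dur in totals.items():
        if dur > 0:
            out[label] = counts[label] / dur * scale
    return out


def paired_t_and_d(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, float]:
    """Paired t-test with the matching Cohen's d.

    D = a - b; d = mean(D)/sd(D) (sample sd); t = d*sqrt(n); two-sided p
    from the t-distribution with n-1 df.  Returns (t, df, p, d).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have the same shape")
    n = a.size
    if n < 2:
        raise InsufficientDataError("need >= 2 pairs")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing values not allowed in paired test")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateTraceError("zero-variance differences: d undefined")
    d = float(diff.mean() / sd)
    t = d * np.sqrt(n)
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p), d


# ---------------------------------------------------------------------------
# Directions
# ---------------------------------------------------------------------------


def align_directions(directions_deg: np.ndarray, rotation_deg: float) -> np.ndarray:
    """Rotate screen-frame directions into the stimulus-aligned frame in
    which the coherent motion direction is 0 deg."""
    d = np.asarray(directions_deg, dtype=float)
    return (d - coherent_direction_deg(rotation_deg)) % 360.0


def direction_histogram(
    directions_deg: np.ndarray, cfg: DirectionConfig | None = None
) -> tuple[np.ndarray, int]:
    """Percentage histogram over [0,10), [10,20), ... bins.

    Returns (percentages, n_events); percentages sum to 100 for non-empty
    input and are all zero (flagged by n_events=0) otherwise.
    """
    cfg = cfg or DirectionConfig()
    d = np.asarray(directions_deg, dtype=float)
    if np.any((d < 0) | (d >= 360.0)):
        raise ValueError("directions must lie in [0, 360)")
    nb = int(round(360.0 / cfg.bin_deg))
    counts, _ = np.histogram(d, bins=nb, range=(0.0, 360.0))
    n = int(d.size)
    if n == 0:
        return np.zeros(nb), 0
    return counts / n * 100.0, n


def _circular_delta(directions: np.ndarray, target_deg: float) -> np.ndarray:
    """Signed circular difference direction - target, wrapped to [-180, 180)."""
    return (np.asarray(directions, dtype=float) - target_deg + 180.0) % 360.0 - 180.0


def opposition_share(
    directions_deg: np.ndarray, reference_deg: float, halfwidth_deg: float = 10.0
) -> float | None:
    """Percent of directions within the sector opposite ``reference_deg``.

    The sector is ``[ref+180-hw, ref+180+hw)`` with circular wraparound
    (closed lower edge, open upper).  Empty input returns None.
    """
    d = np.asarray(directions_deg, dtype=float)
    if d.size == 0:
        return None
    delta = _circular_delta(d, (reference_deg + 180.0) % 360.0)
    inside = (delta >= -halfwidth_deg) & (delta < halfwidth_deg)
    return float(np.mean(inside) * 100.0)


def component_opposition_share(
    directions_deg: np.ndarray,
    coherent_reference_deg: float,
    halfwidth_deg: float = 10.0,
    component_offset_deg: float = COMPONENT_OFFSET_DEG,
) -> float | None:
    """Percent of directions opposite either component motion: the union of
    the two sectors at (ref +/- 67.5) + 180 deg."""
    d = np.asarray(directions_deg, dtype=float)
    if d.size == 0:
        return None
    inside = np.zeros(d.size, dtype=bool)
    for off in (+component_offset_deg, -component_offset_deg):
        target = (coherent_reference_deg + off + 180.0) % 360.0
        delta = _circular_delta(d, target)
        inside |= (delta >= -halfwidth_deg) & (delta < halfwidth_deg)
    return float(np.mean(inside) * 100.0)


# ---------------------------------------------------------------------------
# Participant QC
# ---------------------------------------------------------------------------


@dataclass
class QcDecision:
    include: bool
    reasons: list[str]


def qc_participant(
    blink_rate_per_min: float, missing_fraction: float
) -> QcDecision:
    """Exclude a participant whose blink rate (computed on trials without
    blanks or microshifts) is below 5/min or above 35/min, or whose data
    are more than 39% missing."""
    reasons: list[str] = []
    if blink_rate_per_min < 5.0:
        reasons.append(f"blink rate {blink_rate_per_min:.2f}/min below 5/min")
    if blink_rate_per_min > 35.0:
        reasons.append(f"blink rate {blink_rate_per_min:.2f}/min above 35/min")
    if missing_fraction > 0.39:
        reasons.append(f"missing-data fraction {missing_fraction:.2f} above 0.39")
    return QcDecision(include=not reasons, reasons=reasons)
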