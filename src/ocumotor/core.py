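"""Shared data types, time/coordinate conventions, and delimited-text I/O.

Conventions used throughout the package:

* Time is in seconds, zero at trial start; all intervals are half-open
  ``[onset, offset)``; sample indices are 0-based.
* Gaze is in visual degrees with screen-right = 0 deg and counter-clockwise
  positive (y-axis up).  Pupil diameter is in arbitrary tracker units; a
  sample where the pupil was not detected is NaN and carries ``valid=False``.
* The ambiguous plaid is reported as one of two percepts: ``coherent``
  (one pattern moving in a single direction) or ``component`` (two gratings
  sliding across each other at +/-67.5 deg to the coherent direction).
  Observers hold a button down for the current percept; the button *lift*
  is the first behavioural indicator of a perceptual switch and is the
  anchor for all switch-locked analyses.

All file formats are plain tab-delimited text ('.' decimal, UTF-8) with an
optional sidecar header of ``# key=value`` lines for trial metadata.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a structural invariant (ordering, alignment, labels)."""


class ParseError(ValueError):
    """A delimited-text artifact could not be parsed."""


class InsufficientDataError(ValueError):
    """Too few usable samples/events for the requested computation."""


class DegenerateTraceError(ValueError):
    """A trace has zero variance where variability is required."""


ROTATIONS = (0.0, 22.5, 67.5, 90.0, 112.5, 180.0)
CONDITIONS = ("test", "blank", "microshift")
PERCEPTS = ("coherent", "component")

#: Angular offset of each component-motion direction from the coherent one.
COMPONENT_OFFSET_DEG = 67.5


def coherent_direction_deg(rotation_deg: float) -> float:
    """Direction of coherent plaid motion for a given stimulus rotation.

    At rotation 0 the coherent pattern moves straight down (270 deg in the
    right=0, counter-clockwise-positive frame); rotating the stimulus by
    ``r`` rotates the motion clockwise on screen, so e.g. rotation 90 gives
    leftward (180 deg) and rotation 180 gives upward (90 deg) motion.
    """
    return (270.0 - rotation_deg) % 360.0


def component_directions_deg(rotation_deg: float) -> tuple[float, float]:
    """The two component-motion directions (+/-67.5 deg off coherent)."""
    c = coherent_direction_deg(rotation_deg)
    return ((c + COMPONENT_OFFSET_DEG) % 360.0, (c - COMPONENT_OFFSET_DEG) % 360.0)


# ---------------------------------------------------------------------------
# Event containers
# ---------------------------------------------------------------------------

INTERVAL_LABELS = (
    "blink",
    "blank",
    "microsaccade",
    "percept_coherent",
    "percept_component",
    "no_switch_period",
)
POINT_LABELS = ("microshift", "button_press", "button_lift", "switch_anchor")


@dataclass
class IntervalEvent:
    """A labelled half-open interval ``[onset_s, offset_s)`` on the trial clock."""

    onset_s: float
    offset_s: float
    label: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.onset_s < self.offset_s:
            raise ValidationError(
                f"interval onset {self.onset_s} must precede offset {self.offset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "IntervalEvent") -> bool:
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s


@dataclass
class PointEvent:
    """A labelled instant on the trial clock."""

    time_s: float
    label: str
    attributes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Report timeline
# ---------------------------------------------------------------------------


@dataclass
class ReportRecord:
    time_s: float
    action: str  # "press" | "lift"
    percept: str  # "coherent" | "component"


@dataclass
class ReportTimeline:
    """Ordered button press/lift records defining percept intervals.

    One button per percept, pressed for as long as that percept dominates.
    Records must be strictly time-ordered, a lift must match the percept of
    the preceding press, and press/lift must alternate.  A trailing press
    with no matching lift is tolerated (trial ended mid-percept).
    """

    records: list[ReportRecord] = field(default_factory=list)

    def __post_init__(self):
        t_prev = -np.inf
        open_percept = None
        for i, r in enumerate(self.records):
            if r.action not in ("press", "lift"):
                raise ValidationError(f"record {i}: unknown action {r.action!r}")
            if r.percept not in PERCEPTS:
                raise ValidationError(f"record {i}: unknown percept {r.percept!r}")
            if not r.time_s > t_prev:
                raise ValidationError(
                    f"record {i}: times must strictly increase ({r.time_s} after {t_prev})"
                )
            t_prev = r.time_s
            if r.action == "press":
                if open_percept is not None:
                    raise ValidationError(f"record {i}: press while button held")
                open_percept = r.percept
            else:
                if open_percept is None:
                    raise ValidationError(f"record {i}: lift without press")
                if r.percept != open_percept:
                    raise ValidationError(
                        f"record {i}: lift percept {r.percept!r} does not match "
                        f"press percept {open_percept!r}"
                    )
                open_percept = None

    def __len__(self):
        return len(self.records)


def percept_intervals(timeline: ReportTimeline) -> list[IntervalEvent]:
    """Percept intervals spanning each press to its corresponding lift.

    The gap between a lift and the next press belongs to no percept.  An
    unmatched trailing press (trial ended while the button was held) is
    dropped with a warning, since its duration is unknown.
    """
    out: list[IntervalEvent] = []
    press: ReportRecord | None = None
    for r in timeline.records:
        if r.action == "press":
            press = r
        else:
            out.append(
                IntervalEvent(press.time_s, r.time_s, f"percept_{r.percept}")
            )
            press = None
    if press is not None:
        warnings.warn(
            f"dropping unmatched press at {press.time_s:.3f} s (truncated percept)",
            stacklevel=2,
        )
    return out


def switch_anchors(timeline: ReportTimeline) -> list[PointEvent]:
    """One switch anchor per button lift.

    The lift is the first indicator of a perceptual switch; the percept
    being switched *to* is only known at the next press.  Anchors carry
    ``from_percept`` and ``to_percept`` attributes; a final lift with no
    subsequent press gets ``to_percept='unknown'`` and is excluded from
    switch-type-classed analyses downstream.
    """
    recs = timeline.records
    anchors: list[PointEvent] = []
    for i, r in enumerate(recs):
        if r.action != "lift":
            continue
        to_percept = "unknown"
        for nxt in recs[i + 1 :]:
            if nxt.action == "press":
                to_percept = nxt.percept
                break
        anchors.append(
            PointEvent(
                r.time_s,
                "switch_anchor",
                {"from_percept": r.percept, "to_percept": to_percept},
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------


@dataclass
class EyeTrace:
    """Per-sample monocular traces; NaN pupil <=> valid False."""

    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray


@dataclass
class Recording:
    """Binocular per-sample traces plus trial metadata."""

    sample_times: np.ndarray
    left: EyeTrace
    right: EyeTrace
    sample_rate: float
    trial_id: str = "trial"
    rotation_deg: float = 0.0
    condition: str = "test"
    trial_duration_s: float | None = None

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        self.sample_times = t
        for eye in (self.left, self.right):
            for name in ("gaze_x", "gaze_y", "pupil"):
                arr = np.asarray(getattr(eye, name), dtype=float)
                setattr(eye, name, arr)
                if arr.shape != t.shape:
                    raise ValidationError(f"{name} length does not match sample_times")
            eye.valid = np.asarray(eye.valid, dtype=bool)
            if eye.valid.shape != t.shape:
                raise ValidationError("valid length does not match sample_times")
            if not np.array_equal(np.isnan(eye.pupil), ~eye.valid):
                raise ValidationError("missing pupil must coincide with valid=False")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError("sample_times must be strictly increasing")
            nominal = 1.0 / self.sample_rate
            if np.any(np.abs(dt - nominal) > 0.1 * nominal):
                raise ValidationError(
                    "sample spacing deviates >10% from 1/sample_rate"
                )
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.trial_duration_s is None:
            self.trial_duration_s = float(t[-1] + 1.0 / self.sample_rate) if t.size else 0.0

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    def missing_fraction(self) -> float:
        """Fraction of samples with at least one eye invalid."""
        if self.n_samples == 0:
            return 0.0
        return float(np.mean(~self.left.valid | ~self.right.valid))


def recordings_equal(a: Recording, b: Recording, atol: float = 1e-6) -> bool:
    """Equality up to the 6-decimal round-trip guarantee of the TSV format."""
    if a.n_samples != b.n_samples:
        return False
    meta = (
        a.trial_id == b.trial_id
        and a.condition == b.condition
        and abs(a.rotation_deg - b.rotation_deg) <= atol
        and abs(a.sample_rate - b.sample_rate) <= atol
        and abs(a.trial_duration_s - b.trial_duration_s) <= atol
    )
    if not meta:
        return False
    if not np.allclose(a.sample_times, b.sample_times, atol=atol):
        return False
    for ea, eb in ((a.left, b.left), (a.right, b.right)):
        if not np.array_equal(ea.valid, eb.valid):
            return False
        for name in ("gaze_x", "gaze_y", "pupil"):
            xa, xb = getattr(ea, name), getattr(eb, name)
            if not np.allclose(xa, xb, atol=atol, equal_nan=True):
                return False
    return True


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_REC_COLUMNS = ["time_s", "xl", "yl", "pl", "vl", "xr", "yr", "pr", "vr"]


def _read_sidecar(path) -> tuple[dict, int]:
    """Parse leading '# key=value' lines; returns (metadata, n_header_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if not body:
                continue
            if "=" not in body:
                raise ParseError(f"{path}: malformed header at line {lineno}: {line!r}")
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta, n


def _sidecar_block(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_recording(rec: Recording, path) -> str:
    """Write a Recording as TSV with a '# key=value' metadata sidecar header."""
    meta = {
        "trial_id": rec.trial_id,
        "sample_rate_hz": f"{rec.sample_rate:g}",
        "rotation_deg": f"{rec.rotation_deg:g}",
        "condition": rec.condition,
        "trial_duration_s": f"{rec.trial_duration_s:.6f}",
    }
    df = pd.DataFrame(
        {
            "time_s": rec.sample_times,
            "xl": rec.left.gaze_x,
            "yl": rec.left.gaze_y,
            "pl": rec.left.pupil,
            "vl": rec.left.valid.astype(int),
            "xr": rec.right.gaze_x,
            "yr": rec.right.gaze_y,
            "pr": rec.right.pupil,
            "vr": rec.right.valid.astype(int),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_sidecar_block(meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f", na_rep="")
    return str(path)


def read_recording(path) -> Recording:
    """Read a recording TSV written by :func:`write_recording`.

    Missing pupil is encoded by an empty field; the validity flags must agree
    with pupil missingness, and times must be strictly increasing.
    """
    meta, n_header = _read_sidecar(path)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=n_header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def eye(x, y, p, v):
        return EyeTrace(
            gaze_x=df[x].to_numpy(float),
            gaze_y=df[y].to_numpy(float),
            pupil=df[p].to_numpy(float),
            valid=df[v].to_numpy(float).astype(bool),
        )

    try:
        sample_rate = float(meta["sample_rate_hz"])
    except KeyError as exc:
        raise ParseError(f"{path}: header lacks sample_rate_hz") from exc
    return Recording(
        sample_times=df["time_s"].to_numpy(float),
        left=eye("xl", "yl", "pl", "vl"),
        right=eye("xr", "yr", "pr", "vr"),
        sample_rate=sample_rate,
        trial_id=meta.get("trial_id", "trial"),
        rotation_deg=float(meta.get("rotation_deg", 0.0)),
        condition=meta.get("condition", "test"),
        trial_duration_s=float(meta["trial_duration_s"])
        if "trial_duration_s" in meta
        else None,
    )


def write_events(events: Sequence[IntervalEvent | PointEvent], path, meta: dict | None = None) -> str:
    """Write interval/point events as TSV: onset_s, offset_s, label, attributes.

    Point events leave offset_s empty.  Attribute columns are the union of
    all attribute keys, in first-seen order.
    """
    attr_keys: list[str] = []
    for ev in events:
        for k in ev.attributes:
            if k not in attr_keys:
                attr_keys.append(k)
    rows = []
    for ev in events:
        if isinstance(ev, IntervalEvent):
            row = {"onset_s": ev.onset_s, "offset_s": ev.offset_s, "label": ev.label}
        else:
            row = {"onset_s": ev.time_s, "offset_s": np.nan, "label": ev.label}
        for k in attr_keys:
            row[k] = ev.attributes.get(k, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"] + attr_keys)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(_sidecar_block(meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f", na_rep="")
    return str(path)


def read_events(path) -> list[IntervalEvent | PointEvent]:
    meta, n_header = _read_sidecar(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    if df.empty and "label" not in df.columns:
        raise ParseError(f"{path}: missing label column")
    attr_cols = [c for c in df.columns if c not in ("onset_s", "offset_s", "label")]
    out: list[IntervalEvent | PointEvent] = []
    for _, row in df.iterrows():
        attrs = {}
        for c in attr_cols:
            v = row[c]
            if isinstance(v, float) and np.isnan(v):
                continue
            attrs[c] = v
        if pd.isna(row["offset_s"]):
            out.append(PointEvent(float(row["onset_s"]), str(row["label"]), attrs))
        else:
            out.append(
                IntervalEvent(
                    float(row["onset_s"]), float(row["offset_s"]), str(row["label"]), attrs
                )
            )
    return out


def write_reports(timeline: ReportTimeline, path, meta: dict | None = None) -> str:
    df = pd.DataFrame(
        {
            "time_s": [r.time_s for r in timeline.records],
            "action": [r.action for r in timeline.records],
            "percept": [r.percept for r in timeline.records],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(_sidecar_block(meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return str(path)


def read_reports(path) -> ReportTimeline:
    meta, n_header = _read_sidecar(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    for col in ("time_s", "action", "percept"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return ReportTimeline(
        [
            ReportRecord(float(t), str(a), str(p))
            for t, a, p in zip(df["time_s"], df["action"], df["percept"])
        ]
    )
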