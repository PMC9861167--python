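"""Domain types shared by the whole pipeline.

The pipeline operates on *detection streams*: time-stamped outputs of an
object detector watching a farrowing crate from above.  The detector emits
boxes for one of four sow postures (lateral lying, sternal lying, standing,
sitting) and for newborn piglets.  Everything downstream — the pre-farrowing
warning, the farrowing alarm, the piglet count — is computed from these
events, never from pixels.

Time is real-valued seconds from stream start throughout the package; hours
appear only at the reporting boundary (the transition-frequency statistic is
per hour).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PostureLabel",
    "PIGLET",
    "OBJECT_CLASSES",
    "BoundingBox",
    "DetectionEvent",
    "PostureTimeline",
    "FarrowingState",
    "ConfusionCounts",
    "Rejection",
    "ValidatedStream",
    "validate_stream",
    "timeline_from_stream",
]


class PostureLabel(str, enum.Enum):
    """The four sow postures. Piglet is a separate object class, never a posture."""

    LATERAL_LYING = "lateral_lying"
    STERNAL_LYING = "sternal_lying"
    STANDING = "standing"
    SITTING = "sitting"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Object class for a newborn piglet detection.
PIGLET = "piglet"

#: The full five-class detector vocabulary (four postures + piglet).
OBJECT_CLASSES: tuple[str, ...] = tuple(p.value for p in PostureLabel) + (PIGLET,)

# integer codes used by PostureTimeline; -1 encodes a missing sample
_POSTURE_CODE = {p.value: i for i, p in enumerate(PostureLabel)}
_CODE_POSTURE = {i: p for i, p in enumerate(PostureLabel)}
MISSING = -1


class BoundingBox(NamedTuple):
    """Axis-aligned box in pixel coordinates, origin top-left.

    Coordinates are continuous; validity (x_min < x_max, y_min < y_max)
    is enforced at stream-validation / parse time so that raw detector
    output can be carried around before being screened.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def is_valid(self) -> bool:
        return self.x_min < self.x_max and self.y_min < self.y_max


class DetectionEvent(NamedTuple):
    """One detector output: time (s from stream start), class, box, confidence."""

    t: float
    label: str
    box: BoundingBox
    conf: float


@dataclass(frozen=True)
class Rejection:
    """A record dropped during validation/parsing, with the reason kept."""

    index: int
    reason: str
    payload: object = None


@dataclass
class ValidatedStream:
    """Result of :func:`validate_stream`: clean events plus the rejection report."""

    events: list[DetectionEvent]
    rejections: list[Rejection] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def _check_event(ev: DetectionEvent) -> str | None:
    """Return a rejection reason for *ev*, or None when it is acceptable."""
    if not isinstance(ev.t, (int, float)) or not math.isfinite(ev.t) or ev.t < 0:
        return f"bad timestamp {ev.t!r}"
    if ev.label not in OBJECT_CLASSES:
        return f"unknown class {ev.label!r}"
    box = ev.box
    if not isinstance(box, BoundingBox):
        try:
            box = BoundingBox(*box)
        except (TypeError, ValueError):
            return f"malformed box {ev.box!r}"
    if not all(math.isfinite(v) for v in box):
        return f"non-finite box {tuple(box)!r}"
    if not box.is_valid():
        return f"inverted or zero-area box {tuple(box)!r}"
    if not (0.0 <= ev.conf <= 1.0):
        return f"confidence {ev.conf!r} outside [0, 1]"
    return None


def validate_stream(events: Iterable[DetectionEvent]) -> ValidatedStream:
    """Screen raw events: drop malformed records, sort the rest by time.

    Malformed records (unknown label, inverted box, confidence outside
    [0, 1], negative or non-finite time) are collected into the rejection
    report rather than raised, so one bad detector frame cannot take the
    monitor down.
    """
    good: list[DetectionEvent] = []
    bad: list[Rejection] = []
    for i, ev in enumerate(events):
        reason = _check_event(ev)
        if reason is None:
            good.append(ev)
        else:
            bad.append(Rejection(index=i, reason=reason, payload=ev))
    good.sort(key=lambda e: e.t)
    if bad:
        log.warning("validate_stream rejected %d of %d records", len(bad), len(good) + len(bad))
    return ValidatedStream(events=good, rejections=bad)


@dataclass
class PostureTimeline:
    """Per-sow posture over time: strictly increasing sample times, one label each.

    Labels are stored as small integer codes (``-1`` marks a missing sample,
    i.e. a moment at which the detector emitted no posture box).  Two storage
    conventions are used in the package:

    * a *regular* timeline, one sample per fixed interval — what
      :func:`timeline_from_stream` produces from a detection stream;
    * a *changepoint* timeline, one sample per posture dwell — how the
      simulator stores the true posture path (consecutive samples then
      always differ, so sample count − 1 is the exact transition count).
    """

    times: np.ndarray  # float64 seconds, strictly increasing
    codes: np.ndarray  # int8; -1 = missing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.times.shape != self.codes.shape:
            raise ValueError("times and codes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_pairs(
        cls, samples: Sequence[tuple[float, PostureLabel | str | None]]
    ) -> "PostureTimeline":
        times = np.array([t for t, _ in samples], dtype=np.float64)
        codes = np.array(
            [
                MISSING
                if lab is None
                else _POSTURE_CODE[lab.value if isinstance(lab, PostureLabel) else str(lab)]
                for _, lab in samples
            ],
            dtype=np.int8,
        )
        return cls(times=times, codes=codes)

    def labels(self) -> list[PostureLabel | None]:
        return [None if c == MISSING else _CODE_POSTURE[int(c)] for c in self.codes]

    @property
    def span_seconds(self) -> float:
        if len(self.times) == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def timeline_from_stream(
    events: Sequence[DetectionEvent],
    sample_interval: float,
    span: float | None = None,
) -> PostureTimeline:
    """Collapse a detection stream to one posture sample per interval.

    Intervals are half-open ``[k*dt, (k+1)*dt)``; each interval's label is the
    posture class of the highest-confidence sow-posture detection falling in
    it (piglet events are ignored here), or missing when the interval holds
    none.  Ties on confidence go to the earlier detection, so output is
    deterministic.  *span* fixes the covered stream length; by default it is
    inferred from the last event, giving ``floor(t_last/dt) + 1`` samples.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    dt = float(sample_interval)
    post = [(e.t, e.label, e.conf) for e in events if e.label != PIGLET]
    if span is None:
        t_last = max((e.t for e in events), default=None)
        if t_last is None:
            return PostureTimeline(times=np.empty(0), codes=np.empty(0, dtype=np.int8))
        n = int(t_last // dt) + 1
    else:
        if span <= 0:
            raise ValueError("span must be > 0")
        n = int(math.ceil(span / dt))
    codes = np.full(n, MISSING, dtype=np.int8)
    if post:
        t = np.array([p[0] for p in post])
        conf = np.array([p[2] for p in post])
        lab = np.array([_POSTURE_CODE[p[1]] for p in post], dtype=np.int8)
        idx = (t // dt).astype(np.int64)
        ok = idx < n
        idx, conf, lab = idx[ok], conf[ok], lab[ok]
        # stable lexsort: within an interval, the highest-confidence event wins
        # and ties go to the earliest occurrence in the (time-ordered) stream.
        order = np.lexsort((-conf, idx))  # stable: preserves stream order on ties
        idx_s, lab_s = idx[order], lab[order]
        first = np.ones(len(idx_s), dtype=bool)
        first[1:] = idx_s[1:] != idx_s[:-1]
        codes[idx_s[first]] = lab_s[first]
    times = np.arange(n, dtype=np.float64) * dt
    return PostureTimeline(times=times, codes=codes)


@dataclass
class FarrowingState:
    """Farrowing supervision state.

    ``alarm`` is 1 exactly when ``t_start`` is set (the debounced first-piglet
    detection); ``duration_d = t_end − t_start`` once the end of farrowing has
    been declared.  ``detected_num`` is the running maximum of the per-frame
    piglet count ``cur_num`` and is therefore non-decreasing.
    """

    alarm: int = 0
    t_start: float | None = None
    t_end: float | None = None
    cur_num: int = 0
    detected_num: int = 0

    @property
    def duration_d(self) -> float | None:
        if self.t_start is None or self.t_end is None:
            return None
        return self.t_end - self.t_start

    def check(self) -> None:
        if self.alarm != (0 if self.t_start is None else 1):
            raise ValueError("alarm flag inconsistent with t_start")
        if self.detected_num < self.cur_num:
            raise ValueError("detected_num must dominate cur_num")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN tallies for precision/recall."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
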