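"""Farrowing supervision: debounced alarm, piglet counting, duration.

Farrowing is declared from the piglet channel of the detection stream.  To
keep spurious piglet boxes (a sow's ear or leg flagged as a piglet) from
raising premature alarms, the alarm requires ``k_consecutive`` consecutive
piglet-positive frames (default 3 — "three consecutive detections") before
it trips.  The supervision state tracks:

* ``alarm`` / ``t_start`` — the debounced start of farrowing; ``t_start`` is
  the first frame of the confirming run, the best available estimate of the
  first birth;
* ``cur_num`` — piglet boxes in the current frame;
* ``detected_num`` — running maximum of ``cur_num``, the monotone litter
  estimate available without identity tracking;
* ``t_end`` / ``duration_d`` — the end of farrowing is the last frame that
  raised the running maximum, declared final once ``end_quiet_hours`` pass
  with no new maximum.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .core import PIGLET, DetectionEvent, FarrowingState
from .simulate import GroundTruthScript

log = logging.getLogger(__name__)

__all__ = [
    "MonitorConfig",
    "AlertSink",
    "ConsoleSink",
    "LogSink",
    "MockPinSink",
    "AlarmRecord",
    "MonitorResult",
    "process_stream",
    "count_false_alarms",
    "piglet_count_report",
]

HOUR = 3600.0
ALARM_TEXT = "Delivery Begin! Start time: "


class AlertSink(Protocol):
    """Destination for alarm messages (console, log file, mock GPIO pin)."""

    def emit(self, message: str, t: float) -> None: ...


class ConsoleSink:
    def emit(self, message: str, t: float) -> None:
        print(message)


class LogSink:
    def __init__(self, logger: logging.Logger | None = None) -> None:
        self.logger = logger or log

    def emit(self, message: str, t: float) -> None:
        self.logger.info("[t=%.1fs] %s", t, message)


class MockPinSink:
    """Records every emit, standing in for an LED on a GPIO pin in tests."""

    def __init__(self) -> None:
        self.emitted: list[tuple[float, str]] = []

    def emit(self, message: str, t: float) -> None:
        self.emitted.append((t, message))


@dataclass
class MonitorConfig:
    """Debounce depth, end-of-farrowing quiet period, and alert routing."""

    k_consecutive: int = 3
    end_quiet_hours: float = 1.0
    sinks: list[AlertSink] = field(default_factory=list)
    stream_start: _dt.datetime | None = None  # wall-clock anchor for alarm text

    def __post_init__(self) -> None:
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")
        if self.end_quiet_hours < 0:
            raise ValueError("end_quiet_hours must be >= 0")

    def format_time(self, t_seconds: float) -> str:
        anchor = self.stream_start or _dt.datetime(1970, 1, 1)
        return (anchor + _dt.timedelta(seconds=t_seconds)).isoformat()


@dataclass(frozen=True)
class AlarmRecord:
    t: float
    message: str


@dataclass
class MonitorResult:
    state: FarrowingState
    alarms: list[AlarmRecord]
    frame_times: np.ndarray
    cur_num: np.ndarray
    detected_num: np.ndarray


def _piglet_frame_counts(
    events: Sequence[DetectionEvent], frame_interval: float, n_frames: int
) -> np.ndarray:
    """Piglet boxes per frame; frames are half-open [k*dt, (k+1)*dt)."""
    ts = np.fromiter(
        (e.t for e in events if e.label == PIGLET), dtype=float
    )
    counts = np.zeros(n_frames, dtype=np.int64)
    if len(ts):
        idx = (ts // frame_interval).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        np.add.at(counts, idx, 1)
    return counts


def _n_frames(events: Sequence[DetectionEvent], frame_interval: float, span: float | None) -> int:
    if span is not None:
        return int(np.ceil(span / frame_interval))
    t_last = max((e.t for e in events), default=None)
    if t_last is None:
        return 0
    return int(t_last // frame_interval) + 1


def process_stream(
    events: Sequence[DetectionEvent],
    frame_interval: float = 1.0,
    config: MonitorConfig | None = None,
    span: float | None = None,
) -> MonitorResult:
    """Run the farrowing monitor over a validated detection stream.

    A frame is piglet-positive when at least one piglet event falls in it;
    the alarm trips at the first run of ``k_consecutive`` positive frames,
    with ``t_start`` at the run's first frame.  The alarm message is
    dispatched exactly once to every configured sink.  ``t_end`` is the last
    frame that raised the running maximum of the per-frame count, and is
    only declared (duration computed) once ``end_quiet_hours`` elapse in the
    stream with no new maximum.
    """
    config = config or MonitorConfig()
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n = _n_frames(events, frame_interval, span)
    frame_times = np.arange(n) * frame_interval
    cur = _piglet_frame_counts(events, frame_interval, n)
    state = FarrowingState()
    alarms: list[AlarmRecord] = []
    detected = (
        np.maximum.accumulate(cur) if n else np.zeros(0, dtype=np.int64)
    )

    positive = cur > 0
    k = config.k_consecutive
    # first index where k consecutive positives end
    run = 0
    t_start = None
    for i in range(n):
        run = run + 1 if positive[i] else 0
        if run >= k:
            t_start = float(frame_times[i - k + 1])
            break
    if t_start is not None:
        state.alarm = 1
        state.t_start = t_start
        msg = ALARM_TEXT + config.format_time(t_start)
        alarms.append(AlarmRecord(t=t_start, message=msg))
        for sink in config.sinks:
            sink.emit(msg, t_start)

    if n:
        state.cur_num = int(cur[-1])
        state.detected_num = int(detected[-1])
    if state.alarm and state.detected_num > 0:
        raises = np.flatnonzero(np.diff(np.concatenate([[0], detected])) > 0)
        t_last_raise = float(frame_times[raises[-1]])
        quiet = (n - 1) * frame_interval - t_last_raise
        if quiet >= config.end_quiet_hours * HOUR:
            state.t_end = t_last_raise
        else:
            log.info("farrowing may be ongoing: no quiet period after last new maximum")
    state.check()
    return MonitorResult(
        state=state,
        alarms=alarms,
        frame_times=frame_times,
        cur_num=cur,
        detected_num=detected,
    )


def count_false_alarms(
    events: Sequence[DetectionEvent],
    script: GroundTruthScript,
    frame_interval: float = 1.0,
    k: int = 3,
) -> int:
    """False-alarm episodes: maximal piglet-positive runs of length >= k
    whose first frame precedes the true farrowing onset."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = _n_frames(events, frame_interval, script.span_seconds)
    cur = _piglet_frame_counts(events, frame_interval, n)
    positive = np.concatenate([[False], cur > 0, [False]])
    d = np.diff(positive.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    lengths = stops - starts
    start_times = starts * frame_interval
    return int(np.sum((lengths >= k) & (start_times < script.farrow_onset)))


def piglet_count_report(
    events: Sequence[DetectionEvent],
    script: GroundTruthScript,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Per-frame table (t, cur_num, detected_num, true_num) for the CA/DA metrics.

    ``true_num`` is the number of births at or before the frame time.
    """
    n = _n_frames(events, frame_interval, script.span_seconds)
    t = np.arange(n) * frame_interval
    cur = _piglet_frame_counts(events, frame_interval, n)
    return pd.DataFrame(
        {
            "t": t,
            "cur_num": cur,
            "detected_num": np.maximum.accumulate(cur),
            "true_num": script.births_before(t),
        }
    )
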