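"""Pre-farrowing early warning from the posture-transition frequency.

The warning statistic is the posture-transition frequency

    f = n / T        [transitions per hour]

computed over a sliding window of the posture timeline.  The dual-threshold
rule sends the approaching-farrowing warning when f stays above the upper
threshold (default 17.5/h) for a sustained span, and a second, farrowing-
imminent signal when f subsequently stays below the lower threshold
(default 10/h) for a sustained span; both spans default to 5 h so that
ordinary bouts of eating, drinking and resting cannot trip the rule.

Sustained-condition semantics
-----------------------------
With hourly counting windows the frequency estimate of a sow whose true rate
sits at 20/h is Poisson-noisy (sd ≈ 4.5/h), so requiring the raw series to
clear the threshold at literally every point makes the warning miss most
genuinely nest-building sows.  The default test therefore treats the
condition as an *episode*:

* the episode opens at the first series point satisfying the threshold;
* it is only abandoned when the series stays on the *contrary* side of a
  hysteresis band (``threshold ∓ hysteresis``, default 2.5/h) for longer
  than ``grace_hours`` (default 1.5 h) — brief dropouts of the estimator do
  not erase a real behavioral episode;
* the event fires at the first satisfying point whose distance from the
  episode onset has reached ``persistence_hours``, provided the mean of the
  series over the trailing persistence span also satisfies the threshold
  (so a short high-magnitude burst cannot buy persistence with magnitude).

Setting ``hysteresis = 0`` and ``grace_hours = 0`` recovers the strict
reading in which any single sub-threshold point resets the clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, PostureTimeline

log = logging.getLogger(__name__)

__all__ = [
    "FrequencySeries",
    "WarningConfig",
    "WarningEvent",
    "WarningAssessment",
    "count_transitions",
    "transition_frequency",
    "frequency_series",
    "evaluate_warnings",
    "warning_error",
]

HOUR = 3600.0


@dataclass
class FrequencySeries:
    """Sliding-window transition frequency: (window end time s, f per hour)."""

    window_hours: float
    t_end: np.ndarray  # seconds, strictly increasing window ends
    f: np.ndarray  # transitions/hour, >= 0

    def __post_init__(self) -> None:
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t_end.shape != self.f.shape:
            raise ValueError("t_end and f must have equal length")
        if len(self.t_end) > 1 and not np.all(np.diff(self.t_end) > 0):
            raise ValueError("window ends must be strictly increasing")
        if np.any(self.f < 0):
            raise ValueError("frequencies must be non-negative")

    def __len__(self) -> int:
        return len(self.f)


@dataclass(frozen=True)
class WarningConfig:
    """Thresholds and timing of the dual-threshold persistence rule.

    Units: thresholds in transitions/hour, every *_hours field in hours.
    """

    upper_threshold: float = 17.5
    lower_threshold: float = 10.0
    persistence_hours: float = 5.0
    window_hours: float = 1.0
    step_hours: float = 0.25
    hysteresis: float = 2.5  # how far past the threshold a point must be to count against
    grace_hours: float = 1.5  # longest tolerated contrary stretch inside an episode
    target_lead_hours: float = 5.0  # intended warning lead used by warning_error

    def __post_init__(self) -> None:
        if not self.upper_threshold > self.lower_threshold > 0:
            raise ValueError("need upper_threshold > lower_threshold > 0")
        if self.persistence_hours <= 0:
            raise ValueError("persistence_hours must be > 0")
        if self.window_hours <= 0 or self.step_hours <= 0:
            raise ValueError("window_hours and step_hours must be > 0")
        if self.hysteresis < 0 or self.grace_hours < 0:
            raise ValueError("hysteresis and grace_hours must be >= 0")
        if self.grace_hours >= self.persistence_hours:
            raise ValueError("grace_hours must be shorter than persistence_hours")


@dataclass(frozen=True)
class WarningEvent:
    """An emitted warning: kind, when the condition began, when it was sent."""

    kind: str  # "upper" | "lower"
    condition_onset: float  # seconds
    emitted_at: float  # seconds; == condition_onset + persistence


@dataclass(frozen=True)
class WarningAssessment:
    """How an emitted warning relates to the true farrowing onset."""

    lead_hours: float  # onset − emitted, >0 means warned before farrowing
    error_hours: float  # |lead − target_lead|
    late: bool  # warning after the true onset


def count_transitions(timeline: PostureTimeline, t_from: float, t_to: float) -> int:
    """Number of posture changes between consecutive samples in [t_from, t_to).

    Missing samples are skipped so the comparison bridges detector dropouts:
    the sequence a, missing, b counts one transition iff a != b.  Both
    samples of a counted pair must lie inside the window.
    """
    if not t_from < t_to:
        raise ValueError("need t_from < t_to")
    times, codes = timeline.times, timeline.codes
    lo = np.searchsorted(times, t_from, side="left")
    hi = np.searchsorted(times, t_to, side="left")
    c = codes[lo:hi]
    c = c[c != MISSING]
    if len(c) < 2:
        return 0
    return int(np.count_nonzero(c[1:] != c[:-1]))


def transition_frequency(n: int, t_hours: float) -> float:
    """The frequency statistic f = n / T, in transitions per hour."""
    if t_hours <= 0:
        raise ValueError("t_hours must be > 0")
    return n / t_hours


def frequency_series(timeline: PostureTimeline, config: WarningConfig | None = None) -> FrequencySeries:
    """Sliding-window transition frequency over a posture timeline.

    Windows are ``window_hours`` long, advanced by ``step_hours``; each point
    is the transition frequency over ``[t_end − window, t_end)``.  A timeline
    shorter than one window yields an empty series (with a logged notice).

    The computation is the vectorized equivalent of calling
    :func:`count_transitions` per window: each transition is stamped with the
    time of the later sample of its (gap-bridged) pair, and a window's count
    is the number of stamps inside it.
    """
    config = config or WarningConfig()
    win = config.window_hours * HOUR
    step = config.step_hours * HOUR
    if len(timeline) == 0 or timeline.times[-1] - timeline.times[0] < win:
        log.info("timeline shorter than one window; empty frequency series")
        return FrequencySeries(config.window_hours, np.empty(0), np.empty(0))
    present = timeline.codes != MISSING
    times = timeline.times[present]
    codes = timeline.codes[present]
    if len(times) >= 2:
        chg = codes[1:] != codes[:-1]
        stamp = times[1:][chg]  # a transition "happens" at its later sample
        pair_start = times[:-1][chg]  # earlier sample must also be in-window
    else:
        stamp = np.empty(0)
        pair_start = np.empty(0)
    t0 = timeline.times[0]
    t_last = timeline.times[-1]
    ends = np.arange(t0 + win, t_last + 1e-9, step)
    # count pairs fully inside [end - win, end): stamp < end, pair_start >= end - win
    n_in = np.searchsorted(stamp, ends, side="left") - np.searchsorted(
        pair_start, ends - win, side="left"
    )
    # a pair can only be miscounted if it straddles the window edge; clamp
    n_in = np.maximum(n_in, 0)
    f = n_in / config.window_hours
    return FrequencySeries(config.window_hours, ends, f)


def _sustained_fire(
    t: np.ndarray,
    f: np.ndarray,
    threshold: float,
    above: bool,
    config: WarningConfig,
    start_index: int = 0,
) -> tuple[float, float] | None:
    """First (emitted_at, onset) where the condition is sustained, else None.

    ``above=True`` tests f > threshold (upper warning); ``above=False`` tests
    f < threshold (lower warning).  Episode semantics as documented in the
    module docstring.
    """
    persist = config.persistence_hours * HOUR
    grace = config.grace_hours * HOUR
    step = config.step_hours * HOUR
    if above:
        ok = f > threshold
        contrary = f < threshold - config.hysteresis
    else:
        ok = f < threshold
        contrary = f > threshold + config.hysteresis
    k = int(round(persist / step))  # series points spanning the persistence window
    cs = np.concatenate([[0.0], np.cumsum(f)])
    onset_i: int | None = None
    dip = 0.0
    for i in range(start_index, len(f)):
        if onset_i is None:
            if ok[i]:
                onset_i = i
                dip = 0.0
            continue
        if contrary[i]:
            dip += step
            if dip > grace:
                onset_i = i if ok[i] else None
                dip = 0.0
                continue
        else:
            dip = 0.0
        if ok[i] and t[i] - t[onset_i] >= persist:
            j = i - k
            if j < start_index - 1 or j < 0:
                continue
            mean_f = (cs[i + 1] - cs[j]) / (i + 1 - j)
            if (above and mean_f > threshold) or (not above and mean_f < threshold):
                return float(t[i]), float(t[i] - persist)
    return None


def evaluate_warnings(
    series: FrequencySeries, config: WarningConfig | None = None
) -> list[WarningEvent]:
    """Run the dual-threshold state machine over a frequency series.

    At most one event of each kind is emitted per run: idle → upper-fired →
    lower-fired.  The lower-threshold condition is only armed once the upper
    warning has fired — otherwise any resting sow (f ≈ 0) would trigger it
    immediately, which contradicts the calm pre-nest-building baseline.
    """
    config = config or WarningConfig()
    events: list[WarningEvent] = []
    if len(series) == 0:
        return events
    t, f = series.t_end, series.f
    up = _sustained_fire(t, f, config.upper_threshold, True, config)
    if up is None:
        return events
    emitted, onset = up
    events.append(WarningEvent("upper", onset, emitted))
    start = int(np.searchsorted(t, emitted, side="right"))
    low = _sustained_fire(t, f, config.lower_threshold, False, config, start_index=start)
    if low is not None:
        events.append(WarningEvent("lower", low[1], low[0]))
    return events


def warning_error(
    emitted_at: float,
    true_farrow_onset: float,
    target_lead_hours: float = 5.0,
) -> WarningAssessment:
    """Compare a warning time with the true farrowing onset.

    ``lead_hours`` is positive when the warning preceded farrowing;
    ``error_hours`` is the absolute deviation from the intended lead
    (default 5 h before onset).  A warning after the onset is flagged late.
    """
    lead = (true_farrow_onset - emitted_at) / HOUR
    return WarningAssessment(
        lead_hours=lead,
        error_hours=abs(lead - target_lead_hours),
        late=lead < 0,
    )
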