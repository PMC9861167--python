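"""Synthetic perinatal sow behavior and the noisy detection streams it yields.

The generator has two halves:

* :func:`simulate_sow` draws a ground-truth script — the sow's true posture
  path over the perinatal window and the birth times of her litter.  Posture
  transitions follow an inhomogeneous Poisson clock whose rate traces the
  three-stage perinatal pattern: baseline activity until 24 h before
  farrowing, a pronounced nest-building rise and plateau through the last
  day, a collapse in the final hours, near-quiescence after farrowing.

* :func:`apply_detector_noise` converts a script into the detection stream an
  imperfect frame-by-frame detector would emit: per-frame posture misses and
  wrong labels, per-piglet misses, and spurious piglet boxes, at the rates of
  the named scenario presets (drawn from a field test of the detector in four
  lighting scenarios over 410 images).

Both halves are fully reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .core import (
    PIGLET,
    BoundingBox,
    DetectionEvent,
    PostureLabel,
    PostureTimeline,
)

__all__ = [
    "BehaviorProfile",
    "LitterModel",
    "DetectorNoiseProfile",
    "GroundTruthScript",
    "NOISE_PRESETS",
    "noise_preset",
    "simulate_sow",
    "apply_detector_noise",
]

HOUR = 3600.0


@dataclass(frozen=True)
class BehaviorProfile:
    """Piecewise-linear posture-transition rate (per hour) around farrowing.

    Times are hours relative to the farrowing onset (negative = before).
    Defaults encode: a steady 8/h baseline until 24 h before farrowing; a
    rise to a 20/h nest-building plateau over ``rise_hours``; the plateau
    holds until ``decline_start_hours`` before onset, then falls to
    ``stage_b_decline_end_rate`` by ``decline_end_hours`` before onset;
    after farrowing the rate restarts at ``stage_c_start_rate`` and drifts
    up to ``stage_c_end_rate`` by +24 h.
    """

    stage_a_rate: float = 8.0
    stage_b_peak_rate: float = 20.0
    stage_b_rise_start: float = 24.0  # hours before farrowing the rise begins
    stage_b_decline_end_rate: float = 2.0
    stage_c_start_rate: float = 1.0
    stage_c_end_rate: float = 4.0
    rise_hours: float = 2.0  # how long the rise to peak takes
    decline_start_hours: float = 2.0  # hours before onset the decline begins
    decline_end_hours: float = 1.0  # hours before onset the decline bottoms out

    def __post_init__(self) -> None:
        rates = (
            self.stage_a_rate,
            self.stage_b_peak_rate,
            self.stage_b_decline_end_rate,
            self.stage_c_start_rate,
            self.stage_c_end_rate,
        )
        if min(rates) < 0:
            raise ValueError("all rates must be non-negative")

    def is_warning_scenario(self, upper: float = 17.5, lower: float = 10.0) -> bool:
        """Whether the profile can trip the dual-threshold rule by construction."""
        return self.stage_b_peak_rate > upper and self.stage_b_decline_end_rate < lower

    def rate_at(self, hours_rel: np.ndarray | float) -> np.ndarray:
        """Transition rate (per hour) at hours relative to farrowing onset."""
        h = np.asarray(hours_rel, dtype=float)
        pre_x = np.array(
            [
                -self.stage_b_rise_start,
                -self.stage_b_rise_start + self.rise_hours,
                -self.decline_start_hours,
                -self.decline_end_hours,
            ]
        )
        pre_y = np.array(
            [
                self.stage_a_rate,
                self.stage_b_peak_rate,
                self.stage_b_peak_rate,
                self.stage_b_decline_end_rate,
            ]
        )
        post_x = np.array([0.0, 24.0])
        post_y = np.array([self.stage_c_start_rate, self.stage_c_end_rate])
        out = np.where(
            h < 0.0,
            np.interp(h, pre_x, pre_y),
            np.interp(h, post_x, post_y),
        )
        return out

    @property
    def max_rate(self) -> float:
        return max(
            self.stage_a_rate,
            self.stage_b_peak_rate,
            self.stage_b_decline_end_rate,
            self.stage_c_start_rate,
            self.stage_c_end_rate,
        )


@dataclass(frozen=True)
class LitterModel:
    """Birth process: litter size and inter-birth intervals.

    Litter size is a Poisson draw (mean 12) truncated below at 1 — typical of
    commercial hyperprolific lines; inter-birth intervals are exponential with
    mean 15 min, a common order of magnitude for uncomplicated farrowings.
    """

    litter_mean: float = 12.0
    litter_min: int = 1
    birth_interval_mean_min: float = 15.0

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Birth times in seconds relative to farrowing onset (first birth at 0)."""
        size = 0
        while size < self.litter_min:
            size = int(rng.poisson(self.litter_mean))
        gaps = rng.exponential(self.birth_interval_mean_min * 60.0, size=size - 1)
        return np.concatenate([[0.0], np.cumsum(gaps)])


@dataclass(frozen=True)
class DetectorNoiseProfile:
    """Per-frame detector error rates for one lighting scenario.

    ``posture_miss_rate`` and ``posture_false_rate`` are marginal per-frame
    probabilities of, respectively, emitting no posture box and emitting a
    wrong posture label; they are mutually exclusive outcomes of one draw
    (so the configured numbers are exactly the empirical rates a field count
    over frames would report).  ``piglet_miss_prob`` applies independently to
    every piglet already born; false piglet boxes arrive Poisson with mean
    ``piglet_false_rate`` per frame.
    """

    scenario: str = "ideal"
    posture_miss_rate: float = 0.0
    posture_false_rate: float = 0.0
    piglet_miss_prob: float = 0.0
    piglet_false_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("posture_miss_rate", "posture_false_rate", "piglet_miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.posture_miss_rate + self.posture_false_rate > 1.0:
            raise ValueError("posture miss + false rates exceed 1")
        if self.piglet_false_rate < 0:
            raise ValueError("piglet_false_rate must be >= 0")


# Field error rates of the reference detector in four scenarios (sow-posture
# rates are per-frame percentages; piglet errors were absolute counts over the
# 410 test images, converted to per-frame rates below in noise_preset()).
_SCENARIO_TABLE: dict[str, tuple[float, float, int, int]] = {
    # scenario: (posture_miss, posture_false, piglet_missed_count, piglet_false_count)
    "complex_light": (0.0633, 0.1519, 0, 11),
    "first_piglet_born": (0.0, 0.0, 2, 5),
    "heat_lamp_color": (0.0, 0.012, 7, 1),
    "heat_lamp_night": (0.0336, 0.0756, 15, 10),
}

_SCENARIO_IMAGES = 410


def noise_preset(
    name: str,
    *,
    assumed_piglets_visible: float = 8.0,
) -> DetectorNoiseProfile:
    """Build a named scenario preset.

    Piglet error counts from the field test are totals over 410 images, so a
    per-frame false rate is count/410.  Converting missed-piglet counts to a
    per-piglet miss probability needs an assumed number of piglets visible
    per image; that denominator is not recorded and is configurable here.
    """
    if name == "ideal":
        return DetectorNoiseProfile()
    try:
        miss, false, p_missed, p_false = _SCENARIO_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: ideal, {', '.join(_SCENARIO_TABLE)}"
        ) from None
    return DetectorNoiseProfile(
        scenario=name,
        posture_miss_rate=miss,
        posture_false_rate=false,
        piglet_miss_prob=p_missed / (_SCENARIO_IMAGES * assumed_piglets_visible),
        piglet_false_rate=p_false / _SCENARIO_IMAGES,
    )


NOISE_PRESETS: tuple[str, ...] = ("ideal",) + tuple(_SCENARIO_TABLE)


@dataclass
class GroundTruthScript:
    """True behavior of one simulated sow, in stream time (seconds from start).

    ``posture_path`` is a changepoint timeline: one sample per posture dwell,
    so consecutive samples always differ and ``len(path) − 1`` is the exact
    number of transitions.  ``farrow_onset`` equals the first birth time.
    """

    posture_path: PostureTimeline
    birth_times: np.ndarray  # seconds, strictly increasing
    farrow_onset: float
    litter_size: int
    horizon_s: tuple[float, float] = (0.0, 0.0)  # (start, end) in stream seconds

    def __post_init__(self) -> None:
        self.birth_times = np.asarray(self.birth_times, dtype=float)
        if len(self.birth_times) != self.litter_size:
            raise ValueError("len(birth_times) must equal litter_size")
        if len(self.birth_times) and not np.all(np.diff(self.birth_times) > 0):
            raise ValueError("birth_times must be strictly increasing")
        if len(self.birth_times) and self.farrow_onset != self.birth_times[0]:
            raise ValueError("farrow_onset must equal the first birth time")

    @property
    def span_seconds(self) -> float:
        return self.horizon_s[1] - self.horizon_s[0]

    def posture_codes_at(self, t: np.ndarray) -> np.ndarray:
        """True posture code at each time (seconds from stream start)."""
        idx = np.searchsorted(self.posture_path.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.posture_path) - 1)
        return self.posture_path.codes[idx]

    def births_before(self, t: np.ndarray | float) -> np.ndarray:
        """Cumulative true piglet count at time t (right-continuous step)."""
        return np.searchsorted(self.birth_times, t, side="right")


def simulate_sow(
    profile: BehaviorProfile | None = None,
    litter: LitterModel | None = None,
    horizon: tuple[float, float] = (-48.0, 24.0),
    seed: int = 0,
) -> GroundTruthScript:
    """Draw one sow's ground-truth script over *horizon* hours around farrowing.

    Posture dwell times come from an exponential clock whose instantaneous
    rate follows ``profile.rate_at`` (simulated by thinning); at each
    transition a new posture is drawn uniformly from the three others.
    Births start exactly at farrowing onset (relative hour 0) and follow the
    litter model.  Stream time is seconds from ``horizon[0]``.
    """
    profile = profile or BehaviorProfile()
    litter = litter or LitterModel()
    start_h, end_h = horizon
    if not (start_h < 0.0 < end_h):
        raise ValueError("horizon must satisfy start_h < 0 < end_h")
    rng = np.random.default_rng(seed)

    lam_max = profile.max_rate
    span_h = end_h - start_h
    # transition epochs via thinning of a homogeneous Poisson(lam_max) process
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * span_h)
        cand = np.sort(rng.uniform(start_h, end_h, n_cand))
        keep = rng.random(n_cand) < profile.rate_at(cand) / lam_max
        trans_h = cand[keep]
    else:
        trans_h = np.empty(0)

    # posture labels: initial uniform over 4; each transition uniform over the other 3
    labels = np.empty(len(trans_h) + 1, dtype=np.int8)
    labels[0] = rng.integers(0, 4)
    steps = rng.integers(1, 4, size=len(trans_h))  # shift by 1..3 mod 4 -> never equal
    for i, s in enumerate(steps):
        labels[i + 1] = (labels[i] + s) % 4

    seg_start_h = np.concatenate([[start_h], trans_h])
    times_s = (seg_start_h - start_h) * HOUR
    path = PostureTimeline(times=times_s, codes=labels)

    births_rel = litter.sample(rng)  # seconds relative to onset, first at 0
    births_rel = births_rel[births_rel <= end_h * HOUR]  # clip to horizon
    births_s = births_rel + (-start_h) * HOUR

    return GroundTruthScript(
        posture_path=path,
        birth_times=births_s,
        farrow_onset=float(births_s[0]),
        litter_size=len(births_s),
        horizon_s=(0.0, span_h * HOUR),
    )


# box-geometry defaults: an overhead view of a 2.2 m x 1.8 m crate at roughly
# 500 px/m.  Sizes are coarse; geometry only needs to be plausible and valid.
_PEN = (0.0, 0.0, 1100.0, 900.0)
_SOW_SIZE = {  # (width, height) px by posture code order of PostureLabel
    0: (800.0, 420.0),  # lateral lying
    1: (760.0, 360.0),  # sternal lying
    2: (780.0, 300.0),  # standing
    3: (420.0, 380.0),  # sitting
}
_PIGLET_SIZE = (110.0, 60.0)


def _boxes_in_pen(
    rng: np.random.Generator, n: int, size: tuple[float, float], pen=_PEN
) -> np.ndarray:
    w, h = size
    x0 = rng.uniform(pen[0], pen[2] - w, n)
    y0 = rng.uniform(pen[1], pen[3] - h, n)
    return np.column_stack([x0, y0, x0 + w, y0 + h])


def apply_detector_noise(
    script: GroundTruthScript,
    noise: DetectorNoiseProfile | None = None,
    frame_interval: float = 1.0,
    seed: int = 0,
    pen: tuple[float, float, float, float] = _PEN,
) -> list[DetectionEvent]:
    """Render a script into the detection stream a noisy detector would emit.

    One frame per ``frame_interval`` seconds at times ``k * frame_interval``.
    Per frame, the posture channel emits the true posture, a wrong posture
    (uniform over the three incorrect labels), or nothing, with the profile's
    probabilities.  Every piglet born by the frame time is detected
    independently with probability ``1 − piglet_miss_prob``; false piglet
    boxes are Poisson per frame.  Confidence scores are drawn U(0.6, 1.0)
    for true detections and U(0.3, 0.9) for erroneous ones.
    """
    noise = noise or DetectorNoiseProfile()
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = np.random.default_rng(seed)
    t0, t1 = script.horizon_s
    n_frames = int((t1 - t0) // frame_interval) + 1
    t = np.arange(n_frames) * frame_interval

    true_codes = script.posture_codes_at(t)
    u = rng.random(n_frames)
    missed = u < noise.posture_miss_rate
    wrong = (~missed) & (u < noise.posture_miss_rate + noise.posture_false_rate)
    emit = ~missed
    codes = true_codes.copy()
    if wrong.any():
        shift = rng.integers(1, 4, size=int(wrong.sum()))
        codes[wrong] = (codes[wrong] + shift) % 4
    conf = np.where(wrong, rng.uniform(0.3, 0.9, n_frames), rng.uniform(0.6, 1.0, n_frames))

    born = script.births_before(t)  # piglets alive per frame
    if noise.piglet_miss_prob >= 1.0:
        seen = np.zeros(n_frames, dtype=np.int64)
    elif noise.piglet_miss_prob > 0.0:
        seen = rng.binomial(born, 1.0 - noise.piglet_miss_prob)
    else:
        seen = born.astype(np.int64)
    false_pig = (
        rng.poisson(noise.piglet_false_rate, n_frames)
        if noise.piglet_false_rate > 0
        else np.zeros(n_frames, dtype=np.int64)
    )

    posture_names = [p.value for p in PostureLabel]
    sow_w = np.array([_SOW_SIZE[c][0] for c in range(4)])
    sow_h = np.array([_SOW_SIZE[c][1] for c in range(4)])

    # sow-posture events, geometry drawn in bulk
    w = sow_w[codes]
    hgt = sow_h[codes]
    jx = pen[0] + rng.random(n_frames) * (pen[2] - w - pen[0])
    jy = pen[1] + rng.random(n_frames) * (pen[3] - hgt - pen[1])

    # piglet events: true detections first, then false boxes, per frame
    n_pig = seen + false_pig
    total_pig = int(n_pig.sum())
    pig_boxes = _boxes_in_pen(rng, total_pig, _PIGLET_SIZE, pen)
    pig_frame = np.repeat(np.arange(n_frames), n_pig)
    # per-piglet flag: false box or real detection (real listed first in frame)
    offs = np.concatenate([[0], np.cumsum(n_pig)])
    within = np.arange(total_pig) - offs[pig_frame]
    pig_is_false = within >= seen[pig_frame]
    pig_conf = np.where(
        pig_is_false,
        rng.uniform(0.3, 0.9, total_pig),
        rng.uniform(0.6, 1.0, total_pig),
    )

    # build both channels in bulk, then merge; the sort is stable so a
    # frame's posture event stays ahead of its piglet events
    sow_events = [
        DetectionEvent(ti, posture_names[c], BoundingBox(x0, y0, x0 + ww, y0 + hh), cf)
        for ti, c, x0, y0, ww, hh, cf in zip(
            t[emit].tolist(),
            codes[emit].tolist(),
            jx[emit].tolist(),
            jy[emit].tolist(),
            w[emit].tolist(),
            hgt[emit].tolist(),
            conf[emit].tolist(),
        )
    ]
    pig_events = [
        DetectionEvent(ti, PIGLET, BoundingBox(x0, y0, x1, y1), cf)
        for ti, (x0, y0, x1, y1), cf in zip(
            t[pig_frame].tolist(), pig_boxes.tolist(), pig_conf.tolist()
        )
    ]
    events = sow_events + pig_events
    events.sort(key=lambda e: e.t)
    return events
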