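"""Reference metric and loss implementations used across the pipeline.

* :func:`giou_loss` — generalized-IoU bounding-box regression loss,
  ``1 − (IoU − |C \\ (A∪B)| / |C|)`` with C the smallest axis-aligned box
  enclosing both; lies in [0, 2).
* :func:`bce_loss` — binary cross-entropy summed over the five object
  classes (four postures + piglet), natural log, predictions clipped to
  ``[eps, 1−eps]``.
* :func:`precision` / :func:`recall` — TP/(TP+FP) and TP/(TP+FN);
  degenerate denominators yield None rather than a crash.
* :func:`ca_da` — piglet-counting accuracies over a supervision run:
  CA = Σ cur_num / Σ true_num (how well each frame's count matches),
  DA = Σ detected_num / Σ true_num (how well the running litter estimate
  tracks the true births).  DA ≥ CA whenever detected_num is the running
  maximum of cur_num.
* :func:`summarize_cohort` — unweighted per-sow means and ranges.

``FIELD_TRIAL_CA_DA`` carries the published per-pen CA/DA outcomes of a
22-sow farrowing-house trial of the reference detector, used as a worked
example for the cohort summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BoundingBox, ConfusionCounts

__all__ = [
    "ClassVector",
    "giou_loss",
    "bce_loss",
    "precision",
    "recall",
    "ca_da",
    "summarize_cohort",
    "FIELD_TRIAL_CA_DA",
]

EPS = 1e-7


@dataclass(frozen=True)
class ClassVector:
    """One 5-class target/prediction pair (four postures + piglet).

    ``y_pred`` values are post-sigmoid probabilities and are clipped to
    ``[eps, 1−eps]`` on construction so the log terms stay finite.
    """

    y_true: tuple[float, ...]
    y_pred: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.y_true) != 5 or len(self.y_pred) != 5:
            raise ValueError("class vectors must have exactly 5 entries")
        if any(y not in (0, 1) for y in self.y_true):
            raise ValueError("y_true entries must be 0 or 1")
        clipped = tuple(min(max(p, EPS), 1.0 - EPS) for p in self.y_pred)
        object.__setattr__(self, "y_pred", clipped)


def giou_loss(a: BoundingBox, b: BoundingBox) -> float:
    """Generalized-IoU loss between two boxes; 0 for identical boxes, <2 always."""
    a = BoundingBox(*a)
    b = BoundingBox(*b)
    if not (a.is_valid() and b.is_valid()):
        raise ValueError("giou_loss requires non-degenerate boxes")
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    iou = inter / union
    c = BoundingBox(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
    )
    penalty = (c.area - union) / c.area
    return 1.0 - (iou - penalty)


def bce_loss(v: ClassVector) -> float:
    """Binary cross-entropy summed over the 5 classes (natural logarithm)."""
    total = 0.0
    for y, p in zip(v.y_true, v.y_pred):
        total += y * math.log(p) + (1.0 - y) * math.log(1.0 - p)
    return -total


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP); None when there were no positive predictions."""
    denom = c.tp + c.fp
    return None if denom == 0 else c.tp / denom


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when there were no positive ground-truth samples."""
    denom = c.tp + c.fn
    return None if denom == 0 else c.tp / denom


def ca_da(table: pd.DataFrame) -> tuple[float, float]:
    """Current / Detected Number Accuracy over a per-frame count table.

    Expects the columns of ``piglet_count_report``: cur_num, detected_num,
    true_num; sums run over frames.  Raises when no piglet was truly present
    anywhere in the table (the accuracies are undefined then).
    """
    true_sum = float(table["true_num"].sum())
    if true_sum <= 0:
        raise ValueError("CA/DA undefined: no true piglets in the table")
    ca = float(table["cur_num"].sum()) / true_sum
    da = float(table["detected_num"].sum()) / true_sum
    return ca, da


def summarize_cohort(per_sow: Sequence[Mapping[str, float | None]]) -> dict:
    """Unweighted means and ranges of per-sow metrics.

    *per_sow* is a sequence of dicts; every numeric key present in any entry
    is summarized (None entries are dropped per key).
    """
    if not per_sow:
        raise ValueError("summarize_cohort needs a non-empty cohort")
    keys: list[str] = []
    for row in per_sow:
        for k in row:
            if k not in keys:
                keys.append(k)
    out: dict[str, dict[str, float] | int] = {"n_sows": len(per_sow)}
    for k in keys:
        vals = [float(r[k]) for r in per_sow if r.get(k) is not None]
        if not vals:
            continue
        out[k] = {
            "mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "n": len(vals),
        }
    return out


#: Published per-pen piglet-counting outcomes (percent) for the 22 sows of a
#: farrowing-house field trial of the reference detector.
FIELD_TRIAL_CA_DA: pd.DataFrame = pd.DataFrame(
    [
        ("03", 44.9, 95.0),
        ("04", 50.7, 91.7),
        ("05", 58.1, 94.1),
        ("06", 75.2, 95.9),
        ("07", 52.2, 96.4),
        ("08", 66.6, 96.8),
        ("09", 65.7, 94.3),
        ("10", 66.2, 81.2),
        ("15", 61.7, 84.4),
        ("16", 42.3, 90.3),
        ("17", 52.5, 89.9),
        ("18", 57.9, 92.1),
        ("19", 69.0, 95.2),
        ("20", 93.6, 98.3),
        ("21", 73.9, 99.6),
        ("22", 71.0, 93.1),
        ("25", 58.8, 99.3),
        ("26", 56.3, 83.6),
        ("27", 58.6, 87.1),
        ("28", 66.1, 99.4),
        ("29", 82.3, 88.0),
        ("30", 66.2, 98.4),
    ],
    columns=["sow_id", "ca_pct", "da_pct"],
)
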