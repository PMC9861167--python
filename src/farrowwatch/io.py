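"""On-disk formats: JSONL detection streams, VOC annotations, run configs.

Detection streams are JSON Lines — one object per line with fields
``t`` (seconds from stream start), ``class`` (one of the five object
classes), ``bbox`` ([x_min, y_min, x_max, y_max] pixels) and ``conf`` —
because the nested bbox array does not sit naturally in CSV.  Numbers are
serialized with repr-faithful precision so a write/read round trip is
lossless.

Ground-truth sidecars (simulator output) are a single JSON document holding
the true posture path, birth times and litter size.  Annotation files in the
PASCAL VOC XML dialect can be read for the five-class vocabulary.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    OBJECT_CLASSES,
    BoundingBox,
    DetectionEvent,
    PostureTimeline,
    Rejection,
    ValidatedStream,
    validate_stream,
)
from .simulate import GroundTruthScript

log = logging.getLogger(__name__)

__all__ = [
    "read_stream",
    "write_stream",
    "read_voc_annotations",
    "write_script",
    "read_script",
    "RunConfig",
    "load_config",
]


def write_stream(events: Sequence[DetectionEvent], path: str | Path) -> None:
    """Write events as JSON Lines (UTF-8, one record per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            rec = {
                "t": e.t,
                "class": str(e.label),
                "bbox": list(e.box),
                "conf": e.conf,
            }
            fh.write(json.dumps(rec) + "\n")


def read_stream(path: str | Path) -> ValidatedStream:
    """Read a JSONL stream; malformed lines land in the rejection report.

    The result carries the clean, time-sorted events plus one rejection per
    bad line, each tagged with its 1-based line number.
    """
    raw: list[DetectionEvent] = []
    rejections: list[Rejection] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                ev = DetectionEvent(
                    t=float(rec["t"]),
                    label=str(rec["class"]),
                    box=BoundingBox(*(float(v) for v in rec["bbox"])),
                    conf=float(rec["conf"]),
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                rejections.append(Rejection(index=lineno, reason=f"line {lineno}: {exc}"))
                continue
            raw.append(ev)
    result = validate_stream(raw)
    # re-key validation rejections by 0-based event index is fine; prepend parse failures
    result.rejections = rejections + result.rejections
    if rejections:
        log.warning("read_stream: %d malformed line(s) in %s", len(rejections), path)
    return result


def read_voc_annotations(path: str | Path) -> tuple[list[tuple[str, BoundingBox]], list[Rejection]]:
    """Parse a PASCAL VOC XML annotation file.

    Returns the (label, box) pairs for objects in the five-class vocabulary
    plus a rejection per unknown label or malformed bndbox.  VOC pixel
    coordinates are inclusive; they are used directly as continuous
    coordinates on load.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    objects: list[tuple[str, BoundingBox]] = []
    rejections: list[Rejection] = []
    for i, obj in enumerate(root.iter("object")):
        name_el = obj.find("name")
        name = None if name_el is None else (name_el.text or "").strip()
        if name not in OBJECT_CLASSES:
            rejections.append(Rejection(index=i, reason=f"unknown label {name!r}"))
            continue
        bnd = obj.find("bndbox")
        try:
            if bnd is None:
                raise ValueError("missing bndbox")
            coords = [float(bnd.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax")]
        except (TypeError, ValueError) as exc:
            rejections.append(Rejection(index=i, reason=f"bad bndbox: {exc}"))
            continue
        box = BoundingBox(*coords)
        if not box.is_valid():
            rejections.append(Rejection(index=i, reason=f"inverted box {coords!r}"))
            continue
        objects.append((name, box))
    return objects, rejections


def write_script(script: GroundTruthScript, path: str | Path) -> None:
    """Ground-truth sidecar: true posture path, births, litter size (JSON)."""
    doc = {
        "posture_path": {
            "times": script.posture_path.times.tolist(),
            "codes": script.posture_path.codes.tolist(),
        },
        "birth_times": script.birth_times.tolist(),
        "farrow_onset": script.farrow_onset,
        "litter_size": script.litter_size,
        "horizon_s": list(script.horizon_s),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_script(path: str | Path) -> GroundTruthScript:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruthScript(
        posture_path=PostureTimeline(
            times=np.array(doc["posture_path"]["times"]),
            codes=np.array(doc["posture_path"]["codes"], dtype=np.int8),
        ),
        birth_times=np.array(doc["birth_times"]),
        farrow_onset=doc["farrow_onset"],
        litter_size=doc["litter_size"],
        horizon_s=tuple(doc["horizon_s"]),
    )


class _WarningSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    upper_threshold: float = 17.5
    lower_threshold: float = 10.0
    persistence_hours: float = 5.0
    window_hours: float = 1.0
    step_hours: float = 0.25
    hysteresis: float = 2.5
    grace_hours: float = 1.5
    target_lead_hours: float = 5.0


class _MonitorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_consecutive: int = 3
    end_quiet_hours: float = 1.0
    stream_start_iso: str | None = None


class _ProfileSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage_a_rate: float = 8.0
    stage_b_peak_rate: float = 20.0
    stage_b_rise_start: float = 24.0
    stage_b_decline_end_rate: float = 2.0
    stage_c_start_rate: float = 1.0
    stage_c_end_rate: float = 4.0
    rise_hours: float = 2.0
    decline_start_hours: float = 2.0
    decline_end_hours: float = 1.0


class _LitterSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    litter_mean: float = 12.0
    litter_min: int = 1
    birth_interval_mean_min: float = 15.0


class _NoiseSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "ideal"
    assumed_piglets_visible: float = 8.0


class RunConfig(BaseModel):
    """Full run configuration; unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    frame_interval: float = 1.0
    # posture timeline resolution for the frequency statistic; coarser than
    # the frame rate so isolated wrong-label frames are voted out by
    # confidence, but fine enough (~20 s) that consecutive posture changes at
    # nest-building rates rarely collapse into one sample
    posture_sample_interval: float = 20.0
    horizon: tuple[float, float] = (-48.0, 24.0)
    warning: _WarningSection = Field(default_factory=_WarningSection)
    monitor: _MonitorSection = Field(default_factory=_MonitorSection)
    profile: _ProfileSection = Field(default_factory=_ProfileSection)
    litter: _LitterSection = Field(default_factory=_LitterSection)
    noise: _NoiseSection = Field(default_factory=_NoiseSection)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; a missing path yields all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig.model_validate(data)
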