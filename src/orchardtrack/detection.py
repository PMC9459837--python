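"""Per-frame fruit detections: mask-derived oracle + JSON Lines I/O.

The oracle turns a composite sample's ground-truth masks into the same
detection records a segmentation model would emit, optionally corrupted
(dropouts, vertex jitter, radius bias, spurious blobs) for desk-scale
robustness testing. Any callable ``(image, date) -> list[Detection]``
satisfies the detector adapter contract.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage import measure

from .annotation import mask_to_polygon
from .synthesis import CompositeSample

__all__ = [
    "Detection",
    "CorruptionSpec",
    "detection_from_mask",
    "oracle_detect",
    "write_detections",
    "read_detections",
]


@dataclass
class Detection:
    """One observed fruit in one frame."""

    contour: list[tuple[float, float]]
    bbox: tuple[float, float, float, float]  # half-open (x_min, y_min, x_max, y_max)
    center: tuple[float, float]
    radius: float
    capture_date: dt.date
    score: float = 1.0
    # provenance of oracle detections; None for real detector output
    source_instance: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        x0, y0, x1, y1 = self.bbox
        cx, cy = self.center
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise ValueError("center must lie inside bbox")

    def to_json_obj(self) -> dict:
        return {
            "contour": [[float(x), float(y)] for x, y in self.contour],
            "bbox": [float(v) for v in self.bbox],
            "center": [float(v) for v in self.center],
            "radius": float(self.radius),
            "date": self.capture_date.isoformat(),
            "score": float(self.score),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "Detection":
        return cls(
            contour=[(float(x), float(y)) for x, y in obj["contour"]],
            bbox=tuple(float(v) for v in obj["bbox"]),
            center=tuple(float(v) for v in obj["center"]),
            radius=float(obj["radius"]),
            capture_date=dt.date.fromisoformat(obj["date"]),
            score=float(obj.get("score", 1.0)),
        )


@dataclass
class CorruptionSpec:
    """Detector-imperfection model for the oracle."""

    drop_prob: float = 0.0
    spurious_rate: float = 0.0   # expected false detections per frame
    contour_jitter: float = 0.0  # px std of vertex noise
    radius_bias: float = 0.0     # multiplicative error std
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ValueError("drop_prob must be in [0, 1]")
        if self.spurious_rate < 0 or self.contour_jitter < 0 or self.radius_bias < 0:
            raise ValueError("rates must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.drop_prob == 0.0
            and self.spurious_rate == 0.0
            and self.contour_jitter == 0.0
            and self.radius_bias == 0.0
        )


def detection_from_mask(
    mask: np.ndarray,
    capture_date: dt.date,
    radius_estimator: Literal["equivalent_circle", "bbox"] = "equivalent_circle",
    score: float = 1.0,
    source_instance: int | None = None,
) -> Detection:
    """Derive a detection from a binary mask.

    Contour and bbox come from the largest 4-connected component; the
    center is the mask centroid; the radius defaults to the
    equivalent-circle estimate sqrt(area / pi).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask, connectivity=1)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))

    ys, xs = np.nonzero(mask)
    bbox = (float(xs.min()), float(ys.min()), float(xs.max()) + 1, float(ys.max()) + 1)
    center = (float(xs.mean() + 0.5), float(ys.mean() + 0.5))
    area = float(mask.sum())
    if radius_estimator == "equivalent_circle":
        radius = math.sqrt(area / math.pi)
    elif radius_estimator == "bbox":
        radius = ((bbox[2] - bbox[0]) + (bbox[3] - bbox[1])) / 4.0
    else:
        raise ValueError(f"unknown radius estimator {radius_estimator!r}")
    return Detection(
        contour=mask_to_polygon(mask),
        bbox=bbox,
        center=center,
        radius=radius,
        capture_date=capture_date,
        score=score,
        source_instance=source_instance,
    )


def _spurious_blob(
    rng: np.random.Generator, canvas: tuple[int, int], capture_date: dt.date
) -> Detection:
    """A random elliptical false positive somewhere on the canvas."""
    w, h = canvas
    cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    rx, ry = rng.uniform(8, 40, size=2)
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    contour = [(cx + rx * np.cos(t), cy + ry * np.sin(t)) for t in theta]
    xs = [p[0] for p in contour]
    ys = [p[1] for p in contour]
    return Detection(
        contour=contour,
        bbox=(min(xs), min(ys), max(xs), max(ys)),
        center=(cx, cy),
        radius=math.sqrt(rx * ry),
        capture_date=capture_date,
        score=float(rng.uniform(0.3, 0.9)),
    )


def oracle_detect(
    sample: CompositeSample,
    spec: CorruptionSpec | None = None,
    capture_date: dt.date = dt.date(2016, 7, 1),
    mode: Literal["amodal", "modal"] = "amodal",
    frame_key: int = 0,
) -> list[Detection]:
    """Detections from ground truth, corrupted per ``spec``.

    ``frame_key`` decorrelates corruption across frames while keeping
    each frame deterministic for a fixed spec seed.
    """
    spec = spec or CorruptionSpec()
    rng = np.random.default_rng([spec.seed, frame_key])
    detections: list[Detection] = []
    for inst in sample.instances:
        if spec.drop_prob > 0 and rng.random() < spec.drop_prob:
            continue
        mask = inst.amodal_mask if mode == "amodal" else inst.visible_mask
        if not mask.any():
            continue
        det = detection_from_mask(
            mask, capture_date, source_instance=inst.instance_id
        )
        if spec.contour_jitter > 0:
            noisy = np.asarray(det.contour) + rng.normal(
                0.0, spec.contour_jitter, (len(det.contour), 2)
            )
            xs, ys = noisy[:, 0], noisy[:, 1]
            det.contour = [(float(x), float(y)) for x, y in noisy]
            det.bbox = (float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))
            det.center = (
                min(max(det.center[0], det.bbox[0]), det.bbox[2]),
                min(max(det.center[1], det.bbox[1]), det.bbox[3]),
            )
        if spec.radius_bias > 0:
            det.radius = max(det.radius * (1.0 + rng.normal(0.0, spec.radius_bias)), 1e-3)
        detections.append(det)
    if spec.spurious_rate > 0:
        cw, ch = sample.params_used.canvas_size
        for _ in range(rng.poisson(spec.spurious_rate)):
            detections.append(_spurious_blob(rng, (cw, ch), capture_date))
    return detections


def write_detections(detections: Iterable[Detection], path: str | Path) -> None:
    """Serialize detections as JSON Lines (one object per line)."""
    with open(path, "w") as fh:
        for det in detections:
            fh.write(json.dumps(det.to_json_obj()) + "\n")


def read_detections(path: str | Path) -> list[Detection]:
    with open(path) as fh:
        return [Detection.from_json_obj(json.loads(line)) for line in fh if line.strip()]
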