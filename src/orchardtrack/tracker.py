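"""Same-fruit identification across days with three relaxing gates.

A detection extends a track only if it passes all three filters against
the track's most recent observation:

* distance: center displacement strictly below ``40 + 2*T`` px,
* size: radius change within ``10 + 0.1*T`` percent (inclusive),
* contour: Hu-moment shape dissimilarity at most 0.05 (inclusive),

where ``T`` is the track's count of consecutive non-detect days. ``T``
resets to 0 on a match and otherwise grows by the calendar days elapsed
since the track was last evaluated, linearly relaxing the distance and
size gates.
"""

from __future__ import annotations

import datetime as dt
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .detection import Detection
from .shape import shape_dissimilarity

__all__ = [
    "TrackerConfig",
    "Track",
    "distance_gate",
    "size_gate",
    "contour_gate",
    "shape_dissimilarity",
    "match_frame",
    "track_sequence",
    "tracks_to_json_obj",
    "track_radius_series",
]


@dataclass
class TrackerConfig:
    distance_base: float = 40.0    # px
    distance_slope: float = 2.0    # px per non-detect day
    size_base: float = 10.0        # percent
    size_slope: float = 0.1        # percent per non-detect day
    contour_max: float = 0.05
    max_gap_days: int | None = None      # None: unlimited T growth
    spawn_new_tracks: bool = True
    assignment: Literal["greedy", "exhaustive"] = "greedy"

    def __post_init__(self) -> None:
        for name in ("distance_base", "distance_slope", "size_base", "size_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.contour_max <= 0:
            raise ValueError("contour_max must be positive")


@dataclass
class Track:
    track_id: int
    observations: list[tuple[dt.date, Detection]] = field(default_factory=list)
    T: int = 0
    state: str = "active"  # active | terminated
    last_evaluated: dt.date | None = None

    @property
    def last_observation(self) -> Detection:
        if not self.observations:
            raise ValueError("track has no observations")
        return self.observations[-1][1]

    @property
    def last_date(self) -> dt.date:
        if not self.observations:
            raise ValueError("track has no observations")
        return self.observations[-1][0]

    def append(self, date: dt.date, det: Detection) -> None:
        if self.observations and date <= self.last_date:
            raise ValueError("observation dates must be strictly increasing")
        self.observations.append((date, det))
        self.T = 0
        self.last_evaluated = date


def distance_gate(track: Track, det: Detection, cfg: TrackerConfig) -> bool:
    """Center displacement strictly below ``distance_base + slope*T``."""
    last = track.last_observation
    d = math.dist(last.center, det.center)
    return d < cfg.distance_base + cfg.distance_slope * track.T


def size_gate(track: Track, det: Detection, cfg: TrackerConfig) -> bool:
    """Radius variability within ``size_base + slope*T`` percent, inclusive."""
    r_last = track.last_observation.radius
    if r_last <= 0:
        raise ValueError("reference radius must be positive")
    variability = 100.0 * abs(det.radius - r_last) / r_last
    return variability <= cfg.size_base + cfg.size_slope * track.T


def contour_gate(track: Track, det: Detection, cfg: TrackerConfig) -> bool:
    """Shape dissimilarity at most ``contour_max``, inclusive."""
    d = shape_dissimilarity(track.last_observation.contour, det.contour)
    return d <= cfg.contour_max


def _candidate_pairs(
    tracks: Sequence[Track], detections: Sequence[Detection], cfg: TrackerConfig
) -> list[tuple[float, float, int, int]]:
    """(distance, dissimilarity, track_idx, det_idx) for pairs passing all gates."""
    pairs = []
    for ti, track in enumerate(tracks):
        if track.state != "active" or not track.observations:
            continue
        for di, det in enumerate(detections):
            if not distance_gate(track, det, cfg):
                continue
            if not size_gate(track, det, cfg):
                continue
            d_shape = shape_dissimilarity(track.last_observation.contour, det.contour)
            if d_shape > cfg.contour_max:
                continue
            d_center = math.dist(track.last_observation.center, det.center)
            pairs.append((d_center, d_shape, ti, di))
    return pairs


def _assign_greedy(pairs: list[tuple[float, float, int, int]]) -> dict[int, int]:
    """One-to-one assignment, ascending distance; ties by dissimilarity then id."""
    assignment: dict[int, int] = {}
    used_dets: set[int] = set()
    for _, _, ti, di in sorted(pairs):
        if ti in assignment or di in used_dets:
            continue
        assignment[ti] = di
        used_dets.add(di)
    return assignment


def _assign_exhaustive(pairs: list[tuple[float, float, int, int]]) -> dict[int, int]:
    """Max-cardinality, then min-total-distance, one-to-one assignment."""
    track_ids = sorted({ti for _, _, ti, _ in pairs})
    cost = {(ti, di): d for d, _, ti, di in pairs}
    best: dict[int, int] = {}
    best_key = (-1, math.inf)
    det_ids = sorted({di for _, _, _, di in pairs})
    for r in range(min(len(track_ids), len(det_ids)), 0, -1):
        for t_subset in itertools.combinations(track_ids, r):
            for d_perm in itertools.permutations(det_ids, r):
                if any((ti, di) not in cost for ti, di in zip(t_subset, d_perm)):
                    continue
                total = sum(cost[(ti, di)] for ti, di in zip(t_subset, d_perm))
                key = (r, total)
                if key[0] > best_key[0] or (key[0] == best_key[0] and total < best_key[1]):
                    best_key = key
                    best = dict(zip(t_subset, d_perm))
        if best:
            break
    return best


def match_frame(
    tracks: list[Track],
    detections: Sequence[Detection],
    date: dt.date,
    cfg: TrackerConfig,
    next_track_id: int | None = None,
) -> tuple[dict[int, int], list[Track]]:
    """Process one frame: gate, assign, update T, spawn, terminate.

    Returns ``(assignment, tracks)`` where assignment maps track index in
    ``tracks`` to detection index. ``tracks`` is updated in place (new
    tracks appended at the end).
    """
    for track in tracks:
        if track.observations and track.last_date >= date:
            raise ValueError(
                f"frame date {date} not after track {track.track_id} "
                f"last observation {track.last_date}"
            )
    pairs = _candidate_pairs(tracks, detections, cfg)
    if cfg.assignment == "exhaustive":
        assignment = _assign_exhaustive(pairs)
    else:
        assignment = _assign_greedy(pairs)

    assigned_dets = set(assignment.values())
    for ti, track in enumerate(tracks):
        if track.state != "active":
            continue
        if ti in assignment:
            track.append(date, detections[assignment[ti]])
        else:
            since = track.last_evaluated or track.last_date
            track.T += max((date - since).days, 1)
            track.last_evaluated = date
            if cfg.max_gap_days is not None and track.T > cfg.max_gap_days:
                track.state = "terminated"

    if cfg.spawn_new_tracks:
        tid = next_track_id if next_track_id is not None else (
            max((t.track_id for t in tracks), default=-1) + 1
        )
        for di, det in enumerate(detections):
            if di in assigned_dets:
                continue
            track = Track(track_id=tid)
            track.append(date, det)
            tracks.append(track)
            tid += 1
    return assignment, tracks


def track_sequence(
    frames: Iterable[tuple[dt.date, Sequence[Detection]]] | Iterable[Sequence[Detection]],
    cfg: TrackerConfig | None = None,
    initial_detections: Sequence[Detection] | None = None,
) -> list[Track]:
    """Fold :func:`match_frame` over date-ordered frames.

    Frames are ``(date, detections)`` pairs, or bare detection lists whose
    dates are taken from the detections themselves. ``initial_detections``
    seeds target-restricted tracking (spawning is then disabled).
    """
    cfg = cfg or TrackerConfig()
    tracks: list[Track] = []
    if initial_detections is not None:
        cfg = TrackerConfig(**{**cfg.__dict__, "spawn_new_tracks": False})
        for i, det in enumerate(initial_detections):
            track = Track(track_id=i)
            track.append(det.capture_date, det)
            tracks.append(track)

    seen_dates: set[dt.date] = set()
    last_date: dt.date | None = None
    for frame in frames:
        if isinstance(frame, tuple) and len(frame) == 2 and isinstance(frame[0], dt.date):
            date, dets = frame
        else:
            dets = list(frame)
            if not dets:
                continue
            dates = {d.capture_date for d in dets}
            if len(dates) > 1:
                raise ValueError("detections within a frame must share a capture date")
            date = dates.pop()
        if date in seen_dates:
            raise ValueError(f"duplicate frame date {date}")
        if last_date is not None and date < last_date:
            raise ValueError("frames must be in strictly increasing date order")
        seen_dates.add(date)
        last_date = date
        if tracks and tracks[0].observations and tracks[0].last_date == date:
            # initial seed frame duplicated in the stream: skip it
            continue
        match_frame(tracks, list(dets), date, cfg)
    return tracks


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def tracks_to_json_obj(tracks: Sequence[Track]) -> dict:
    return {
        str(t.track_id): {
            "state": t.state,
            "T": t.T,
            "observations": [
                {"date": date.isoformat(), **det.to_json_obj()}
                for date, det in t.observations
            ],
        }
        for t in tracks
    }


def track_radius_series(
    track: Track, reference_year: int | None = None
) -> pd.DataFrame:
    """Per-track radius series: columns date, elapsed_day, radius_px.

    ``elapsed_day`` counts calendar days since April 1 of the reference
    year (day 0 = April 1), the growth model's time axis.
    """
    if not track.observations:
        return pd.DataFrame(columns=["date", "elapsed_day", "radius_px"])
    year = reference_year or track.observations[0][0].year
    april1 = dt.date(year, 4, 1)
    rows = [
        {
            "date": date.isoformat(),
            "elapsed_day": (date - april1).days,
            "radius_px": det.radius,
        }
        for date, det in track.observations
    ]
    return pd.DataFrame(rows)


def write_tracks(tracks: Sequence[Track], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "tracks.json", "w") as fh:
        json.dump(tracks_to_json_obj(tracks), fh, sort_keys=True)
    for track in tracks:
        series = track_radius_series(track)
        series.to_csv(out_dir / f"track_{track.track_id:04d}_radius.csv", index=False)
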