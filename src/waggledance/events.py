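"""From behaviour-class probabilities to dance and dance-following events.

A per-frame classifier emits probabilities for the three behaviour classes
(other, dance, follow).  This module smooths and argmaxes those series
into labels, extracts dance events (dance-labeled runs merged over short
gaps and filtered by a minimum duration), finds the bees attending each
dance (within 14 mm of the dancer and facing her), splits them into
followers and mere attendees by their own behaviour label, and assigns
each dance to the feeder its dancer visited in the preceding five minutes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DanceEvent",
    "FollowEvent",
    "smooth_and_label",
    "extract_dance_events",
    "detect_attendance",
    "classify_follow_events",
    "assign_dance_to_feeder",
    "detect_events",
]

CLASS_COLUMNS = ("p_other", "p_dance", "p_follow")
# argmax tie-break priority, lowest to highest
_PRIORITY = ("p_other", "p_follow", "p_dance")


@dataclass
class DanceEvent:
    bee_id: int
    start: float           # s
    end: float             # s
    feeder_id: int | None = None
    dance_id: int | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FollowEvent:
    follower_id: int
    dancer_id: int
    dance_id: int | None
    start: float
    end: float
    label: str             # "follower" | "attendee"
    initial_position: tuple[float, float] | None = None


def smooth_and_label(class_probs: pd.DataFrame,
                     kernel: int = 5) -> pd.DataFrame:
    """Median-filter class probabilities per bee and take the argmax.

    Each class column is median-filtered with a centred kernel (default 5;
    the window shrinks at series edges), then each frame is labeled with
    the argmax class.  Exact ties go to the higher-priority class
    (other < follow < dance).  Rows must lie on the probability simplex to
    within 1e-6.

    Returns a frame with ``bee_id``, ``frame``, ``label``.
    """
    sums = class_probs[list(CLASS_COLUMNS)].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("class probability rows must sum to 1 (within 1e-6)")
    pieces = []
    for bee, grp in class_probs.groupby("bee_id"):
        grp = grp.sort_values("frame")
        sm = np.column_stack([
            grp[c].rolling(kernel, center=True, min_periods=1).median().to_numpy()
            for c in _PRIORITY
        ])
        # argmax with ties resolved toward the last (highest-priority) column
        winner = sm.shape[1] - 1 - np.argmax(sm[:, ::-1], axis=1)
        label = np.array([c[2:] for c in _PRIORITY], dtype=object)[winner]
        pieces.append(pd.DataFrame(
            {"bee_id": bee, "frame": grp["frame"].to_numpy(int), "label": label}))
    if not pieces:
        return pd.DataFrame(columns=["bee_id", "frame", "label"])
    return pd.concat(pieces, ignore_index=True)


def _runs(frames: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as (first, last) pairs."""
    if frames.size == 0:
        return []
    brk = np.flatnonzero(np.diff(frames) > 1)
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [frames.size - 1]))
    return [(int(frames[a]), int(frames[b])) for a, b in zip(starts, ends)]


def _merge_runs(runs: list[tuple[int, int]], max_gap_frames: float,
                strict: bool = False) -> list[tuple[int, int]]:
    """Merge runs whose separating gap is <= (or < when strict) the limit."""
    merged = []
    for first, last in runs:
        if merged:
            gap = first - merged[-1][1] - 1
            ok = gap < max_gap_frames if strict else gap <= max_gap_frames
            if ok:
                merged[-1] = (merged[-1][0], last)
                continue
        merged.append((first, last))
    return merged


def extract_dance_events(
    labels: pd.DataFrame,
    frame_rate: float = 6.0,
    min_duration_s: float = 4.0,
    max_gap_s: float = 3.0,
) -> list[DanceEvent]:
    """Dance events: dance-labeled runs merged over gaps <= ``max_gap_s``
    and at least ``min_duration_s`` long after merging."""
    events = []
    for bee, grp in labels.groupby("bee_id"):
        frames = np.sort(grp.loc[grp["label"] == "dance", "frame"].to_numpy(int))
        runs = _merge_runs(_runs(frames), max_gap_s * frame_rate)
        for first, last in runs:
            start = first / frame_rate
            end = (last + 1) / frame_rate
            if end - start >= min_duration_s:
                events.append(DanceEvent(bee_id=int(bee), start=start, end=end))
    events.sort(key=lambda e: (e.start, e.bee_id))
    for i, e in enumerate(events):
        e.dance_id = i
    return events


def detect_attendance(
    dance_event: DanceEvent,
    detections: pd.DataFrame,
    frame_rate: float = 6.0,
    radius_mm: float = 14.0,
    min_duration_s: float = 1.0,
    merge_gap_s: float = 3.0,
) -> dict[int, list[tuple[float, float]]]:
    """Candidate attention intervals per neighbour bee for one dance event.

    For each frame of the event, bees within ``radius_mm`` of the dancer
    whose orientation unit vector has a nonnegative dot product with the
    unit vector toward the dancer are candidates.  Per bee, candidate
    frames are merged across gaps strictly shorter than ``merge_gap_s``
    and intervals shorter than ``min_duration_s`` are dropped.

    Returns bee id -> list of (start, end) in seconds.  If the dancer has
    no detections during the event, warns and returns {}.
    """
    f_lo = int(np.ceil(dance_event.start * frame_rate))
    f_hi = int(np.floor(dance_event.end * frame_rate))
    window = detections[(detections["frame"] >= f_lo) & (detections["frame"] <= f_hi)]
    dancer = window[window["bee_id"] == dance_event.bee_id]
    if len(dancer) == 0:
        warnings.warn(f"dancer {dance_event.bee_id} has no detections during "
                      f"her dance event [{dance_event.start}, {dance_event.end}]",
                      stacklevel=2)
        return {}
    others = window[window["bee_id"] != dance_event.bee_id]
    merged = others.merge(
        dancer[["frame", "x_mm", "y_mm"]], on="frame", suffixes=("", "_dancer"))
    dx = merged["x_mm_dancer"].to_numpy(float) - merged["x_mm"].to_numpy(float)
    dy = merged["y_mm_dancer"].to_numpy(float) - merged["y_mm"].to_numpy(float)
    dist = np.hypot(dx, dy)
    ori = merged["orientation_rad"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        facing = (np.cos(ori) * dx + np.sin(ori) * dy) / np.where(dist > 0, dist, 1.0)
    # tiny epsilon keeps the inclusive "nonnegative dot product" boundary
    # stable against rounding (e.g. an exactly orthogonal orientation)
    ok = (dist <= radius_mm) & (facing >= -1e-12)
    cand = merged[ok]
    out: dict[int, list[tuple[float, float]]] = {}
    for bee, grp in cand.groupby("bee_id"):
        frames = np.sort(grp["frame"].to_numpy(int))
        runs = _merge_runs(_runs(frames), merge_gap_s * frame_rate, strict=True)
        ivals = []
        for first, last in runs:
            start, end = first / frame_rate, (last + 1) / frame_rate
            if end - start >= min_duration_s:
                ivals.append((start, end))
        if ivals:
            out[int(bee)] = ivals
    return out


def classify_follow_events(
    dance_event: DanceEvent,
    candidates: dict[int, list[tuple[float, float]]],
    labels: pd.DataFrame,
    detections: pd.DataFrame,
    frame_rate: float = 6.0,
) -> list[FollowEvent]:
    """Split candidate attention intervals into followers and attendees.

    A candidate interval becomes a *follower* event when the bee's own
    behaviour label is "follow" for the majority of the interval's frames,
    otherwise an *attendee* event.  The initial position is the bee's
    detection at (or nearest after) the interval start.
    """
    events = []
    lab_by_bee = {b: g.set_index("frame")["label"] for b, g in labels.groupby("bee_id")}
    det_by_bee = {b: g.sort_values("frame") for b, g in detections.groupby("bee_id")}
    for bee, ivals in sorted(candidates.items()):
        lab = lab_by_bee.get(bee)
        for start, end in ivals:
            f_lo, f_hi = int(np.ceil(start * frame_rate)), int(np.floor(end * frame_rate))
            frames = np.arange(f_lo, max(f_hi, f_lo + 1))
            if lab is not None:
                sub = lab.reindex(frames).dropna()
                is_follower = len(sub) > 0 and (sub == "follow").mean() > 0.5
            else:
                is_follower = False
            init = None
            det = det_by_bee.get(bee)
            if det is not None:
                after = det[det["frame"] >= f_lo]
                if len(after):
                    r = after.iloc[0]
                    init = (float(r["x_mm"]), float(r["y_mm"]))
            events.append(FollowEvent(
                follower_id=int(bee), dancer_id=int(dance_event.bee_id),
                dance_id=dance_event.dance_id, start=start, end=end,
                label="follower" if is_follower else "attendee",
                initial_position=init))
    return events


def assign_dance_to_feeder(
    dance_event: DanceEvent,
    feeder_visits: pd.DataFrame,
    lookback_s: float = 300.0,
) -> int | None | str:
    """Feeder the dancer visited in the ``lookback_s`` before her dance.

    Returns the feeder id when exactly one distinct feeder was visited by
    the dancer in [start - lookback, start); None when none was; the string
    ``"dropped"`` when visits to two or more distinct feeders fall in the
    window (the dance is excluded from feeder-specific analyses).
    """
    v = feeder_visits[
        (feeder_visits["bee_id"] == dance_event.bee_id)
        & (feeder_visits["time"] >= dance_event.start - lookback_s)
        & (feeder_visits["time"] < dance_event.start)
    ]
    feeders = v["feeder_id"].unique()
    if len(feeders) == 0:
        return None
    if len(feeders) > 1:
        return "dropped"
    return int(feeders[0])


def detect_events(
    class_probs: pd.DataFrame,
    detections: pd.DataFrame,
    feeder_visits: pd.DataFrame | None = None,
    frame_rate: float = 6.0,
    min_dance_duration_s: float = 4.0,
    dance_max_gap_s: float = 3.0,
    attendance_radius_mm: float = 14.0,
    min_follow_duration_s: float = 1.0,
    follow_merge_gap_s: float = 3.0,
    feeder_lookback_s: float = 300.0,
) -> tuple[list[DanceEvent], list[FollowEvent]]:
    """Full postprocessing chain: labels -> dance events -> follow events.

    Dance events keep ``feeder_id`` None when no feeder visit is found and
    are dropped from feeder assignment (``feeder_id`` None) when the dancer
    was seen at both feeders in the lookback window.
    """
    labels = smooth_and_label(class_probs)
    dance_events = extract_dance_events(
        labels, frame_rate, min_dance_duration_s, dance_max_gap_s)
    follow_events: list[FollowEvent] = []
    for ev in dance_events:
        if feeder_visits is not None and len(feeder_visits):
            assignment = assign_dance_to_feeder(ev, feeder_visits, feeder_lookback_s)
            ev.feeder_id = assignment if isinstance(assignment, (int, np.integer)) else None
        cand = detect_attendance(
            ev, detections, frame_rate, attendance_radius_mm,
            min_follow_duration_s, follow_merge_gap_s)
        follow_events.extend(
            classify_follow_events(ev, cand, labels, detections, frame_rate))
    return dance_events, follow_events


def events_to_frame(dance_events: list[DanceEvent],
                    follow_events: list[FollowEvent]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Events as flat tables (one row per event) for CSV output."""
    de = pd.DataFrame([
        {"dance_id": e.dance_id, "bee_id": e.bee_id, "start": e.start,
         "end": e.end, "feeder_id": e.feeder_id}
        for e in dance_events
    ], columns=["dance_id", "bee_id", "start", "end", "feeder_id"])
    fe = pd.DataFrame([
        {"follower_id": e.follower_id, "dancer_id": e.dancer_id,
         "dance_id": e.dance_id, "start": e.start, "end": e.end,
         "label": e.label,
         "x_mm": e.initial_position[0] if e.initial_position else np.nan,
         "y_mm": e.initial_position[1] if e.initial_position else np.nan}
        for e in follow_events
    ], columns=["follower_id", "dancer_id", "dance_id", "start", "end",
                "label", "x_mm", "y_mm"])
    return de, fe
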