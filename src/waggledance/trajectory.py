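"""Trajectory preprocessing: tag-rotation correction, gap interpolation,
and ego-motion features.

Marker tags are not glued onto bees perfectly aligned with the body axis,
so decoded orientations carry a constant per-bee bias.  Because a briskly
walking bee moves forward along her body axis, the bias can be estimated
from the circular average difference between decoded orientation and
movement direction over many tracks, robustified by discarding
high-dispersion tracks and histogram outliers.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from ._angles import circular_mean, circular_std, wrap_angle

__all__ = [
    "tracks_from_detections",
    "estimate_orientation_offset",
    "estimate_all_offsets",
    "apply_orientation_correction",
    "interpolate_single_gaps",
    "compute_egomotion_features",
    "FeatureNormalizer",
    "fit_normalizer",
    "apply_normalizer",
]

FEATURE_NAMES = (
    "velocity",
    "cos_movement_direction",
    "sin_movement_direction",
    "delta_cos_orientation",
    "delta_sin_orientation",
    "mask",
)


def tracks_from_detections(detections: pd.DataFrame,
                           max_gap_frames: int = 1) -> dict[int, list[pd.DataFrame]]:
    """Split each bee's detections into contiguous tracks.

    A new track starts whenever more than ``max_gap_frames`` frames are
    missing between consecutive detections.  Returns bee id -> list of
    frame-ordered DataFrames.
    """
    out: dict[int, list[pd.DataFrame]] = {}
    for bee, grp in detections.groupby("bee_id"):
        grp = grp.sort_values("frame").reset_index(drop=True)
        gaps = np.diff(grp["frame"].to_numpy(int))
        breaks = np.flatnonzero(gaps > max_gap_frames) + 1
        bounds = [0, *breaks.tolist(), len(grp)]
        out[int(bee)] = [grp.iloc[a:b].reset_index(drop=True)
                         for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    return out


def estimate_orientation_offset(
    tracks: list[pd.DataFrame],
    min_confidence: float = 0.1,
    min_track_len: int = 6,
    hist_bin_deg: float = 10.0,
) -> float | None:
    """Estimate one bee's tag-orientation offset from her tracks.

    Per track with at least ``min_track_len`` sufficiently confident
    detections, movement directions between successive positions are
    computed and the circular mean of (decoded orientation - movement
    direction) taken.  Tracks in the upper half of circular dispersion are
    discarded; the surviving per-track means are histogrammed in
    ``hist_bin_deg`` bins and only values in the modal bin kept; the
    estimate is their median.  Returns None when no track qualifies.
    """
    per_track_mean, per_track_std = [], []
    for track in tracks:
        t = track[track["confidence"] >= min_confidence]
        if len(t) < min_track_len:
            continue
        x = t["x_mm"].to_numpy(float)
        y = t["y_mm"].to_numpy(float)
        ori = t["orientation_rad"].to_numpy(float)
        dx, dy = np.diff(x), np.diff(y)
        moved = np.hypot(dx, dy) > 0
        if moved.sum() == 0:
            continue
        move_dir = np.arctan2(dy[moved], dx[moved])
        diffs = wrap_angle(ori[:-1][moved] - move_dir)
        per_track_mean.append(circular_mean(diffs))
        per_track_std.append(circular_std(diffs))
    if not per_track_mean:
        return None
    means = np.array(per_track_mean)
    stds = np.array(per_track_std)
    keep = stds <= np.median(stds)  # lower-dispersion half, ties kept
    means = means[keep]
    # modal 10-degree bin; ties broken toward the bin centred nearest 0
    nbins = int(round(360.0 / hist_bin_deg))
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    counts, _ = np.histogram(means, bins=edges)
    top = np.flatnonzero(counts == counts.max())
    centers = (edges[top] + edges[top + 1]) / 2
    b = top[np.argmin(np.abs(centers))]
    in_mode = (means >= edges[b]) & (means < edges[b + 1])
    kept = means[in_mode]
    if kept.size == 0:  # can only happen through edge effects at +pi
        kept = means
    ref = (edges[b] + edges[b + 1]) / 2
    return float(wrap_angle(ref + np.median(wrap_angle(kept - ref))))


def estimate_all_offsets(detections: pd.DataFrame, **kwargs) -> dict[int, float]:
    """Per-bee orientation offsets for every bee with a usable estimate."""
    out = {}
    for bee, tracks in tracks_from_detections(detections).items():
        est = estimate_orientation_offset(tracks, **kwargs)
        if est is not None:
            out[bee] = est
    return out


def apply_orientation_correction(detections: pd.DataFrame,
                                 offsets: dict[int, float]) -> pd.DataFrame:
    """Subtract each bee's estimated tag offset from her orientations.

    Bees without an entry in ``offsets`` pass through unchanged.
    """
    out = detections.copy()
    shift = out["bee_id"].map(lambda b: offsets.get(b, 0.0)).to_numpy(float)
    out["orientation_rad"] = wrap_angle(out["orientation_rad"].to_numpy(float) - shift)
    return out


def interpolate_single_gaps(track: pd.DataFrame) -> pd.DataFrame:
    """Fill gaps of exactly one frame by interpolation.

    Positions are interpolated linearly and orientations along the
    shortest arc; filled rows get ``mask`` 0 (observed rows 1).  Gaps of
    two or more frames are left open.  Idempotent.
    """
    t = track.sort_values("frame").reset_index(drop=True)
    if "mask" not in t.columns:
        t["mask"] = 1
    frames = t["frame"].to_numpy(int)
    gaps = np.diff(frames)
    fill_at = np.flatnonzero(gaps == 2)
    if fill_at.size == 0:
        return t
    new_rows = []
    dt_per_frame = None
    if len(frames) > 1:
        times = t["time"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            dt_per_frame = np.median(np.diff(times) / gaps)
    for i in fill_at:
        a, b = t.iloc[i], t.iloc[i + 1]
        row = a.copy()
        row["frame"] = frames[i] + 1
        if dt_per_frame is not None:
            row["time"] = a["time"] + dt_per_frame
        row["x_mm"] = (a["x_mm"] + b["x_mm"]) / 2
        row["y_mm"] = (a["y_mm"] + b["y_mm"]) / 2
        row["orientation_rad"] = wrap_angle(
            a["orientation_rad"]
            + 0.5 * wrap_angle(b["orientation_rad"] - a["orientation_rad"]))
        row["mask"] = 0
        if "confidence" in t.columns:
            row["confidence"] = 0.0
        new_rows.append(row)
    out = pd.concat([t, pd.DataFrame(new_rows)], ignore_index=True)
    return out.sort_values("frame").reset_index(drop=True)


def compute_egomotion_features(
    track: pd.DataFrame,
    window_length: int,
    frame_rate: float = 6.0,
    start_frame: int | None = None,
    max_missing_frac: float = 0.5,
) -> np.ndarray | None:
    """Ego-motion features for one fixed-length window of a track.

    The window covers ``window_length`` consecutive nominal frames starting
    at ``start_frame`` (default: the track's first frame).  Frames missing
    from the track are zero-filled with mask 0; if more than
    ``max_missing_frac`` of the window is missing the sample is dropped
    (returns None).  A window extending beyond the track's frame span
    raises ``ValueError``.

    Features per frame (columns, see ``FEATURE_NAMES``): speed in mm/s
    median-filtered with kernel 3; cosine and sine of the movement
    direction relative to the body orientation; frame-to-frame change of
    the orientation's cosine and sine; and the observed/interpolated mask.
    """
    t = track.sort_values("frame").reset_index(drop=True)
    frames = t["frame"].to_numpy(int)
    if start_frame is None:
        start_frame = int(frames[0])
    stop = start_frame + window_length
    if start_frame < frames[0] or stop - 1 > frames[-1]:
        raise ValueError("feature window extends beyond the track")
    grid = np.arange(start_frame, stop)
    present = np.isin(grid, frames)
    if (1.0 - present.mean()) > max_missing_frac:
        return None
    sel = t.set_index("frame").reindex(grid)
    mask = sel["mask"].fillna(0).to_numpy(float) if "mask" in sel.columns \
        else present.astype(float)
    mask = np.where(present, mask, 0.0)
    x = sel["x_mm"].to_numpy(float)
    y = sel["y_mm"].to_numpy(float)
    ori = sel["orientation_rad"].to_numpy(float)
    # carry last observation over unobserved frames so diffs stay finite
    for arr in (x, y, ori):
        idx = np.where(np.isfinite(arr), np.arange(len(arr)), 0)
        np.maximum.accumulate(idx, out=idx)
        arr[:] = arr[idx]
        if not np.isfinite(arr[0]):
            arr[:] = np.nan_to_num(arr, nan=0.0)
    dx = np.diff(x, prepend=x[0])
    dy = np.diff(y, prepend=y[0])
    speed = np.hypot(dx, dy) * frame_rate
    speed = medfilt(speed, kernel_size=3)
    move_dir = np.arctan2(dy, dx)
    rel = wrap_angle(move_dir - ori)
    still = np.hypot(dx, dy) == 0
    cos_rel = np.where(still, 1.0, np.cos(rel))  # a still bee "moves" forward
    sin_rel = np.where(still, 0.0, np.sin(rel))
    dcos = np.diff(np.cos(ori), prepend=np.cos(ori[0]))
    dsin = np.diff(np.sin(ori), prepend=np.sin(ori[0]))
    return np.column_stack((speed, cos_rel, sin_rel, dcos, dsin, mask))


@dataclass
class FeatureNormalizer:
    """Percentile-clip + z-transform parameters fitted on training windows."""

    p5: np.ndarray
    p95: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k).tolist()
                           for k in ("p5", "p95", "mean", "std")})

    @classmethod
    def from_json(cls, text: str) -> "FeatureNormalizer":
        d = json.loads(text)
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


def fit_normalizer(windows: list[np.ndarray]) -> FeatureNormalizer:
    """Fit clip bounds (5th/95th percentiles) and z-transform parameters.

    Percentiles use linear interpolation between order statistics.  The
    mean and std are those of the clipped training values; a constant
    feature's std is floored at 1e-8 with a warning.
    """
    stacked = np.concatenate([np.asarray(w, float) for w in windows], axis=0)
    p5 = np.percentile(stacked, 5, axis=0)
    p95 = np.percentile(stacked, 95, axis=0)
    clipped = np.clip(stacked, p5, p95)
    mean = clipped.mean(axis=0)
    std = clipped.std(axis=0)
    if np.any(std < 1e-8):
        warnings.warn("constant feature(s) during normalizer fit; "
                      "std floored at 1e-8", stacklevel=2)
        std = np.maximum(std, 1e-8)
    return FeatureNormalizer(p5, p95, mean, std)


def apply_normalizer(normalizer: FeatureNormalizer,
                     windows: list[np.ndarray]) -> list[np.ndarray]:
    """Clip to the fitted [p5, p95] and z-transform with fitted moments."""
    return [
        (np.clip(np.asarray(w, float), normalizer.p5, normalizer.p95)
         - normalizer.mean) / normalizer.std
        for w in windows
    ]
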