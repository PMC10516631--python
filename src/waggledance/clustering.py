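"""Clustering waggle-phase detections into dances.

Waggle-phase detections arrive without identity; detections that are close
in both space and time are chained into one dance (single linkage), short
chains are discarded, and the dance's waggle angle is agreed on by a
consensus search that tolerates outlier detections: every phase's angle is
tried as a hypothesis, phases within an angular tolerance are its inliers,
and the hypothesis with the most inliers wins if it captures at least 60%
of the group.  Because groups are small, the hypothesis set is enumerated
exhaustively, making the result deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._angles import circular_distance, circular_mean, circular_std

__all__ = ["Dance", "cluster_waggle_phases", "ransac_angle_consensus", "detect_dances"]


@dataclass
class Dance:
    """A clustered dance: its phases, consensus angle, and inlier structure."""

    phases: pd.DataFrame          # the full group, frame-ordered
    consensus_angle: float        # rad, circular mean of the inliers
    inliers: np.ndarray           # boolean flag per phase
    median_position: tuple[float, float]
    dancer_id: int | None = None

    @property
    def inlier_phases(self) -> pd.DataFrame:
        return self.phases[self.inliers]


def cluster_waggle_phases(
    phases: pd.DataFrame,
    max_distance_mm: float = 30.0,
    max_gap_s: float = 5.0,
    min_size: int = 3,
) -> list[pd.DataFrame]:
    """Chain waggle-phase detections into dance groups (single linkage).

    Two phases belong to the same group when they are connected by a chain
    of pairs each at most ``max_distance_mm`` apart in start position AND
    ``max_gap_s`` apart in start time.  Groups smaller than ``min_size``
    are discarded.
    """
    n = len(phases)
    if n == 0:
        return []
    p = phases.sort_values("start_time").reset_index(drop=True)
    t = p["start_time"].to_numpy(float)
    xy = p[["x_mm", "y_mm"]].to_numpy(float)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        j = i + 1
        while j < n and t[j] - t[i] <= max_gap_s:
            if np.hypot(*(xy[j] - xy[i])) <= max_distance_mm:
                parent[find(i)] = find(j)
            j += 1
    roots = np.array([find(i) for i in range(n)])
    groups = []
    for r in np.unique(roots):
        grp = p[roots == r]
        if len(grp) >= min_size:
            groups.append(grp.reset_index(drop=True))
    groups.sort(key=lambda g: float(g["start_time"].iloc[0]))
    return groups


def ransac_angle_consensus(
    group: pd.DataFrame,
    inlier_tolerance_rad: float = 0.52,
    min_inlier_frac: float = 0.6,
    direction_col: str = "direction_rad",
) -> Dance | None:
    """Deterministic consensus on a group's waggle angle.

    Each phase's own angle serves as a candidate hypothesis; a phase is an
    inlier of a hypothesis when its circular distance to it is at most
    ``inlier_tolerance_rad``.  The hypothesis with the most inliers wins
    (ties: the smaller circular spread among inliers, then the earlier
    phase).  If the best hypothesis's inlier fraction reaches
    ``min_inlier_frac`` a :class:`Dance` is returned whose consensus angle
    is the circular mean of the inliers; otherwise the group is discarded
    (returns None).
    """
    angles = group[direction_col].to_numpy(float)
    n = len(angles)
    if n == 0:
        return None
    pair_dist = circular_distance(angles[:, None], angles[None, :])
    inlier_matrix = pair_dist <= inlier_tolerance_rad   # row i: hypothesis i
    counts = inlier_matrix.sum(axis=1)
    best_count = int(counts.max())
    candidates = np.flatnonzero(counts == best_count)
    if len(candidates) > 1:  # tie-break: smaller circular spread of inliers
        spreads = [circular_std(angles[inlier_matrix[i]]) for i in candidates]
        candidates = candidates[[int(np.argmin(spreads))]]
    inliers = inlier_matrix[candidates[0]]
    if best_count / n < min_inlier_frac:
        return None
    consensus = circular_mean(angles[inliers])
    med = group[["x_mm", "y_mm"]].median()
    return Dance(
        phases=group.reset_index(drop=True),
        consensus_angle=consensus,
        inliers=np.asarray(inliers),
        median_position=(float(med["x_mm"]), float(med["y_mm"])),
    )


def detect_dances(
    phases: pd.DataFrame,
    max_distance_mm: float = 30.0,
    max_gap_s: float = 5.0,
    min_size: int = 3,
    inlier_tolerance_rad: float = 0.52,
    min_inlier_frac: float = 0.6,
) -> list[Dance]:
    """Cluster phases and keep groups with an angle consensus."""
    dances = []
    for grp in cluster_waggle_phases(phases, max_distance_mm, max_gap_s, min_size):
        d = ransac_angle_consensus(grp, inlier_tolerance_rad, min_inlier_frac)
        if d is not None:
            dances.append(d)
    return dances
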