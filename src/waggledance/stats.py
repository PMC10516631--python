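"""Dance-floor statistics.

Descriptive spatial and circular statistics for waggle-phase and
dance-following data: the alignment between a phase's offset from the
dance-floor centre and its waggle direction (with a one-sided sign test),
binned mean-orientation fields, the comb fraction covered by the dance
floor, Mood's median test, intra-/inter-group distance time courses,
follower target maps, and the choice-situation distance analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "dance_floor_center",
    "offset_alignment_scores",
    "sign_test_one_sided",
    "OrientationField",
    "binned_orientation_field",
    "median_location_by_direction",
    "dance_floor_area_fraction",
    "filter_days_by_median_count",
    "moods_median_test",
    "group_distance_timeseries",
    "follower_target_map",
    "choice_situation_analysis",
    "alignment_report",
]


def dance_floor_center(positions: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Component-wise median of phase positions — the dance-floor centre.

    ``positions`` is an (n, 2) array or a frame with ``x_mm``/``y_mm``.
    """
    if isinstance(positions, pd.DataFrame):
        positions = positions[["x_mm", "y_mm"]].to_numpy(float)
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("dance_floor_center requires at least one position")
    med = np.median(positions, axis=0)
    return (float(med[0]), float(med[1]))


class AlignmentScores(NamedTuple):
    scores: np.ndarray      # dot products in [-1, 1], one per off-centre phase
    n_at_center: int        # phases exactly at the centre (undefined direction)


def offset_alignment_scores(
    phases: pd.DataFrame,
    center: tuple[float, float],
    direction_col: str = "alpha_rad",
) -> AlignmentScores:
    """Dot product of the unit offset-from-centre vector with the waggle direction.

    A score of 1 means the phase lies exactly in the direction it points,
    -1 exactly opposite.  Phases coinciding with the centre have no defined
    offset direction; they are excluded from the scores and counted in
    ``n_at_center``.
    """
    off = phases[["x_mm", "y_mm"]].to_numpy(float) - np.asarray(center, float)
    norm = np.linalg.norm(off, axis=1)
    at_center = norm == 0.0
    off = off[~at_center] / norm[~at_center, None]
    a = phases[direction_col].to_numpy(float)[~at_center]
    scores = off[:, 0] * np.cos(a) + off[:, 1] * np.sin(a)
    return AlignmentScores(scores, int(at_center.sum()))


def sign_test_one_sided(scores: np.ndarray) -> tuple[int, int, float]:
    """One-sided sign test that the median of ``scores`` exceeds zero.

    Zeros are excluded; the p-value is the exact upper-tail binomial
    probability of observing at least the seen number of positives among
    the non-zero values under p=1/2.

    Returns (n_positive, n_nonzero, p_value).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    nonzero = scores[scores != 0.0]
    n = nonzero.size
    if n == 0:
        raise ValueError("sign test undefined with no non-zero scores")
    n_pos = int((nonzero > 0).sum())
    p = float(sps.binom.sf(n_pos - 1, n, 0.5))
    return n_pos, n, p


@dataclass
class OrientationField:
    """Mean waggle orientation on a regular spatial grid.

    ``counts[i, j]`` is the number of phases in column i, row j (10 mm bins
    by default); ``mean_vector`` holds the mean of the phases' unit
    direction vectors per bin, whose norm ``mean_length`` is 1 for a bin of
    identical directions and shrinks toward 0 for an even mix.
    """

    bin_mm: float
    counts: np.ndarray          # (nx, ny)
    mean_vector: np.ndarray     # (nx, ny, 2); zero where count == 0
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def mean_length(self) -> np.ndarray:
        return np.linalg.norm(self.mean_vector, axis=-1)

    @property
    def mean_direction(self) -> np.ndarray:
        return np.arctan2(self.mean_vector[..., 1], self.mean_vector[..., 0])


def binned_orientation_field(
    phases: pd.DataFrame,
    comb_bounds: tuple[float, float] = (400.0, 240.0),
    bin_mm: float = 10.0,
    direction_col: str = "alpha_rad",
) -> OrientationField:
    """Mean of the unit waggle-direction vectors on a ``bin_mm`` grid."""
    width, height = comb_bounds
    x_edges = np.arange(0.0, width + bin_mm, bin_mm)
    y_edges = np.arange(0.0, height + bin_mm, bin_mm)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    x = phases["x_mm"].to_numpy(float)
    y = phases["y_mm"].to_numpy(float)
    a = phases[direction_col].to_numpy(float)
    ix = np.clip(np.floor(x / bin_mm).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(y / bin_mm).astype(int), 0, ny - 1)
    counts = np.zeros((nx, ny))
    vec = np.zeros((nx, ny, 2))
    np.add.at(counts, (ix, iy), 1.0)
    np.add.at(vec, (ix, iy), np.column_stack((np.cos(a), np.sin(a))))
    occupied = counts > 0
    vec[occupied] /= counts[occupied, None]
    return OrientationField(bin_mm, counts, vec, x_edges, y_edges)


def median_location_by_direction(
    phases: pd.DataFrame,
    step_deg: float = 5.0,
    direction_col: str = "alpha_rad",
) -> pd.DataFrame:
    """Component-wise median phase location per waggle-direction bin.

    Directions are binned on [0, 360) degrees in half-open ``step_deg``
    bins; empty bins are omitted.  Returns columns ``bin`` (index),
    ``direction_rad`` (bin centre), ``x_mm``, ``y_mm``, ``n``.
    """
    a_deg = np.degrees(np.mod(phases[direction_col].to_numpy(float), 2.0 * np.pi))
    n_bins = int(round(360.0 / step_deg))
    idx = np.clip((a_deg // step_deg).astype(int), 0, n_bins - 1)
    df = phases.assign(_bin=idx)
    rows = []
    for b, grp in df.groupby("_bin"):
        rows.append(
            {
                "bin": int(b),
                "direction_rad": np.radians((b + 0.5) * step_deg),
                "x_mm": float(grp["x_mm"].median()),
                "y_mm": float(grp["y_mm"].median()),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


def dance_floor_area_fraction(
    positions: np.ndarray | pd.DataFrame,
    comb_bounds: tuple[float, float] = (400.0, 240.0),
    cell_mm: float = 10.0,
    coverage: float = 0.95,
) -> float:
    """Fraction of the comb needed to cover a share of all waggle phases.

    The comb is divided into square cells (1 cm^2 by default); the cells
    are ranked by phase count and the smallest prefix whose cumulative
    count reaches ``coverage`` of the total is taken.  The returned value
    is that prefix size over the total number of cells.
    """
    if isinstance(positions, pd.DataFrame):
        positions = positions[["x_mm", "y_mm"]].to_numpy(float)
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("area fraction undefined for empty input")
    width, height = comb_bounds
    nx = int(np.ceil(width / cell_mm))
    ny = int(np.ceil(height / cell_mm))
    counts, _, _ = np.histogram2d(
        positions[:, 0], positions[:, 1],
        bins=[nx, ny], range=[[0, nx * cell_mm], [0, ny * cell_mm]],
    )
    return minimal_covering_fraction(counts, coverage)


def minimal_covering_fraction(counts: np.ndarray, coverage: float) -> float:
    """Greedy minimal prefix of descending cell counts reaching ``coverage``."""
    flat = np.sort(np.asarray(counts, dtype=float).ravel())[::-1]
    total = flat.sum()
    if total == 0:
        raise ValueError("no observations in any cell")
    needed = coverage * total
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, needed - 1e-12) + 1)
    return k / flat.size


def filter_days_by_median_count(counts: Mapping[object, int]) -> list:
    """Days with strictly more detections than the median daily count.

    Used to drop low-activity days on which no proper dance floor emerges.
    """
    if not counts:
        raise ValueError("at least one day required")
    values = np.array(list(counts.values()), dtype=float)
    med = float(np.median(values))
    return [day for day, c in counts.items() if c > med]


def moods_median_test(a, b) -> tuple[float, float, int]:
    """Mood's median test for a difference in medians between two samples.

    Values are dichotomised at the pooled median (above vs not-above, ties
    counted below) and the resulting 2x2 table is tested with a Pearson
    chi-square on 1 df without continuity correction.

    Returns (chi2, p_value, n_total).  Degenerate tables (a zero marginal,
    e.g. all values identical) give chi2 = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled_med = float(np.median(np.concatenate([a, b])))
    table = np.array(
        [
            [(a > pooled_med).sum(), (a <= pooled_med).sum()],
            [(b > pooled_med).sum(), (b <= pooled_med).sum()],
        ],
        dtype=float,
    )
    n = int(table.sum())
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0, 1.0, n
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p, n


def group_distance_timeseries(
    samples: pd.DataFrame,
    bin_width_s: float = 5.0,
    time_col: str = "rel_time",
    group_col: str = "group",
    event_col: str = "event_id",
) -> pd.DataFrame:
    """Mean intra- and inter-group distances over event-aligned time.

    ``samples`` is tidy: one row per (event, relative time) with columns
    ``event_id``, ``group``, ``rel_time`` (seconds relative to the event
    alignment point, e.g. dance start), ``x_mm``, ``y_mm``.  Relative times
    are binned to ``bin_width_s``; within each bin all pairwise distances
    between distinct events' positions are split into intra (same group)
    and inter (different group).  Bins with fewer than two events are
    omitted.

    Returns one row per time bin with means and 95% normal-approximation
    confidence half-widths (1.96 * SEM) for both distance sets.
    """
    df = samples.copy()
    df["_bin"] = np.floor(df[time_col].to_numpy(float) / bin_width_s).astype(int)
    rows = []
    for b, grp in df.groupby("_bin"):
        # one position per event per bin (mean over the bin)
        per_event = grp.groupby(event_col).agg(
            x=("x_mm", "mean"), y=("y_mm", "mean"), g=(group_col, "first")
        )
        if len(per_event) < 2:
            continue
        pos = per_event[["x", "y"]].to_numpy(float)
        lab = per_event["g"].to_numpy()
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(len(pos), k=1)
        d = dist[iu]
        same = (lab[:, None] == lab[None, :])[iu]
        row = {"rel_time": (b + 0.5) * bin_width_s, "n_events": len(per_event)}
        for name, sel in (("intra", same), ("inter", ~same)):
            vals = d[sel]
            if vals.size:
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_ci95"] = float(
                    1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
                ) if vals.size > 1 else np.nan
            else:
                row[f"{name}_mean"] = np.nan
                row[f"{name}_ci95"] = np.nan
        rows.append(row)
    columns = ["rel_time", "n_events", "intra_mean", "intra_ci95",
               "inter_mean", "inter_ci95"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).sort_values("rel_time").reset_index(drop=True)


def follower_target_map(
    events: pd.DataFrame,
    comb_bounds: tuple[float, float] = (400.0, 240.0),
    bin_mm: float = 10.0,
    density_mask: float = 0.90,
) -> pd.DataFrame:
    """Most-frequent dance target per spatial bin of follower start positions.

    ``events`` needs ``x_mm``, ``y_mm`` (the follower's initial position)
    and ``feeder_id`` (the followed dance's target).  Returns one row per
    occupied bin: bin indices, count, modal ``feeder_id``, and ``in_mask``
    marking the minimal set of highest-count bins that jointly hold at
    least ``density_mask`` of all events.
    """
    width, height = comb_bounds
    nx, ny = int(np.ceil(width / bin_mm)), int(np.ceil(height / bin_mm))
    ix = np.clip((events["x_mm"].to_numpy(float) // bin_mm).astype(int), 0, nx - 1)
    iy = np.clip((events["y_mm"].to_numpy(float) // bin_mm).astype(int), 0, ny - 1)
    df = events.assign(_ix=ix, _iy=iy)
    rows = []
    for (bx, by), grp in df.groupby(["_ix", "_iy"]):
        mode = grp["feeder_id"].mode()
        rows.append(
            {
                "ix": int(bx),
                "iy": int(by),
                "count": len(grp),
                "feeder_id": mode.iloc[0],
            }
        )
    out = pd.DataFrame(rows).sort_values("count", ascending=False).reset_index(drop=True)
    total = out["count"].sum()
    cum = out["count"].cumsum()
    k = int(np.searchsorted(cum.to_numpy(), density_mask * total - 1e-12) + 1)
    out["in_mask"] = np.arange(len(out)) < k
    return out


def choice_situation_analysis(
    follow_events: pd.DataFrame,
    dance_events: pd.DataFrame,
    detections: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Distances from a follower to the candidate dances she chose between.

    For every consecutive pair of follow events by one bee, the moment the
    second ("next") follow starts is treated as a decision point.  The
    candidate set is every dance event running at that instant whose dancer
    is neither the follower nor the initial dance's dancer.  A choice
    situation is recorded when the candidates span both feeders with at
    least two distinct dancers and the dance actually followed next is
    among them.  The distance to each candidate is measured from the
    follower's position to the candidate dancer's position at the decision
    time (nearest detection in time).

    Parameters
    ----------
    follow_events : frame with ``follower_id``, ``dancer_id``, ``start``,
        ``end``, and ``dance_id`` referencing ``dance_events``.
    dance_events : frame with ``dance_id``, ``bee_id``, ``start``, ``end``,
        ``feeder_id`` (rows without a feeder are ignored).
    detections : frame with ``bee_id``, ``time``, ``x_mm``, ``y_mm``.

    Returns
    -------
    (records, summary): one record row per (situation, candidate dance),
    and a summary dict with mean/std distances for followed vs not-followed
    and same-feeder vs other-feeder candidates.
    """
    dances = dance_events.dropna(subset=["feeder_id"]).copy()
    det_by_bee = {bee: grp.sort_values("time") for bee, grp in detections.groupby("bee_id")}

    def position_at(bee, t):
        grp = det_by_bee.get(bee)
        if grp is None or len(grp) == 0:
            return None
        i = int(np.argmin(np.abs(grp["time"].to_numpy(float) - t)))
        r = grp.iloc[i]
        return float(r["x_mm"]), float(r["y_mm"])

    records = []
    situation = 0
    for follower, fe in follow_events.sort_values("start").groupby("follower_id"):
        fe = fe.reset_index(drop=True)
        for i in range(len(fe) - 1):
            initial, nxt = fe.iloc[i], fe.iloc[i + 1]
            t = float(nxt["start"])
            cand = dances[
                (dances["start"] <= t)
                & (dances["end"] >= t)
                & (dances["bee_id"] != follower)
                & (dances["bee_id"] != initial["dancer_id"])
            ]
            if cand["bee_id"].nunique() < 2 or cand["feeder_id"].nunique() < 2:
                continue
            if nxt["dance_id"] not in set(cand["dance_id"]):
                continue
            fpos = position_at(follower, t)
            if fpos is None:
                continue
            initial_feeder = dances.set_index("dance_id")["feeder_id"].get(
                initial["dance_id"], None
            )
            for _, c in cand.iterrows():
                dpos = position_at(c["bee_id"], t)
                if dpos is None:
                    continue
                records.append(
                    {
                        "situation": situation,
                        "follower_id": follower,
                        "decision_time": t,
                        "dance_id": c["dance_id"],
                        "dancer_id": c["bee_id"],
                        "feeder_id": c["feeder_id"],
                        "distance_mm": float(np.hypot(fpos[0] - dpos[0], fpos[1] - dpos[1])),
                        "followed": bool(c["dance_id"] == nxt["dance_id"]),
                        "same_feeder_as_initial": (
                            bool(c["feeder_id"] == initial_feeder)
                            if initial_feeder is not None else None
                        ),
                    }
                )
            situation += 1
    rec = pd.DataFrame(records)
    summary = {}
    if len(rec):
        for key, sel in (
            ("followed", rec["followed"]),
            ("not_followed", ~rec["followed"]),
            ("same_feeder", rec["same_feeder_as_initial"] == True),  # noqa: E712
            ("other_feeder", rec["same_feeder_as_initial"] == False),  # noqa: E712
        ):
            vals = rec.loc[sel, "distance_mm"]
            summary[key] = {
                "mean_mm": float(vals.mean()) if len(vals) else np.nan,
                "std_mm": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            }
    return rec, summary


def alignment_report(phases: pd.DataFrame) -> dict:
    """Centre, alignment scores, and sign test for a set of waggle phases."""
    center = dance_floor_center(phases)
    scores, n_at_center = offset_alignment_scores(phases, center)
    n_pos, n_nonzero, p = sign_test_one_sided(scores)
    return {
        "center_mm": list(center),
        "n_phases": int(len(phases)),
        "n_at_center": n_at_center,
        "median_alignment": float(np.median(scores)),
        "n_positive": n_pos,
        "n_nonzero": n_nonzero,
        "sign_test_p": p,
    }
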