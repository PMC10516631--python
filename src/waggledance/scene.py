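"""Synthetic hive scenes with known ground truth.

Generates the four tables the analysis pipeline consumes — per-frame tag
detections, waggle-phase detections, per-frame behaviour-class
probabilities, and feeder visits — for a scene populated by dancing bees,
dance followers, and idle bees, together with the ground truth needed for
recovery tests.

The emulated structure:

* Dancers alternate waggle and return phases.  Successive waggle-phase
  start points drift by a forward offset ~ N(mu_forward, sigma_forward)
  along the waggle direction plus a sideways offset ~ N(0, sigma_sideways)
  orthogonal to it, the same process as :mod:`waggledance.drift`.  Dances
  advertising a feeder share that feeder's waggle direction (up or down on
  the comb for the two-feeder default, mirroring a feeder toward vs away
  from the sun) and start near a feeder-specific dance-floor anchor.
* Followers attach to a dancer during planted follow intervals: they sit
  within 14 mm of her, facing her; some are instead planted as attendees
  (near and facing, but never emitting the "follow" behaviour class).
* Idle bees and off-duty followers perform a bounded correlated random
  walk.
* Each bee's tag is glued on with a per-bee angular misalignment; the
  detection table reports tag orientations (body orientation + offset).
* Detections drop out independently per frame and positions carry
  Gaussian noise; every dance is preceded by a feeder visit within the
  five minutes before its start.

All randomness derives from ``SceneConfig.seed``; identical configs give
identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._angles import wrap_angle
from .drift import MotionModelParams

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "Scene",
    "generate_scene",
    "plant_tag_offsets",
    "emit_class_probabilities",
]

LABELS = ("other", "dance", "follow")

# dancer kinematics (per waggle cycle)
WAGGLE_DURATION_S = 1.5
RETURN_DURATION_S = 2.5
WAGGLE_RUN_MM = 9.0


@dataclass
class SceneConfig:
    """Configuration of one synthetic hive scene."""

    n_dancers: int = 5
    n_followers: int = 10
    n_idle: int = 20
    n_feeders: int = 2
    frame_rate: float = 6.0                  # Hz
    duration: float = 600.0                  # s
    comb_width: float = 400.0                # mm
    comb_height: float = 240.0               # mm
    tag_offset_spread: float = 0.2           # rad, std of per-bee tag misalignment
    detection_dropout: float = 0.0           # per-frame missing probability
    position_noise: float = 0.0              # mm, std
    class_prob_noise: float = 0.0            # std on the probability simplex
    seed: int = 0
    dances_per_dancer: int = 2
    waggle_phases_per_dance: int = 8
    follows_per_follower: int = 1
    attendee_fraction: float = 0.25          # planted attendees among follower bees
    overlapping_dances: bool = False         # allow dances to run concurrently
    dance_floor_anchor: tuple[float, float] = (80.0, 160.0)   # mm
    anchor_spread: float = 15.0              # mm, std of dance start around anchor
    feeder_anchor_offset_mm: float = 12.0    # per-feeder displacement of the anchor
    drift: MotionModelParams = field(default_factory=MotionModelParams)

    def __post_init__(self):
        if min(self.n_dancers, self.n_followers, self.n_idle, self.n_feeders) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.detection_dropout < 1.0):
            raise ValueError("detection_dropout must be in [0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def n_bees(self) -> int:
        return self.n_dancers + self.n_followers + self.n_idle

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def feeder_direction(self, feeder_id: int) -> float:
        """Waggle direction advertised for a feeder (radians).

        Feeders are spread evenly over the circle starting from straight
        up; with two feeders this gives upward vs downward dances.
        """
        return float(np.mod(np.pi / 2 + 2 * np.pi * feeder_id / max(self.n_feeders, 1),
                            2 * np.pi))


@dataclass
class GroundTruth:
    """What actually happened in a generated scene."""

    tag_offsets: dict[int, float]
    dance_events: pd.DataFrame    # dance_id, bee_id, start, end, feeder_id
    follow_events: pd.DataFrame   # follower_id, dancer_id, dance_id, start, end, label
    waggle_phases: pd.DataFrame   # dance_id, bee_id, phase, start_time, duration,
    #                               x_mm, y_mm, direction_rad
    frame_labels: pd.DataFrame    # bee_id, frame, label in {other, dance, follow}


class Scene(NamedTuple):
    detections: pd.DataFrame
    waggle_phases: pd.DataFrame
    class_probs: pd.DataFrame
    feeder_visits: pd.DataFrame
    ground_truth: GroundTruth


def _empty_scene(config: SceneConfig) -> Scene:
    det = pd.DataFrame(columns=["bee_id", "frame", "time", "x_mm", "y_mm",
                                "orientation_rad", "confidence", "comb_side"])
    wp = pd.DataFrame(columns=["start_time", "duration", "x_mm", "y_mm",
                               "direction_rad", "comb_side"])
    cp = pd.DataFrame(columns=["bee_id", "frame", "p_other", "p_dance", "p_follow"])
    fv = pd.DataFrame(columns=["bee_id", "feeder_id", "time"])
    gt = GroundTruth(
        tag_offsets={},
        dance_events=pd.DataFrame(columns=["dance_id", "bee_id", "start", "end", "feeder_id"]),
        follow_events=pd.DataFrame(
            columns=["follower_id", "dancer_id", "dance_id", "start", "end", "label"]),
        waggle_phases=pd.DataFrame(
            columns=["dance_id", "bee_id", "phase", "start_time", "duration",
                     "x_mm", "y_mm", "direction_rad"]),
        frame_labels=pd.DataFrame(columns=["bee_id", "frame", "label"]),
    )
    return Scene(det, wp, cp, fv, gt)


def _random_walk(rng, n_frames, dt, bounds, start=None, heading=None):
    """Bounded correlated random walk; returns (pos (n,2), orientation (n,))."""
    width, height = bounds
    margin = 5.0
    if start is None:
        start = rng.uniform([margin, margin], [width - margin, height - margin])
    if heading is None:
        heading = rng.uniform(0, 2 * np.pi)
    pos = np.empty((n_frames, 2))
    ori = np.empty(n_frames)
    p, h = np.asarray(start, float).copy(), float(heading)
    for i in range(n_frames):
        pos[i] = p
        ori[i] = wrap_angle(h)
        h += rng.normal(0.0, 0.35)
        speed = abs(rng.normal(3.0, 1.5))  # mm/s
        step = speed * dt
        q = p + step * np.array([np.cos(h), np.sin(h)])
        # reflect off the comb edges
        if q[0] < margin or q[0] > width - margin:
            h = np.pi - h
            q = p
        if q[1] < margin or q[1] > height - margin:
            h = -h
            q = p
        p = q
    return pos, ori


def _schedule_dances(config: SceneConfig, rng):
    """Assign start times, feeders, and phase counts to every dance."""
    cycle = WAGGLE_DURATION_S + RETURN_DURATION_S
    n_total = config.n_dancers * config.dances_per_dancer
    if n_total == 0:
        return []
    dancers = np.repeat(np.arange(config.n_dancers), config.dances_per_dancer)
    schedule = []
    if config.overlapping_dances:
        for d_idx, bee in enumerate(dancers):
            n_phases = config.waggle_phases_per_dance
            dur = n_phases * cycle
            latest = max(config.duration - dur - 1.0, 1.0)
            start = rng.uniform(min(1.0, latest), latest)
            schedule.append((d_idx, int(bee), start, n_phases))
    else:
        order = rng.permutation(n_total)
        slot = config.duration / n_total
        for pos_in_time, d_idx in enumerate(order):
            n_phases = config.waggle_phases_per_dance
            dur = n_phases * cycle
            if dur > slot - 4.0:
                n_phases = max(3, int((slot - 4.0) // cycle))
                dur = n_phases * cycle
            slot_start = pos_in_time * slot
            latest = max(slot - dur - 2.0, 0.5)
            start = slot_start + rng.uniform(min(0.5, latest), latest)
            schedule.append((int(d_idx), int(dancers[d_idx]), start, n_phases))
    schedule.sort(key=lambda s: s[0])
    return schedule


def _simulate_dance_path(config: SceneConfig, rng, start_xy, direction, n_phases):
    """Waggle-phase start points for one dance under the drift process."""
    sigma_f, sigma_s, _ = config.drift.effective_scales
    mu_f = config.drift.mu_forward
    width, height = config.comb_width, config.comb_height
    ca, sa = np.cos(direction), np.sin(direction)
    pts = [np.asarray(start_xy, float)]
    for _ in range(n_phases - 1):
        for _try in range(config.drift.max_resamples):
            fwd = rng.normal(mu_f, sigma_f)
            side = rng.normal(0.0, sigma_s)
            q = pts[-1] + np.array([fwd * ca - side * sa, fwd * sa + side * ca])
            if 2.0 <= q[0] <= width - 2.0 and 2.0 <= q[1] <= height - 2.0:
                break
        pts.append(q)
    return np.array(pts)


def generate_scene(config: SceneConfig) -> Scene:
    """Generate one synthetic hive scene.

    Returns a :class:`Scene` of (detections, waggle_phases, class_probs,
    feeder_visits, ground_truth).  A zero-duration or empty-population
    config yields empty tables.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    if n_frames == 0 or config.n_bees == 0:
        return _empty_scene(config)

    dt = 1.0 / config.frame_rate
    times = np.arange(n_frames) * dt
    bounds = (config.comb_width, config.comb_height)
    cycle = WAGGLE_DURATION_S + RETURN_DURATION_S

    n_bees = config.n_bees
    dancer_ids = list(range(config.n_dancers))
    follower_ids = list(range(config.n_dancers, config.n_dancers + config.n_followers))

    # base motion: everyone walks
    pos = np.empty((n_bees, n_frames, 2))
    ori = np.empty((n_bees, n_frames))
    for b in range(n_bees):
        pos[b], ori[b] = _random_walk(rng, n_frames, dt, bounds)
    labels = np.zeros((n_bees, n_frames), dtype=int)  # index into LABELS

    # --- dances -----------------------------------------------------------
    schedule = _schedule_dances(config, rng)
    dance_rows, phase_rows, visit_rows = [], [], []
    for dance_id, bee, start, n_phases in schedule:
        feeder = bee % config.n_feeders if config.n_feeders else 0
        direction = wrap_angle(
            config.feeder_direction(feeder) + rng.normal(0.0, 0.1))
        anchor = np.asarray(config.dance_floor_anchor, float) + \
            config.feeder_anchor_offset_mm * np.array(
                [np.cos(config.feeder_direction(feeder)),
                 np.sin(config.feeder_direction(feeder))])
        start_xy = rng.normal(anchor, config.anchor_spread)
        start_xy = np.clip(start_xy, 10.0,
                           [config.comb_width - 10.0, config.comb_height - 10.0])
        starts = _simulate_dance_path(config, rng, start_xy, direction, n_phases)
        end = start + n_phases * cycle
        # trajectory: waggle run along `direction`, then return to next start
        uv = np.array([np.cos(direction), np.sin(direction)])
        for k in range(n_phases):
            t0 = start + k * cycle
            p0 = starts[k]
            p1 = p0 + WAGGLE_RUN_MM * uv
            p_next = starts[k + 1] if k + 1 < n_phases else p0
            f_lo = int(np.ceil(t0 * config.frame_rate))
            f_mid = int(np.ceil((t0 + WAGGLE_DURATION_S) * config.frame_rate))
            f_hi = min(int(np.ceil((t0 + cycle) * config.frame_rate)), n_frames)
            for f in range(f_lo, min(f_mid, n_frames)):
                u = (times[f] - t0) / WAGGLE_DURATION_S
                pos[bee, f] = p0 + u * (p1 - p0)
                ori[bee, f] = direction
            for f in range(min(f_mid, n_frames), f_hi):
                u = (times[f] - t0 - WAGGLE_DURATION_S) / RETURN_DURATION_S
                pos[bee, f] = p1 + u * (p_next - p1)
                move = p_next - p1
                ori[bee, f] = np.arctan2(move[1], move[0]) if np.hypot(*move) > 1e-9 \
                    else direction
            phase_rows.append(
                {"dance_id": dance_id, "bee_id": bee, "phase": k,
                 "start_time": t0, "duration": WAGGLE_DURATION_S,
                 "x_mm": p0[0], "y_mm": p0[1], "direction_rad": direction})
        f_lo = int(np.ceil(start * config.frame_rate))
        f_hi = min(int(np.ceil(end * config.frame_rate)), n_frames)
        labels[bee, f_lo:f_hi] = LABELS.index("dance")
        dance_rows.append({"dance_id": dance_id, "bee_id": bee,
                           "start": start, "end": min(end, config.duration),
                           "feeder_id": feeder})
        visit_rows.append({"bee_id": bee, "feeder_id": feeder,
                           "time": max(0.0, start - rng.uniform(60.0, 280.0))})

    dance_events = pd.DataFrame(
        dance_rows, columns=["dance_id", "bee_id", "start", "end", "feeder_id"])

    # --- followers and attendees -----------------------------------------
    follow_rows = []
    if len(dance_events) and config.n_followers:
        for j, bee in enumerate(follower_ids):
            is_attendee = rng.uniform() < config.attendee_fraction
            n_follows = config.follows_per_follower
            dance = dance_events.iloc[j % len(dance_events)]
            prev_end = None
            for rep in range(n_follows):
                if rep > 0:
                    # subsequent follows: pick the nearest dance running shortly
                    # after the previous follow ends (choice behaviour)
                    t_choice = prev_end + rng.uniform(2.0, 8.0)
                    running = dance_events[
                        (dance_events["start"] <= t_choice)
                        & (dance_events["end"] >= t_choice + 5.0)
                        & (dance_events["bee_id"] != bee)
                        & (dance_events["dance_id"] != dance["dance_id"])
                    ]
                    if len(running) == 0:
                        break
                    here = pos[bee, min(int(t_choice * config.frame_rate),
                                        n_frames - 1)]
                    danced_at = np.array([
                        pos[int(r.bee_id),
                            min(int(t_choice * config.frame_rate), n_frames - 1)]
                        for r in running.itertuples()])
                    dists = np.linalg.norm(danced_at - here, axis=1)
                    dance = running.iloc[int(np.argmin(dists))]
                    f_start = t_choice
                else:
                    span = dance["end"] - dance["start"]
                    f_start = dance["start"] + rng.uniform(0.0, 0.25 * span)
                f_end = min(dance["end"],
                            f_start + rng.uniform(5.0, dance["end"] - f_start + 1e-9))
                if f_end - f_start < 2.0:
                    continue
                dancer = int(dance["bee_id"])
                f_lo = int(np.ceil(f_start * config.frame_rate))
                f_hi = min(int(np.ceil(f_end * config.frame_rate)), n_frames)
                if f_hi <= f_lo:
                    continue
                bearing = rng.uniform(0, 2 * np.pi)
                radius = rng.uniform(4.0, 10.0)
                offset = radius * np.array([np.cos(bearing), np.sin(bearing)])
                for f in range(f_lo, f_hi):
                    pos[bee, f] = pos[dancer, f] + offset
                    to_dancer = -offset
                    ori[bee, f] = np.arctan2(to_dancer[1], to_dancer[0])
                if not is_attendee:
                    labels[bee, f_lo:f_hi] = LABELS.index("follow")
                # dash away afterwards so the attendance window closes,
                # then resume the random walk
                away = np.arctan2(offset[1], offset[0])
                dash_frames = min(int(4.0 * config.frame_rate), n_frames - f_hi)
                p = pos[bee, f_hi - 1].copy()
                uv_away = np.array([np.cos(away), np.sin(away)])
                for f in range(f_hi, f_hi + dash_frames):
                    p = np.clip(p + 15.0 * dt * uv_away, 5.0,
                                [config.comb_width - 5.0, config.comb_height - 5.0])
                    pos[bee, f] = p
                    ori[bee, f] = away
                if f_hi + dash_frames < n_frames:
                    tail_pos, tail_ori = _random_walk(
                        rng, n_frames - f_hi - dash_frames, dt, bounds,
                        start=p, heading=away)
                    pos[bee, f_hi + dash_frames:] = tail_pos
                    ori[bee, f_hi + dash_frames:] = tail_ori
                follow_rows.append(
                    {"follower_id": bee, "dancer_id": dancer,
                     "dance_id": int(dance["dance_id"]),
                     "start": f_start, "end": f_end,
                     "label": "attendee" if is_attendee else "follower"})
                prev_end = f_end
    follow_events = pd.DataFrame(
        follow_rows,
        columns=["follower_id", "dancer_id", "dance_id", "start", "end", "label"])

    # --- tables -----------------------------------------------------------
    bee_idx = np.repeat(np.arange(n_bees), n_frames)
    frame_idx = np.tile(np.arange(n_frames), n_bees)
    det = pd.DataFrame({
        "bee_id": bee_idx,
        "frame": frame_idx,
        "time": np.tile(times, n_bees),
        "x_mm": pos.reshape(-1, 2)[:, 0],
        "y_mm": pos.reshape(-1, 2)[:, 1],
        "orientation_rad": wrap_angle(ori.reshape(-1)),
        "confidence": np.clip(rng.normal(0.9, 0.05, n_bees * n_frames), 0.0, 1.0),
        "comb_side": 0,
    })
    if config.position_noise > 0:
        det[["x_mm", "y_mm"]] += rng.normal(
            0.0, config.position_noise, (len(det), 2))
    offsets = {b: float(rng.normal(0.0, config.tag_offset_spread))
               for b in range(n_bees)} if config.tag_offset_spread > 0 \
        else {b: 0.0 for b in range(n_bees)}
    det = plant_tag_offsets(det, offsets)
    if config.detection_dropout > 0:
        keep = rng.uniform(size=len(det)) >= config.detection_dropout
        det = det[keep].reset_index(drop=True)

    waggle_phase_truth = pd.DataFrame(
        phase_rows, columns=["dance_id", "bee_id", "phase", "start_time",
                             "duration", "x_mm", "y_mm", "direction_rad"])
    waggle_phases = waggle_phase_truth[
        ["start_time", "duration", "x_mm", "y_mm", "direction_rad"]].copy()
    waggle_phases["comb_side"] = 0

    frame_labels = pd.DataFrame({
        "bee_id": bee_idx,
        "frame": frame_idx,
        "label": np.array(LABELS, dtype=object)[labels.reshape(-1)],
    })
    class_probs = emit_class_probabilities(
        frame_labels, config.class_prob_noise, rng)
    feeder_visits = pd.DataFrame(
        visit_rows, columns=["bee_id", "feeder_id", "time"])

    gt = GroundTruth(
        tag_offsets=offsets,
        dance_events=dance_events,
        follow_events=follow_events,
        waggle_phases=waggle_phase_truth,
        frame_labels=frame_labels,
    )
    return Scene(det, waggle_phases, class_probs, feeder_visits, gt)


def plant_tag_offsets(detections: pd.DataFrame,
                      offsets: dict[int, float]) -> pd.DataFrame:
    """Rotate each bee's reported orientation by her tag misalignment.

    Orientations are wrapped to (-pi, pi]; positions are untouched.  Every
    bee named in ``offsets`` must appear in ``detections``.
    """
    present = set(detections["bee_id"].unique())
    unknown = sorted(set(offsets) - present)
    if unknown:
        raise KeyError(f"bee id(s) not present in detections: {unknown}")
    out = detections.copy()
    shift = out["bee_id"].map(lambda b: offsets.get(b, 0.0)).to_numpy(float)
    out["orientation_rad"] = wrap_angle(out["orientation_rad"].to_numpy(float) + shift)
    return out


def emit_class_probabilities(
    frame_labels: pd.DataFrame,
    noise: float,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Per-frame class probabilities consistent with ground-truth labels.

    Emulates a behaviour classifier's softmax output: the true class gets
    probability mass 1 before perturbation; independent Gaussian noise of
    scale ``noise`` is added to every class, negatives are clipped, and
    rows are renormalised to the simplex.  ``noise=0`` reproduces the
    labels exactly under argmax.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(frame_labels)
    onehot = np.zeros((n, 3))
    lab_idx = frame_labels["label"].map({l: i for i, l in enumerate(LABELS)})
    if lab_idx.isna().any():
        raise ValueError("labels must be one of " + ", ".join(LABELS))
    onehot[np.arange(n), lab_idx.to_numpy(int)] = 1.0
    if noise > 0:
        onehot = onehot + rng.normal(0.0, noise, onehot.shape)
    onehot = np.clip(onehot, 1e-6, None)
    onehot /= onehot.sum(axis=1, keepdims=True)
    out = frame_labels[["bee_id", "frame"]].copy()
    out[["p_other", "p_dance", "p_follow"]] = onehot
    return out
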