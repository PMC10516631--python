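"""End-to-end pipeline: generate -> preprocess -> cluster -> detect -> analyze.

Stages communicate through files in the run's output directory so any
stage can be re-run and every number in the final report is traceable to a
written intermediate table.  A run is fully determined by its config
(including the seed).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import drift, events, scene, stats, trajectory
from .clustering import detect_dances

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]

log = logging.getLogger("waggledance")


class ConfigError(ValueError):
    """Raised with the aggregated list of config violations."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialises round-trip to YAML/JSON."""

    scene: scene.SceneConfig = field(default_factory=scene.SceneConfig)
    drift: drift.MotionModelParams = field(default_factory=drift.MotionModelParams)
    seed: int = 0
    out_dir: str = "waggledance_run"
    # stage thresholds, defaulting to the published analysis values
    cluster_max_distance_mm: float = 30.0
    cluster_max_gap_s: float = 5.0
    cluster_min_size: int = 3
    ransac_inlier_tolerance_rad: float = 0.52
    ransac_min_inlier_frac: float = 0.6
    min_dance_duration_s: float = 4.0
    dance_max_gap_s: float = 3.0
    attendance_radius_mm: float = 14.0
    min_follow_duration_s: float = 1.0
    follow_merge_gap_s: float = 3.0
    feeder_lookback_s: float = 300.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML/JSON round trips
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene_d = dict(d.pop("scene", {}))
        drift_inner = scene_d.pop("drift", None)
        drift_d = d.pop("drift", {})
        kwargs = {}
        for f in dataclasses.fields(scene.SceneConfig):
            if f.name in scene_d:
                v = scene_d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        if drift_inner is not None:
            kwargs["drift"] = _params_from_dict(drift_inner)
        sc = scene.SceneConfig(**kwargs)
        return cls(scene=sc, drift=_params_from_dict(drift_d), **d)


def _params_from_dict(d: dict) -> drift.MotionModelParams:
    kwargs = {}
    for f in dataclasses.fields(drift.MotionModelParams):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return drift.MotionModelParams(**kwargs)


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and validate a raw config (YAML/JSON text or mapping).

    All violations are collected and raised together as a
    :class:`ConfigError`; an empty input yields the all-defaults config.
    Unknown keys are rejected.
    """
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        return RunConfig()
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as e:
            raise ConfigError([f"unparseable config: {e}"]) from e
        if data is None:
            return RunConfig()
    else:
        data = raw
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            errors.append(f"unknown key: {key}")
    for section, cls in (("scene", scene.SceneConfig),
                         ("drift", drift.MotionModelParams)):
        sub = data.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"{section} must be a mapping")
            continue
        sub_known = {f.name for f in dataclasses.fields(cls)}
        for key in sub:
            if key not in sub_known:
                errors.append(f"unknown key: {section}.{key}")
    numeric_floor = {
        "cluster_max_distance_mm": 0.0, "cluster_max_gap_s": 0.0,
        "attendance_radius_mm": 0.0, "min_dance_duration_s": 0.0,
        "min_follow_duration_s": 0.0, "feeder_lookback_s": 0.0,
        "ransac_inlier_tolerance_rad": 0.0,
    }
    for key, lo in numeric_floor.items():
        if key in data and not (isinstance(data[key], (int, float))
                                and data[key] >= lo):
            errors.append(f"{key} must be a number >= {lo}")
    if errors:
        raise ConfigError(errors)
    try:
        return RunConfig.from_dict(
            {k: v for k, v in data.items() if k in known})
    except (ValueError, TypeError) as e:
        raise ConfigError([str(e)]) from e


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages on one scene and write every intermediate.

    Writes the scene tables, corrected detections, clustered dances,
    detected events, the drift-model simulation, the statistics report
    (``report.json``), and a log with stage timings and record counts.
    Identical config + seed give identical reports.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    timings: list[str] = []

    def stage(name):
        t0 = _time.perf_counter()

        def done(**counts):
            dt = _time.perf_counter() - t0
            # timings go to the log only, so reports stay byte-identical
            # across repeated runs of one config+seed
            report["stages"][name] = dict(counts)
            timings.append(f"{name}: {dt:.3f}s {counts}")
            log.info("stage %s: %.3fs %s", name, dt, counts)
        return done

    # --- generate ---------------------------------------------------------
    end = stage("generate")
    sc = dataclasses.replace(config.scene, seed=config.seed)
    sn = scene.generate_scene(sc)
    sn.detections.to_csv(out / "detections.csv", index=False)
    sn.waggle_phases.to_csv(out / "waggle_phases.csv", index=False)
    sn.class_probs.to_csv(out / "class_probs.csv", index=False)
    sn.feeder_visits.to_csv(out / "feeder_visits.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps({
        "tag_offsets": {str(k): v for k, v in sn.ground_truth.tag_offsets.items()},
        "dance_events": sn.ground_truth.dance_events.to_dict("records"),
        "follow_events": sn.ground_truth.follow_events.to_dict("records"),
    }, indent=1))
    end(detections=len(sn.detections), waggle_phases=len(sn.waggle_phases))

    # --- preprocess -------------------------------------------------------
    end = stage("preprocess")
    if len(sn.detections):
        offsets = trajectory.estimate_all_offsets(sn.detections)
        corrected = trajectory.apply_orientation_correction(sn.detections, offsets)
    else:
        offsets, corrected = {}, sn.detections
    corrected.to_csv(out / "detections_corrected.csv", index=False)
    (out / "orientation_offsets.json").write_text(
        json.dumps({str(k): v for k, v in offsets.items()}, indent=1))
    end(bees_corrected=len(offsets))

    # --- cluster ----------------------------------------------------------
    end = stage("cluster")
    dances = detect_dances(
        sn.waggle_phases,
        config.cluster_max_distance_mm, config.cluster_max_gap_s,
        config.cluster_min_size,
        config.ransac_inlier_tolerance_rad, config.ransac_min_inlier_frac,
    ) if len(sn.waggle_phases) else []
    pd.DataFrame([
        {"cluster": i, "n_phases": len(d.phases),
         "n_inliers": int(d.inliers.sum()),
         "consensus_rad": d.consensus_angle,
         "x_mm": d.median_position[0], "y_mm": d.median_position[1]}
        for i, d in enumerate(dances)
    ]).to_csv(out / "dances_clustered.csv", index=False)
    end(dances=len(dances))

    # --- detect events ----------------------------------------------------
    end = stage("detect_events")
    if len(sn.class_probs):
        dance_events, follow_events = events.detect_events(
            sn.class_probs, corrected, sn.feeder_visits,
            frame_rate=sc.frame_rate,
            min_dance_duration_s=config.min_dance_duration_s,
            dance_max_gap_s=config.dance_max_gap_s,
            attendance_radius_mm=config.attendance_radius_mm,
            min_follow_duration_s=config.min_follow_duration_s,
            follow_merge_gap_s=config.follow_merge_gap_s,
            feeder_lookback_s=config.feeder_lookback_s,
        )
    else:
        dance_events, follow_events = [], []
    de, fe = events.events_to_frame(dance_events, follow_events)
    de.to_csv(out / "dance_events.csv", index=False)
    fe.to_csv(out / "follow_events.csv", index=False)
    end(dance_events=len(de), follow_events=len(fe))

    # --- analyze ----------------------------------------------------------
    end = stage("analyze")
    analysis: dict = {}
    if len(sn.waggle_phases):
        phases = sn.waggle_phases.rename(columns={"direction_rad": "alpha_rad"})
        analysis["scene_alignment"] = stats.alignment_report(phases)
        analysis["scene_area_fraction"] = stats.dance_floor_area_fraction(
            phases, (sc.comb_width, sc.comb_height))
    analysis["n_dance_events"] = len(de)
    analysis["n_follow_events"] = int((fe["label"] == "follower").sum()) if len(fe) else 0
    analysis["n_attendee_events"] = int((fe["label"] == "attendee").sum()) if len(fe) else 0

    sim = drift.simulate_dances(config.drift, seed=config.seed)
    sim.to_csv(out / "drift_simulation.csv", index=False)
    analysis["drift_simulation"] = stats.alignment_report(sim)
    pairs = drift.measure_projected_drift(sim)
    analysis["drift_simulation"]["mean_forward_mm"] = float(
        pairs["forward_mm"].mean()) if len(pairs) else None
    report["analysis"] = analysis
    end(report_keys=len(analysis))

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(timings) + "\n")
    return report
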