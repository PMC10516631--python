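import numpy as np
import pandas as pd
import pytest

from waggledance import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A modest scene with every population present, reused across tests."""
    cfg = SceneConfig(
        n_dancers=3, n_followers=4, n_idle=8, duration=300.0,
        tag_offset_spread=0.3, seed=42,
    )
    return cfg, generate_scene(cfg)


def make_straight_track(
    bee_id=0, n=30, heading=0.7, speed_mm_s=8.0, frame_rate=6.0,
    start=(50.0, 50.0), orientation_offset=0.0, confidence=0.9,
):
    """A noise-free straight walk whose orientation equals heading + offset."""
    t = np.arange(n) / frame_rate
    step = speed_mm_s / frame_rate
    x = start[0] + step * np.arange(n) * np.cos(heading)
    y = start[1] + step * np.arange(n) * np.sin(heading)
    return pd.DataFrame(
        {
            "bee_id": bee_id,
            "frame": np.arange(n),
            "time": t,
            "x_mm": x,
            "y_mm": y,
            "orientation_rad": np.mod(heading + orientation_offset + np.pi,
                                      2 * np.pi) - np.pi,
            "confidence": confidence,
        }
    )
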