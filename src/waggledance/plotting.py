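"""Quick-look figures for drift simulations and dance-floor statistics."""
from __future__ import annotations

import numpy as np

from .stats import OrientationField


def plot_orientation_field(field: OrientationField, ax=None):
    """Quiver plot of the binned mean waggle orientations.

    Arrow length is the mean resultant vector length per bin, so bins with
    an even mix of directions show short arrows.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    occupied = field.counts > 0
    cx = (field.x_edges[:-1] + field.x_edges[1:]) / 2
    cy = (field.y_edges[:-1] + field.y_edges[1:]) / 2
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    ax.quiver(
        gx[occupied], gy[occupied],
        field.mean_vector[..., 0][occupied], field.mean_vector[..., 1][occupied],
        field.counts[occupied], angles="xy", pivot="mid", cmap="viridis",
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    return ax


def plot_group_distances(timeseries, ax=None):
    """Intra- vs inter-group mean distance bands over event-aligned time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = timeseries["rel_time"]
    for name, color in (("intra", "tab:blue"), ("inter", "tab:orange")):
        m = timeseries[f"{name}_mean"]
        ci = timeseries[f"{name}_ci95"]
        ax.plot(t, m, color=color, label=f"{name}-group")
        ax.fill_between(t, m - ci, m + ci, color=color, alpha=0.25)
    ax.set_xlabel("time relative to alignment point (s)")
    ax.set_ylabel("mean pairwise distance (mm)")
    ax.legend()
    return ax
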