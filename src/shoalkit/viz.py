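"""Figure export: correlation heat maps and focal arrow/alignment maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .focal import FocalAlignmentMap
from .pairwise import SpeedDistanceGrid


def plot_speed_distance_grid(grid: SpeedDistanceGrid, title: str = ""):
    """Heat map of mean directional correlation over speed x distance."""
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        grid.distance_edges,
        grid.speed_edges,
        grid.mean_r,
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
    )
    fig.colorbar(mesh, ax=ax, label="directional correlation r")
    ax.set_xlabel("pair distance (mm)")
    ax.set_ylabel("mutual speed (mm/s)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_focal_map(fmap: FocalAlignmentMap, title: str = ""):
    """R surface with mean-direction arrows, focal fish at the origin (+x)."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    mesh = ax.pcolormesh(fmap.x_edges, fmap.y_edges, fmap.R.T, cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(mesh, ax=ax, label="alignment R")
    xc = 0.5 * (fmap.x_edges[:-1] + fmap.x_edges[1:])
    yc = 0.5 * (fmap.y_edges[:-1] + fmap.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    ok = np.isfinite(fmap.mean_direction)
    ax.quiver(
        xx[ok],
        yy[ok],
        np.cos(fmap.mean_direction[ok]),
        np.sin(fmap.mean_direction[ok]),
        color="white",
        scale=30,
        width=0.004,
    )
    ax.plot(0, 0, "r>", markersize=8)
    ax.set_xlabel("relative x (mm, focal heading +x)")
    ax.set_ylabel("relative y (mm)")
    ax.set_aspect("equal")
    ax.set_title(title)
    fig.tight_layout()
    return fig
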