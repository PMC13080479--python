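"""Matplotlib views of response maps, regions, and spatial profiles."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .binding import RateMap, RegionMask
from .diffusion import ConcentrationField, SpatialGermination

__all__ = ["plot_rate_map", "plot_profiles", "plot_spatial_germination"]


def plot_rate_map(
    rate_map: RateMap, region: Optional[RegionMask] = None, ax=None
):
    """Heatmap of the germination rate over the (L, D) grid.

    Axes are log-scaled where the grid allows it; an optional region mask
    is drawn as a contour at its threshold.
    """
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(rate_map.L_grid, rate_map.D_grid, rate_map.rate, shading="nearest")
    if np.all(rate_map.L_grid > 0):
        ax.set_xscale("log")
    if np.all(rate_map.D_grid > 0):
        ax.set_yscale("log")
    if region is not None:
        ax.contour(
            region.L_grid,
            region.D_grid,
            region.inside.astype(float),
            levels=[0.5],
            colors="w",
        )
    ax.set_xlabel("L-alanine (mM)")
    ax.set_ylabel("D-alanine (mM)")
    plt.colorbar(mesh, ax=ax, label="germination rate (h$^{-1}$)")
    return ax


def plot_profiles(field: ConcentrationField, every: int = 1, ax=None):
    """Concentration profiles L(x) (solid) and D(x) (dashed) over time."""
    if ax is None:
        _, ax = plt.subplots()
    idx = range(0, field.times.size, every)
    cmap = plt.get_cmap("viridis")
    for i in idx:
        color = cmap(i / max(field.times.size - 1, 1))
        label = f"{field.times[i] / 3600:.1f} h"
        ax.plot(field.x, field.L[i], color=color, label=label)
        if np.any(field.D[i] > 0):
            ax.plot(field.x, field.D[i], color=color, linestyle="--")
    ax.set_xlabel("position (cm)")
    ax.set_ylabel("concentration (mM)")
    ax.legend(fontsize="small", ncols=2)
    return ax


def plot_spatial_germination(sg: SpatialGermination, ax=None):
    """Predicted germination probability by exposure time T versus position."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(sg.x, sg.p_germ)
    ax.set_xlabel("position (cm)")
    ax.set_ylabel(f"P(germinated by {sg.T:g} h)")
    ax.set_ylim(-0.02, 1.02)
    return ax
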