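"""Matplotlib views of trajectories, correlation paths and interval maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .area2d import AreaTrajectory
from .trajectory import CorrelationResult, FeatureTrajectory

__all__ = ["plot_trajectory", "plot_correlation", "plot_interval_map", "plot_area_trajectory"]


def plot_trajectory(traj: FeatureTrajectory, title: str | None = None):
    """Percent-change feature curves vs time (volume, width, height, mean
    and cumulative intensity per channel)."""
    table = traj.table
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), constrained_layout=True)
    t = table["t_min"]
    axes[0].plot(t, table["dV_pct"], "o-", label="ΔV%")
    axes[0].plot(t, table["dw_pct"], "s-", label="Δw%")
    axes[0].plot(t, table["dh_pct"], "^-", label="Δh%")
    axes[0].set_ylabel("dimension change (%)")
    axes[1].plot(t, table["dimean_f_pct"], "o-", label="ΔĪ% (f)")
    axes[1].plot(t, table["dimean_epi_pct"], "s-", label="ΔĪ% (epi)")
    axes[1].set_ylabel("mean intensity change (%)")
    axes[2].plot(t, table["disum_f_pct"], "o-", label="Δ∑I% (f)")
    axes[2].plot(t, table["disum_epi_pct"], "s-", label="Δ∑I% (epi)")
    axes[2].set_ylabel("cumulative intensity change (%)")
    for ax in axes:
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_xlabel("time (min)")
        ax.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    return fig


def plot_correlation(corr: CorrelationResult, title: str | None = None):
    """Time-ordered 2D feature path with the through-origin slope."""
    fig, ax = plt.subplots(figsize=(4, 4), constrained_layout=True)
    ax.plot(corr.x, corr.y, "o-", ms=4)
    xs = np.linspace(min(0, corr.x.min()), max(0, corr.x.max()), 50)
    ax.plot(xs, corr.slope_origin * xs, "--", color="0.5",
            label=f"slope {corr.slope_origin:.2f}, r = {corr.pearson_r:.3f}")
    ax.set_xlabel(corr.x_name)
    ax.set_ylabel(corr.y_name)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return fig


def plot_area_trajectory(traj: AreaTrajectory, title: str | None = None):
    fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    t = traj.table["t_s"]
    ax.plot(t, traj.table["ratio"], "k-o", ms=3, label="total")
    ax.plot(t, traj.table["ratio_left"], "-", label="left of margin")
    ax.plot(t, traj.table["ratio_right"], "-", label="right of margin")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("area ratio to first frame")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return fig


def plot_interval_map(label_image: np.ndarray, margin_mask: np.ndarray, title: str | None = None):
    """Colour-coded map of the area newly covered in each time interval,
    with the original sample margin overlaid in white."""
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    shown = np.ma.masked_equal(label_image, 0)
    im = ax.imshow(shown, cmap="viridis", interpolation="nearest")
    overlay = np.zeros(label_image.shape + (4,))
    overlay[margin_mask] = (1, 1, 1, 1)
    ax.imshow(overlay, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="interval index")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    return fig
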