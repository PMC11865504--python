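"""Quick-look figures for simulations and quantification output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .osc_metrics import WaveSeries

__all__ = ["plot_half_volumes", "plot_radius_histogram", "plot_kymogram"]


def plot_half_volumes(upper: WaveSeries, lower: WaveSeries, ax=None):
    """Upper/lower-half total droplet volume against time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(upper.t / 60.0, upper.v, label="upper half", color="tab:orange")
    ax.plot(lower.t / 60.0, lower.v, label="lower half", color="tab:blue")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("total droplet volume (µm³)")
    ax.legend(frameon=False)
    return ax


def plot_radius_histogram(radii, ax=None, bins=30):
    """Droplet radius distribution of an emulsion snapshot."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.hist(np.asarray(radii), bins=bins, color="tab:purple", alpha=0.8)
    ax.set_xlabel("radius (µm)")
    ax.set_ylabel("droplets")
    return ax


def plot_kymogram(trajectory, r_cell: float, out_dt: float | None = None, ax=None,
                  n_bins: int = 40):
    """Space–time map of droplet volume along the cell's vertical axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    times = np.unique(trajectory["t"])
    edges = np.linspace(-r_cell, r_cell, n_bins + 1)
    img = np.zeros((n_bins, times.size))
    vol = 4.0 / 3.0 * np.pi * trajectory["R"].to_numpy() ** 3
    t_idx = np.searchsorted(times, trajectory["t"].to_numpy())
    z_idx = np.clip(np.digitize(trajectory["z"].to_numpy(), edges) - 1, 0, n_bins - 1)
    np.add.at(img, (z_idx, t_idx), vol)
    ax.imshow(img, aspect="auto", origin="lower", cmap="magma",
              extent=(times[0] / 60.0, times[-1] / 60.0, -r_cell, r_cell))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("z (µm)")
    return ax
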