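"""Figure helpers: plane trajectories, angle histograms, shuffle bars.

All functions accept an optional matplotlib Axes and are safe on
headless backends (no pyplot state is required to render to file).
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .stats import AngleHistogram  # noqa: E402
from .shuffle import ShuffleResult  # noqa: E402

__all__ = ["plot_plane_trajectories", "plot_angle_histogram", "plot_shuffle_bars"]


def plot_plane_trajectories(proj: np.ndarray, ax=None, cmap: str = "coolwarm"):
    """Per-condition trajectories in a jPCA plane, colored by the
    initial-state projection onto jPC1 (the standard presentation)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    starts = proj[:, 0, 0]
    order = np.argsort(starts)
    colors = plt.get_cmap(cmap)(np.linspace(0, 1, proj.shape[0]))
    for rank, c in enumerate(order):
        ax.plot(proj[c, 0], proj[c, 1], color=colors[rank], lw=1.5)
        ax.plot(proj[c, 0, 0], proj[c, 1, 0], "o", color=colors[rank], ms=4)
    ax.set_xlabel("jPC$_1$ (a.u.)")
    ax.set_ylabel("jPC$_2$ (a.u.)")
    ax.set_aspect("equal")
    return ax


def plot_angle_histogram(hist: AngleHistogram, ax=None, **line_kw):
    """Density of the state/derivative angle over [0, pi]; a peak at
    pi/2 indicates rotational dynamics."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(hist.bin_centers, hist.density, **{"lw": 1.8, **line_kw})
    ax.axvline(np.pi / 2, color="0.6", ls=":")
    ax.set_xlim(0, np.pi)
    ax.set_xticks([0, np.pi / 2, np.pi], ["0", r"$\pi/2$", r"$\pi$"])
    ax.set_xlabel(r"angle $q$ between $x$ and $\dot{x}$")
    ax.set_ylabel("density")
    return ax


def plot_shuffle_bars(result: ShuffleResult, ax=None):
    """Original vs shuffled rotational variance fraction with an SD
    error bar across shuffle trials."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3.5))
    ax.bar([0], [result.original_r2], color="#8c510a", label="original")
    ax.bar([1], [result.mean], yerr=[result.sd], color="#4575b4", capsize=4, label="shuffled")
    ax.set_xticks([0, 1], ["original", result.shuffle_kind])
    ax.set_ylabel("rotational variance fraction")
    ax.set_ylim(0, 1)
    return ax
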