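"""Figure helpers for histograms and phasor plots."""

from __future__ import annotations

import numpy as np

from .histograms import HistogramND, TrivariateHistogram
from .phasor import PhasorField

__all__ = ["plot_histogram", "plot_trivariate_surface", "plot_phasor_density"]


def plot_histogram(hist: HistogramND, ax=None, label: str | None = None, **kwargs):
    """Percent-of-pixels line plot against bin centres."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(hist.centers[0], hist.counts_percent, label=label, **kwargs)
    ax.set_ylabel("% of pixels")
    if label:
        ax.legend()
    return ax


def plot_trivariate_surface(tri: TrivariateHistogram, ax=None, log10: bool = True,
                            cmap: str = "viridis"):
    """Surface of bin percentages colour-coded by the per-bin mean of z.

    With ``log10`` the surface height is log10 percent of pixels (empty bins
    are left out).
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm as _cm

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    cx, cy = tri.base.centers
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    Z = tri.base.counts_percent.copy()
    if log10:
        with np.errstate(divide="ignore"):
            Z = np.where(Z > 0, np.log10(Z), np.nan)
    colors = _cm.get_cmap(cmap)(np.nan_to_num(
        (tri.z_mean - np.nanmin(tri.z_mean))
        / max(np.nanmax(tri.z_mean) - np.nanmin(tri.z_mean), 1e-12)
    ))
    ax.plot_surface(X, Y, np.nan_to_num(Z, nan=np.nanmin(Z[np.isfinite(Z)]) if np.isfinite(Z).any() else 0),
                    facecolors=colors, shade=False)
    ax.set_zlabel("log10 % of pixels" if log10 else "% of pixels")
    return ax


def plot_phasor_density(field: PhasorField, ax=None, bins: int = 200):
    """2-D phasor histogram with the universal circle overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g, s = field.points()
    ax.hist2d(g, s, bins=bins, range=[[0, 1], [0, 0.6]], cmin=1)
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k--", lw=1,
            label="universal circle")
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_aspect("equal")
    return ax
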