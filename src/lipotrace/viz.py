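"""Plotting helpers: isotopologue distributions, parameter histograms, maps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_profile_fit", "plot_parameter_histogram", "plot_pixel_map"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_profile_fit(observed: np.ndarray, fitted: np.ndarray | None = None, ax=None):
    """Bar plot of an even-isotopologue distribution with the model overlay."""
    ax = _get_ax(ax)
    x = 2 * np.arange(len(observed))
    ax.bar(x, observed, width=1.2, color="#7fb3d5", label="observed")
    if fitted is not None:
        ax.plot(x, fitted, "o-", color="#1a237e", label="model")
    ax.set_xlabel("mass shift (M+j)")
    ax.set_ylabel("normalized intensity")
    ax.set_xticks(x)
    ax.legend(frameon=False)
    return ax


def plot_parameter_histogram(values, bin_width: float = 0.025, ax=None,
                             label: str = "p"):
    """Histogram of fitted parameters on fixed-width bins over [0, 1]."""
    ax = _get_ax(ax)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    ax.hist(np.asarray(values, float), bins=edges, color="#7fb3d5",
            edgecolor="white")
    ax.set_xlabel(label)
    ax.set_ylabel("cells")
    return ax


def plot_pixel_map(pmap, ax=None, cmap: str = "viridis", **imshow_kwargs):
    """Spatial heat map of a per-pixel statistic; masked pixels shown black."""
    import matplotlib.pyplot as plt

    ax = _get_ax(ax)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.imshow(np.ma.masked_invalid(pmap.values), cmap=cm, **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, label=pmap.statistic)
    extent_um = pmap.values.shape[1] * pmap.pitch
    ax.set_title(f"{pmap.statistic} ({pmap.pitch:g} µm pitch, {extent_um:g} µm wide)")
    return ax
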