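"""Minimal plotting helpers for rasters and weight matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["raster_plot", "weight_matrix_plot"]


def raster_plot(spikes: pd.DataFrame, ax=None, **scatter_kw):
    """Spike raster: time on x, neuron id on y."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    kw = {"s": 4, "color": "k", "marker": "|"}
    kw.update(scatter_kw)
    ax.scatter(spikes.time_ms, spikes.neuron_id, **kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    return ax


def weight_matrix_plot(w: np.ndarray, ax=None, w_max: float = 1.0):
    """Dense weight matrix, presynaptic rows, with a colourbar."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(w, vmin=0.0, vmax=w_max, cmap="viridis", origin="lower")
    ax.set_xlabel("postsynaptic neuron")
    ax.set_ylabel("presynaptic neuron")
    plt.colorbar(im, ax=ax, label="w")
    return ax
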