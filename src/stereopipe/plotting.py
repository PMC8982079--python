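"""Minimal spatial map plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_bin_map(bins: pd.DataFrame, values, ax=None, cmap="viridis", title=None):
    """Scatter a per-bin quantity on the chip layout.

    ``bins`` needs columns x, y; ``values`` is an aligned vector (UMI
    totals, a module score, a cell-type weight, a regulon activity...).
    Returns the matplotlib axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(bins["x"], bins["y"], c=np.asarray(values), s=12, marker="s", cmap=cmap)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("bin x")
    ax.set_ylabel("bin y")
    if title:
        ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
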