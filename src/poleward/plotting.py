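"""Simple static figures: evenness bubbles, trait heatmaps, breakpoint fits, band maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breakpoints import BreakpointResult
from .climate import BAND_NAMES, MASKED

_BAND_COLORS = {"blue": "#2166ac", "yellow": "#ffd92f", "orange": "#f46d43", "red": "#b2182b"}


def evenness_bubble_plot(evenness: pd.DataFrame, ax=None):
    """Occupancy vs dispersion; bubble radius sqrt(abundance)/pi."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sizes = np.sqrt(evenness["total_abundance"].to_numpy()) / np.pi
    ax.scatter(evenness["occupancy"], evenness["dispersion"], s=sizes, alpha=0.5)
    ax.set_xlabel("occupancy (stations)")
    ax.set_ylabel("dispersion evenness")
    return ax


def trait_heatmap(r: pd.DataFrame, p: pd.DataFrame, ax=None):
    """Module × covariate correlation heatmap annotated r (p)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.imshow(r.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    for i, m in enumerate(r.index):
        for j, c in enumerate(r.columns):
            ax.text(j, i, f"{r.loc[m, c]:.2f}\n({p.loc[m, c]:.1e})",
                    ha="center", va="center", fontsize=7)
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax


def breakpoint_plot(x, y, result: BreakpointResult, ax=None):
    """Scatter of beta vs gradient with the fitted broken stick and psi marker."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    x = np.asarray(x, dtype=float)
    ax.scatter(x, y, s=12, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, result.predict(grid), color="k")
    ax.axvline(result.psi, linestyle="--", color="grey")
    ax.set_title(f"psi = {result.psi:.2f}, p = {result.p_value:.2e}")
    return ax


def band_map(bands: np.ndarray, latitudes, longitudes, ax=None):
    """Categorical map of the breakpoint temperature bands."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    ax = ax or plt.gca()
    codes = np.full(bands.shape, -1, dtype=float)
    for i, name in enumerate(BAND_NAMES):
        codes[bands == name] = i
    codes = np.ma.masked_where(bands == MASKED, codes)
    cmap = ListedColormap([_BAND_COLORS[b] for b in BAND_NAMES])
    ax.pcolormesh(longitudes, latitudes, codes, cmap=cmap, vmin=-0.5, vmax=3.5)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
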