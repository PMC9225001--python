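"""Basic map-slice and time-trace plots (matplotlib is imported lazily and
is an optional dependency; install the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .grids import Grid


def plot_map_slice(flat_image: np.ndarray, grid: Grid, z_mm: float,
                   ax=None, **imshow_kw):
    """Plot one axial (constant-z) slice of a flattened voxel image."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    zs = grid.origin[2] + grid.spacing * np.arange(grid.shape[2])
    k = int(np.argmin(np.abs(zs - z_mm)))
    vol = grid.to_volume(np.asarray(flat_image))
    extent = [grid.origin[0], grid.origin[0] + grid.spacing * (grid.shape[0] - 1),
              grid.origin[1], grid.origin[1] + grid.spacing * (grid.shape[1] - 1)]
    im = ax.imshow(vol[:, :, k].T, origin="lower", extent=extent,
                   **{"cmap": "RdBu_r", **imshow_kw})
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"z = {zs[k]:g} mm")
    return im


def plot_trace(lags_s: np.ndarray, mean: np.ndarray, se: np.ndarray | None = None,
               ax=None, label: str | None = None):
    """Event-related time trace with optional standard-error band."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(lags_s, mean, label=label)
    if se is not None:
        ax.fill_between(lags_s, mean - se, mean + se, alpha=0.3)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from onset (s)")
    ax.set_ylabel(r"$\Delta$HbO ($\mu$M)")
    return ax
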