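"""Optional target-plot rendering (polar scatter of onsets).

Draws the assay's standard summary figure: onset locations in normalized
polar coordinates, points colored by freezing temperature, concentric
rings at the equal-volume sector boundaries shaded by per-sector
nucleation frequency. Only the underlying data contract is tested; the
figure itself is a convenience.
"""

from __future__ import annotations

import numpy as np

from .geometry import SectorScheme, summarize_sectors


def target_plot(records, scheme: SectorScheme | None = None, ax=None):
    """Polar scatter of onset locations over equal-volume sector shading."""
    import matplotlib.pyplot as plt

    scheme = scheme or SectorScheme()
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    summary = summarize_sectors(records, scheme)
    bounds = scheme.boundaries
    cmap = plt.get_cmap("YlOrRd")
    fmax = max(summary.frequencies.max(), 1e-9)
    theta_grid = np.linspace(0, 2 * np.pi, 181)
    for k in range(scheme.n_sectors):
        ax.fill_between(
            theta_grid,
            bounds[k],
            bounds[k + 1],
            color=cmap(summary.frequencies[k] / fmax),
            alpha=0.5,
            linewidth=0,
        )
    sc = ax.scatter(
        records["theta_rad"],
        records["r_norm"],
        c=records.get("temp_C"),
        cmap="winter",
        edgecolors="k",
        zorder=3,
    )
    ax.set_rmax(1.0)
    ax.set_rticks(bounds[1:].round(2))
    if records.get("temp_C") is not None:
        ax.figure.colorbar(sc, ax=ax, label="freezing temperature (°C)")
    return ax
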