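"""Freezing-temperature spectra, T50, blank screening and cycle drift.

A freezing spectrum is the empirical frozen-fraction curve over decreasing
temperature: during a cooling ramp, the fraction of events already frozen
at temperature T is the fraction with freezing temperature >= T. T50 is the
sample median freezing temperature. Events falling inside the pure-water
blank's freezing range are flagged as possible background rather than
silently discarded, and drift of freezing temperature across freeze-thaw
cycles is checked with a least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import SectorScheme, summarize_sectors

__all__ = [
    "FreezingSpectrum",
    "compute_spectrum",
    "blank_screen",
    "freeze_thaw_drift",
]


@dataclass
class FreezingSpectrum:
    """Sorted freezing temperatures with frozen-fraction curve and T50."""

    temperatures: np.ndarray  # degrees C, sorted descending (cooling order)
    frozen_fraction: np.ndarray  # fraction frozen at or above each temperature
    t50: float
    t_range: tuple[float, float]  # (min, max) degrees C

    @property
    def n(self) -> int:
        return len(self.temperatures)

    def to_dict(self) -> dict:
        return {
            "t50": float(self.t50),
            "n": self.n,
            "t_min": float(self.t_range[0]),
            "t_max": float(self.t_range[1]),
            "curve": [
                [float(t), float(f)]
                for t, f in zip(self.temperatures, self.frozen_fraction)
            ],
        }


def compute_spectrum(temperatures) -> FreezingSpectrum:
    """Empirical frozen-fraction spectrum and median freezing temperature.

    T50 is the sample median (for even n, the mean of the two central order
    statistics). The curve lists temperatures in cooling order (warmest
    first) with the cumulative fraction frozen at each.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0:
        raise ValueError("cannot compute a spectrum from zero freezing events")
    order = np.sort(temps)[::-1]
    frac = np.arange(1, temps.size + 1) / temps.size
    return FreezingSpectrum(
        temperatures=order,
        frozen_fraction=frac,
        t50=float(np.median(temps)),
        t_range=(float(temps.min()), float(temps.max())),
    )


def blank_screen(
    records: pd.DataFrame, blank_range: tuple[float, float] = (-30.0, -23.2)
) -> tuple[pd.DataFrame, int]:
    """Flag events that freeze inside or below the blank's freezing range.

    ``blank_range`` is (T_low, T_high) of the pure-water blank, both in
    degrees C with T_low < T_high (e.g. -30.0 to -23.2). Events with
    freezing temperature <= T_high cannot be distinguished from background
    nucleation; they are excluded from mechanism statistics and counted.

    Returns the retained records and the number excluded.
    """
    t_low, t_high = blank_range
    if not t_low < t_high:
        raise ValueError(f"blank_range must satisfy T_low < T_high, got {blank_range}")
    if len(records) == 0:
        return records.copy(), 0
    keep = records["temp_C"].to_numpy() > t_high
    return records.loc[keep].reset_index(drop=True), int((~keep).sum())


def freeze_thaw_drift(
    records: pd.DataFrame, scheme: SectorScheme | None = None
) -> dict:
    """Stability of a sample across repeated freeze-thaw cycles.

    Fits an ordinary least-squares slope of freezing temperature against
    cycle index (degrees C per cycle, with standard error) and tabulates
    the outermost-sector frequency per cycle. A stable sample shows a slope
    indistinguishable from zero and no trend in the location frequencies.
    """
    scheme = scheme or SectorScheme()
    if records["cycle"].nunique() < 2:
        raise ValueError("drift analysis needs at least two freeze-thaw cycles")
    cyc = records["cycle"].to_numpy(dtype=float)
    temp = records["temp_C"].to_numpy(dtype=float)
    fit = stats.linregress(cyc, temp)
    per_cycle = (
        records.groupby("cycle", sort=True)
        .apply(
            lambda g: summarize_sectors(g, scheme).outermost_frequency,
            include_groups=False,
        )
        .rename("outermost_frequency")
        .reset_index()
    )
    return {
        "slope_C_per_cycle": float(fit.slope),
        "slope_stderr": float(fit.stderr),
        "intercept_C": float(fit.intercept),
        "per_cycle_outermost": per_cycle,
    }
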