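"""Equal-volume sector geometry for pancake-shaped droplets.

A droplet squeezed between two slides is a short cylinder, so the volume
enclosed within normalized radius ``r`` is simply ``r**2`` of the total.
Concentric annuli with boundaries at ``sqrt(k/n)`` therefore partition the
droplet into ``n`` sectors of exactly equal volume; the outermost sector is
the one adjacent to the air-water interface (AWI). Nucleation-onset
statistics over these sectors are the core readout of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SectorScheme",
    "SectorSummary",
    "volume_fraction",
    "assign_sector",
    "summarize_sectors",
    "frozen_fraction_vs_volume",
]


@dataclass(frozen=True)
class SectorScheme:
    """Concentric equal-volume sectors of a cylindrical droplet.

    Sector ``k`` (1-based) covers volume fractions ``[(k-1)/n, k/n)``;
    the outermost sector ``n`` is closed at 1 so rim events belong to it.
    """

    n_sectors: int = 5

    def __post_init__(self) -> None:
        if self.n_sectors < 1:
            raise ValueError(f"n_sectors must be >= 1, got {self.n_sectors}")

    @property
    def boundaries(self) -> np.ndarray:
        """Radial sector boundaries ``sqrt(k/n)`` for k = 0..n."""
        return np.sqrt(np.arange(self.n_sectors + 1) / self.n_sectors)


@dataclass
class SectorSummary:
    """Per-sector counts and frequencies of nucleation onsets."""

    counts: np.ndarray
    frequencies: np.ndarray
    outermost_frequency: float
    n_events: int
    scheme: SectorScheme = field(default_factory=SectorScheme)

    def to_dict(self) -> dict:
        return {
            "counts": [int(c) for c in self.counts],
            "frequencies": [float(f) for f in self.frequencies],
            "outermost_frequency": float(self.outermost_frequency),
            "n_events": int(self.n_events),
            "n_sectors": self.scheme.n_sectors,
        }


def volume_fraction(r_norm):
    """Volume fraction enclosed within normalized radius ``r_norm``.

    For the cylindrical (pancake) geometry this is the squared normalized
    radius; 0 is the droplet center, 1 the AWI.
    """
    r = np.asarray(r_norm, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("r_norm must lie in [0, 1]")
    out = r * r
    return float(out) if np.isscalar(r_norm) else out


def assign_sector(r_norm, scheme: SectorScheme | None = None):
    """Assign normalized radii to 1-based equal-volume sector indices.

    The comparison is done on volume fractions (``r**2`` against ``k/n``)
    rather than on square-root boundaries; a radius within one part in 10^9
    of a boundary is treated as sitting exactly on it (so ``sqrt(k/n)``
    round-trips into sector ``k+1`` despite float rounding). Volume
    fraction 1 maps to the outermost sector.
    """
    scheme = scheme or SectorScheme()
    vf = volume_fraction(r_norm)
    scaled = np.asarray(vf) * scheme.n_sectors
    nearest = np.round(scaled)
    on_boundary = (np.abs(scaled - nearest) <= 1e-9) & (nearest > 0)
    idx = np.where(on_boundary, nearest, np.floor(scaled)).astype(int) + 1
    idx = np.minimum(idx, scheme.n_sectors)
    return int(idx) if np.isscalar(r_norm) else idx


def summarize_sectors(
    records: pd.DataFrame, scheme: SectorScheme | None = None
) -> SectorSummary:
    """Count onsets per equal-volume sector and report frequencies.

    Parameters
    ----------
    records
        Table with an ``r_norm`` column (one row per freezing event).
    scheme
        Sector scheme; defaults to five equal-volume sectors.
    """
    scheme = scheme or SectorScheme()
    if len(records) == 0:
        raise ValueError("cannot summarize an empty event table")
    sectors = assign_sector(records["r_norm"].to_numpy(), scheme)
    counts = np.bincount(sectors, minlength=scheme.n_sectors + 1)[1:]
    n = int(counts.sum())
    freqs = counts / n
    return SectorSummary(
        counts=counts,
        frequencies=freqs,
        outermost_frequency=float(freqs[-1]),
        n_events=n,
        scheme=scheme,
    )


def frozen_fraction_vs_volume(records: pd.DataFrame) -> pd.DataFrame:
    """Cumulative frozen fraction against onset volume fraction.

    Events are sorted by the volume fraction of their onset location; the
    curve gives, at each event, the fraction of all events whose onset lies
    within that volume. Pure bulk nucleation (onsets uniform in volume)
    yields the identity line; nucleation at the AWI piles the curve up
    against volume fraction 1.
    """
    if len(records) == 0:
        raise ValueError("cannot compute a frozen-fraction curve without events")
    vf = np.sort(volume_fraction(records["r_norm"].to_numpy()))
    frac = np.arange(1, len(vf) + 1) / len(vf)
    return pd.DataFrame({"volume_fraction": vf, "frozen_fraction": frac})
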