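"""Ice-front propagation velocity from image stacks.

After the onset is localized, the frozen region is segmented in every
subsequent frame with the same change-detection rule used for onset
detection. The front's radial extent is the maximum distance from the
onset pixel to any frozen pixel (the dendrite tip sets the propagation
speed), converted to micrometers; an ordinary least-squares slope of
extent against time gives the velocity in cm/s. Frames in which the front
has reached the droplet rim are masked out — beyond the rim the geometry,
not the growth kinetics, limits the extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import label, regionprops

from .io import ImageStack
from .locate import DropletGeometry, OnsetLocation, _noise_sigma

__all__ = [
    "FrontTrack",
    "track_front",
    "fit_velocity",
    "velocity_vs_supercooling",
]

UM_PER_S_TO_CM_PER_S = 1.0e-4


class TrackError(RuntimeError):
    """The stack does not contain a usable front track."""


@dataclass
class FrontTrack:
    """Per-frame radial extent of the frozen region from the onset point."""

    frame_index: np.ndarray
    time_s: np.ndarray
    extent_um: np.ndarray
    valid: np.ndarray  # False once the front touches the droplet rim

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def track_front(
    stack: ImageStack,
    onset: OnsetLocation,
    geometry: DropletGeometry,
    k_sigma: float = 5.0,
    area_min_px: int = 25,
    rim_margin: float = 0.97,
) -> FrontTrack:
    """Track the frozen region's maximal extent frame by frame.

    Segmentation thresholds each frame's absolute difference against the
    mean of the pre-onset frames at ``k_sigma`` times the noise level and
    keeps the largest connected changed component (isolated noise pixels
    would otherwise dominate a max-distance metric). A frame is valid
    while the frozen region stays clear of the rim (no frozen pixel beyond
    ``rim_margin`` of the droplet radius).

    Raises :class:`TrackError` when fewer than 3 valid frames remain.
    """
    rows, cols = np.mgrid[0 : stack.shape[0], 0 : stack.shape[1]]
    dist_center = np.hypot(rows - geometry.center[0], cols - geometry.center[1])
    inside = dist_center <= geometry.radius_px
    dist_onset = np.hypot(
        rows - onset.pixel_coords[0], cols - onset.pixel_coords[1]
    )

    sigma = _noise_sigma(stack, inside)
    thresh = max(k_sigma * sigma * np.sqrt(2.0), 4.0)
    ref = stack.frames[: onset.frame_index].astype(float).mean(axis=0)

    idx, extent, valid = [], [], []
    for i in range(onset.frame_index, len(stack)):
        changed = (np.abs(stack.frames[i].astype(float) - ref) > thresh) & inside
        if int(changed.sum()) < area_min_px:
            continue
        lab = label(changed)
        largest = max(regionprops(lab), key=lambda p: p.area)
        frozen = lab == largest.label
        d = dist_onset[frozen]
        idx.append(i)
        extent.append(float(d.max()) * stack.pixel_size)
        valid.append(bool(dist_center[frozen].max() < rim_margin * geometry.radius_px))
    track = FrontTrack(
        frame_index=np.asarray(idx, dtype=int),
        time_s=np.asarray(idx, dtype=float) / stack.frame_rate,
        extent_um=np.asarray(extent, dtype=float),
        valid=np.asarray(valid, dtype=bool),
    )
    if track.n_valid < 3:
        raise TrackError(
            f"track too short: {track.n_valid} valid frames (need >= 3)"
        )
    return track


def fit_velocity(track: FrontTrack) -> tuple[float, float]:
    """Front velocity in cm/s from an OLS fit of extent against time.

    Returns (velocity, standard error). Only frames where the front is
    still inside the rim enter the fit.
    """
    t = track.time_s[track.valid]
    x = track.extent_um[track.valid]
    if t.size < 3:
        raise TrackError(f"track too short: {t.size} valid frames (need >= 3)")
    if np.ptp(t) == 0:
        raise ValueError("degenerate track: zero-variance time axis")
    fit = stats.linregress(t, x)
    return fit.slope * UM_PER_S_TO_CM_PER_S, fit.stderr * UM_PER_S_TO_CM_PER_S


def velocity_vs_supercooling(velocities, delta_t) -> dict:
    """Monotone association between front velocity and supercooling.

    ``delta_t`` is the supercooling 0 degC minus the freezing temperature
    (strictly positive). Reports the Spearman rank correlation and an OLS
    slope; no functional form is asserted — faster growth at stronger
    supercooling is the only claim being quantified.
    """
    v = np.asarray(velocities, dtype=float)
    dt = np.asarray(delta_t, dtype=float)
    if v.size != dt.size or v.size < 3:
        raise ValueError("need >= 3 matched (velocity, supercooling) pairs")
    if np.any(dt <= 0):
        raise ValueError("supercooling must be positive (freezing below 0 degC)")
    rho, pval = stats.spearmanr(dt, v)
    fit = stats.linregress(dt, v)
    return {
        "n_pairs": int(v.size),
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "slope_cm_s_per_C": float(fit.slope),
        "slope_stderr": float(fit.stderr),
        "pairs": [[float(a), float(b)] for a, b in zip(dt, v)],
    }
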