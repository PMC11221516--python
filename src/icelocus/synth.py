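"""Synthetic freezing experiments with known ground truth.

Two generators stand in for the instrument:

* :func:`generate_onsets` draws tables of freezing events for a mixture of
  two mechanisms — *bulk* nucleation, uniform in the cylinder volume (so the
  normalized radius is ``sqrt(U)``), and *interfacial* (AWI) nucleation,
  confined to a thin shell just inside the rim — together with per-event
  freezing temperatures drawn around a sample T50.
* :func:`generate_video` renders an image stack of a pancake droplet
  (bright interior, dark rim = the projected AWI) in which a frozen region
  grows radially from a chosen onset point at a fixed front velocity.

Every generated object comes with a truth table that downstream code never
reads; only tests consume it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ImageStack

__all__ = [
    "MechanismParams",
    "VideoParams",
    "generate_onsets",
    "generate_video",
    "sample_onset_radii",
]

#: Conversion factor: 1 cm/s expressed in um/s.
CM_PER_S_TO_UM_PER_S = 1.0e4


@dataclass(frozen=True)
class MechanismParams:
    """Design of a simulated freezing-location experiment.

    Defaults mirror the assay design of 8 droplets frozen through 4
    freeze-thaw cycles each (32 events). ``p_awi`` is the probability that
    an individual onset is interfacial; interfacial onsets sit in a thin
    shell of width ``shell_width`` (in normalized radius) under the rim,
    because the assay cannot distinguish nucleation exactly at the interface
    from nucleation very close to it. Freezing temperatures are Gaussian
    around ``t50`` with spread ``t_sigma``; ``t_drift`` adds a deterministic
    per-cycle temperature trend (0 = a stable sample).
    """

    p_awi: float = 0.0
    shell_width: float = 0.02
    n_droplets: int = 8
    cycles_per_droplet: int = 4
    t50: float = -6.5
    t_sigma: float = 1.0
    t_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_awi <= 1.0:
            raise ValueError(f"p_awi must be in [0, 1], got {self.p_awi}")
        if not 0.0 < self.shell_width <= 0.2:
            raise ValueError(f"shell_width must be in (0, 0.2], got {self.shell_width}")
        if self.n_droplets < 1 or self.cycles_per_droplet < 1:
            raise ValueError("n_droplets and cycles_per_droplet must be >= 1")
        if self.t_sigma < 0:
            raise ValueError("t_sigma must be >= 0")

    @property
    def n_events(self) -> int:
        return self.n_droplets * self.cycles_per_droplet


def sample_onset_radii(
    n: int, p_awi: float, shell_width: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` normalized onset radii from the bulk/AWI mixture.

    Bulk radii are ``sqrt(U)`` with ``U`` uniform on [0, 1) — uniform in
    cylinder volume; AWI radii are uniform on ``[1 - shell_width, 1]``.
    Returns ``(r_norm, is_awi)``.
    """
    is_awi = rng.random(n) < p_awi
    r = np.sqrt(rng.random(n))
    r[is_awi] = 1.0 - shell_width * rng.random(int(is_awi.sum()))
    return r, is_awi


def generate_onsets(
    params: MechanismParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one freezing-location experiment.

    Returns
    -------
    records, truth
        ``records`` has columns ``droplet_id, cycle, r_norm, theta_rad,
        temp_C`` (one row per freezing event, the pipeline's input format);
        ``truth`` carries the same keys plus ``_truth`` columns with the
        generating mechanism. Reproducible: the same params (including seed)
        give byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    droplet_id = np.repeat(np.arange(1, params.n_droplets + 1), params.cycles_per_droplet)
    cycle = np.tile(np.arange(1, params.cycles_per_droplet + 1), params.n_droplets)

    r, is_awi = sample_onset_radii(n, params.p_awi, params.shell_width, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    temp = params.t50 + params.t_sigma * rng.standard_normal(n)
    temp = temp + params.t_drift * (cycle - 1)

    records = pd.DataFrame(
        {
            "droplet_id": droplet_id,
            "cycle": cycle,
            "r_norm": r,
            "theta_rad": theta,
            "temp_C": temp,
        }
    )
    truth = records.assign(
        r_norm_truth=r,
        theta_truth=theta,
        mechanism_truth=np.where(is_awi, "awi", "bulk"),
        temp_C_truth=temp,
    )
    return records, truth


@dataclass(frozen=True)
class VideoParams:
    """Rendering parameters for a synthetic freezing video.

    Physical defaults follow the instrument: 2100 frames per second,
    droplet radius 750 um (diameter ~1.5 mm), slide spacing 220 um. The
    synthetic frames are 8-bit grayscale: a bright droplet interior, a dark
    rim of width 3% of the radius marking the AWI, and Gaussian pixel noise.
    From ``onset_frame`` onward a frozen region grows radially from the
    onset point at ``front_velocity``; frozen pixels lose
    ``freeze_intensity_drop`` of their intensity.
    """

    frame_rate: float = 2100.0
    pixel_size: float = 7.5
    droplet_radius: float = 750.0
    slide_spacing: float = 220.0
    onset_r_norm: float = 0.9
    onset_theta: float = 0.0
    front_velocity: float = 5.9
    noise_sigma: float = 2.0
    n_frames: int = 40
    onset_frame: int = 5
    freeze_intensity_drop: float = 0.45
    dendrite_lobes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.front_velocity <= 0:
            raise ValueError("frame_rate and front_velocity must be positive")
        if not 0.0 <= self.onset_r_norm <= 1.0:
            raise ValueError("onset_r_norm must be in [0, 1]")
        if self.onset_frame < 1 or self.onset_frame >= self.n_frames:
            raise ValueError("need at least one pre-onset frame and one post-onset frame")
        if not 0.0 < self.freeze_intensity_drop <= 1.0:
            raise ValueError("freeze_intensity_drop must be in (0, 1]")

    @property
    def radius_px(self) -> float:
        return self.droplet_radius / self.pixel_size

    @property
    def advance_um_per_frame(self) -> float:
        """Front advance per frame in micrometers."""
        return self.front_velocity * CM_PER_S_TO_UM_PER_S / self.frame_rate


_INTERIOR, _RIM, _OUTSIDE = 220.0, 60.0, 150.0
_RIM_WIDTH_FRAC = 0.03  # rim width as a fraction of the droplet radius


def generate_video(params: VideoParams) -> tuple[ImageStack, pd.DataFrame]:
    """Render a synthetic freezing video with known onset and velocity.

    Returns the stack and a one-row truth table (onset location, onset
    frame, front velocity). The frozen region is a disk (or, with
    ``dendrite_lobes > 0``, a lobed star whose tips advance at the nominal
    velocity) centered at the onset point, clipped to the droplet interior.
    """
    rng = np.random.default_rng(params.seed)
    R = params.radius_px
    half = int(np.ceil(R * 1.12)) + 2
    size = 2 * half
    cr = cc = half - 0.5  # droplet center in pixel coordinates

    rows, cols = np.mgrid[0:size, 0:size]
    x = cols - cc
    y = -(rows - cr)  # +y up so theta is counterclockwise from +x
    dist_center = np.hypot(x, y)

    inside = dist_center <= R * (1.0 - _RIM_WIDTH_FRAC)
    rim = (dist_center > R * (1.0 - _RIM_WIDTH_FRAC)) & (dist_center <= R)
    base = np.full((size, size), _OUTSIDE)
    base[inside] = _INTERIOR
    base[rim] = _RIM

    onset_x = params.onset_r_norm * R * np.cos(params.onset_theta)
    onset_y = params.onset_r_norm * R * np.sin(params.onset_theta)
    onset_row = cr - onset_y
    onset_col = cc + onset_x
    dist_onset = np.hypot(x - onset_x, y - onset_y)

    adv_px = params.advance_um_per_frame / params.pixel_size
    if adv_px >= 2.0 * R:
        warnings.warn(
            "front crosses the whole droplet between consecutive frames; "
            "onset remains localizable only in the first changed frame",
            stacklevel=2,
        )

    if params.dendrite_lobes > 0:
        phi = np.arctan2(y - onset_y, x - onset_x)
        lobe_dir = rng.uniform(0.0, 2.0 * np.pi)
        profile = 0.6 + 0.4 * np.cos(params.dendrite_lobes * (phi - lobe_dir)) ** 2
    else:
        profile = 1.0

    frames = np.empty((params.n_frames, size, size), dtype=np.uint8)
    droplet = dist_center <= R
    for i in range(params.n_frames):
        img = base.copy()
        if i >= params.onset_frame:
            k = i - params.onset_frame
            front_px = k * adv_px
            frozen = (dist_onset <= np.maximum(front_px * profile, 1.5)) & droplet
            img[frozen] *= 1.0 - params.freeze_intensity_drop
        img += rng.normal(0.0, params.noise_sigma, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    stack = ImageStack(
        frames=frames, frame_rate=params.frame_rate, pixel_size=params.pixel_size
    )
    truth = pd.DataFrame(
        {
            "r_norm_truth": [params.onset_r_norm],
            "theta_truth": [params.onset_theta],
            "onset_frame_truth": [params.onset_frame],
            "front_velocity_truth": [params.front_velocity],
            "onset_row_truth": [onset_row],
            "onset_col_truth": [onset_col],
            "center_row_truth": [cr],
            "center_col_truth": [cc],
            "radius_px_truth": [R],
        }
    )
    return stack, truth
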