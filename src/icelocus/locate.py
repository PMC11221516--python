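"""Droplet-boundary fitting and freezing-onset localization.

The droplet's air-water interface projects as a dark circular rim in the
microscope's top view; fitting a circle to that rim gives the coordinate
frame in which every onset is expressed (radius normalized to 1, angle
counterclockwise from the +x image axis). Onset detection compares each
frame against a rolling pre-onset reference; the first frame whose changed
area inside the droplet exceeds a minimum is the onset frame, and the
centroid of its largest changed component is the onset point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import CircleModel, label, regionprops

from .io import ImageStack

__all__ = [
    "DetectionError",
    "OnsetNotFoundError",
    "DropletGeometry",
    "OnsetLocation",
    "fit_droplet_circle",
    "detect_onset",
]


class DetectionError(RuntimeError):
    """Image content does not support the requested detection."""


class OnsetNotFoundError(DetectionError):
    """No frame in the stack shows a freezing event."""


@dataclass(frozen=True)
class DropletGeometry:
    """Fitted droplet circle plus the physical scale of the assay."""

    center: tuple[float, float]  # (row, col) in pixels
    radius_px: float
    pixel_size: float  # um per pixel
    slide_spacing: float = 220.0  # um between the slides

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")

    @property
    def radius_um(self) -> float:
        return self.radius_px * self.pixel_size

    @property
    def volume_ul(self) -> float:
        """Cylinder volume pi * r^2 * h, converted from um^3 to uL."""
        return np.pi * self.radius_um**2 * self.slide_spacing * 1e-9

    def to_polar(self, row: float, col: float) -> tuple[float, float]:
        """Normalized polar coordinates of a pixel position.

        Theta is measured counterclockwise from the +x (column) axis, with
        the image's row axis pointing down, i.e. the usual math convention
        on the displayed image.
        """
        dx = col - self.center[1]
        dy = -(row - self.center[0])
        r_norm = float(np.hypot(dx, dy) / self.radius_px)
        theta = float(np.arctan2(dy, dx) % (2.0 * np.pi))
        return r_norm, theta


@dataclass(frozen=True)
class OnsetLocation:
    """A localized freezing onset in normalized polar coordinates."""

    frame_index: int
    r_norm: float
    theta_rad: float
    pixel_coords: tuple[float, float]  # (row, col)
    clamped: bool = False


def fit_droplet_circle(
    stack: ImageStack,
    slide_spacing: float = 220.0,
    dark_fraction: float = 0.25,
) -> DropletGeometry:
    """Fit a circle to the dark rim of the droplet in the first frame.

    Rim pixels are those darker than ``min + dark_fraction * (max - min)``
    of the first (pre-onset) frame; a total-least-squares circle fitted to
    them locates the center, and the droplet radius is taken as the outer
    edge of the dark band (99th percentile of rim-pixel distances) — the
    rim has finite width and the AWI is its outside. Raises
    :class:`DetectionError` when the frame has no usable dark-rim contrast
    (e.g. a uniform image).
    """
    img = stack.frames[0].astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 20.0:
        raise DetectionError("no dark rim found: first frame is near-uniform")
    dark = img < lo + dark_fraction * (hi - lo)
    rows, cols = np.nonzero(dark)
    if rows.size < 20:
        raise DetectionError("no dark rim found: too few dark pixels")
    model = CircleModel.from_estimate(np.column_stack([rows, cols]).astype(float))
    if not model:
        raise DetectionError("circle fit to rim pixels failed")
    cr, cc = model.center
    r = float(np.percentile(np.hypot(rows - cr, cols - cc), 99.0))
    h, w = stack.shape
    if r <= 0 or not (0 <= cr < h and 0 <= cc < w):
        raise DetectionError("fitted circle lies outside the frame")
    return DropletGeometry(
        center=(float(cr), float(cc)),
        radius_px=float(r),
        pixel_size=stack.pixel_size,
        slide_spacing=slide_spacing,
    )


def _noise_sigma(stack: ImageStack, inside: np.ndarray) -> float:
    """Per-pixel noise level from the first pre-onset frame pair."""
    if len(stack) < 2:
        raise DetectionError("need at least two frames to estimate noise")
    d = stack.frames[1].astype(float) - stack.frames[0].astype(float)
    return float(d[inside].std() / np.sqrt(2.0))


def detect_onset(
    stack: ImageStack,
    geometry: DropletGeometry,
    area_min_px: int = 25,
    k_sigma: float = 5.0,
) -> OnsetLocation:
    """Locate the first freezing event in a stack.

    Each frame is compared against a rolling average of the preceding
    unchanged frames; pixels whose absolute difference exceeds
    ``k_sigma`` times the estimated noise level count as changed. The onset
    frame is the first with at least ``area_min_px`` changed pixels inside
    the droplet; the onset point is the centroid of its largest changed
    connected component, reported in normalized polar coordinates
    (``r_norm > 1`` is clamped to 1 and flagged).
    """
    if area_min_px < 1:
        raise ValueError("area_min_px must be >= 1")
    rows, cols = np.mgrid[0 : stack.shape[0], 0 : stack.shape[1]]
    dist = np.hypot(rows - geometry.center[0], cols - geometry.center[1])
    inside = dist <= geometry.radius_px
    rim_band = (dist >= geometry.radius_px * 0.97) & inside

    sigma = _noise_sigma(stack, inside)
    # threshold the frame-minus-reference difference, whose noise is
    # sqrt(2) times the per-frame level
    thresh = max(k_sigma * sigma * np.sqrt(2.0), 4.0)

    ref = stack.frames[0].astype(float)
    for i in range(1, len(stack)):
        frame = stack.frames[i].astype(float)
        changed = (np.abs(frame - ref) > thresh) & inside
        if int(changed.sum()) >= area_min_px:
            lab = label(changed)
            props = max(regionprops(lab), key=lambda p: p.area)
            comp = lab == props.label
            if rim_band.any() and comp[rim_band].mean() > 0.5:
                warnings.warn(
                    "onset component covers most of the rim in its first "
                    "frame; the event may predate the stack",
                    stacklevel=2,
                )
            row_c, col_c = props.centroid
            r_norm, theta = geometry.to_polar(row_c, col_c)
            clamped = r_norm > 1.0
            return OnsetLocation(
                frame_index=i,
                r_norm=min(r_norm, 1.0),
                theta_rad=theta,
                pixel_coords=(float(row_c), float(col_c)),
                clamped=clamped,
            )
        # fold unchanged frames into the reference to track slow drifts
        ref = 0.5 * ref + 0.5 * frame
    raise OnsetNotFoundError(
        f"no onset detected: no frame changed by >= {area_min_px} px"
    )
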