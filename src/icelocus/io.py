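"""Image-stack container and on-disk format plumbing.

Stacks travel as multi-page grayscale TIFF (or a glob of numbered PNGs)
with a JSON sidecar ``{"frame_rate_fps": ..., "pixel_size_um": ...}``;
event tables travel as CSV with the header
``droplet_id,cycle,r_norm,theta_rad,temp_C``.
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_onsets_csv",
    "write_onsets_csv",
]

ONSET_COLUMNS = ["droplet_id", "cycle", "r_norm", "theta_rad", "temp_C"]


@dataclass
class ImageStack:
    """Ordered grayscale frames plus acquisition metadata.

    Attributes
    ----------
    frames
        Array of shape (n_frames, height, width), any integer or float dtype.
    frame_rate
        Acquisition rate in frames per second.
    pixel_size
        Physical size of one pixel in micrometers.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(len(self)) / self.frame_rate


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page 8-bit TIFF with a JSON metadata sidecar."""
    path = Path(path)
    frames = np.clip(stack.frames, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {"frame_rate_fps": stack.frame_rate, "pixel_size_um": stack.pixel_size}
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_stack(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF or a glob of PNG frames into an ImageStack.

    Metadata is taken from the ``<path>.json`` sidecar unless overridden
    explicitly. For PNG sequences the glob is sorted lexicographically and
    the sidecar sits next to the first frame.
    """
    path = Path(path)
    if any(ch in str(path) for ch in "*?["):
        files = sorted(_glob.glob(str(path)))
        if not files:
            raise FileNotFoundError(f"no frames match {path}")
        frames = np.stack([iio.imread(f) for f in files])
        sidecar = _sidecar_path(Path(files[0]))
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = _sidecar_path(path)
    if frames.ndim == 4:  # drop a color axis if present
        frames = frames.mean(axis=-1)
    if frame_rate is None or pixel_size is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"metadata sidecar {sidecar} not found and no explicit "
                "frame_rate/pixel_size given"
            )
        meta = json.loads(sidecar.read_text())
        frame_rate = frame_rate if frame_rate is not None else meta["frame_rate_fps"]
        pixel_size = pixel_size if pixel_size is not None else meta["pixel_size_um"]
    return ImageStack(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def write_onsets_csv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_onsets_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("r_norm",) if c not in df.columns]
    if missing:
        raise ValueError(f"onset CSV {path} lacks required columns: {missing}")
    return df
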