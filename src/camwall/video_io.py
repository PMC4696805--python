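"""Reading, writing and slicing grayscale video stacks.

Every analysis stage consumes a :class:`VideoStack` — an ordered stack of 8-bit
grayscale frames with a sampling rate — and most spectral operations consume a
:class:`PixelSeries`, the brightness of one pixel (or the mean over a line ROI)
across the stack.  Stacks are stored on disk as multi-page TIFF files or
directories of numbered PNG/TIFF frames; the frame rate, which neither format
carries natively, lives in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "VideoStack",
    "PixelSeries",
    "rgb_to_gray",
    "read_stack",
    "write_stack",
    "extract_line_series",
    "save_map_png",
    "save_map_csv",
    "save_histogram_csv",
]

#: ITU-R BT.601 luma weights.
_GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class PixelSeries:
    """Brightness of one location over time."""

    values: np.ndarray
    frame_rate_hz: float
    location: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("PixelSeries values must be one-dimensional")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.values)) / self.frame_rate_hz


@dataclass
class VideoStack:
    """T x H x W stack of 8-bit grayscale frames sampled at ``frame_rate_hz``."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if frames.shape[0] < 2:
            raise ValueError("a video stack needs at least two frames")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if frames.dtype != np.uint8:
            if frames.min() < 0 or frames.max() > 255:
                raise ValueError("gray levels must lie in [0, 255]")
            frames = np.round(frames).astype(np.uint8)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def pixel_series(self, row: int, col: int) -> PixelSeries:
        """Brightness time series of a single pixel."""
        h, w = self.frame_shape
        if not (0 <= row < h and 0 <= col < w):
            raise IndexError(f"pixel ({row}, {col}) outside {h}x{w} frame")
        return PixelSeries(
            self.frames[:, row, col].astype(float), self.frame_rate_hz, (row, col)
        )


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to 8-bit grayscale (BT.601 luma).

    gray = round(0.2989 R + 0.5870 G + 0.1140 B), clipped to [0, 255].
    A gray-replicated RGB input maps back onto its own gray plane.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB frame")
    gray = frame.astype(float) @ _GRAY_WEIGHTS
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def _as_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return rgb_to_gray(frame)
    return frame.astype(np.uint8)


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "metadata.json"
    return path.with_suffix(".json")


def write_stack(stack: VideoStack, path: str | Path) -> Path:
    """Write a stack as a multi-page 8-bit grayscale TIFF plus a JSON sidecar.

    The sidecar (``<stem>.json``) records the frame rate and pixel pitch so a
    write → read round trip is lossless, metadata included.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    meta = {"frame_rate_hz": stack.frame_rate_hz}
    if stack.pixel_pitch_um is not None:
        meta["pixel_pitch_um"] = stack.pixel_pitch_um
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_pitch_um: float | None = None,
) -> VideoStack:
    """Read a multi-page TIFF or a directory of numbered PNG/TIFF frames.

    RGB input is converted to grayscale.  The frame rate comes from the JSON
    sidecar unless overridden by ``frame_rate_hz``; without either, this is an
    error, because every analysis stage needs the sampling rate.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = [_as_gray(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
        data = np.stack(frames)
    else:
        data = tifffile.imread(path)
        if data.ndim == 4:  # pages of RGB frames
            data = np.stack([rgb_to_gray(f) for f in data])
        if data.ndim != 3:
            raise ValueError("expected a multi-page TIFF stack")
        data = data.astype(np.uint8)

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if rate is None:
        raise ValueError(
            f"no frame-rate metadata for {path}; pass frame_rate_hz explicitly"
        )
    pitch = pixel_pitch_um if pixel_pitch_um is not None else meta.get("pixel_pitch_um")
    return VideoStack(data, float(rate), pitch)


def extract_line_series(
    stack: VideoStack, p0: tuple[int, int], p1: tuple[int, int]
) -> PixelSeries:
    """Mean brightness over the Bresenham segment p0–p1, per frame.

    This is the line-ROI brightness plot used to find systolic and diastolic
    frames.  A degenerate segment (p0 == p1) reduces to that pixel's series.
    """
    from skimage.draw import line

    h, w = stack.frame_shape
    for r, c in (p0, p1):
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(f"endpoint ({r}, {c}) outside {h}x{w} frame")
    rr, cc = line(p0[0], p0[1], p1[0], p1[1])
    values = stack.frames[:, rr, cc].astype(float).mean(axis=1)
    return PixelSeries(values, stack.frame_rate_hz, p0)


def save_map_png(
    map2d: np.ndarray,
    path: str | Path,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    title: str | None = None,
    colorbar_label: str | None = None,
) -> Path:
    """Render a 2-D map as a false-color PNG (NaNs transparent)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.2), dpi=150)
    im = ax.imshow(map2d, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=colorbar_label)
    ax.set_xlabel("column (px)")
    ax.set_ylabel("row (px)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def save_map_csv(map2d: np.ndarray, path: str | Path) -> Path:
    """Lossless floating-point sidecar for a false-color map."""
    path = Path(path)
    np.savetxt(path, np.asarray(map2d, dtype=float), delimiter=",", fmt="%.10g")
    return path


def save_histogram_csv(table, path: str | Path) -> Path:
    """Write a phase histogram (bin_center_deg, count) to CSV."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
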